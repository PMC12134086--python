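# Methods

## The observation model

The package analyses longitudinal surveys of coral-dwelling gall crabs on
individually tagged host colonies. The atomic observation is the status of a
*dwelling* (the skeletal pit/tunnel/gall housing one crab) on one colony at
one time point: `not_yet_present`, `occupied`, `overgrown` (host tissue has
closed over the dwelling) or `empty_on_dead_skeleton` (the dwelling is
visible on dead coral). The two loss states are absorbing: there is no
evidence that gall crabs re-occupy vacant dwellings, so a transition out of
`overgrown` or `empty_on_dead_skeleton` is rejected as a data error rather
than interpreted. Colonies carry their own survival state (`alive`,
`dead_recent`, `dead_old`) plus health and fragmentation descriptors that do
not enter the rate calculations.

Comparing consecutive snapshots yields three event classes per transitional
period TR*t* (the interval T*t−1* → T*t*):

| event | observed transition |
|---|---|
| colonization | `not_yet_present` → `occupied` |
| extinction (background) | `occupied` → `overgrown` |
| host-mortality extinction | `occupied` → `empty_on_dead_skeleton`, or any occupied dwelling on a colony recorded dead |

Event counts obey the accounting identity
`D_curr = D_prev + C − E − HM` for every colony-transition; the rate builder
enforces it and refuses inconsistent inputs. Because surveys are snapshots
roughly six months apart, a colonization and extinction of the same dwelling
within one interval is unobservable; the model treats such pairs as absent.

## Rates

Turnover per colony-transition is `(E′ + C) / (D_prev + D_curr) × 100`.
By default `E′ = E + HM`: the event taxonomy defines two kinds of extinction
and the broad reading counts both. A flag (`include_hm=False`) restricts the
numerator to background extinctions for the narrower reading. A zero
denominator (no dwellings at either bounding time point) yields an
*undefined* value that is excluded from modelling — coercing it to zero
would inflate the zero-inflation mass artificially.

Background mortality is `E / D_prev × 100` and disturbance-based mortality
`HM / D_prev × 100`, both undefined when `D_prev = 0`. Under the
accounting precondition (`E + HM ≤ D_prev`) turnover is guaranteed to lie in
[0, 100] and the two mortality rates sum to at most 100.

The modelling set keeps colonies that were observed at every time point, or
at every time point up to and including full host mortality (mortality is a
natural outcome of the system, not missingness), and that hosted at least
one crab at some point during the study. Dropped colonies are reported with
a reason (`incomplete_series`, `never_inhabited`).

## Zero-one-inflated beta regression

Turnover proportions y ∈ [0, 1] show point masses at both boundaries. The
BEINF distribution used here is a three-part mixture: mass ν at 0, mass
(1 − ν)τ at 1, and density (1 − ν)(1 − τ)·Beta(y; a, b) on the interior,
with the mean/dispersion parameterization a = μ(1 − σ²)/σ²,
b = (1 − μ)(1 − σ²)/σ² (precision a + b falls as σ rises). ν is the
probability of a zero and τ the probability of a one *given* the value is
non-zero; under this conditional reading the cell probabilities always sum
to one for any ν, τ ∈ [0, 1], which is the only internally consistent way to
accommodate large estimates of both (e.g. ν near 0.9 together with τ near
0.5).

The regression puts a logit link on μ with site and time-period fixed
effects (baseline site configurable; first alphabetical level otherwise), a
logit link on σ, and intercept-only logits α₀, γ₀ on ν and τ. Because the
inflation components are intercept-only, their maximum-likelihood estimates
are the boundary-count proportions and the likelihood separates exactly; the
continuous beta block is maximized numerically — three-start BFGS on the
unconstrained (logit) scale, moment-based initial values, followed by a
damped Newton polish using central-difference gradients and a
finite-difference Hessian, driving the gradient to ~1e−10 so that the fit
agrees with an independent beta-MLE root-finder to 1e−6 when no boundary
values are present. Wald standard errors come from the numerical Hessian of
the joint log-likelihood (block-diagonal between the beta block and the two
Bernoulli intercepts). Data entirely on the boundaries leave the beta block
unidentified and raise a degenerate-fit error; non-convergence is flagged,
not raised.

## Permutation tests

Colony-level mortality rates are the permutation unit (rates are computed
per colony, so colony observations are the exchangeable draws; permuting
site means would discard sample size). Two procedures:

* **Two-sample (pre/post disturbance).** Statistic mean(post) − mean(pre);
  null by relabelling the pooled values. Transitional periods up to and
  including the disturbance time point count as "pre" (TR1–TR2 for a T2
  event), later ones as "post". Two-sided by default; the effect direction
  is reported separately.
* **Multi-sample (trend across periods).** ANOVA-numerator statistic
  Σ n_g (mean_g − grand mean)²; null by permuting period labels. The
  reported direction is the sign of the least-squares slope of period means
  against period order, so a significant result reads as an increasing or
  decreasing trend.

When the number of distinct relabellings is at most `exact_enumeration_limit`
(default 20 000) the null is enumerated exhaustively and p = hits/total with
the identity relabelling included — an exact rational. Otherwise `n_perm`
Monte-Carlo draws give the add-one estimate p = (hits + 1)/(n_perm + 1),
which cannot report zero. The pipeline runs both tests separately per site.

## Thermal stress

Daily means are calendar-day averages of the logger readings; days with
fewer than half the readings expected at the series' median interval are
flagged. Missing or flagged days are bridged by linear interpolation only
when the gap is at most 2 days — longer holes stay missing and every 84-day
window touching them is reported as missing rather than silently truncated.
The daily hotspot is the anomaly above the maximum monthly mean (MMM) when
it reaches at least 1 °C, else zero; Degree Heating Weeks are the rolling
84-day hotspot sum divided by 7 (°C-weeks), the NOAA convention — adopted
here because DHW levels of 4 and 8 °C-weeks are the standard bleaching and
mortality benchmarks the results are read against. MMM is an input constant
(default 30.9 °C, a central Red Sea climatological value; threshold
MMM + 1 = 31.9 °C), not recomputed from climatology. DHW is translation
invariant (shifting series and MMM together changes nothing) and monotone in
temperature; a constant anomaly a ≥ 1 °C held for a full window gives
exactly 12·a °C-weeks.

## Community statistics

Baseline surveys produce a community matrix of live host-colony counts per
(site, transect, time point) row and genus column. Analyses run on
Hellinger-transformed relative abundances (square root of row proportions),
whose rows have unit squared norm, making Euclidean distance well behaved
for composition data. PCA is a column-centred SVD with a fixed sign
convention (largest-magnitude loading per axis positive) for cross-platform
reproducibility.

PERMANOVA partitions the total sum of squared distances (via the
Gower-centred matrix) sequentially into site, transect-within-site, time
point and residual, so R² terms sum to one by construction. Euclidean
distance on Hellinger abundances keeps the test consistent with the
ordination. Pseudo-F for the site term uses the transect-within-site mean
square as its error term (the transect is the replicated unit under site);
the other terms use the residual. Permutations respect the nesting: site
labels permute across whole transect units, transect labels permute rows
within a site, time labels permute rows within a transect. One-way designs
additionally support exhaustive enumeration for small matrices.

SIMPER averages per-genus Bray–Curtis contributions
`|y_gj − y_gk| / Σ_g (y_gj + y_gk)` over all between-group row pairs on
untransformed relative abundances (the conventional SIMPER pairing), so the
per-genus contributions sum exactly to the mean between-group dissimilarity.
Hill numbers are N0 (richness), N1 = exp(−Σ p ln p) and N2 = 1/Σ p², with
N2 ≤ N1 ≤ N0 always.

## The synthetic-data generator

The generator emulates the monitored system so the whole chain is testable
offline: 4 sites (coded AS, AF, RR, SN, nearshore to offshore) × 3 permanent
belt transects × 43 tagged colonies (516 total), five semiannual time points
T0–T4, and a bleaching disturbance at T2 that switches host-mortality
probabilities from a "pre" to a "post" set (one switch; a single event).
Default parameters are fixed study conditions, chosen once as realistic for
this system:

| parameter | default | rationale |
|---|---|---|
| `p_initial_occupancy` | 0.25 | gall crabs typically inhabit ~20 % of hosts at reef scale; transect prevalences span ~16–43 % |
| `mean_initial_dwellings` | 2.0 | ≈270 dwellings across ≈130 inhabited of 516 colonies; drawn as 1 + Poisson(mean − 1) so inhabited colonies hold ≥ 1 crab |
| `colonization_intensity` | 4.0 / transect / transition | colonizations consistently exceed extinctions |
| `settlement_preference` ψ | 5.0 | strong preference for already-inhabited hosts; weight 1 + ψ·[inhabited] |
| `p_background_extinction` | 0.10 / dwelling / transition | overgrowth is common but secondary to host mortality |
| host mortality (full, pre → post) | AS 0.10→0.20, AF 0.02→0.12, RR 0.02→0.05, SN 0.03→0.08 | nearshore site chronically disturbed and hit hardest by bleaching |
| host mortality (partial, pre → post) | AS 0.08→0.18, AF 0.05→0.15, RR 0.04→0.12, SN 0.04→0.08 | partial mortality more frequent than whole-colony death |

Partial mortality kills ⌊U(0,1)·D⌋ dwellings (minimum 1 when triggered) —
the event class has no documented size distribution, so a uniform fraction
is the least-informative choice. Fully dead colonies stay in the tables
(state `dead_recent`, then `dead_old`) with no occupied dwellings, but are
excluded from further dynamics. Every stochastic event is appended to a
ground-truth log, which the event classifier must reproduce *exactly* — the
oracle-equivalence test that anchors the suite.

Temperature loggers are emulated as a sinusoidal annual cycle whose seasonal
maximum touches the MMM (early-September peak, amplitude 3 °C), plus a
triangular heatwave (linear rise and fall — the forcing shape is not the
object of study, only the DHW arithmetic downstream) and Gaussian noise, at
10- or 30-minute intervals.

What the generator does **not** emulate: larval dispersal and connectivity,
coral growth or shrinkage, observer error in dwelling counts, within-interval
birth–death pairs, and satellite SST. Passing tests therefore demonstrate
the correctness of the accounting, models and inference machinery under the
assumed generating process — not the field realism of any particular rate
estimate.

## Numerical and design choices

* Transitional periods are indexed TR1 = T0→T1 … TR4 = T3→T4; the "post"
  mortality era covers transitions ending after the disturbance time point.
* Undefined rates propagate as NaN in tables and are excluded from means;
  cell summaries report n, mean, and SE = sd/√n (NaN when n < 2).
* The BEINF optimizer clips μ and σ to (1e−12, 1 − 1e−12) inside the
  likelihood to avoid overflow at extreme linear predictors; multi-start
  jitter uses a fixed internal seed so fits are reproducible.
* Permutation and simulation randomness all flows from user-supplied seeds
  through `numpy.random.default_rng`; the pipeline derives stage seeds by
  fixed offsets, making end-to-end runs byte-identical under a fixed seed.
* Statistic comparisons in permutation tests use a 1e−12 absolute margin so
  ties are counted as "at least as extreme" despite float rounding.
* The suite's simulation sizes (50 replicate campaigns for the
  classification oracle, 100 pipeline replicates for the power check, 1000
  replicates for test calibration) are chosen to keep Monte-Carlo error
  well below the asserted tolerances while the whole suite stays fast.

## Known limitations

* ν and τ are intercept-only, as specified by the model equations; covariate
  effects on the inflation probabilities are out of scope.
* No random effects or model selection in the BEINF regression; transect is
  not a grouping level there.
* PERMANOVA assumes a crossed time factor and balanced-ish designs; heavily
  unbalanced designs keep a valid partition but the nested permutation
  scheme loses exchangeability guarantees.
* The pipeline reports per-site permutation p-values without multiplicity
  correction across sites.
* DHW is computed from supplied logger series only; no satellite retrieval
  or per-site MMM estimation.
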