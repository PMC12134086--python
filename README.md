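# crabfate

Fate-tracking analytics for coral-dwelling gall crab (Cryptochiridae)
populations.

Gall crabs are obligate symbionts that live in skeletal dwellings (pits,
tunnels, galls) of their host corals. Revisiting individually tagged host
colonies at successive survey time points ("fate-tracking") turns symbiont
demography into an observable process: new dwellings appear
(**colonization**), dwellings are overgrown by living host tissue
(**extinction**), or partial/full death of the host kills the crab and leaves
the empty dwelling on dead skeleton (**host-mortality-driven extinction**).
`crabfate` implements the full analysis chain for such campaigns — and a
synthetic-data generator that emulates the study design, so every stage is
testable without field data.

## What it computes

For colony *i* and transitional period *t* (the interval between consecutive
surveys), with dwelling counts `D_prev`, `D_curr` at the bounding time points
and event counts `C` (colonizations), `E` (extinctions), `HM` (host-mortality
extinctions):

* **Turnover** `= (E' + C) / (D_prev + D_curr) × 100`, with `E' = E + HM` by
  default (a flag restricts the numerator to background extinctions only);
  undefined — never coerced to zero — when the colony holds no dwellings at
  either time point.
* **Background mortality** `= E / D_prev × 100` and **disturbance-based
  mortality** `= HM / D_prev × 100`.
* **BEINF regression** — turnover proportions y ∈ [0, 1] pile up at exactly 0
  and 1, so they are modelled as zero-one-inflated beta:
  y ~ BEINF(μ, σ, ν, τ) with point mass ν at 0, mass (1 − ν)τ at 1, and a
  Beta(a, b) interior with a = μ(1 − σ²)/σ², b = (1 − μ)(1 − σ²)/σ²;
  logit(μ) = β₀ + β_site + β_time, logit(ν) = α₀, logit(τ) = γ₀; fitted by
  maximum likelihood with Wald standard errors from the numerical Hessian.
* **Permutation tests** — background-mortality trends across periods
  (between-group sum-of-squares statistic, period labels permuted) and
  pre/post-disturbance comparison of disturbance mortality (difference in
  means, pooled relabelling), with exact enumeration on small samples and
  add-one Monte-Carlo p-values otherwise.
* **Thermal stress** — daily means from logger series, hotspots (anomalies
  ≥ 1 °C above the maximum monthly mean), and Degree Heating Weeks as the
  rolling 84-day hotspot sum / 7, with the bleaching threshold at MMM + 1 °C.
* **Community statistics** — Hellinger-transformed host relative abundances,
  PCA ordination, PERMANOVA with transect nested within site (sequential
  distance-based partition; permutations respect the nesting), SIMPER
  decomposition of Bray–Curtis dissimilarity, and Hill diversity
  (N0 richness, N1 = exp(Shannon), N2 = inverse Simpson).

## Worked example

```python
from crabfate import (SimulationConfig, simulate_fate_tracking, filter_analysis_set,
                      compute_transition_rates, fit_beinf, two_sample_perm_test,
                      PermTestConfig, pre_post_split)

config = SimulationConfig(seed=1)            # 4 sites x 3 transects x 43 colonies
dataset = simulate_fate_tracking(config)

colonies, dwellings, report = filter_analysis_set(
    dataset.colony_table, dataset.dwelling_table)
rates = compute_transition_rates(colonies, dwellings)
print(f"analysis set: {report['kept'].sum()} of {len(report)} colonies")

turnover = rates.dropna(subset=["turnover_pct"])
fit = fit_beinf(turnover["turnover_pct"] / 100.0,
                site=turnover["site"], time_point=turnover["transition"],
                baseline_site="AS")
p = fit.params
print(f"BEINF fit: nu={p.nu:.3f} sigma={p.sigma:.3f} tau={p.tau:.3f}")

site_as = rates[rates["site"] == "AS"]
pre, post, _ = pre_post_split(site_as, disturbance_time_point=2)
res = two_sample_perm_test(pre, post, PermTestConfig(n_perm=9999, seed=1))
print(f"AS disturbance mortality pre vs post: stat={res.observed_stat:.2f}, "
      f"p={res.p_value:.4f}")
```

Output:

```
analysis set: 186 of 516 colonies
BEINF fit: nu=0.476 sigma=0.239 tau=0.403
AS disturbance mortality pre vs post: stat=6.42, p=0.2385
```

Reading: of 516 tagged colonies, 186 were inhabited at least once and
observed across the whole study (or until host mortality), the spec for the
modelling set. Roughly half the colony-period turnover values are exactly
zero (ν ≈ 0.48: nothing changed on those colonies), and among non-zero
values 40% are complete replacement (τ ≈ 0.40). The pre/post comparison of
disturbance mortality at site AS is positive (higher after the event) but
not significant under this seed's simulated mortality regime.

## Command line

```bash
crabfate simulate --out run/ --seed 1          # synthetic survey tables
crabfate validate --colonies run/colonies.csv --dwellings run/dwellings.csv
crabfate rates --colonies run/colonies.csv --dwellings run/dwellings.csv --out run/
crabfate fit-beinf --input run/transition_rates.csv --baseline-site AS
crabfate perm-test --input run/transition_rates.csv --rate disturbance --n-perm 9999
crabfate community --input run/colonies.csv --time-points 1,3 --out run/community
crabfate thermal --input run/temperature_AS.csv --mmm 30.9 --out run/
crabfate run-all --out run/ --seed 1           # everything, with report.json
```

Exit codes: 0 success, 1 validation error, 2 runtime error.

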