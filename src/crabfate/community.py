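"""Baseline host-community statistics.

Operates on a community matrix of host-colony counts per (site, transect,
time point) row and coral genus column, derived from the baseline belt
transect surveys.  Provides the Hellinger transform, PCA ordination, a
distance-based PERMANOVA with transect nested within site, SIMPER
decomposition of Bray-Curtis dissimilarity, and Hill-number diversity
(N0 richness, N1 = exp(Shannon), N2 = inverse Simpson).

The PERMANOVA partitions the total sum of squared distances sequentially into
site, transect-within-site, time point and residual via projections on the
Gower-centered distance matrix, so the R-squared terms always sum to one.
Permutations respect the nesting: the site term permutes site labels across
whole transect units, the nested transect term permutes rows within sites,
and the time term permutes rows within transects.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import factorial
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError

INDEX_COLS = ["site", "transect", "time_point"]


def build_community_matrix(
    colonies: pd.DataFrame, time_points: Sequence[int] = (1, 3)
) -> pd.DataFrame:
    """Host-colony counts per (site, transect, time_point) row and genus column.

    Only live colonies enter the community composition.
    """
    sub = colonies[
        colonies["time_point"].isin(list(time_points))
        & (colonies["mortality_state"] == "alive")
    ]
    counts = (
        sub.groupby(INDEX_COLS + ["genus"]).size().unstack(fill_value=0).sort_index()
    )
    counts.columns.name = "genus"
    return counts


def to_relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    sums = counts.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValidationError(f"all-zero community row(s): {list(zero.index)}")
    return counts.div(sums, axis=0)


def hellinger(counts: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform: square root of row-relative abundances.

    Rows of the result have unit squared norm, which makes Euclidean distances
    between them ecologically well behaved (no double-zero inflation).
    """
    return np.sqrt(to_relative_abundance(counts))


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained: np.ndarray  # variance-explained ratios, summing to 1

    def to_frame(self) -> pd.DataFrame:
        return self.scores


def pca(matrix: pd.DataFrame) -> PCAResult:
    """Column-centered PCA via singular value decomposition.

    Sign convention: the largest-magnitude loading of each axis is positive,
    making ordinations reproducible across platforms.
    """
    if len(matrix) < 2:
        raise ValidationError("PCA needs at least two rows")
    X = matrix.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0.0):
        raise ValidationError("community matrix has zero total variance")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # fix signs: largest-|loading| positive per axis
    for k in range(len(s)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * s
    var = s**2
    explained = var / var.sum()
    axes = [f"PC{i + 1}" for i in range(len(s))]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=axes),
        loadings=pd.DataFrame(Vt.T, index=matrix.columns, columns=axes),
        explained=explained,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    terms: dict  # term -> {ss, df, r2, pseudo_f, p}
    total_ss: float
    n_perm: int
    exact: bool = False

    def to_dict(self) -> dict:
        return {
            "terms": {
                t: {k: (None if v is None else float(v)) for k, v in d.items()}
                for t, d in self.terms.items()
            },
            "total_ss": float(self.total_ss),
            "n_perm": int(self.n_perm),
            "exact": bool(self.exact),
        }


def euclidean_distance(matrix: pd.DataFrame) -> np.ndarray:
    X = matrix.to_numpy(dtype=float)
    sq = (X**2).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * X @ X.T, 0.0)
    d = np.sqrt(d2)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def _gower_center(dist: np.ndarray) -> np.ndarray:
    n = dist.shape[0]
    A = -0.5 * dist**2
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def _proj(X: np.ndarray) -> np.ndarray:
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    r = int((s > s[0] * 1e-10).sum()) if len(s) else 0
    Ur = U[:, :r]
    return Ur @ Ur.T


def _dummies(labels: np.ndarray) -> np.ndarray:
    levels = sorted(set(labels))
    return np.column_stack([(labels == lev).astype(float) for lev in levels])


def _sequential_ss(
    G: np.ndarray,
    site: np.ndarray,
    transect: np.ndarray | None,
    time_point: np.ndarray | None,
) -> dict[str, tuple[float, int]]:
    """Sequential (Type-I) sums of squares and dfs for the nested design."""
    n = G.shape[0]
    total = float(np.trace(G))
    blocks: list[tuple[str, np.ndarray, int]] = []
    X = np.ones((n, 1))
    k_site = len(set(site))
    blocks.append(("site", _dummies(site), k_site - 1))
    if transect is not None:
        units = np.array([f"{s}||{t}" for s, t in zip(site, transect)])
        k_units = len(set(units))
        blocks.append(("transect_within_site", _dummies(units), k_units - k_site))
    if time_point is not None:
        k_time = len(set(time_point))
        blocks.append(("time_point", _dummies(np.asarray(time_point)), k_time - 1))

    out: dict[str, tuple[float, int]] = {}
    prev_tr = 0.0
    model_df = 0
    for name, dummies, df in blocks:
        X = np.column_stack([X, dummies])
        tr = float(np.trace(_proj(X) @ G))
        out[name] = (tr - prev_tr, df)
        prev_tr = tr
        model_df += df
    out["residual"] = (total - prev_tr, n - 1 - model_df)
    return out


def _f_stats(ss: dict[str, tuple[float, int]], nested: bool) -> dict[str, float]:
    """Pseudo-F per term; site is tested against the nested transect term."""
    res_ss, res_df = ss["residual"]
    ms_res = res_ss / res_df if res_df > 0 else np.nan
    out: dict[str, float] = {}
    for term, (s, df) in ss.items():
        if term == "residual":
            continue
        ms = s / df if df > 0 else np.nan
        if term == "site" and nested:
            e_ss, e_df = ss["transect_within_site"]
            ms_err = e_ss / e_df if e_df > 0 else np.nan
        else:
            ms_err = ms_res
        out[term] = ms / ms_err if ms_err and np.isfinite(ms_err) else np.nan
    return out


def permanova(
    dist: np.ndarray,
    site: Sequence,
    transect: Sequence | None = None,
    time_point: Sequence | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> PermanovaResult:
    """Distance-based PERMANOVA with transect nested within site.

    ``dist`` is a symmetric pairwise distance matrix with zero diagonal
    (Euclidean distance on Hellinger-transformed abundances in this package's
    pipeline).  p-values are permutational with the add-one correction, each
    term permuted at the exchangeable level of the design:

    * site — site labels permuted across whole transect units (rows move in
      transect blocks), tested against the transect-within-site mean square;
    * transect_within_site — rows permuted within each site;
    * time_point — rows permuted within each transect.

    ``exact=True`` enumerates all row permutations for the site term of a
    one-way design (no transect/time factors), feasible for tiny matrices;
    the exact p then counts the identity permutation (p = hits / n!).
    """
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.shape != (n, n) or not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    site = np.asarray([str(s) for s in site])
    if len(site) != n:
        raise ValidationError("site labels must match distance matrix rows")
    transect_arr = None if transect is None else np.asarray([str(t) for t in transect])
    time_arr = None if time_point is None else np.asarray([str(t) for t in time_point])
    _check_dfs(n, site, transect_arr, time_arr)

    G = _gower_center(dist)
    nested = transect_arr is not None
    ss = _sequential_ss(G, site, transect_arr, time_arr)
    total = float(np.trace(G))
    f_obs = _f_stats(ss, nested)

    rng = np.random.default_rng(seed)
    terms: dict[str, dict] = {}

    if exact:
        if nested or time_arr is not None:
            raise ValidationError("exact enumeration supported for one-way designs only")
        total_perms = factorial(n)
        hits = 0
        for perm in itertools.permutations(range(n)):
            s_perm = site[list(perm)]
            f_p = _f_stats(_sequential_ss(G, s_perm, None, None), False)["site"]
            if f_p >= f_obs["site"] - 1e-12:
                hits += 1
        p_site = hits / total_perms
        terms["site"] = _term_entry(ss, total, "site", f_obs["site"], p_site)
        terms["residual"] = _term_entry(ss, total, "residual", None, None)
        return PermanovaResult(terms, total, total_perms, exact=True)

    counts = {t: 0 for t in f_obs}
    for _ in range(n_perm):
        # site: permute site labels over transect units (or rows if one-way)
        if nested:
            units = np.array([f"{s}||{t}" for s, t in zip(site, transect_arr)])
            uniq = sorted(set(units))
            unit_site = {u: u.split("||")[0] for u in uniq}
            perm_sites = rng.permutation([unit_site[u] for u in uniq])
            site_map = dict(zip(uniq, perm_sites))
            s_perm = np.array([site_map[u] for u in units])
            f_site = _f_stats(_sequential_ss(G, s_perm, transect_arr, time_arr), True)["site"]
        else:
            s_perm = rng.permutation(site)
            f_site = _f_stats(_sequential_ss(G, s_perm, None, time_arr), False)["site"]
        if f_site >= f_obs["site"] - 1e-12:
            counts["site"] += 1

        if nested:
            # transect: permute rows within each site
            tr_perm = transect_arr.copy()
            for s_lev in sorted(set(site)):
                mask = site == s_lev
                tr_perm[mask] = rng.permutation(transect_arr[mask])
            f_tr = _f_stats(_sequential_ss(G, site, tr_perm, time_arr), True)[
                "transect_within_site"
            ]
            if f_tr >= f_obs["transect_within_site"] - 1e-12:
                counts["transect_within_site"] += 1

        if time_arr is not None:
            tp_perm = time_arr.copy()
            groups = transect_arr if nested else site
            for g in sorted(set(groups)):
                mask = groups == g
                tp_perm[mask] = rng.permutation(time_arr[mask])
            f_tp = _f_stats(_sequential_ss(G, site, transect_arr, tp_perm), nested)[
                "time_point"
            ]
            if f_tp >= f_obs["time_point"] - 1e-12:
                counts["time_point"] += 1

    for term in ss:
        if term == "residual":
            terms[term] = _term_entry(ss, total, term, None, None)
        else:
            p = (counts[term] + 1) / (n_perm + 1)
            terms[term] = _term_entry(ss, total, term, f_obs[term], p)
    return PermanovaResult(terms, total, n_perm, exact=False)


def _term_entry(ss, total, term, f, p) -> dict:
    s, df = ss[term]
    return {
        "ss": s,
        "df": df,
        "r2": s / total if total > 0 else np.nan,
        "pseudo_f": f,
        "p": p,
    }


def _check_dfs(n, site, transect, time_point) -> None:
    def _single_row_levels(labels):
        vals, counts = np.unique(labels, return_counts=True)
        return [v for v, c in zip(vals, counts) if c < 2]

    bad = _single_row_levels(site)
    if bad:
        raise ValidationError(f"site level(s) with a single row: {bad} (no degrees of freedom)")
    if len(set(site)) < 2:
        raise ValidationError("need at least two site levels")
    model_df = len(set(site)) - 1
    if transect is not None:
        units = {f"{s}||{t}" for s, t in zip(site, transect)}
        model_df += len(units) - len(set(site))
    if time_point is not None:
        model_df += len(set(time_point)) - 1
    if n - 1 - model_df <= 0:
        raise ValidationError("no residual degrees of freedom for this design")


# ---------------------------------------------------------------------------
# SIMPER


@dataclass
class SimperResult:
    table: pd.DataFrame  # per genus: average_contribution, contribution_pct, cumulative_pct
    mean_dissimilarity: float

    def to_frame(self) -> pd.DataFrame:
        return self.table


def bray_curtis(u: np.ndarray, v: np.ndarray) -> float:
    denom = float((u + v).sum())
    return float(np.abs(u - v).sum() / denom) if denom > 0 else 0.0


def simper(relabund: pd.DataFrame, groups: Sequence) -> SimperResult:
    """SIMPER: per-genus contributions to between-group Bray-Curtis dissimilarity.

    For every pair of rows from different groups, the per-genus contribution
    is ``|y_gj - y_gk| / sum_g (y_gj + y_gk)``; contributions are averaged
    over all between-group pairs and ranked descending, so they sum exactly
    to the mean between-group dissimilarity.
    """
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != len(relabund):
        raise ValidationError("groups must match matrix rows")
    if len(set(groups)) < 2:
        raise ValidationError("SIMPER needs at least two groups")
    X = relabund.to_numpy(dtype=float)
    contrib = np.zeros(X.shape[1])
    n_pairs = 0
    levels = sorted(set(groups))
    for g1, g2 in itertools.combinations(levels, 2):
        for j in np.flatnonzero(groups == g1):
            for k in np.flatnonzero(groups == g2):
                denom = float((X[j] + X[k]).sum())
                if denom > 0:
                    contrib += np.abs(X[j] - X[k]) / denom
                n_pairs += 1
    contrib /= n_pairs
    mean_diss = float(contrib.sum())
    pct = contrib / mean_diss * 100.0 if mean_diss > 0 else np.zeros_like(contrib)
    table = pd.DataFrame(
        {
            "average_contribution": contrib,
            "contribution_pct": pct,
        },
        index=relabund.columns,
    ).sort_values("average_contribution", ascending=False, kind="stable")
    table["cumulative_pct"] = table["contribution_pct"].cumsum()
    table.index.name = "genus"
    return SimperResult(table, mean_diss)


# ---------------------------------------------------------------------------
# Hill numbers


@dataclass
class DiversityResult:
    N0: float  # genus richness
    N1: float  # exponential Shannon
    N2: float  # inverse Simpson

    def to_dict(self) -> dict:
        return {"N0": float(self.N0), "N1": float(self.N1), "N2": float(self.N2)}


def hill_numbers(counts: Sequence[float]) -> DiversityResult:
    """Hill diversity: N0 richness, N1 = exp(Shannon), N2 = inverse Simpson."""
    c = np.asarray(list(counts), dtype=float)
    if (c < 0).any():
        raise ValidationError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValidationError("counts sum to zero")
    p = c[c > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    return DiversityResult(
        N0=float(len(p)),
        N1=float(np.exp(shannon)),
        N2=float(1.0 / (p**2).sum()),
    )


def diversity_by_row(counts: pd.DataFrame) -> pd.DataFrame:
    """Hill numbers for every community row."""
    rows = [hill_numbers(counts.loc[idx].to_numpy()).to_dict() for idx in counts.index]
    return pd.DataFrame(rows, index=counts.index)
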