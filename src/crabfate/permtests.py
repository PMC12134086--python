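"""Permutation tests for mortality-rate comparisons.

Colony-level mortality rates are few, bounded, and far from normal, so
pre/post-disturbance differences and multi-period trends are tested by
permuting colony-level observations:

* two-sample test — statistic ``mean(b) - mean(a)``, null built by random
  relabelling of the pooled values (used for disturbance-based mortality,
  pooling transitional periods before vs. after the bleaching event);
* multi-sample test — ANOVA-numerator statistic (between-group sum of squares
  of group means weighted by group size), null by permuting period labels
  (used for background-mortality trends across transitional periods), with
  the direction of the trend reported as the sign of the least-squares slope
  of group means against period order.

Small problems are solved by exact enumeration of all relabellings
(p = hits / total, the identity relabelling included); larger ones by Monte
Carlo with the add-one correction p = (hits + 1) / (n_perm + 1), which can
never report p = 0.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, factorial
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

_EPS = 1e-12  # float-safety margin when comparing permuted to observed statistics

ALTERNATIVES = ("two_sided", "less", "greater")


@dataclass
class PermTestConfig:
    n_perm: int = 9999
    seed: int | None = None
    alternative: str = "two_sided"
    exact_enumeration_limit: int = 20000

    def __post_init__(self) -> None:
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")
        if self.alternative not in ALTERNATIVES:
            raise ValueError(f"alternative must be one of {ALTERNATIVES}")


@dataclass
class PermTestResult:
    observed_stat: float
    p_value: float
    n_perm_used: int
    exact: bool
    direction: int  # sign of the effect (two-sample: mean(b)-mean(a); multi: slope)

    def to_dict(self) -> dict:
        return {
            "observed_stat": float(self.observed_stat),
            "p_value": float(self.p_value),
            "n_perm_used": int(self.n_perm_used),
            "exact": bool(self.exact),
            "direction": int(self.direction),
        }


def _as_array(x, name: str) -> np.ndarray:
    arr = np.asarray(list(x), dtype=float)
    if arr.size == 0:
        raise ValueError(f"sample {name!r} is empty")
    return arr


# ---------------------------------------------------------------------------
# Two-sample test


def two_sample_perm_test(
    a: Sequence[float], b: Sequence[float], config: PermTestConfig | None = None
) -> PermTestResult:
    """Permutation test of a difference in means between two samples.

    The statistic is ``mean(b) - mean(a)``.  When the number of relabellings
    C(n_a + n_b, n_a) does not exceed the configured limit the null is
    enumerated exactly; otherwise ``n_perm`` random relabellings are drawn.
    """
    cfg = config or PermTestConfig()
    a = _as_array(a, "a")
    b = _as_array(b, "b")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    n = na + nb
    obs = float(b.mean() - a.mean())
    direction = int(np.sign(obs))

    def _count(stats: np.ndarray) -> int:
        if cfg.alternative == "two_sided":
            return int((np.abs(stats) >= abs(obs) - _EPS).sum())
        if cfg.alternative == "greater":
            return int((stats >= obs - _EPS).sum())
        return int((stats <= obs + _EPS).sum())

    total = comb(n, na)
    if total <= cfg.exact_enumeration_limit:
        idx = np.fromiter(
            (i for combo in itertools.combinations(range(n), na) for i in combo),
            dtype=np.intp,
        ).reshape(total, na)
        sum_a = pooled[idx].sum(axis=1)
        stats = (pooled.sum() - sum_a) / nb - sum_a / na
        return PermTestResult(obs, _count(stats) / total, total, True, direction)

    rng = np.random.default_rng(cfg.seed)
    order = np.argsort(rng.random((cfg.n_perm, n)), axis=1)
    perm = pooled[order]
    stats = perm[:, na:].mean(axis=1) - perm[:, :na].mean(axis=1)
    p = (_count(stats) + 1) / (cfg.n_perm + 1)
    return PermTestResult(obs, p, cfg.n_perm, False, direction)


# ---------------------------------------------------------------------------
# Multi-sample test


def _between_group_ss(pooled: np.ndarray, sizes: Sequence[int]) -> float:
    grand = pooled.mean()
    ss = 0.0
    start = 0
    for sz in sizes:
        m = pooled[start : start + sz].mean()
        ss += sz * (m - grand) ** 2
        start += sz
    return float(ss)


def _multiset_assignments(n: int, sizes: Sequence[int]) -> Iterator[np.ndarray]:
    """Yield index orderings that realize every distinct group assignment."""
    indices = list(range(n))

    def rec(remaining: list[int], sizes_left: Sequence[int]):
        if not sizes_left:
            yield []
            return
        k = sizes_left[0]
        for combo in itertools.combinations(remaining, k):
            rest = [i for i in remaining if i not in combo]
            for tail in rec(rest, sizes_left[1:]):
                yield list(combo) + tail

    for order in rec(indices, list(sizes)):
        yield np.asarray(order, dtype=np.intp)


def n_assignments(sizes: Sequence[int]) -> int:
    n = sum(sizes)
    total = factorial(n)
    for sz in sizes:
        total //= factorial(sz)
    return total


def multi_sample_perm_test(
    groups: Mapping[object, Sequence[float]], config: PermTestConfig | None = None
) -> PermTestResult:
    """Permutation test of equality of means across ordered groups.

    ``groups`` maps transitional-period keys (ordered by sorted key) to
    colony-level rates.  The statistic is the between-group sum of squares of
    group means weighted by group size; the reported direction is the sign of
    the least-squares slope of group means against period order, so a
    significant result can be read as an increasing or decreasing trend.
    """
    cfg = config or PermTestConfig()
    keys = sorted(groups.keys(), key=lambda k: str(k))
    arrays = [_as_array(groups[k], str(k)) for k in keys]
    if len(arrays) < 2:
        raise ValueError("need at least two non-empty groups")
    sizes = [len(arr) for arr in arrays]
    pooled = np.concatenate(arrays)
    obs = _between_group_ss(pooled, sizes)

    means = np.array([arr.mean() for arr in arrays])
    order_idx = np.arange(len(keys), dtype=float)
    slope = np.polyfit(order_idx, means, 1)[0] if len(keys) > 1 else 0.0
    direction = int(np.sign(slope)) if abs(slope) > _EPS else 0

    total = n_assignments(sizes)
    if total <= cfg.exact_enumeration_limit:
        hits = 0
        for order in _multiset_assignments(len(pooled), sizes):
            if _between_group_ss(pooled[order], sizes) >= obs - _EPS:
                hits += 1
        return PermTestResult(obs, hits / total, total, True, direction)

    rng = np.random.default_rng(cfg.seed)
    hits = 0
    for _ in range(cfg.n_perm):
        perm = rng.permutation(pooled)
        if _between_group_ss(perm, sizes) >= obs - _EPS:
            hits += 1
    p = (hits + 1) / (cfg.n_perm + 1)
    return PermTestResult(obs, p, cfg.n_perm, False, direction)


# ---------------------------------------------------------------------------
# Pre/post split and site-wise drivers


def pre_post_split(
    rates: pd.DataFrame,
    disturbance_time_point: int = 2,
    value_col: str = "disturbance_mortality_pct",
) -> tuple[np.ndarray, np.ndarray, int]:
    """Partition colony-level rates into pre- and post-disturbance pools.

    Transitional periods up to and including the disturbance time point are
    "pre" (TR1, TR2 for a T2 event), later ones "post" (TR3, TR4).  Undefined
    (NaN) rates are excluded; their count is returned alongside.
    """
    vals = rates[[value_col, "transition"]]
    n_undefined = int(vals[value_col].isna().sum())
    defined = vals.dropna(subset=[value_col])
    pre = defined.loc[defined["transition"] <= disturbance_time_point, value_col]
    post = defined.loc[defined["transition"] > disturbance_time_point, value_col]
    return pre.to_numpy(), post.to_numpy(), n_undefined


def run_mortality_perm_tests(
    rates: pd.DataFrame,
    disturbance_time_point: int = 2,
    config: PermTestConfig | None = None,
) -> dict:
    """Per-site permutation tests matching the fate-tracking report layout.

    For each site: a multi-sample test of background mortality across
    transitional periods (trend over time) and a two-sample pre/post test of
    disturbance-based mortality.  Sites where a test is infeasible (an empty
    pool on either side) report the reason instead of a result.
    """
    cfg = config or PermTestConfig()
    out: dict = {}
    for site, group in rates.groupby("site", sort=True):
        site_res: dict = {}
        bg = {
            tr: sub["background_mortality_pct"].dropna().to_numpy()
            for tr, sub in group.groupby("transition", sort=True)
        }
        bg = {tr: v for tr, v in bg.items() if len(v)}
        if len(bg) >= 2:
            site_res["background_trend"] = multi_sample_perm_test(bg, cfg).to_dict()
        else:
            site_res["background_trend"] = {"skipped": "fewer than two periods with data"}
        pre, post, n_undef = pre_post_split(
            group, disturbance_time_point, "disturbance_mortality_pct"
        )
        if len(pre) and len(post):
            res = two_sample_perm_test(pre, post, cfg).to_dict()
            res["n_pre"], res["n_post"], res["n_undefined"] = len(pre), len(post), n_undef
            site_res["disturbance_pre_post"] = res
        else:
            site_res["disturbance_pre_post"] = {
                "skipped": "empty pre or post pool",
                "n_pre": int(len(pre)),
                "n_post": int(len(post)),
            }
        out[site] = site_res
    return out
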