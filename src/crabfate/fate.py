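"""Fate-tracking of coral-dwelling gall crabs.

Longitudinal surveys revisit individually tagged host colonies at successive
time points (T0, T1, ...) and record the status of every crab dwelling on each
colony.  Comparing consecutive snapshots yields three event classes:

* ``colonization`` — a new occupied dwelling appears on the host surface;
* ``extinction`` — a dwelling is overgrown by living host tissue (the crab is
  lost while the host survives, i.e. background loss);
* ``host_mortality_extinction`` — partial or full death of the host colony
  kills the crab, leaving the empty dwelling visible on dead skeleton.

From per-colony event counts this module derives turnover

    turnover = (extinctions + colonizations)
               / (dwellings at previous tp + dwellings at current tp) * 100

and the two mortality rates (background and disturbance-based), each expressed
as crabs lost per crab present at the previous time point, in percent.

Intervals between consecutive time points are called transitional periods and
indexed TR1 = T0→T1, TR2 = T1→T2, etc.; an event at transition ``t`` happened
between T(t-1) and T(t).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DataInconsistencyError,
    UndefinedValueError,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Vocabulary

OCCUPIED = "occupied"
OVERGROWN = "overgrown"
EMPTY_ON_DEAD = "empty_on_dead_skeleton"
NOT_YET_PRESENT = "not_yet_present"
DWELLING_STATUSES = (OCCUPIED, OVERGROWN, EMPTY_ON_DEAD, NOT_YET_PRESENT)

ALIVE = "alive"
DEAD_RECENT = "dead_recent"
DEAD_OLD = "dead_old"
MORTALITY_STATES = (ALIVE, DEAD_RECENT, DEAD_OLD)
DEAD_STATES = frozenset({DEAD_RECENT, DEAD_OLD})

COLONIZATION = "colonization"
EXTINCTION = "extinction"
HOST_MORTALITY = "host_mortality_extinction"
EVENT_TYPES = (COLONIZATION, EXTINCTION, HOST_MORTALITY)

HEALTH_STATES = (
    "healthy",
    "paling",
    "partially_bleached",
    "fully_bleached",
    "fluorescent",
    "partial_fresh_mortality",
)
FRAGMENT_CLASSES = ("none", "small", "medium", "large", "mixed")

# overgrown and empty_on_dead_skeleton are absorbing; re-occupation of vacant
# dwellings is excluded (no evidence cryptochirids recolonize empty dwellings)
_ALLOWED_NEXT = {
    NOT_YET_PRESENT: {NOT_YET_PRESENT, OCCUPIED},
    OCCUPIED: {OCCUPIED, OVERGROWN, EMPTY_ON_DEAD},
    OVERGROWN: {OVERGROWN},
    EMPTY_ON_DEAD: {EMPTY_ON_DEAD},
}

COLONY_COLUMNS = [
    "colony_id",
    "site",
    "transect",
    "time_point",
    "genus",
    "max_diameter_cm",
    "fragment_class",
    "health_state",
    "mortality_state",
]
DWELLING_COLUMNS = ["dwelling_id", "colony_id", "time_point", "status"]
EVENT_COLUMNS = ["dwelling_id", "colony_id", "transition", "event_type"]

RATE_COLUMNS = [
    "colony_id",
    "site",
    "transect",
    "transition",
    "D_prev",
    "D_curr",
    "C",
    "E",
    "HM",
    "turnover_pct",
    "background_mortality_pct",
    "disturbance_mortality_pct",
]


# ---------------------------------------------------------------------------
# Records


@dataclass(frozen=True)
class ColonyObservation:
    """One tagged host colony at one survey time point."""

    colony_id: str
    site: str
    transect: str
    time_point: int
    genus: str
    max_diameter_cm: float | None = None
    fragment_class: str = "none"
    health_state: str = "healthy"
    mortality_state: str = ALIVE


@dataclass(frozen=True)
class DwellingObservation:
    """Per-time-point status of one gall crab dwelling; the atom of fate-tracking."""

    dwelling_id: str
    colony_id: str
    time_point: int
    status: str


@dataclass(frozen=True)
class EventRecord:
    dwelling_id: str
    colony_id: str
    transition: int
    event_type: str


class Snapshot(NamedTuple):
    """Colony and dwelling observations restricted to one time point."""

    time_point: int
    colonies: pd.DataFrame
    dwellings: pd.DataFrame


def snapshot(colonies: pd.DataFrame, dwellings: pd.DataFrame, time_point: int) -> Snapshot:
    """Slice full observation tables down to one time point."""
    return Snapshot(
        time_point,
        colonies[colonies["time_point"] == time_point],
        dwellings[dwellings["time_point"] == time_point],
    )


def events_to_frame(events: Iterable[EventRecord]) -> pd.DataFrame:
    rows = [(e.dwelling_id, e.colony_id, e.transition, e.event_type) for e in events]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


# ---------------------------------------------------------------------------
# Event classification


def classify_events(prev: Snapshot, curr: Snapshot) -> list[EventRecord]:
    """Classify dwelling fates between two consecutive snapshots.

    Rules
    -----
    * ``not_yet_present`` (or absent) → ``occupied``: colonization.
    * ``occupied`` → ``overgrown``: extinction.
    * ``occupied`` → ``empty_on_dead_skeleton``: host-mortality extinction.
    * any ``occupied`` dwelling on a colony whose mortality state turns
      ``dead_recent``/``dead_old`` (or that disappears from the survey):
      host-mortality extinction.

    Raises
    ------
    ValidationError
        On an illegal status transition (absorbing states re-opening, e.g.
        ``overgrown`` → ``occupied``), naming the offending dwelling.
    """
    prev_status: dict[str, tuple[str, str]] = {
        d: (c, s)
        for d, c, s in zip(
            prev.dwellings["dwelling_id"],
            prev.dwellings["colony_id"],
            prev.dwellings["status"],
        )
    }
    curr_status: dict[str, tuple[str, str]] = {
        d: (c, s)
        for d, c, s in zip(
            curr.dwellings["dwelling_id"],
            curr.dwellings["colony_id"],
            curr.dwellings["status"],
        )
    }

    def _dead_set(snap: Snapshot) -> set[str]:
        cols = snap.colonies
        return set(cols.loc[cols["mortality_state"].isin(DEAD_STATES), "colony_id"])

    prev_dead = _dead_set(prev)
    curr_dead = _dead_set(curr)
    curr_colonies = set(curr.colonies["colony_id"])
    newly_dead = curr_dead - prev_dead
    transition = curr.time_point

    events: list[EventRecord] = []
    for dwelling_id in sorted(curr_status):
        colony_id, status_c = curr_status[dwelling_id]
        colony_p, status_p = prev_status.get(dwelling_id, (colony_id, NOT_YET_PRESENT))
        if colony_p != colony_id:
            raise ValidationError(
                f"dwelling {dwelling_id!r} maps to two colonies "
                f"({colony_p!r} at T{prev.time_point}, {colony_id!r} at T{curr.time_point})"
            )
        if status_c not in _ALLOWED_NEXT.get(status_p, set()):
            raise ValidationError(
                f"illegal status transition {status_p!r} -> {status_c!r} "
                f"for dwelling {dwelling_id!r} at transition TR{transition}"
            )
        if status_p == NOT_YET_PRESENT and status_c == OCCUPIED:
            events.append(EventRecord(dwelling_id, colony_id, transition, COLONIZATION))
        elif status_p == OCCUPIED and status_c == OVERGROWN:
            events.append(EventRecord(dwelling_id, colony_id, transition, EXTINCTION))
        elif status_p == OCCUPIED and status_c == EMPTY_ON_DEAD:
            events.append(EventRecord(dwelling_id, colony_id, transition, HOST_MORTALITY))
        elif status_p == OCCUPIED and status_c == OCCUPIED and colony_id in newly_dead:
            # surveyed status lags colony death; the crab cannot survive its host
            events.append(EventRecord(dwelling_id, colony_id, transition, HOST_MORTALITY))

    # dwellings occupied at t but never re-surveyed at t+1
    for dwelling_id in sorted(set(prev_status) - set(curr_status)):
        colony_id, status_p = prev_status[dwelling_id]
        if status_p != OCCUPIED:
            continue
        if colony_id in curr_dead or colony_id not in curr_colonies:
            events.append(EventRecord(dwelling_id, colony_id, transition, HOST_MORTALITY))
        else:
            raise ValidationError(
                f"occupied dwelling {dwelling_id!r} missing at T{curr.time_point} "
                f"while colony {colony_id!r} is alive"
            )

    events.sort(key=lambda e: (e.colony_id, e.dwelling_id))
    return events


def classify_all_events(colonies: pd.DataFrame, dwellings: pd.DataFrame) -> pd.DataFrame:
    """Classify events for every consecutive pair of time points."""
    tps = sorted(colonies["time_point"].unique())
    records: list[EventRecord] = []
    for t_prev, t_curr in zip(tps[:-1], tps[1:]):
        records.extend(
            classify_events(
                snapshot(colonies, dwellings, t_prev),
                snapshot(colonies, dwellings, t_curr),
            )
        )
    return events_to_frame(records)


# ---------------------------------------------------------------------------
# Rates


def _check_counts(C: int, E: int, HM: int, D_prev: int, D_curr: int) -> None:
    for name, v in (("C", C), ("E", E), ("HM", HM), ("D_prev", D_prev), ("D_curr", D_curr)):
        if v < 0:
            raise ValueError(f"count {name} must be non-negative, got {v}")
    if D_curr != D_prev + C - E - HM:
        raise DataInconsistencyError(
            f"accounting identity violated: D_curr={D_curr} != "
            f"D_prev + C - E - HM = {D_prev + C - E - HM}"
        )
    if E + HM > D_prev:
        raise DataInconsistencyError(
            f"more dwellings lost (E+HM={E + HM}) than present (D_prev={D_prev})"
        )


def compute_turnover(
    C: int, E: int, HM: int, D_prev: int, D_curr: int, include_hm: bool = True
) -> float | None:
    """Percent turnover for one colony and one transitional period.

    ``(E' + C) / (D_prev + D_curr) * 100`` with ``E' = E + HM`` when
    ``include_hm`` (default: host-mortality losses count as extinctions, the
    broad reading of the three-event taxonomy) else ``E' = E``.

    Returns ``None`` (undefined, never coerced to 0) when the colony holds no
    dwellings at either bounding time point.
    """
    _check_counts(C, E, HM, D_prev, D_curr)
    denom = D_prev + D_curr
    if denom == 0:
        return None
    lost = E + HM if include_hm else E
    return (lost + C) / denom * 100.0


def compute_mortality_rates(E: int, HM: int, D_prev: int) -> tuple[float | None, float | None]:
    """Background and disturbance-based mortality, percent of crabs present at t-1.

    Background mortality = E / D_prev * 100 (overgrowth while the host lives);
    disturbance-based mortality = HM / D_prev * 100 (losses through host
    mortality).  Both are ``None`` when no crabs were present.
    """
    if D_prev < 0 or E < 0 or HM < 0:
        raise ValueError("counts must be non-negative")
    if D_prev == 0:
        if E + HM > 0:
            raise DataInconsistencyError(
                f"{E + HM} crabs lost from a colony with no crabs present"
            )
        return None, None
    if E + HM > D_prev:
        raise DataInconsistencyError(
            f"more dwellings lost (E+HM={E + HM}) than present (D_prev={D_prev})"
        )
    return E / D_prev * 100.0, HM / D_prev * 100.0


def compute_prevalence(colonies: pd.DataFrame, dwellings: pd.DataFrame) -> float:
    """Percent of host colonies carrying at least one occupied dwelling.

    ``colonies``/``dwellings`` should already be restricted to one transect
    and time point (e.g. via :func:`snapshot`).
    """
    n = colonies["colony_id"].nunique()
    if n == 0:
        raise UndefinedValueError("prevalence undefined for an empty transect")
    occ = set(dwellings.loc[dwellings["status"] == OCCUPIED, "colony_id"])
    inhabited = len(set(colonies["colony_id"]) & occ)
    return inhabited / n * 100.0


def compute_transition_rates(
    colonies: pd.DataFrame,
    dwellings: pd.DataFrame,
    include_hm: bool = True,
    events: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-colony, per-transitional-period counts and rates.

    One row per colony alive at the start of each transition, with occupied
    dwelling counts at the bounding time points (``D_prev``, ``D_curr``),
    event counts (``C``, ``E``, ``HM``) and the three derived rates
    (NaN where undefined).  The accounting identity
    ``D_curr = D_prev + C - E - HM`` is enforced row by row.
    """
    if events is None:
        events = classify_all_events(colonies, dwellings)
    tps = sorted(colonies["time_point"].unique())

    occ = dwellings[dwellings["status"] == OCCUPIED]
    occ_counts = occ.groupby(["colony_id", "time_point"]).size()
    ev_counts = (
        events.groupby(["colony_id", "transition", "event_type"]).size()
        if len(events)
        else pd.Series(dtype=int)
    )

    meta = (
        colonies.sort_values("time_point")
        .groupby("colony_id")[["site", "transect"]]
        .first()
    )
    alive = {
        (c, t)
        for c, t, m in zip(
            colonies["colony_id"], colonies["time_point"], colonies["mortality_state"]
        )
        if m == ALIVE
    }

    rows = []
    for t_prev, t_curr in zip(tps[:-1], tps[1:]):
        for colony_id in sorted(meta.index):
            if (colony_id, t_prev) not in alive:
                continue  # colony already dead: excluded thereafter
            d_prev = int(occ_counts.get((colony_id, t_prev), 0))
            d_curr = int(occ_counts.get((colony_id, t_curr), 0))
            c = int(ev_counts.get((colony_id, t_curr, COLONIZATION), 0))
            e = int(ev_counts.get((colony_id, t_curr, EXTINCTION), 0))
            hm = int(ev_counts.get((colony_id, t_curr, HOST_MORTALITY), 0))
            turnover = compute_turnover(c, e, hm, d_prev, d_curr, include_hm=include_hm)
            background, disturbance = compute_mortality_rates(e, hm, d_prev)
            rows.append(
                (
                    colony_id,
                    meta.at[colony_id, "site"],
                    meta.at[colony_id, "transect"],
                    t_curr,
                    d_prev,
                    d_curr,
                    c,
                    e,
                    hm,
                    np.nan if turnover is None else turnover,
                    np.nan if background is None else background,
                    np.nan if disturbance is None else disturbance,
                )
            )
    return pd.DataFrame(rows, columns=RATE_COLUMNS)


def aggregate_rates(
    rates: pd.DataFrame,
    value_cols: Sequence[str] = (
        "turnover_pct",
        "background_mortality_pct",
        "disturbance_mortality_pct",
    ),
    by: Sequence[str] = ("site", "transition"),
) -> pd.DataFrame:
    """Mean, standard error and n per grouping cell, excluding undefined values.

    SE is the sample standard deviation over sqrt(n); cells with n < 2 report
    SE as NaN and empty cells keep n = 0 with undefined mean.
    """
    out = []
    for keys, group in rates.groupby(list(by), dropna=False, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        for col in value_cols:
            vals = group[col].dropna().to_numpy()
            n = len(vals)
            mean = float(np.mean(vals)) if n else np.nan
            se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n >= 2 else np.nan
            out.append((*keys, col, mean, se, n))
    return pd.DataFrame(out, columns=[*by, "rate", "mean", "se", "n"])


# ---------------------------------------------------------------------------
# Analysis-set filter

KEPT = "kept"
NEVER_INHABITED = "never_inhabited"
INCOMPLETE_SERIES = "incomplete_series"


def filter_analysis_set(
    colonies: pd.DataFrame,
    dwellings: pd.DataFrame,
    time_points: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Restrict to colonies usable for turnover/mortality inference.

    Keeps colonies that (a) were observed at every study time point, or at
    every time point up to and including their recorded full mortality, and
    (b) hosted at least one occupied dwelling at some time point.  Host
    mortality is a natural outcome of the system, so colonies followed "until
    mortality" stay in.

    Returns ``(colonies_kept, dwellings_kept, report)`` where ``report`` has
    one row per colony with ``kept`` and a ``reason`` in
    ``{kept, incomplete_series, never_inhabited}``.
    """
    if time_points is None:
        time_points = sorted(colonies["time_point"].unique())
    full_set = set(time_points)

    occupied_ever = set(
        dwellings.loc[dwellings["status"] == OCCUPIED, "colony_id"].unique()
    )

    report_rows = []
    keep: set[str] = set()
    for colony_id, group in colonies.groupby("colony_id", sort=True):
        observed = set(group["time_point"])
        dead_tps = group.loc[group["mortality_state"].isin(DEAD_STATES), "time_point"]
        if len(dead_tps):
            required = {t for t in full_set if t <= int(dead_tps.min())}
        else:
            required = full_set
        if not required <= observed:
            reason = INCOMPLETE_SERIES
        elif colony_id not in occupied_ever:
            reason = NEVER_INHABITED
        else:
            reason = KEPT
            keep.add(colony_id)
        report_rows.append((colony_id, reason == KEPT, reason))

    report = pd.DataFrame(report_rows, columns=["colony_id", "kept", "reason"])
    return (
        colonies[colonies["colony_id"].isin(keep)].reset_index(drop=True),
        dwellings[dwellings["colony_id"].isin(keep)].reset_index(drop=True),
        report,
    )
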