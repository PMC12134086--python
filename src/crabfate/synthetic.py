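"""Synthetic study-design generator.

Emulates a semiannual reef monitoring campaign: a fixed set of tagged host
colonies spread over sites and permanent belt transects, surveyed at five time
points, with gall crab dwellings appearing (colonization), vanishing under
living tissue (background extinction) or dying with their host (full or
partial colony mortality), plus a mid-study bleaching disturbance that raises
host-mortality probabilities.  Every stochastic event is written to a
ground-truth log so the downstream event classifier can be checked exactly.

The generator also produces in situ temperature-logger series (sinusoidal
annual cycle + triangular heatwave + Gaussian noise) for thermal-stress
computation, and raw draws from the zero-one-inflated beta distribution for
regression testing.

All routines are deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .fate import (
    ALIVE,
    COLONIZATION,
    COLONY_COLUMNS,
    DEAD_OLD,
    DEAD_RECENT,
    DWELLING_COLUMNS,
    EMPTY_ON_DEAD,
    EVENT_COLUMNS,
    EXTINCTION,
    HOST_MORTALITY,
    NOT_YET_PRESENT,
    OCCUPIED,
    OVERGROWN,
)
from .thermal import TemperatureSeries

DEFAULT_SITES = ("AS", "AF", "RR", "SN")
DEFAULT_GENERA = (
    "Pocillopora",
    "Pavona",
    "Echinopora",
    "Goniastrea",
    "Dipsastraea",
    "Platygyra",
)

# Site-specific genus composition: the nearshore site is Pocillopora-heavy and
# Pavona-poor, offshore sites carry a more even mix.
_DEFAULT_GENUS_WEIGHTS = np.array(
    [
        [0.30, 0.05, 0.15, 0.20, 0.20, 0.10],
        [0.15, 0.25, 0.15, 0.15, 0.15, 0.15],
        [0.15, 0.20, 0.15, 0.20, 0.15, 0.15],
        [0.35, 0.10, 0.15, 0.15, 0.10, 0.15],
    ]
)

# Per-site mortality gradients (by site position): the nearshore site suffers
# chronic disturbance from the study onset and the worst bleaching losses,
# offshore sites stay mild before the event and moderate after it.
_FULL_PRE = (0.10, 0.02, 0.02, 0.03)
_FULL_POST = (0.20, 0.12, 0.05, 0.08)
_PARTIAL_PRE = (0.08, 0.05, 0.04, 0.04)
_PARTIAL_POST = (0.18, 0.15, 0.12, 0.08)

# Fraction of surviving colonies showing a bleached/paling state at the
# disturbance time point (cosmetic; drives health_state only).
_BLEACH_PREVALENCE = (0.34, 0.55, 0.75, 0.47)


def _site_param(value: float | Mapping[str, float], site: str) -> float:
    if isinstance(value, Mapping):
        try:
            return float(value[site])
        except KeyError as err:
            raise ConfigurationError(f"no probability configured for site {site!r}") from err
    return float(value)


def _check_prob(name: str, value: float | Mapping[str, float]) -> None:
    vals = value.values() if isinstance(value, Mapping) else (value,)
    for v in vals:
        if not (0.0 <= float(v) <= 1.0):
            raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class SimulationConfig:
    """Study-design parameters for the fate-tracking simulator.

    Defaults emulate the monitored system: 4 sites x 3 transects x 43 tagged
    colonies (516 total), five semiannual time points, a bleaching disturbance
    at T2 switching host-mortality probabilities from the "pre" to the "post"
    set, density-dependent settlement (inhabited colonies attract new recruits
    with weight ``1 + settlement_preference``), and background dwelling
    overgrowth.  Mortality probabilities may be scalars or per-site mappings.
    """

    n_sites: int = 4
    transects_per_site: int = 3
    colonies_per_transect: int = 43
    time_points: int = 5
    genus_pool: Sequence[str] = DEFAULT_GENERA
    site_names: Sequence[str] | None = None
    site_genus_weights: np.ndarray | None = None
    p_initial_occupancy: float = 0.25
    mean_initial_dwellings: float = 2.0
    colonization_intensity: float = 4.0
    settlement_preference: float = 5.0
    p_background_extinction: float = 0.10
    p_host_full_mortality_pre: float | Mapping[str, float] | None = None
    p_host_full_mortality_post: float | Mapping[str, float] | None = None
    p_host_partial_mortality_pre: float | Mapping[str, float] | None = None
    p_host_partial_mortality_post: float | Mapping[str, float] | None = None
    disturbance_time_point: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site_names is None:
            names = list(DEFAULT_SITES[: self.n_sites])
            names += [f"S{i + 1}" for i in range(len(names), self.n_sites)]
            self.site_names = tuple(names)
        else:
            self.site_names = tuple(self.site_names)
        self.genus_pool = tuple(self.genus_pool)

        def _gradient(grad: Sequence[float]) -> dict[str, float]:
            return {
                s: grad[min(i, len(grad) - 1)] for i, s in enumerate(self.site_names)
            }

        if self.p_host_full_mortality_pre is None:
            self.p_host_full_mortality_pre = _gradient(_FULL_PRE)
        if self.p_host_full_mortality_post is None:
            self.p_host_full_mortality_post = _gradient(_FULL_POST)
        if self.p_host_partial_mortality_pre is None:
            self.p_host_partial_mortality_pre = _gradient(_PARTIAL_PRE)
        if self.p_host_partial_mortality_post is None:
            self.p_host_partial_mortality_post = _gradient(_PARTIAL_POST)

        if self.site_genus_weights is None:
            k = len(self.genus_pool)
            rows = []
            for i in range(self.n_sites):
                if i < _DEFAULT_GENUS_WEIGHTS.shape[0] and k == _DEFAULT_GENUS_WEIGHTS.shape[1]:
                    rows.append(_DEFAULT_GENUS_WEIGHTS[i])
                else:
                    rows.append(np.full(k, 1.0 / k))
            self.site_genus_weights = np.asarray(rows, dtype=float)
        else:
            self.site_genus_weights = np.asarray(self.site_genus_weights, dtype=float)

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        for name in ("n_sites", "transects_per_site", "colonies_per_transect"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.time_points < 1:
            raise ConfigurationError("time_points must be >= 1")
        if not (0 <= self.disturbance_time_point):
            raise ConfigurationError("disturbance_time_point must be >= 0")
        _check_prob("p_initial_occupancy", self.p_initial_occupancy)
        _check_prob("p_background_extinction", self.p_background_extinction)
        for name in (
            "p_host_full_mortality_pre",
            "p_host_full_mortality_post",
            "p_host_partial_mortality_pre",
            "p_host_partial_mortality_post",
        ):
            _check_prob(name, getattr(self, name))
        if self.mean_initial_dwellings < 1.0:
            raise ConfigurationError("mean_initial_dwellings must be >= 1 (inhabited colonies hold >= 1 crab)")
        if self.colonization_intensity < 0:
            raise ConfigurationError("colonization_intensity must be >= 0")
        if self.settlement_preference < 0:
            raise ConfigurationError("settlement_preference (psi) must be >= 0")
        w = self.site_genus_weights
        if w.shape != (self.n_sites, len(self.genus_pool)):
            raise ConfigurationError(
                f"site_genus_weights must be {self.n_sites} x {len(self.genus_pool)}, got {w.shape}"
            )
        if (w < 0).any() or (w.sum(axis=1) <= 0).any():
            raise ConfigurationError("site_genus_weights rows must be non-negative with positive sums")

    @property
    def normalized_genus_weights(self) -> np.ndarray:
        w = self.site_genus_weights
        return w / w.sum(axis=1, keepdims=True)

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "n_sites": self.n_sites,
            "transects_per_site": self.transects_per_site,
            "colonies_per_transect": self.colonies_per_transect,
            "time_points": self.time_points,
            "genus_pool": list(self.genus_pool),
            "site_names": list(self.site_names),
            "site_genus_weights": self.site_genus_weights.tolist(),
            "p_initial_occupancy": self.p_initial_occupancy,
            "mean_initial_dwellings": self.mean_initial_dwellings,
            "colonization_intensity": self.colonization_intensity,
            "settlement_preference": self.settlement_preference,
            "p_background_extinction": self.p_background_extinction,
            "disturbance_time_point": self.disturbance_time_point,
            "seed": self.seed,
        }
        for name in (
            "p_host_full_mortality_pre",
            "p_host_full_mortality_post",
            "p_host_partial_mortality_pre",
            "p_host_partial_mortality_post",
        ):
            v = getattr(self, name)
            d[name] = dict(v) if isinstance(v, Mapping) else v
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))


@dataclass
class SyntheticDataset:
    """Simulated survey tables plus the ground-truth event log."""

    colony_table: pd.DataFrame
    dwelling_table: pd.DataFrame
    true_event_log: pd.DataFrame
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write colonies.csv / dwellings.csv and a JSON truth sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "colonies": out / "colonies.csv",
            "dwellings": out / "dwellings.csv",
            "truth": out / "true_events.json",
        }
        self.colony_table.to_csv(paths["colonies"], index=False)
        self.dwelling_table.to_csv(paths["dwellings"], index=False)
        counts = (
            self.true_event_log.groupby("event_type").size().to_dict()
            if len(self.true_event_log)
            else {}
        )
        truth = {
            "event_counts": {k: int(v) for k, v in sorted(counts.items())},
            "n_events": int(len(self.true_event_log)),
            "events": self.true_event_log.to_dict(orient="records"),
        }
        paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
        return paths


# ---------------------------------------------------------------------------
# Internal simulation state


@dataclass
class _Colony:
    colony_id: str
    site: str
    transect: str
    genus: str
    diameter: float
    dead_at: int | None = None  # time point at which full mortality was first recorded
    partial_at: int | None = None
    fragment: str = "none"
    dwellings: list[str] = field(default_factory=list)

    def alive_at(self, tp: int) -> bool:
        return self.dead_at is None or tp < self.dead_at


@dataclass
class _Dwelling:
    dwelling_id: str
    colony_id: str
    created: int  # first time point at which it is occupied
    ended: int | None = None  # time point from which it is no longer occupied
    end_event: str | None = None  # extinction | host_mortality_extinction

    def status_at(self, tp: int) -> str:
        if tp < self.created:
            return NOT_YET_PRESENT
        if self.ended is not None and tp >= self.ended:
            return OVERGROWN if self.end_event == EXTINCTION else EMPTY_ON_DEAD
        return OCCUPIED


def _init_community(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[list[_Colony], dict[str, _Dwelling]]:
    weights = config.normalized_genus_weights
    colonies: list[_Colony] = []
    dwellings: dict[str, _Dwelling] = {}
    genus_idx = np.arange(len(config.genus_pool))
    for s_i, site in enumerate(config.site_names):
        for t_i in range(config.transects_per_site):
            transect = f"{site}-T{t_i + 1}"
            for c_i in range(config.colonies_per_transect):
                colony_id = f"{transect}-c{c_i + 1:03d}"
                genus = config.genus_pool[rng.choice(genus_idx, p=weights[s_i])]
                diameter = float(np.round(rng.lognormal(math.log(15.0), 0.5), 1))
                colony = _Colony(colony_id, site, transect, genus, diameter)
                if rng.random() < config.p_initial_occupancy:
                    # >= 1 dwelling with the configured mean: 1 + Poisson(mean - 1)
                    n_dw = 1 + int(rng.poisson(config.mean_initial_dwellings - 1.0))
                    for d_i in range(n_dw):
                        d_id = f"{colony_id}-d{d_i + 1:03d}"
                        dwellings[d_id] = _Dwelling(d_id, colony_id, created=0)
                        colony.dwellings.append(d_id)
                colonies.append(colony)
    return colonies, dwellings


def _emit_tables(
    config: SimulationConfig,
    colonies: list[_Colony],
    dwellings: dict[str, _Dwelling],
    time_points: Sequence[int],
    health: dict[tuple[str, int], str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    colony_rows = []
    dwelling_rows = []
    for colony in colonies:
        for tp in time_points:
            if colony.dead_at is not None and tp >= colony.dead_at:
                mortality = DEAD_RECENT if tp == colony.dead_at else DEAD_OLD
            else:
                mortality = ALIVE
            fragment = (
                colony.fragment
                if colony.partial_at is not None and tp >= colony.partial_at
                else "none"
            )
            colony_rows.append(
                (
                    colony.colony_id,
                    colony.site,
                    colony.transect,
                    tp,
                    colony.genus,
                    colony.diameter,
                    fragment,
                    health.get((colony.colony_id, tp), "healthy"),
                    mortality,
                )
            )
    for d_id in sorted(dwellings):
        dw = dwellings[d_id]
        for tp in time_points:
            dwelling_rows.append((dw.dwelling_id, dw.colony_id, tp, dw.status_at(tp)))
    return (
        pd.DataFrame(colony_rows, columns=COLONY_COLUMNS),
        pd.DataFrame(dwelling_rows, columns=DWELLING_COLUMNS),
    )


def generate_host_community(config: SimulationConfig) -> SyntheticDataset:
    """Tag the T0 host community: colonies, genera, initial occupancy.

    Returns a dataset restricted to T0 with an empty event log.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    colonies, dwellings = _init_community(config, rng)
    colony_table, dwelling_table = _emit_tables(config, colonies, dwellings, [0], {})
    return SyntheticDataset(
        colony_table, dwelling_table, pd.DataFrame(columns=EVENT_COLUMNS), config
    )


def simulate_fate_tracking(config: SimulationConfig) -> SyntheticDataset:
    """Run the full multi-time-point fate-tracking simulation.

    Per transition t-1 → t (in order): (i) whole-colony mortality with the
    era-appropriate probability (all live dwellings become host-mortality
    extinctions, the colony is excluded from further dynamics but retained in
    the tables); (ii) partial mortality on survivors, killing a uniform random
    fraction of dwellings (floor, minimum 1); (iii) per-dwelling background
    overgrowth; (iv) Poisson colonization per transect allocated over live
    colonies with weight ``1 + psi * [currently inhabited]``.  The era switches
    from "pre" to "post" for transitions ending after ``disturbance_time_point``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    colonies, dwellings = _init_community(config, rng)
    time_points = list(range(config.time_points))
    health: dict[tuple[str, int], str] = {}
    events: list[tuple[str, str, int, str]] = []

    by_transect: dict[str, list[_Colony]] = {}
    for colony in colonies:
        by_transect.setdefault(colony.transect, []).append(colony)

    site_pos = {s: i for i, s in enumerate(config.site_names)}

    def occupied_ids(colony: _Colony) -> list[str]:
        return [d for d in colony.dwellings if dwellings[d].ended is None]

    counter = {c.colony_id: len(c.dwellings) for c in colonies}

    for t in time_points[1:]:
        post = t > config.disturbance_time_point
        for colony in colonies:
            if not colony.alive_at(t - 1) or colony.dead_at is not None:
                continue
            site = colony.site
            p_full = _site_param(
                config.p_host_full_mortality_post if post else config.p_host_full_mortality_pre,
                site,
            )
            p_partial = _site_param(
                config.p_host_partial_mortality_post
                if post
                else config.p_host_partial_mortality_pre,
                site,
            )
            # (i) full colony mortality
            if rng.random() < p_full:
                colony.dead_at = t
                for d_id in occupied_ids(colony):
                    dwellings[d_id].ended = t
                    dwellings[d_id].end_event = HOST_MORTALITY
                    events.append((d_id, colony.colony_id, t, HOST_MORTALITY))
                continue
            # (ii) partial mortality
            if rng.random() < p_partial:
                colony.partial_at = t
                colony.fragment = str(rng.choice(["small", "medium", "large", "mixed"]))
                health[(colony.colony_id, t)] = "partial_fresh_mortality"
                occ = occupied_ids(colony)
                if occ:
                    frac = rng.random()
                    k = max(1, int(math.floor(frac * len(occ))))
                    killed = rng.choice(len(occ), size=k, replace=False)
                    for j in sorted(killed):
                        d_id = occ[j]
                        dwellings[d_id].ended = t
                        dwellings[d_id].end_event = HOST_MORTALITY
                        events.append((d_id, colony.colony_id, t, HOST_MORTALITY))
            # (iii) background overgrowth
            for d_id in occupied_ids(colony):
                if rng.random() < config.p_background_extinction:
                    dwellings[d_id].ended = t
                    dwellings[d_id].end_event = EXTINCTION
                    events.append((d_id, colony.colony_id, t, EXTINCTION))

        # bleaching-state cosmetics at the disturbance time point
        if t == config.disturbance_time_point:
            for colony in colonies:
                if not colony.alive_at(t) or (colony.colony_id, t) in health:
                    continue
                prev = _BLEACH_PREVALENCE[
                    min(site_pos[colony.site], len(_BLEACH_PREVALENCE) - 1)
                ]
                if rng.random() < prev:
                    health[(colony.colony_id, t)] = str(
                        rng.choice(["paling", "partially_bleached", "fully_bleached"])
                    )

        # (iv) colonization per transect, preference for inhabited hosts
        psi = config.settlement_preference
        for transect in sorted(by_transect):
            live = [c for c in by_transect[transect] if c.dead_at is None]
            if not live:
                continue
            n_new = int(rng.poisson(config.colonization_intensity))
            if n_new == 0:
                continue
            weights = np.array(
                [1.0 + psi * (len(occupied_ids(c)) > 0) for c in live], dtype=float
            )
            weights /= weights.sum()
            chosen = rng.choice(len(live), size=n_new, replace=True, p=weights)
            for j in chosen:
                colony = live[j]
                counter[colony.colony_id] += 1
                d_id = f"{colony.colony_id}-d{counter[colony.colony_id]:03d}"
                dwellings[d_id] = _Dwelling(d_id, colony.colony_id, created=t)
                colony.dwellings.append(d_id)
                events.append((d_id, colony.colony_id, t, COLONIZATION))

    colony_table, dwelling_table = _emit_tables(
        config, colonies, dwellings, time_points, health
    )
    event_log = pd.DataFrame(events, columns=EVENT_COLUMNS)
    event_log = event_log.sort_values(
        ["transition", "colony_id", "dwelling_id", "event_type"]
    ).reset_index(drop=True)
    return SyntheticDataset(colony_table, dwelling_table, event_log, config)


# ---------------------------------------------------------------------------
# Temperature-logger emulation


def generate_temperature_series(
    mmm: float = 30.9,
    annual_amplitude: float = 3.0,
    heatwave_start: date = date(2023, 7, 20),
    heatwave_peak_anomaly: float = 2.0,
    heatwave_days: int = 90,
    noise_sd: float = 0.15,
    interval_minutes: int = 30,
    span: tuple[date, date] = (date(2022, 9, 1), date(2024, 9, 30)),
    seed: int = 0,
    site: str = "logger",
) -> TemperatureSeries:
    """Emulate an in situ temperature logger.

    The baseline is a sinusoidal annual cycle whose seasonal maximum touches
    the maximum monthly mean (early September peak), so only the heatwave bump
    pushes readings past the bleaching threshold.  The heatwave is triangular:
    a linear rise to ``heatwave_peak_anomaly`` at the midpoint of
    ``heatwave_days``, then a linear fall.  Gaussian noise is added on top.
    """
    if interval_minutes not in (10, 30):
        raise ConfigurationError("interval_minutes must be 10 or 30")
    start, end = span
    if end < start:
        raise ConfigurationError("span end precedes start")
    n_steps = int(
        (datetime.combine(end, datetime.min.time()) + timedelta(days=1)
         - datetime.combine(start, datetime.min.time())).total_seconds()
        // (interval_minutes * 60)
    )
    if n_steps < 1:
        raise ConfigurationError("span shorter than one logging interval")
    rng = np.random.default_rng(seed)
    timestamps = pd.date_range(
        start=datetime.combine(start, datetime.min.time()),
        periods=n_steps,
        freq=f"{interval_minutes}min",
    )
    doy = timestamps.dayofyear.to_numpy()
    frac = (timestamps.hour.to_numpy() * 60 + timestamps.minute.to_numpy()) / 1440.0
    t_days = doy + frac
    base = (mmm - annual_amplitude) + annual_amplitude * np.cos(
        2 * np.pi * (t_days - 244.0) / 365.25
    )
    # triangular heatwave anomaly
    hw_mid = datetime.combine(heatwave_start, datetime.min.time()) + timedelta(
        days=heatwave_days / 2
    )
    dt_days = (timestamps - hw_mid).total_seconds() / 86400.0
    half = heatwave_days / 2.0
    bump = (
        heatwave_peak_anomaly * np.clip(1.0 - np.abs(dt_days) / half, 0.0, None)
        if half > 0
        else np.zeros_like(dt_days)
    )
    temp = base + np.asarray(bump) + rng.normal(0.0, noise_sd, size=n_steps)
    frame = pd.DataFrame({"timestamp": timestamps, "temp_c": temp})
    return TemperatureSeries(frame, site=site)


# ---------------------------------------------------------------------------
# BEINF sampling


def sample_beinf(
    mu: float | np.ndarray,
    sigma: float,
    nu: float,
    tau: float,
    n: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw from the zero-one-inflated beta distribution.

    With probability ``nu`` emit 0; otherwise with probability ``tau`` emit 1;
    otherwise draw from Beta with mean ``mu`` and dispersion ``sigma`` (shape
    parameters ``a = mu (1 - sigma^2) / sigma^2``, ``b = (1 - mu)(1 - sigma^2)
    / sigma^2``).  ``mu`` may be an array (one draw per element).
    """
    from .beinf import beinf_shapes  # local import to avoid a cycle

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    for name, v in (("nu", nu), ("tau", tau)):
        if not (0.0 <= v <= 1.0):
            raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
    if not (0.0 < sigma < 1.0):
        raise ConfigurationError(f"sigma must lie in (0, 1), got {sigma}")
    mu_arr = np.atleast_1d(np.asarray(mu, dtype=float))
    if n is None:
        n = mu_arr.shape[0]
    if mu_arr.shape[0] == 1:
        mu_arr = np.full(n, mu_arr[0])
    if mu_arr.shape[0] != n:
        raise ConfigurationError("mu length must match n")
    if ((mu_arr <= 0) | (mu_arr >= 1)).any():
        raise ConfigurationError("mu must lie strictly inside (0, 1)")

    u = rng.random(n)
    out = np.empty(n)
    is_zero = u < nu
    is_one = (~is_zero) & (rng.random(n) < tau)
    cont = ~(is_zero | is_one)
    out[is_zero] = 0.0
    out[is_one] = 1.0
    if cont.any():
        a, b = beinf_shapes(mu_arr[cont], sigma)
        out[cont] = rng.beta(a, b)
    return out


def generate_beinf_sample(
    params,
    design: pd.DataFrame | None = None,
    n: int | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Sample turnover proportions under fitted/true BEINF parameters.

    ``params`` is a :class:`crabfate.beinf.BEINFParams`; when ``design`` (a
    table with ``site``/``time_point`` columns) is given, each row gets its
    own mean through the model's logit link, otherwise the intercept mean is
    used for all ``n`` draws.
    """
    rng = np.random.default_rng(seed)
    if design is not None:
        mu = params.mu_for_design(design)
        n = len(design)
    else:
        mu = params.mu_for_design(None)
    return sample_beinf(mu, params.sigma, params.nu, params.tau, n=n, rng=rng)
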