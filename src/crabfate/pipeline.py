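"""End-to-end orchestration: simulate/load → validate → events → rates → models.

Stages run in a fixed order and every intermediate artifact is written to the
output directory (auditable pipeline):

    colonies.csv, dwellings.csv, temperature_<site>.csv   inputs (or simulated)
    events.csv                                            classified events
    transition_rates.csv, site_period_summary.csv         per-colony / per-cell rates
    beinf_fit.json                                        turnover regression
    perm_tests.json                                       mortality permutation tests
    community/*.csv|json                                  ordination, PERMANOVA, SIMPER, diversity
    thermal_<site>.csv, thermal_summary.json              daily means, hotspots, DHW
    report.json                                           run report + provenance

A fixed seed makes the whole run deterministic; running twice with the same
configuration yields byte-identical reports.  Failures in the optional
community or thermal stages are recorded in the report without corrupting the
other stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from . import beinf, community, fate, permtests, synthetic, thermal
from .exceptions import ConfigurationError, DegenerateFitError, ValidationError
from .fate import DEAD_STATES, OCCUPIED, _ALLOWED_NEXT
from .synthetic import SimulationConfig

logger = logging.getLogger("crabfate")


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_colony_rows: int = 0
    n_dwelling_rows: int = 0

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "errors": self.errors,
            "warnings": self.warnings,
            "n_colony_rows": self.n_colony_rows,
            "n_dwelling_rows": self.n_dwelling_rows,
        }


def validate_inputs(colonies: pd.DataFrame, dwellings: pd.DataFrame) -> ValidationReport:
    """Structural checks on the observation tables; reports, never mutates.

    Checks id referential integrity (dwelling → colony at the same time
    point), one colony per dwelling id, status-transition legality (absorbing
    states stay absorbed), dead colonies carrying occupied dwellings, and
    time-point coverage gaps (warning).
    """
    rep = ValidationReport(
        n_colony_rows=len(colonies), n_dwelling_rows=len(dwellings)
    )

    for name, frame, cols in (
        ("colonies", colonies, fate.COLONY_COLUMNS),
        ("dwellings", dwellings, fate.DWELLING_COLUMNS),
    ):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            rep.errors.append(f"{name}: missing columns {missing}")
    if rep.errors:
        return rep

    colony_keys = set(zip(colonies["colony_id"], colonies["time_point"]))
    for d_id, c_id, tp in zip(
        dwellings["dwelling_id"], dwellings["colony_id"], dwellings["time_point"]
    ):
        if (c_id, tp) not in colony_keys:
            rep.errors.append(
                f"dwelling {d_id!r} references unknown colony {c_id!r} at T{tp}"
            )

    multi = dwellings.groupby("dwelling_id")["colony_id"].nunique()
    for d_id in multi[multi > 1].index:
        rep.errors.append(f"dwelling {d_id!r} maps to more than one colony")

    dup = dwellings.duplicated(subset=["dwelling_id", "time_point"])
    if dup.any():
        for d_id, tp in dwellings.loc[dup, ["dwelling_id", "time_point"]].itertuples(index=False):
            rep.errors.append(f"duplicate observation of dwelling {d_id!r} at T{tp}")

    bad_status = set(dwellings["status"]) - set(fate.DWELLING_STATUSES)
    if bad_status:
        rep.errors.append(f"unknown dwelling statuses: {sorted(bad_status)}")
    bad_mort = set(colonies["mortality_state"]) - set(fate.MORTALITY_STATES)
    if bad_mort:
        rep.errors.append(f"unknown mortality states: {sorted(bad_mort)}")
    if rep.errors:
        return rep

    # status-transition legality per dwelling
    for d_id, hist in dwellings.sort_values("time_point").groupby("dwelling_id"):
        prev = None
        for tp, status in zip(hist["time_point"], hist["status"]):
            if prev is not None and status not in _ALLOWED_NEXT[prev]:
                rep.errors.append(
                    f"illegal status transition {prev!r} -> {status!r} for dwelling {d_id!r} at T{tp}"
                )
            prev = status

    # dead colonies must not carry occupied dwellings at the same time point
    dead_keys = set(
        zip(
            colonies.loc[colonies["mortality_state"].isin(DEAD_STATES), "colony_id"],
            colonies.loc[colonies["mortality_state"].isin(DEAD_STATES), "time_point"],
        )
    )
    occ = dwellings[dwellings["status"] == OCCUPIED]
    for d_id, c_id, tp in zip(occ["dwelling_id"], occ["colony_id"], occ["time_point"]):
        if (c_id, tp) in dead_keys:
            rep.errors.append(
                f"dead colony {c_id!r} carries occupied dwelling {d_id!r} at T{tp}"
            )

    # coverage warnings: the study range is the full span of observed time points
    tps = list(range(int(colonies["time_point"].min()), int(colonies["time_point"].max()) + 1))
    for c_id, group in colonies.groupby("colony_id"):
        observed = set(group["time_point"])
        dead_tp = group.loc[group["mortality_state"].isin(DEAD_STATES), "time_point"]
        horizon = int(dead_tp.min()) if len(dead_tp) else tps[-1]
        gaps = [t for t in tps if t <= horizon and t not in observed]
        if gaps:
            rep.warnings.append(f"colony {c_id!r} missing time point(s) {gaps}")
    return rep


# ---------------------------------------------------------------------------
# Pipeline configuration


@dataclass
class PipelineConfig:
    """Either a simulation config or paths to observation CSVs, plus knobs."""

    simulation: SimulationConfig | None = None
    colonies_path: str | None = None
    dwellings_path: str | None = None
    temperature_paths: Mapping[str, str] | None = None
    out_dir: str = "crabfate_run"
    mmm: float = 30.9
    disturbance_time_point: int = 2
    include_hm_in_turnover: bool = True
    n_perm: int = 999
    seed: int = 42
    baseline_site: str | None = "AS"
    community_time_points: Sequence[int] = (1, 3)

    def __post_init__(self) -> None:
        if self.simulation is None and (
            self.colonies_path is None or self.dwellings_path is None
        ):
            raise ConfigurationError(
                "either a simulation config or colonies/dwellings paths are required"
            )

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig.from_dict(sim)
        tp = d.pop("community_time_points", (1, 3))
        return cls(simulation=sim, community_time_points=tuple(tp), **d)

    def to_dict(self) -> dict:
        return {
            "simulation": None if self.simulation is None else self.simulation.to_dict(),
            "colonies_path": self.colonies_path,
            "dwellings_path": self.dwellings_path,
            "temperature_paths": None
            if self.temperature_paths is None
            else dict(self.temperature_paths),
            "out_dir": str(self.out_dir),
            "mmm": self.mmm,
            "disturbance_time_point": self.disturbance_time_point,
            "include_hm_in_turnover": self.include_hm_in_turnover,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "baseline_site": self.baseline_site,
            "community_time_points": list(self.community_time_points),
        }


def _config_hash(config: PipelineConfig) -> str:
    d = config.to_dict()
    d.pop("out_dir", None)  # the report must not depend on where it is written
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (bool, np.bool_)):
        return bool(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if np.isnan(f) else f
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


# ---------------------------------------------------------------------------
# Stages


def _stage_data(config: PipelineConfig, out: Path):
    if config.simulation is not None:
        sim_cfg = config.simulation
        dataset = synthetic.simulate_fate_tracking(sim_cfg)
        dataset.write(out)
        colonies, dwellings = dataset.colony_table, dataset.dwelling_table
        truth = dataset.true_event_log
        series = []
        anomalies = (2.2, 2.0, 1.8, 1.6)  # nearshore loggers run hotter
        for i, site in enumerate(sim_cfg.site_names):
            ts = synthetic.generate_temperature_series(
                mmm=config.mmm,
                heatwave_peak_anomaly=anomalies[min(i, len(anomalies) - 1)],
                seed=int(sim_cfg.seed) + 1000 + i,
                site=site,
            )
            ts.to_csv(out / f"temperature_{site}.csv")
            series.append(ts)
    else:
        colonies = pd.read_csv(config.colonies_path)
        dwellings = pd.read_csv(config.dwellings_path)
        truth = None
        series = []
        if config.temperature_paths:
            for site, path in sorted(config.temperature_paths.items()):
                series.append(thermal.TemperatureSeries.from_csv(path, site=site))
    logger.info("data stage: %d colony rows, %d dwelling rows", len(colonies), len(dwellings))
    return colonies, dwellings, truth, series


def _summarize_events(events: pd.DataFrame, colonies: pd.DataFrame) -> dict:
    meta = colonies.sort_values("time_point").groupby("colony_id")["site"].first()
    ev = events.copy()
    ev["site"] = ev["colony_id"].map(meta)
    table = (
        ev.groupby(["site", "transition", "event_type"]).size().sort_index()
        if len(ev)
        else pd.Series(dtype=int)
    )
    out: dict = {}
    for (site, tr, etype), count in table.items():
        out.setdefault(str(site), {}).setdefault(f"TR{tr}", {})[str(etype)] = int(count)
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report (also written as report.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "crabfate_version": __version__,
        },
        "stages": {},
    }

    colonies, dwellings, truth, temp_series = _stage_data(config, out)

    validation = validate_inputs(colonies, dwellings)
    report["stages"]["validate"] = validation.to_dict()
    if not validation.ok:
        write_json(_jsonable(report), out / "report.json")
        raise ValidationError(
            f"{len(validation.errors)} validation error(s); see report.json"
        )

    events = fate.classify_all_events(colonies, dwellings)
    events.to_csv(out / "events.csv", index=False)
    report["stages"]["events"] = {"n_events": int(len(events))}
    if truth is not None and len(truth):
        match = _events_equal(events, truth)
        report["stages"]["events"]["matches_ground_truth"] = bool(match)

    colonies_f, dwellings_f, filter_report = fate.filter_analysis_set(colonies, dwellings)
    filter_report.to_csv(out / "analysis_set.csv", index=False)
    rates = fate.compute_transition_rates(
        colonies_f, dwellings_f, include_hm=config.include_hm_in_turnover
    )
    rates.to_csv(out / "transition_rates.csv", index=False)
    summary = fate.aggregate_rates(rates)
    summary.to_csv(out / "site_period_summary.csv", index=False)
    report["stages"]["rates"] = {
        "n_colonies_kept": int(filter_report["kept"].sum()),
        "n_colonies_dropped": int((~filter_report["kept"]).sum()),
        "n_rate_rows": int(len(rates)),
    }
    report["event_counts"] = _summarize_events(events, colonies)
    report["rate_summary"] = _summary_to_dict(summary)
    report["dwelling_totals"] = _dwelling_totals(dwellings, colonies)

    # consistency audit: report counts must equal the shipped events.csv aggregate
    audit = _summarize_events(pd.read_csv(out / "events.csv"), colonies)
    if audit != report["event_counts"]:
        raise ValidationError("internal audit failed: report does not match events.csv")

    # BEINF turnover model
    try:
        defined = rates.dropna(subset=["turnover_pct"])
        fit = beinf.fit_beinf(
            defined["turnover_pct"].to_numpy() / 100.0,
            site=defined["site"],
            time_point=defined["transition"],
            baseline_site=config.baseline_site
            if config.baseline_site in set(defined["site"])
            else None,
        )
        fit_dict = fit.to_dict()
        write_json(_jsonable(fit_dict), out / "beinf_fit.json")
        report["beinf_fit"] = _jsonable(fit_dict)
        report["stages"]["beinf"] = {"ok": True}
    except (DegenerateFitError, ValueError) as err:
        report["stages"]["beinf"] = {"ok": False, "error": str(err)}

    # permutation tests per site
    perm_cfg = permtests.PermTestConfig(n_perm=config.n_perm, seed=config.seed + 1)
    perm_results = permtests.run_mortality_perm_tests(
        rates, config.disturbance_time_point, perm_cfg
    )
    write_json(_jsonable(perm_results), out / "perm_tests.json")
    report["perm_tests"] = _jsonable(perm_results)
    report["stages"]["perm_tests"] = {"ok": True}

    # community statistics (optional stage)
    try:
        report["community"] = _stage_community(config, colonies, out)
        report["stages"]["community"] = {"ok": True}
    except Exception as err:  # optional stage must not corrupt the run
        report["stages"]["community"] = {"ok": False, "error": str(err)}

    # thermal stress (optional stage)
    try:
        thermal_summaries = {}
        results = []
        for ts in temp_series:
            res = thermal.thermal_stress(ts, config.mmm)
            res.to_csv(out / f"thermal_{res.site}.csv")
            results.append(res)
            thermal_summaries[res.site] = res.summary()
        if results:
            thermal.write_summary(results, out / "thermal_summary.json")
        report["thermal"] = _jsonable(thermal_summaries)
        report["stages"]["thermal"] = {"ok": True, "n_sites": len(results)}
    except Exception as err:
        report["stages"]["thermal"] = {"ok": False, "error": str(err)}

    write_json(_jsonable(report), out / "report.json")
    return report


def _events_equal(a: pd.DataFrame, b: pd.DataFrame) -> bool:
    key = ["dwelling_id", "colony_id", "transition", "event_type"]
    aa = a[key].sort_values(key).reset_index(drop=True)
    bb = b[key].sort_values(key).reset_index(drop=True)
    return aa.equals(bb)


def _summary_to_dict(summary: pd.DataFrame) -> dict:
    out: dict = {}
    for row in summary.itertuples(index=False):
        cell = out.setdefault(str(row.site), {}).setdefault(f"TR{row.transition}", {})
        cell[row.rate] = {
            "mean": None if pd.isna(row.mean) else round(float(row.mean), 4),
            "se": None if pd.isna(row.se) else round(float(row.se), 4),
            "n": int(row.n),
        }
    return out


def _dwelling_totals(dwellings: pd.DataFrame, colonies: pd.DataFrame) -> dict:
    meta = colonies.sort_values("time_point").groupby("colony_id")["site"].first()
    occ = dwellings[dwellings["status"] == OCCUPIED].copy()
    occ["site"] = occ["colony_id"].map(meta)
    table = occ.groupby(["site", "time_point"]).size()
    out: dict = {}
    for (site, tp), count in table.items():
        out.setdefault(str(site), {})[f"T{tp}"] = int(count)
    return out


def _stage_community(config: PipelineConfig, colonies: pd.DataFrame, out: Path) -> dict:
    cdir = out / "community"
    cdir.mkdir(exist_ok=True)
    counts = community.build_community_matrix(colonies, config.community_time_points)
    hel = community.hellinger(counts)
    ord_res = community.pca(hel)
    ord_res.scores.reset_index().to_csv(cdir / "ordination_scores.csv", index=False)

    idx = counts.index.to_frame(index=False)
    dist = community.euclidean_distance(hel)
    perm = community.permanova(
        dist,
        site=idx["site"],
        transect=idx["transect"],
        time_point=idx["time_point"],
        n_perm=config.n_perm,
        seed=config.seed + 2,
    )
    write_json(_jsonable(perm.to_dict()), cdir / "permanova.json")

    relabund = community.to_relative_abundance(counts)
    simp = community.simper(relabund, idx["site"])
    simp.table.reset_index().to_csv(cdir / "simper.csv", index=False)

    div = community.diversity_by_row(counts)
    div.reset_index().to_csv(cdir / "diversity.csv", index=False)

    return _jsonable(
        {
            "permanova": perm.to_dict(),
            "pca_explained": [round(float(v), 6) for v in ord_res.explained[:3]],
            "mean_between_site_bray_curtis": round(simp.mean_dissimilarity, 6),
            "diversity_mean": {
                k: round(float(div[k].mean()), 4) for k in ("N0", "N1", "N2")
            },
        }
    )
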