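"""Synthetic study-design generator: structure, limits, and calibration."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from crabfate.exceptions import ConfigurationError
from crabfate.fate import COLONIZATION, HOST_MORTALITY, OCCUPIED
from crabfate.synthetic import (
    SimulationConfig,
    generate_host_community,
    generate_temperature_series,
    sample_beinf,
    simulate_fate_tracking,
)


def _frozen(**kw) -> SimulationConfig:
    base = dict(
        n_sites=1,
        transects_per_site=2,
        colonies_per_transect=20,
        p_initial_occupancy=0.5,
        colonization_intensity=0.0,
        p_background_extinction=0.0,
        p_host_full_mortality_pre=0.0,
        p_host_full_mortality_post=0.0,
        p_host_partial_mortality_pre=0.0,
        p_host_partial_mortality_post=0.0,
        seed=3,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"p_initial_occupancy": 1.5},
            {"p_background_extinction": -0.1},
            {"colonization_intensity": -1.0},
            {"settlement_preference": -0.5},
            {"mean_initial_dwellings": 0.5},
            {"p_host_full_mortality_pre": {"AS": 2.0}},
        ],
    )
    def test_invalid_values_rejected(self, kw):
        with pytest.raises(ConfigurationError):
            SimulationConfig(n_sites=1, **kw).validate()

    def test_genus_weights_normalized(self):
        cfg = SimulationConfig(site_genus_weights=np.ones((4, 6)) * 2.0)
        cfg.validate()
        assert np.allclose(cfg.normalized_genus_weights.sum(axis=1), 1.0)

    def test_roundtrip_through_dict(self):
        cfg = SimulationConfig(seed=9)
        again = SimulationConfig.from_dict(cfg.to_dict())
        assert again.to_dict() == cfg.to_dict()


class TestHostCommunity:
    def test_zero_occupancy_means_no_dwellings(self):
        ds = generate_host_community(_frozen(p_initial_occupancy=0.0))
        assert len(ds.dwelling_table) == 0

    def test_full_occupancy_every_colony_inhabited(self):
        ds = generate_host_community(
            _frozen(p_initial_occupancy=1.0, mean_initial_dwellings=1.0)
        )
        occupied = set(ds.dwelling_table.loc[ds.dwelling_table["status"] == OCCUPIED, "colony_id"])
        assert occupied == set(ds.colony_table["colony_id"])

    def test_occupancy_fraction_within_binomial_bound(self):
        cfg = SimulationConfig(
            n_sites=4,
            transects_per_site=3,
            colonies_per_transect=43,
            p_initial_occupancy=0.25,
            seed=1,
        )
        ds = generate_host_community(cfg)
        n = len(ds.colony_table)
        assert n == 516
        inhabited = ds.dwelling_table.loc[
            ds.dwelling_table["status"] == OCCUPIED, "colony_id"
        ].nunique()
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(inhabited / n - 0.25) < 3 * se

    def test_genus_composition_follows_site_weights(self):
        cfg = SimulationConfig(
            n_sites=2,
            transects_per_site=1,
            colonies_per_transect=400,
            genus_pool=("A", "B"),
            site_genus_weights=np.array([[1.0, 0.0], [0.2, 0.8]]),
            p_initial_occupancy=0.0,
            seed=2,
        )
        ds = generate_host_community(cfg)
        by_site = ds.colony_table.groupby("site")["genus"].value_counts(normalize=True)
        assert by_site[("AS", "A")] == 1.0
        assert abs(by_site[("AF", "B")] - 0.8) < 3 * np.sqrt(0.8 * 0.2 / 400)


class TestFateTracking:
    def test_frozen_dynamics_keep_everything_constant(self):
        ds = simulate_fate_tracking(_frozen())
        assert len(ds.true_event_log) == 0
        occ = ds.dwelling_table[ds.dwelling_table["status"] == OCCUPIED]
        per_tp = occ.groupby("time_point").size()
        assert per_tp.nunique() == 1  # identical occupied count at every time point

    def test_certain_post_disturbance_mortality_kills_all(self):
        cfg = _frozen(p_host_full_mortality_post=1.0, time_points=5)
        ds = simulate_fate_tracking(cfg)
        tp_after = cfg.disturbance_time_point + 1
        states = ds.colony_table[ds.colony_table["time_point"] == tp_after]
        assert (states["mortality_state"] == "dead_recent").all()
        assert set(ds.true_event_log["event_type"]) <= {HOST_MORTALITY}

    def test_accounting_identity_every_colony_transition(self):
        ds = simulate_fate_tracking(SimulationConfig(seed=17))
        occ = ds.dwelling_table[ds.dwelling_table["status"] == OCCUPIED]
        counts = occ.groupby(["colony_id", "time_point"]).size()
        ev = ds.true_event_log.groupby(["colony_id", "transition", "event_type"]).size()
        colonies = ds.colony_table["colony_id"].unique()
        for colony in colonies:
            for t in range(1, 5):
                d_prev = counts.get((colony, t - 1), 0)
                d_curr = counts.get((colony, t), 0)
                c = ev.get((colony, t, "colonization"), 0)
                e = ev.get((colony, t, "extinction"), 0)
                hm = ev.get((colony, t, "host_mortality_extinction"), 0)
                assert d_curr == d_prev + c - e - hm

    def test_fixed_seed_is_bitwise_reproducible(self):
        a = simulate_fate_tracking(SimulationConfig(seed=99))
        b = simulate_fate_tracking(SimulationConfig(seed=99))
        pd.testing.assert_frame_equal(a.colony_table, b.colony_table)
        pd.testing.assert_frame_equal(a.dwelling_table, b.dwelling_table)
        pd.testing.assert_frame_equal(a.true_event_log, b.true_event_log)

    def test_event_frequency_matches_configured_probability(self):
        # background overgrowth frequency converges to its probability
        cfg = _frozen(
            n_sites=1,
            transects_per_site=1,
            colonies_per_transect=400,
            p_initial_occupancy=1.0,
            mean_initial_dwellings=3.0,
            p_background_extinction=0.1,
            time_points=5,
            seed=8,
        )
        ds = simulate_fate_tracking(cfg)
        occ = ds.dwelling_table[ds.dwelling_table["status"] == OCCUPIED]
        at_risk = sum(occ.groupby("time_point").size().iloc[:-1])
        n_ext = (ds.true_event_log["event_type"] == "extinction").sum()
        p_hat = n_ext / at_risk
        se = np.sqrt(0.1 * 0.9 / at_risk)
        assert abs(p_hat - 0.1) < 3 * se

    def test_settlement_preference_shifts_colonizations(self):
        """Inhabited hosts attract recruits when psi > 0 (Monte-Carlo comparison)."""

        def inhabited_fraction(psi: float, seed: int) -> float:
            cfg = _frozen(
                n_sites=1,
                transects_per_site=1,
                colonies_per_transect=500,
                p_initial_occupancy=0.5,
                time_points=2,
                colonization_intensity=20.0,
                settlement_preference=psi,
                seed=seed,
            )
            ds = simulate_fate_tracking(cfg)
            initially_inhabited = set(
                ds.dwelling_table.loc[
                    (ds.dwelling_table["time_point"] == 0)
                    & (ds.dwelling_table["status"] == OCCUPIED),
                    "colony_id",
                ]
            )
            col = ds.true_event_log[ds.true_event_log["event_type"] == COLONIZATION]
            if len(col) == 0:
                return np.nan
            return col["colony_id"].isin(initially_inhabited).mean()

        n_rep = 200
        with_pref = np.array([inhabited_fraction(10.0, 7 + i) for i in range(n_rep)])
        without = np.array([inhabited_fraction(0.0, 7 + i) for i in range(n_rep)])
        gap = np.nanmean(with_pref) - np.nanmean(without)
        se = np.sqrt(np.nanvar(with_pref) / n_rep + np.nanvar(without) / n_rep)
        assert gap > 3 * se


class TestTemperatureSeries:
    def test_constant_when_all_forcing_zero(self):
        ts = generate_temperature_series(
            mmm=30.0,
            annual_amplitude=0.0,
            heatwave_peak_anomaly=0.0,
            noise_sd=0.0,
            span=(date(2023, 1, 1), date(2023, 3, 31)),
        )
        assert np.allclose(ts.frame["temp_c"], 30.0)

    def test_heatwave_peak_adds_exactly_its_anomaly(self):
        start = date(2023, 7, 1)
        ts_hw = generate_temperature_series(
            heatwave_start=start,
            heatwave_peak_anomaly=2.0,
            heatwave_days=60,
            noise_sd=0.0,
            span=(date(2023, 6, 1), date(2023, 10, 1)),
        )
        ts_base = generate_temperature_series(
            heatwave_start=start,
            heatwave_peak_anomaly=0.0,
            heatwave_days=60,
            noise_sd=0.0,
            span=(date(2023, 6, 1), date(2023, 10, 1)),
        )
        diff = ts_hw.frame["temp_c"] - ts_base.frame["temp_c"]
        assert diff.max() == pytest.approx(2.0, abs=1e-9)
        peak_ts = ts_hw.frame.loc[diff.idxmax(), "timestamp"]
        assert abs((peak_ts - pd.Timestamp(2023, 7, 31)).total_seconds()) < 86400

    def test_seeded_noise_is_bitwise_reproducible(self):
        kw = dict(noise_sd=0.1, seed=42, span=(date(2023, 1, 1), date(2023, 2, 1)))
        a = generate_temperature_series(**kw)
        b = generate_temperature_series(**kw)
        assert (a.frame["temp_c"].to_numpy() == b.frame["temp_c"].to_numpy()).all()

    def test_bad_interval_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_temperature_series(interval_minutes=15)

    def test_reversed_span_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_temperature_series(span=(date(2023, 2, 1), date(2023, 1, 1)))


class TestBeinfSampling:
    def test_degenerate_masses(self):
        assert (sample_beinf(0.4, 0.3, 1.0, 0.5, n=50, rng=1) == 0.0).all()
        assert (sample_beinf(0.4, 0.3, 0.0, 1.0, n=50, rng=1) == 1.0).all()

    def test_zero_mass_matches_nu_within_binomial_bound(self):
        n = 10000
        y = sample_beinf(0.4, 0.3, 0.3, 0.2, n=n, rng=3)
        p0 = (y == 0.0).mean()
        assert abs(p0 - 0.3) < 3 * np.sqrt(0.3 * 0.7 / n)

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            sample_beinf(0.4, 1.2, 0.1, 0.1, n=10, rng=0)
        with pytest.raises(ConfigurationError):
            sample_beinf(1.2, 0.3, 0.1, 0.1, n=10, rng=0)
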