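"""Event classification, turnover and mortality accounting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crabfate import fate
from crabfate.exceptions import (
    DataInconsistencyError,
    UndefinedValueError,
    ValidationError,
)
from crabfate.fate import (
    COLONIZATION,
    EXTINCTION,
    HOST_MORTALITY,
    Snapshot,
    aggregate_rates,
    classify_all_events,
    classify_events,
    compute_mortality_rates,
    compute_prevalence,
    compute_transition_rates,
    compute_turnover,
    filter_analysis_set,
)

from conftest import make_colonies, make_dwellings


def _snap(tp, colony_rows, dwelling_rows):
    return Snapshot(tp, make_colonies(colony_rows), make_dwellings(dwelling_rows))


class TestClassifyEvents:
    def test_no_change_yields_no_events(self):
        cols = [("c1", "AS", "AS-T1", 0, "alive")]
        dwells = [(f"d{i}", "c1", 0, "occupied") for i in range(3)]
        prev = _snap(0, cols, dwells)
        curr = _snap(
            1,
            [("c1", "AS", "AS-T1", 1, "alive")],
            [(f"d{i}", "c1", 1, "occupied") for i in range(3)],
        )
        assert classify_events(prev, curr) == []

    def test_net_growth_requires_colonizations(self):
        # 16 occupied dwellings growing to 18 implies at least two colonizations
        prev = _snap(
            0,
            [("c1", "RR", "RR-T1", 0, "alive")],
            [(f"d{i}", "c1", 0, "occupied") for i in range(16)],
        )
        curr_dwellings = [(f"d{i}", "c1", 2, "occupied") for i in range(16)]
        curr_dwellings += [(f"new{i}", "c1", 2, "occupied") for i in range(2)]
        curr = _snap(2, [("c1", "RR", "RR-T1", 2, "alive")], curr_dwellings)
        events = classify_events(prev, curr)
        n_col = sum(e.event_type == COLONIZATION for e in events)
        assert n_col >= 2

    def test_full_colony_mortality_converts_all_occupied(self):
        prev = _snap(
            0,
            [("c1", "AS", "AS-T1", 0, "alive")],
            [(f"d{i}", "c1", 0, "occupied") for i in range(5)],
        )
        curr = _snap(
            1,
            [("c1", "AS", "AS-T1", 1, "dead_recent")],
            [(f"d{i}", "c1", 1, "empty_on_dead_skeleton") for i in range(5)],
        )
        events = classify_events(prev, curr)
        assert len(events) == 5
        assert all(e.event_type == HOST_MORTALITY for e in events)

    def test_overgrowth_is_background_extinction(self):
        prev = _snap(0, [("c1", "AS", "AS-T1", 0, "alive")], [("d1", "c1", 0, "occupied")])
        curr = _snap(1, [("c1", "AS", "AS-T1", 1, "alive")], [("d1", "c1", 1, "overgrown")])
        (event,) = classify_events(prev, curr)
        assert event.event_type == EXTINCTION
        assert event.transition == 1

    def test_reoccupation_of_vacant_dwelling_rejected(self):
        prev = _snap(0, [("c1", "AS", "AS-T1", 0, "alive")], [("d1", "c1", 0, "overgrown")])
        curr = _snap(1, [("c1", "AS", "AS-T1", 1, "alive")], [("d1", "c1", 1, "occupied")])
        with pytest.raises(ValidationError, match="d1"):
            classify_events(prev, curr)

    def test_matches_simulated_ground_truth(self, study_dataset):
        """Classification must reproduce the simulator's event log exactly."""
        events = classify_all_events(
            study_dataset.colony_table, study_dataset.dwelling_table
        )
        key = ["dwelling_id", "colony_id", "transition", "event_type"]
        got = events[key].sort_values(key).reset_index(drop=True)
        want = study_dataset.true_event_log[key].sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want)


class TestTurnover:
    @pytest.mark.parametrize(
        "C,E,HM,D_prev,D_curr,expected",
        [
            (0, 0, 0, 3, 3, 0.0),
            (0, 1, 0, 1, 0, 100.0),
            (2, 1, 0, 4, 5, (1 + 2) / (4 + 5) * 100),
        ],
    )
    def test_known_values(self, C, E, HM, D_prev, D_curr, expected):
        assert compute_turnover(C, E, HM, D_prev, D_curr) == pytest.approx(expected)

    def test_undefined_for_empty_colony(self):
        assert compute_turnover(0, 0, 0, 0, 0) is None

    def test_include_hm_flag(self):
        # host-mortality losses enter the numerator only when requested
        full = compute_turnover(1, 1, 2, 5, 3, include_hm=True)
        narrow = compute_turnover(1, 1, 2, 5, 3, include_hm=False)
        assert full == pytest.approx((1 + 1 + 2) / 8 * 100)
        assert narrow == pytest.approx((1 + 1) / 8 * 100)

    def test_accounting_violations_raise(self):
        with pytest.raises(DataInconsistencyError):
            compute_turnover(0, 1, 0, 3, 3)  # identity broken
        with pytest.raises(DataInconsistencyError):
            compute_turnover(3, 2, 0, 1, 2)  # lost more than present

    def test_exhaustive_grid_matches_hand_formula(self):
        """Independent re-derivation over all consistent count combinations."""
        checked = 0
        for C, E, HM, D_prev in itertools.product(
            range(6), range(6), range(6), range(11)
        ):
            if E + HM > D_prev:
                continue
            D_curr = D_prev + C - E - HM
            for include_hm in (True, False):
                lost = E + HM if include_hm else E
                got = compute_turnover(C, E, HM, D_prev, D_curr, include_hm)
                if D_prev + D_curr == 0:
                    assert got is None
                else:
                    expected = (lost + C) / (D_prev + D_curr) * 100
                    assert got == pytest.approx(expected)
                    assert 0.0 <= got <= 100.0
                checked += 1
        assert checked > 1000

    @given(
        C=st.integers(0, 8),
        E=st.integers(0, 8),
        HM=st.integers(0, 8),
        extra=st.integers(0, 8),
    )
    def test_boundary_characterization(self, C, E, HM, extra):
        """Turnover is 0 iff nothing happened and 100 iff complete replacement."""
        D_prev = E + HM + extra
        D_curr = D_prev + C - E - HM
        got = compute_turnover(C, E, HM, D_prev, D_curr)
        if D_prev + D_curr == 0:
            assert got is None
            return
        assert 0.0 <= got <= 100.0
        assert (got == 0.0) == (C == 0 and E + HM == 0)
        assert (got == 100.0) == (E + HM + C == D_prev + D_curr)


class TestMortalityRates:
    @pytest.mark.parametrize(
        "E,HM,D_prev,expected",
        [
            (2, 0, 10, (20.0, 0.0)),
            (0, 10, 10, (0.0, 100.0)),
            (1, 3, 8, (12.5, 37.5)),
        ],
    )
    def test_known_values(self, E, HM, D_prev, expected):
        assert compute_mortality_rates(E, HM, D_prev) == pytest.approx(expected)

    def test_undefined_when_no_crabs(self):
        assert compute_mortality_rates(0, 0, 0) == (None, None)

    def test_losses_without_crabs_is_inconsistent(self):
        with pytest.raises(DataInconsistencyError):
            compute_mortality_rates(1, 0, 0)


class TestPrevalence:
    @pytest.mark.parametrize("n_inhabited,expected", [(0, 0.0), (40, 100.0), (17, 42.5)])
    def test_proportion_of_inhabited_colonies(self, n_inhabited, expected):
        cols = [(f"c{i}", "AS", "AS-T1", 1, "alive") for i in range(40)]
        dwells = [(f"d{i}", f"c{i}", 1, "occupied") for i in range(n_inhabited)]
        snap_df = make_colonies(cols)
        assert compute_prevalence(snap_df, make_dwellings(dwells)) == pytest.approx(expected)

    def test_empty_transect_is_undefined(self):
        with pytest.raises(UndefinedValueError):
            compute_prevalence(make_colonies([]), make_dwellings([]))


class TestFilterAnalysisSet:
    def _base(self):
        colonies = []
        dwellings = []
        # c_full: full series, inhabited at T0
        for t in range(5):
            colonies.append(("c_full", "AS", "AS-T1", t, "alive"))
            dwellings.append(("dA", "c_full", t, "occupied"))
        # c_dead: inhabited at T0, dies at T2, observed T0-T4 (retained after death)
        for t in range(5):
            state = "alive" if t < 2 else ("dead_recent" if t == 2 else "dead_old")
            colonies.append(("c_dead", "AS", "AS-T1", t, state))
            dwellings.append(
                ("dB", "c_dead", t, "occupied" if t < 2 else "empty_on_dead_skeleton")
            )
        # c_gap: alive but missing the T3 observation
        for t in (0, 1, 2, 4):
            colonies.append(("c_gap", "AS", "AS-T1", t, "alive"))
            dwellings.append(("dC", "c_gap", t, "occupied"))
        # c_empty: never inhabited
        for t in range(5):
            colonies.append(("c_empty", "AS", "AS-T1", t, "alive"))
        return make_colonies(colonies), make_dwellings(dwellings)

    def test_reasons(self):
        colonies, dwellings = self._base()
        kept_c, _, report = filter_analysis_set(colonies, dwellings)
        reasons = dict(zip(report["colony_id"], report["reason"]))
        assert reasons["c_full"] == "kept"
        assert reasons["c_dead"] == "kept"  # followed until mortality
        assert reasons["c_gap"] == "incomplete_series"
        assert reasons["c_empty"] == "never_inhabited"
        assert set(kept_c["colony_id"]) == {"c_full", "c_dead"}

    def test_dead_observed_only_until_death(self):
        colonies, dwellings = self._base()
        # drop the post-mortality rows entirely: still a complete series
        keep = ~((colonies["colony_id"] == "c_dead") & (colonies["time_point"] > 2))
        _, _, report = filter_analysis_set(colonies[keep], dwellings)
        reasons = dict(zip(report["colony_id"], report["reason"]))
        assert reasons["c_dead"] == "kept"


class TestTransitionRates:
    def test_accounting_identity_on_simulation(self, study_dataset):
        rates = compute_transition_rates(
            study_dataset.colony_table, study_dataset.dwelling_table
        )
        assert len(rates) > 0
        lhs = rates["D_curr"]
        rhs = rates["D_prev"] + rates["C"] - rates["E"] - rates["HM"]
        assert (lhs == rhs).all()
        defined = rates["turnover_pct"].dropna()
        assert ((defined >= 0) & (defined <= 100)).all()
        both = rates.dropna(subset=["background_mortality_pct", "disturbance_mortality_pct"])
        assert (
            both["background_mortality_pct"] + both["disturbance_mortality_pct"] <= 100 + 1e-9
        ).all()


class TestAggregateRates:
    def test_cells(self):
        rates = pd.DataFrame(
            {
                "site": ["AS"] * 3 + ["AF"],
                "transition": [1, 1, 2, 1],
                "turnover_pct": [0.0, 100.0, 40.0, np.nan],
            }
        )
        out = aggregate_rates(rates, value_cols=("turnover_pct",))
        out = out.set_index(["site", "transition"])
        two = out.loc[("AS", 1)]
        assert two["mean"] == pytest.approx(50.0)
        assert two["se"] == pytest.approx(50.0)  # sd of {0,100} / sqrt(2)
        single = out.loc[("AS", 2)]
        assert single["mean"] == pytest.approx(40.0)
        assert np.isnan(single["se"]) and single["n"] == 1
        empty = out.loc[("AF", 1)]
        assert empty["n"] == 0 and np.isnan(empty["mean"])
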