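import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.tsa.stattools import kpss as sm_kpss

from bridgevar.panel import EmaPanel, GriddedPanel, PersonGrid
from bridgevar.preprocess import (GridAligner, align_to_grid, collinearity_check,
                                  descriptives, kpss_screen, kpss_stat,
                                  reverse_code)
from bridgevar.catalog import default_catalog

CODES = default_catalog().codes


def make_panel(t_min, scores=None, answered=None, person="p1", group="comorbid",
               likert=True, coded=False):
    """Single-person panel; ``scores`` is per-record 7-vectors (or a scalar)."""
    n = len(t_min)
    answered = [True] * n if answered is None else answered
    if scores is None:
        scores = [[4.0] * 7] * n
    rows = []
    for t, a, s in zip(t_min, answered, scores):
        s = [s] * 7 if np.isscalar(s) else s
        rows.append({"person_id": person, "group": group, "t_min": float(t),
                     "answered": a,
                     **{c: (v if a else np.nan) for c, v in zip(CODES, s)}})
    return EmaPanel(data=pd.DataFrame(rows), likert=likert, coded=coded)


class TestReverseCode:
    @pytest.mark.parametrize("code,raw,expected", [
        ("CHE", 7.0, 1.0), ("CHE", 2.0, 6.0), ("REL", 1.0, 7.0),
        ("WOR", 5.0, 5.0), ("DOW", 3.0, 3.0),
    ])
    def test_flip_rule(self, code, raw, expected):
        panel = make_panel([0.0], scores=[[raw] * 7])
        coded = reverse_code(panel)
        assert coded.data[code].iloc[0] == expected
        assert coded.coded

    def test_involution_restores_raw_scores(self):
        rng = np.random.default_rng(0)
        scores = rng.integers(1, 8, size=(10, 7)).astype(float)
        panel = make_panel(np.arange(10) * 180.0, scores=list(scores))
        back = reverse_code(reverse_code(panel))
        assert not back.coded
        assert np.array_equal(back.data[CODES].to_numpy(), scores)

    def test_out_of_range_likert_rejected(self):
        panel = make_panel([0.0], scores=[[9.0] * 7], likert=True)
        with pytest.raises(ValueError, match=r"\[1, 7\]"):
            reverse_code(panel)


class TestAlignToGrid:
    def test_nearest_slot_with_night_gap(self):
        # 550/180 = 3.06 -> slot 3; slot 2 is an explicit missing cell
        panel = make_panel([0.0, 183.0, 550.0, 720.0])
        g = align_to_grid(panel, 180.0)
        pg = g.persons[0]
        assert pg.n_slots == 5
        assert pg.observed_mask.tolist() == [True, True, False, True, True]

    def test_exact_lattice_no_missing(self):
        g = align_to_grid(make_panel([0.0, 180.0, 360.0]), 180.0)
        assert g.persons[0].n_slots == 3
        assert g.persons[0].observed_mask.all()

    def test_collision_keeps_earlier_record(self):
        panel = make_panel([0.0, 60.0], scores=[[2.0] * 7, [5.0] * 7])
        g = align_to_grid(panel, 180.0)
        pg = g.persons[0]
        assert pg.n_slots == 1
        assert pg.n_collisions == 1
        assert pg.values[0, 0] == 2.0  # the earlier record survives

    def test_unanswered_prompts_leave_missing_slots(self):
        panel = make_panel([0.0, 180.0, 360.0], answered=[True, False, True])
        pg = align_to_grid(panel, 180.0).persons[0]
        assert pg.observed_mask.tolist() == [True, False, True]

    def test_origin_is_first_answered_prompt(self):
        panel = make_panel([0.0, 180.0, 360.0], answered=[False, True, True])
        pg = align_to_grid(panel, 180.0).persons[0]
        assert pg.t0_min == 180.0
        assert pg.n_slots == 2

    def test_single_record_person_degenerates_to_one_slot(self):
        pg = align_to_grid(make_panel([42.0]), 180.0).persons[0]
        assert pg.n_slots == 1 and pg.n_observed == 1

    @given(st.lists(st.integers(min_value=0, max_value=4000), min_size=1,
                    max_size=40, unique=True))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_conservation_and_order(self, raw_times):
        t_min = sorted(float(t) for t in raw_times)
        scores = [[float(k % 7 + 1)] * 7 for k in range(len(t_min))]
        panel = make_panel(t_min, scores=scores)
        pg = align_to_grid(panel, 180.0).persons[0]
        # grid conservation: observed slots = answered records - collisions
        assert pg.observed_mask.sum() == len(t_min) - pg.n_collisions
        # order preservation: surviving values appear in original order
        kept = pg.values[pg.observed_mask][:, 0]
        original = [s[0] for s in scores]
        it = iter(original)
        assert all(any(v == o for o in it) for v in kept)

    def test_transformer_wrapper_matches_function(self):
        panel = make_panel([0.0, 183.0, 550.0])
        a = GridAligner(delta_min=180.0).fit(panel).transform(panel)
        b = align_to_grid(panel, 180.0)
        assert np.array_equal(a.persons[0].values, b.persons[0].values,
                              equal_nan=True)
        assert GridAligner().get_params() == {"delta_min": 180.0}


class TestDescriptives:
    def test_endorsement_and_person_mean(self):
        panel = make_panel(np.arange(4) * 180.0,
                           scores=[[1.0] * 7, [1.0] * 7, [2.0] * 7, [3.0] * 7],
                           coded=True)
        d = descriptives(panel)
        row = d[(d["group"] == "comorbid") & (d["item"] == "WOR")].iloc[0]
        assert row["percent_endorsed"] == pytest.approx(50.0)
        assert row["person_mean"] == pytest.approx(1.75)

    def test_floor_scores_give_zero_endorsement_and_sd(self):
        panel = make_panel(np.arange(3) * 180.0, scores=[[1.0] * 7] * 3,
                           coded=True)
        d = descriptives(panel)
        assert (d["percent_endorsed"] == 0.0).all()
        assert (d["within_person_sd"] == 0.0).all()

    def test_identical_persons_have_zero_between_person_sd(self):
        frames = [make_panel(np.arange(3) * 180.0,
                             scores=[[2.0] * 7, [3.0] * 7, [4.0] * 7],
                             person=f"p{i}", coded=True).data for i in range(3)]
        panel = EmaPanel(data=pd.concat(frames, ignore_index=True), coded=True)
        d = descriptives(panel)
        assert (d["person_mean_sd"] == 0.0).all()

    def test_uncoded_panel_rejected(self):
        with pytest.raises(ValueError, match="reverse-coded"):
            descriptives(make_panel([0.0], coded=False))


def _grid_of_series(series_per_person):
    persons = [PersonGrid(person_id=f"p{i}", group="comorbid",
                          values=np.column_stack([x] * 7).astype(float),
                          delta_min=180.0, t0_min=0.0)
               for i, x in enumerate(series_per_person)]
    return GriddedPanel(persons=persons, delta_min=180.0, item_codes=CODES)


class TestKpss:
    def test_white_noise_mostly_stationary(self):
        rng = np.random.default_rng(0)
        grid = _grid_of_series([rng.normal(size=500) for _ in range(40)])
        rep = kpss_screen(grid, alpha=0.05)
        assert (rep["fractions"] >= 0.9).all()

    def test_linear_trend_flagged_nonstationary(self):
        x = np.linspace(0.0, 5.0, 300) + 0.01 * np.random.default_rng(1).normal(size=300)
        rep = kpss_screen(_grid_of_series([x]))
        assert not rep["table"]["stationary"].any()

    def test_constant_series_is_stationary_by_convention(self):
        stat, _ = kpss_stat(np.full(100, 3.0))
        assert stat == 0.0
        rep = kpss_screen(_grid_of_series([np.full(100, 3.0)]))
        assert rep["table"]["stationary"].all()

    def test_short_series_untestable_and_excluded(self):
        rng = np.random.default_rng(2)
        grid = _grid_of_series([rng.normal(size=10), rng.normal(size=100)])
        rep = kpss_screen(grid, min_points=20)
        assert (~rep["table"][rep["table"]["person_id"] == "p0"]["testable"]).all()
        assert rep["fractions"].notna().all()

    def test_statistic_matches_direct_formula(self):
        # independent reference: partial-sum statistic with Bartlett weights
        x = np.sin(np.arange(200) / 7.0) + np.random.default_rng(3).normal(size=200)
        lags = 5
        e = x - x.mean()
        s = np.cumsum(e)
        gamma0 = (e @ e) / len(x)
        lrv = gamma0
        for k in range(1, lags + 1):
            w = 1.0 - k / (lags + 1.0)
            lrv += 2.0 * w * (e[:-k] @ e[k:]) / len(x)
        expected = (s @ s) / (len(x) ** 2 * lrv)
        with np.errstate(all="ignore"), pytest.warns(Warning):
            stat = sm_kpss(x, regression="c", nlags=lags)[0]
        assert stat == pytest.approx(expected, abs=1e-6)


class TestCollinearity:
    def test_duplicated_column_flagged(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(80, 7))
        base[:, 1] = base[:, 0]
        pg = PersonGrid("p1", "comorbid", base, 180.0, 0.0)
        res = collinearity_check(GriddedPanel([pg], 180.0, CODES))
        assert res["flag"] and res["max_abs_r"] == pytest.approx(1.0)

    def test_independent_columns_not_flagged(self):
        rng = np.random.default_rng(1)
        pg = PersonGrid("p1", "comorbid", rng.normal(size=(400, 7)), 180.0, 0.0)
        res = collinearity_check(GriddedPanel([pg], 180.0, CODES))
        assert not res["flag"] and res["max_abs_r"] < 0.3

    def test_anticorrelated_pair_detected(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(300, 7))
        vals[:, 2] = -vals[:, 3] + 0.05 * rng.normal(size=300)
        pg = PersonGrid("p1", "comorbid", vals, 180.0, 0.0)
        res = collinearity_check(GriddedPanel([pg], 180.0, CODES))
        assert res["correlations"].loc["IRR", "LIS"] < -0.95
        assert res["flag"]
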