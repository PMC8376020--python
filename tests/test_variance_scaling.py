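import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import synoptic as sy
from synoptic.variance_scaling import LOG_2PI


def enumerate_best(values, beta, min_seg=2):
    """Independent oracle: score every admissible segmentation explicitly."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    best = (None, math.inf)
    positions = range(min_seg, n - min_seg + 1)
    for k in range(n // min_seg):
        for cps in itertools.combinations(positions, k):
            bounds = [0, *cps, n]
            if any(b - a < min_seg for a, b in zip(bounds, bounds[1:])):
                continue
            cost = beta * k + sum(
                sy.segment_cost(v[a:b]) for a, b in zip(bounds, bounds[1:])
            )
            if cost < best[1]:
                best = (tuple(c - 1 for c in cps), cost)
    return best


class TestScale:
    def test_worked_examples(self):
        assert np.allclose(sy.scale_concentrations([2, 4, 6]), [-1, 0, 1])
        z = sy.scale_concentrations([1, 2, 3, 4, 5])
        assert z[0] == pytest.approx(-2 / math.sqrt(2.5))
        assert np.mean(z) == pytest.approx(0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1, abs=1e-12)

    def test_degenerate_and_short_series(self):
        with pytest.raises(sy.DegenerateSeriesError, match="degenerate"):
            sy.scale_concentrations([5, 5, 5])
        with pytest.raises(ValueError):
            sy.scale_concentrations([1.0])


class TestOrderByArea:
    def test_sorts_and_scales(self, table):
        s = sy.order_by_area(table, "Cl", season="Spring")
        assert list(s.areas_km2) == [0.0, 5.0, 10.0, 30.0, 100.0]
        assert np.mean(s.values) == pytest.approx(0, abs=1e-9)
        assert np.std(s.values, ddof=1) == pytest.approx(1, abs=1e-9)

    def test_zero_area_point_sources_sort_first(self, table):
        s = sy.order_by_area(table, "Cl", season="Spring")
        assert s.site_ids[0] == "V2"

    def test_area_ties_break_by_site_id(self, frame):
        frame.loc[frame.site_id == "V1", "area_km2"] = 10.0  # ties with P1
        s = sy.order_by_area(
            sy.site_table_from_frame(frame), "Cl", season="Spring"
        )
        tied = [sid for sid, a in zip(s.site_ids, s.areas_km2) if a == 10.0]
        assert tied == ["P1", "V1"]

    def test_sites_missing_the_solute_are_dropped(self, table):
        s = sy.order_by_area(table, "DOC", season="Summer")
        assert "P2" not in list(s.site_ids)

    def test_too_few_sites(self, table):
        with pytest.raises(ValueError, match="fewer than 4"):
            sy.order_by_area(sy.select(table, network="Provo"), "DOC", season="Spring")


class TestSegmentCost:
    def test_unit_variance_segment(self):
        assert sy.segment_cost([1.0, -1.0]) == pytest.approx(2 * (LOG_2PI + 1))

    def test_floor_keeps_cost_finite_on_constant_segment(self):
        c = sy.segment_cost([0.0, 0.0], sigma_floor=1e-8)
        assert c == pytest.approx(2 * (LOG_2PI + math.log(1e-8) + 1))
        assert math.isfinite(c)

    @pytest.mark.parametrize("m", [2, 5, 17])
    def test_doubling_values_adds_2m_log2(self, m):
        rng = np.random.default_rng(m)
        v = rng.normal(0, 1.3, m)
        assert sy.segment_cost(2 * v) - sy.segment_cost(v) == pytest.approx(
            2 * m * math.log(2)
        )


TWELVE = [0.10, -0.12, 0.05, -0.07, 0.11, -0.09, 2.0, -1.6, 1.9, -2.1, 2.4, -1.8]


class TestChangepoints:
    def test_twelve_point_series_against_full_enumeration(self):
        res = sy.pelt_changepoints(TWELVE, penalty="bic")
        cps, cost = enumerate_best(TWELVE, 2 * math.log(12))
        assert res.changepoint_indices == cps == (5,)
        # objective includes the per-changepoint penalty
        assert res.cost_total == pytest.approx(cost, abs=1e-9)
        oracle = sy.brute_force_changepoints(TWELVE, penalty="bic")
        assert oracle.changepoint_indices == res.changepoint_indices
        assert oracle.cost_total == pytest.approx(res.cost_total, abs=1e-12)

    def test_segment_variances_and_invariants(self):
        res = sy.pelt_changepoints(TWELVE, penalty="bic")
        assert len(res.segment_variances) == res.n_changepoints + 1
        assert res.segment_variances[1] > res.segment_variances[0]
        assert res.n == 12 and res.min_seg == 2

    def test_planted_two_regime_series(self):
        rng = np.random.default_rng(0)
        v = np.concatenate([rng.normal(0, 0.1, 50), rng.normal(0, 3.0, 50)])
        res = sy.pelt_changepoints(sy.scale_concentrations(v), penalty="bic")
        assert res.n_changepoints == 1
        assert abs(res.changepoint_indices[0] - 49) <= 3

    def test_constant_variance_series_has_no_changepoint(self):
        rng = np.random.default_rng(5)
        res = sy.pelt_changepoints(rng.normal(0, 1, 200), penalty="bic")
        oracle = sy.brute_force_changepoints(
            rng.normal(0, 1, 30), penalty="bic"
        )
        assert res.n_changepoints == 0
        assert oracle.n_changepoints == 0

    def test_changepoint_count_monotone_in_penalty(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0, 1, 80) * np.repeat([0.2, 2.0, 0.5, 4.0], 20)
        counts = [
            sy.pelt_changepoints(v, penalty=b).n_changepoints
            for b in (0.5, 2.0, 5.0, 10.0, 50.0, 1e6)
        ]
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] == 0

    def test_shift_invariance_through_zscoring(self, watershed):
        _, table, _ = watershed
        shifted = table.copy()
        shifted.df["Cl"] = shifted.df["Cl"] + 123.0
        a = sy.pelt_changepoints(sy.order_by_area(table, "Cl"))
        b = sy.pelt_changepoints(sy.order_by_area(shifted, "Cl"))
        assert a.changepoint_indices == b.changepoint_indices
        assert a.cost_total == pytest.approx(b.cost_total)

    def test_result_carries_boundary_areas(self, watershed):
        _, table, _ = watershed
        series = sy.order_by_area(table, "PO4")
        res = sy.pelt_changepoints(series)
        assert res.solute == "PO4"
        for idx, area in zip(res.changepoint_indices, res.changepoint_areas_km2):
            assert area == pytest.approx(series.areas_km2[idx])

    def test_input_guards(self):
        with pytest.raises(ValueError, match="n >= 2"):
            sy.pelt_changepoints([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="finite"):
            sy.pelt_changepoints([1.0, np.nan, 2.0, 3.0])
        with pytest.raises(ValueError, match="min_seg"):
            sy.pelt_changepoints([1.0, 2.0, 3.0, 4.0], min_seg=1)
        with pytest.raises(sy.OracleLimitError, match="oracle limit"):
            sy.brute_force_changepoints(np.zeros(41))
        with pytest.raises(ValueError, match="penalty"):
            sy.pelt_changepoints(np.ones(10), penalty="aic")


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    seed=st.integers(0, 2**31 - 1),
    n=st.integers(8, 30),
    n_cp=st.integers(0, 2),
    penalty=st.sampled_from(["bic", "mbic", 0.5, 3.0]),
)
def test_pelt_equals_unpruned_dp_on_random_series(seed, n, n_cp, penalty):
    """Pruning must never change the optimum, for any penalty."""
    rng = np.random.default_rng(seed)
    bounds = sorted(rng.choice(np.arange(2, n - 1), size=n_cp, replace=False))
    sds = rng.uniform(0.05, 3.0, n_cp + 1)
    v = rng.normal(0, 1, n)
    for i, (a, b) in enumerate(zip([0, *bounds], [*bounds, n])):
        v[a:b] *= sds[i]
    fast = sy.pelt_changepoints(v, penalty=penalty)
    slow = sy.brute_force_changepoints(v, penalty=penalty)
    assert fast.changepoint_indices == slow.changepoint_indices
    assert fast.cost_total == pytest.approx(slow.cost_total, abs=1e-9)


def test_changepoint_table_tidy_shape(watershed):
    _, table, _ = watershed
    tidy, meta = sy.changepoint_table(table, solutes=["Cl", "DOC"])
    assert set(tidy["solute"]) <= {"Cl", "DOC"}
    assert {"segment_id", "segment_variance", "changepoint_area_km2"} <= set(
        tidy.columns
    )
    assert "2*log(n)" in meta["penalty"]
    per_sol = tidy.groupby("solute").size()
    cps = tidy.groupby("solute")["changepoint_index"].apply(lambda s: s.notna().sum())
    assert (per_sol == cps + 1).all()
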