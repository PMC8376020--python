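import numpy as np
import pandas as pd
import pytest

import synoptic as sy


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs,match",
        [
            (dict(n_sites=5), "n_sites"),
            (dict(area_range_km2=(2.0, 1.0)), "area_range"),
            (dict(category_weights={"MixedDammed": 0.0}), "weights"),
            (dict(point_source_fraction=1.5), "point_source_fraction"),
            (dict(persistence_mode="chaotic"), "persistence_mode"),
            (dict(noise_sd_log=-0.1), "noise_sd_log"),
        ],
    )
    def test_invalid_configs_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            sy.WatershedConfig(**kwargs)

    def test_weights_normalized(self):
        cfg = sy.WatershedConfig(
            category_weights={"MixedDammed": 2.0, "MountainUrban": 2.0}
        )
        assert sum(cfg.category_weights.values()) == pytest.approx(1.0)

    def test_dict_round_trip(self):
        cfg = sy.WatershedConfig(seed=5, point_source_strength=2.0)
        assert sy.WatershedConfig.from_dict(cfg.to_dict()) == cfg


class TestNetwork:
    def test_deterministic_under_seed(self):
        cfg = sy.WatershedConfig(seed=42, n_sites=20)
        a = sy.generate_network(cfg)
        b = sy.generate_network(cfg)
        pd.testing.assert_frame_equal(a.sites, b.sites)
        assert a.children == b.children
        t1, _ = sy.generate_concentrations(a, cfg)
        t2, _ = sy.generate_concentrations(b, cfg)
        assert t1 == t2

    def test_changing_seed_changes_values_not_schema(self):
        t1, _ = sy.generate_watershed(sy.WatershedConfig(seed=1, n_sites=30))
        t2, _ = sy.generate_watershed(sy.WatershedConfig(seed=2, n_sites=30))
        assert list(t1.df.columns) == list(t2.df.columns)
        assert not t1.df.equals(t2.df)

    def test_outlet_area_is_sum_of_leaf_areas(self, skeleton):
        for net, root in skeleton.roots.items():
            grp = skeleton.sites[skeleton.sites.network == net]
            leaf_sum = grp[grp.is_leaf].area_km2.sum()
            root_area = grp.set_index("site_id").loc[root, "area_km2"]
            assert root_area == pytest.approx(leaf_sum, rel=1e-12)

    def test_valley_networks_carry_no_outlet_flag(self, skeleton):
        valley = skeleton.sites[skeleton.sites.category == "ValleyTributaries"]
        assert not valley.is_outlet.any()
        assert valley.network.nunique() > 1  # disjoint small networks

    def test_cover_fractions_valid(self, skeleton):
        covers = skeleton.sites[list(sy.LAND_COVER)]
        assert ((covers >= 0) & (covers <= 1)).all().all()
        assert (covers.sum(axis=1) <= 1.0 + 1e-9).all()


class TestConcentrations:
    def test_generated_table_passes_io_validation(self, tmp_path, watershed):
        _, table, _ = watershed
        p = tmp_path / "gen.csv"
        sy.write_site_table(table, p)
        reread = sy.read_site_table(p)
        assert reread.solutes == table.solutes
        assert len(reread) == len(table)

    def test_degenerate_limit_reproduces_baselines_and_zero_leverage(self):
        specs = {
            name: sy.SoluteSpec(baseline=s.baseline)
            for name, s in sy.synthetic.default_solute_specs().items()
        }
        cfg = sy.WatershedConfig(
            seed=0,
            n_sites=40,
            solutes=specs,
            season_factors={"Spring": 1.0, "Summer": 1.0, "Fall": 1.0},
            noise_sd_log=0.0,
            site_effect_sd_log=0.0,
            point_source_fraction=0.0,
            hourglass=False,
            conservative_routing=True,
        )
        t, _ = sy.generate_watershed(cfg)
        for name, spec in specs.items():
            assert np.allclose(t.df[name], spec.baseline)
        recs = sy.leverage_table(t)
        assert np.allclose(recs.leverage_conc, 0.0, atol=1e-12)

    def test_ground_truth_structure(self, watershed, skeleton):
        cfg, table, truth = watershed
        assert truth.planted_source_sites <= set(table.site_ids)
        leaves = set(skeleton.sites[skeleton.sites.is_leaf].site_id)
        assert truth.planted_source_sites <= leaves
        assert truth.true_predictor_subsets["PO4"] == ("impervious",)
        assert set(truth.site_effects) == set(table.solutes)

    def test_planted_sources_are_highly_influential(self, watershed):
        _, table, truth = watershed
        recs = sy.leverage_table(table, solutes=["PO4"])
        planted = recs[recs.site_id.isin(truth.planted_source_sites)]
        frac = (planted.influence_class == "highly_influential_positive").mean()
        assert frac > 0.9

    def test_persistent_mode_outranks_scrambled(self):
        p, _ = sy.generate_watershed(sy.WatershedConfig(seed=3, n_sites=120))
        s, _ = sy.generate_watershed(
            sy.WatershedConfig(seed=3, n_sites=120, persistence_mode="scrambled")
        )
        rho_p = sy.persistence_matrix(p).rho.mean()
        rho_s = sy.persistence_matrix(s).rho.mean()
        assert rho_p > 0.7 > abs(rho_s)

    def test_conservative_ions_more_persistent_than_nutrients(self, watershed):
        _, table, _ = watershed
        rho = sy.persistence_matrix(table).groupby("solute").rho.mean()
        assert min(rho["Cl"], rho["SO4"]) > max(rho["DOC"], rho["PO4"])


def _decile_profile(hourglass: bool, seeds=(0, 1, 2)) -> np.ndarray:
    """Mean per-decile variance of area-ordered z-scores, pooled over
    solutes and seeds; sources disabled to isolate the variance pattern."""
    agg = np.zeros(10)
    count = 0
    for seed in seeds:
        t, _ = sy.generate_watershed(
            sy.WatershedConfig(seed=seed, hourglass=hourglass, point_source_fraction=0.0)
        )
        for sol in t.solutes:
            z = sy.order_by_area(t, sol).values
            agg += [float(np.var(d)) for d in np.array_split(z, 10)]
            count += 1
    return agg / count


class TestVariancePatterns:
    def test_hourglass_inflates_smallest_and_largest_deciles(self):
        prof = _decile_profile(hourglass=True)
        waist = prof[4:8].max()
        assert prof[0] > waist and prof[9] > waist

    def test_without_hourglass_variance_funnels(self):
        prof = _decile_profile(hourglass=False)
        assert prof[9] < prof[4:8].max()
        assert prof[9] < prof[0]

    def test_valley_sites_raise_no_single_outlet(self, watershed):
        _, table, _ = watershed
        with pytest.raises(sy.NoSingleOutletError):
            sy.leverage_table(table, solutes=["Cl"], exclude_valley=False)


class TestPlantedVarianceRegime:
    def test_single_boundary_recovered(self, skeleton):
        t, truth = sy.plant_variance_regime(
            skeleton, 20.0, sd_small=1.0, sd_large=0.1, seed=4
        )
        series = sy.order_by_area(t, "tracer")
        res = sy.pelt_changepoints(series)
        (b,) = truth.planted_variance_boundary_km2
        true_idx = int(np.searchsorted(series.areas_km2, b)) - 1
        assert any(abs(i - true_idx) <= 1 for i in res.changepoint_indices)

    def test_two_boundaries_recoverable(self, skeleton):
        t, truth = sy.plant_variance_regime(
            skeleton, [5.0, 60.0], sds=[2.0, 0.1, 2.0], seed=4
        )
        series = sy.order_by_area(t, "tracer")
        res = sy.pelt_changepoints(series)
        idx = [
            int(np.searchsorted(series.areas_km2, b)) - 1
            for b in truth.planted_variance_boundary_km2
        ]
        for true_idx in idx:
            assert any(abs(i - true_idx) <= 2 for i in res.changepoint_indices)

    def test_boundary_outside_area_range_rejected(self, skeleton):
        with pytest.raises(ValueError, match="outside"):
            sy.plant_variance_regime(skeleton, 1e6)

    def test_sd_count_must_match_boundaries(self, skeleton):
        with pytest.raises(ValueError, match="sds"):
            sy.plant_variance_regime(skeleton, [5.0, 60.0], sds=[1.0, 2.0])
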