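"""Closure expansion, water-quality improvement and intervention dispatch."""

import numpy as np
import pytest

import reefnet as rn
from conftest import collinear_reefs


class TestDistanceMatrix:
    def test_zero_diagonal_and_symmetry(self, reefs10):
        d = rn.distance_matrix(reefs10)
        assert np.all(np.diag(d) == 0.0)
        np.testing.assert_allclose(d, d.T, atol=1e-9)

    def test_one_degree_of_longitude_at_equator(self):
        # closed form: 6371 km * pi / 180
        d = rn.haversine_km(0.0, 0.0, 1.0, 0.0)
        assert d == pytest.approx(6371.0 * np.pi / 180.0, rel=1e-9)
        assert d == pytest.approx(111.195, abs=5e-4)

    def test_invalid_latitude_rejected(self):
        reefs = collinear_reefs([0.0, 1.0], [False, False])
        reefs.loc[0, "lat"] = 95.0
        with pytest.raises(ValueError):
            rn.distance_matrix(reefs)


class TestExpandClosures:
    def test_radius_zero_changes_nothing(self):
        reefs = collinear_reefs([0.0, 1.5, 6.0], [True, False, False])
        g = np.array([0.5, 0.2, 0.2])
        res = rn.expand_closures(reefs, g, rn.distance_matrix(reefs), 0.0, True)
        assert res.newly_included == frozenset()
        np.testing.assert_array_equal(res.g, g)

    def test_collinear_capture_within_radius(self):
        reefs = collinear_reefs([0.0, 1.5, 6.0], [True, False, False])
        g = np.array([0.5, 0.2, 0.2])
        res = rn.expand_closures(reefs, g, rn.distance_matrix(reefs), 2.0, True)
        assert res.newly_included == frozenset({2})
        np.testing.assert_allclose(res.g, [0.5, 0.5, 0.2])
        assert res.g_changed_up == frozenset({2})
        assert res.g_changed_down == frozenset()

    def test_multi_closure_capture_averages(self):
        # reef 2 sits within 2 km of closures at 0 km (g=0.4) and 3 km (g=0.6)
        reefs = collinear_reefs([0.0, 1.5, 3.0], [True, False, True])
        g = np.array([0.4, 0.2, 0.6])
        res = rn.expand_closures(reefs, g, rn.distance_matrix(reefs), 2.0, True)
        assert res.g[1] == pytest.approx(0.5)

    def test_original_closure_reefs_captured_by_each_other_average(self):
        # two single-reef closures 1 km apart capture one another
        reefs = collinear_reefs([0.0, 1.0], [True, True])
        g = np.array([0.4, 0.6])
        res = rn.expand_closures(reefs, g, rn.distance_matrix(reefs), 2.0, True)
        np.testing.assert_allclose(res.g, [0.5, 0.5])
        assert res.newly_included == frozenset()

    def test_same_ground_rule_blocks_capture(self):
        reefs = collinear_reefs([0.0, 1.5], [True, False], grounds=["q1", "q2"])
        g = np.array([0.5, 0.2])
        same = rn.expand_closures(reefs, g, rn.distance_matrix(reefs), 2.0, True)
        assert same.newly_included == frozenset()
        anyg = rn.expand_closures(reefs, g, rn.distance_matrix(reefs), 2.0, False)
        assert anyg.newly_included == frozenset({2})

    def test_newly_included_monotone_in_radius(self, reefs75):
        g = rn.grazing_from_density(reefs75["herbivore_density"].to_numpy(), "medium")
        dist = rn.distance_matrix(reefs75)
        small = rn.expand_closures(reefs75, g, dist, 2.0, False)
        large = rn.expand_closures(reefs75, g, dist, 5.0, False)
        assert small.newly_included <= large.newly_included

    def test_no_closures_is_structural_error(self):
        reefs = collinear_reefs([0.0, 1.0], [False, False])
        with pytest.raises(ValueError):
            rn.expand_closures(reefs, np.array([0.1, 0.1]),
                               rn.distance_matrix(reefs), 2.0, True)


class TestImproveWaterQuality:
    def test_forced_arithmetic(self):
        out = rn.improve_water_quality(np.array([0.1]), 25.0)
        assert out[0] == pytest.approx(0.075)

    def test_full_improvement_zeroes_mortality(self):
        out = rn.improve_water_quality(np.array([0.3, 0.5]), 100.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_subset_masking(self):
        d = np.array([0.1, 0.2, 0.3])
        out = rn.improve_water_quality(d, 50.0, subset=np.array([True, False, True]))
        np.testing.assert_allclose(out, [0.05, 0.2, 0.15])

    def test_never_increases_mortality(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 1, 20)
        for pct in (10.0, 25.0, 99.0):
            assert np.all(rn.improve_water_quality(d, pct) <= d)

    @pytest.mark.parametrize("pct", [0.0, -5.0, 150.0])
    def test_out_of_range_percent(self, pct):
        with pytest.raises(ValueError):
            rn.improve_water_quality(np.array([0.1]), pct)


class TestApplyIntervention:
    @pytest.fixture()
    def system75(self, reefs75):
        K = rn.generate_connectivity(reefs75, 50, seed=1, kind="coral")
        N = rn.generate_connectivity(reefs75, 5, seed=2, kind="macroalgae")
        return rn.build_system(reefs75, K, N, "medium")

    def test_combined_commutes_and_touches_disjoint_params(self, reefs75, system75):
        combined = rn.apply_intervention(
            reefs=reefs75, system=system75,
            spec=rn.InterventionSpec("combined", radius_km=2.0,
                                     same_ground_only=True, wq_percent=25.0))
        closure_only = rn.apply_intervention(
            reefs=reefs75, system=system75, spec=rn.STANDARD_ARMS["M1-2km"])
        wq_only = rn.apply_intervention(
            reefs=reefs75, system=system75, spec=rn.STANDARD_ARMS["M2-25%"])
        np.testing.assert_array_equal(combined.params.g, closure_only.params.g)
        np.testing.assert_array_equal(combined.params.d, wq_only.params.d)
        # closure expansion only edits g; water quality only edits d
        np.testing.assert_array_equal(closure_only.params.d, system75.d)
        np.testing.assert_array_equal(wq_only.params.g, system75.g)

    def test_scattered_scope_edits_only_newly_included(self, reefs75, system75):
        res = rn.apply_intervention(
            reefs=reefs75, system=system75, spec=rn.ALL_ARMS["M2-25% scat"])
        ids = reefs75["reef_id"].to_numpy()
        changed = np.flatnonzero(res.params.d != system75.d)
        assert frozenset(ids[changed]) == res.d_changed
        expansion = rn.apply_intervention(
            reefs=reefs75, system=system75, spec=rn.STANDARD_ARMS["M1-2km"])
        assert res.d_changed == expansion.newly_included
        np.testing.assert_array_equal(res.params.g, system75.g)

    def test_scattered_with_empty_capture_changes_nothing(self):
        reefs = collinear_reefs([0.0, 50.0], [True, False])
        K = rn.ConnectivityMatrix(np.eye(2) * 0.5, reefs["reef_id"].to_numpy(),
                                  "coral", 30.0)
        N = rn.ConnectivityMatrix(np.eye(2) * 0.5, reefs["reef_id"].to_numpy(),
                                  "macroalgae", 5.0)
        system = rn.build_system(reefs, K, N, "medium")
        res = rn.apply_intervention(
            reefs=reefs, system=system,
            spec=rn.InterventionSpec("water_quality", wq_percent=25.0,
                                     wq_scope="scattered", radius_km=2.0,
                                     same_ground_only=True))
        np.testing.assert_array_equal(res.params.d, system.d)
        assert res.d_changed == frozenset()

    def test_newly_included_disjoint_from_original_closures(self, reefs75, system75):
        res = rn.apply_intervention(
            reefs=reefs75, system=system75, spec=rn.STANDARD_ARMS["M1-5km"])
        original = set(reefs75.loc[reefs75["closure_id"].notna(), "reef_id"])
        assert res.newly_included.isdisjoint(original)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            rn.InterventionSpec("expand_closures")  # missing radius
        with pytest.raises(ValueError):
            rn.InterventionSpec("water_quality", wq_percent=150.0)
        with pytest.raises(ValueError):
            rn.InterventionSpec("water_quality", wq_percent=10.0, wq_scope="scattered")
        with pytest.raises(ValueError):
            rn.InterventionSpec("bulldoze")
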