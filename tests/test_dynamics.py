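"""Schoener's D, E/S/U decomposition, permutation tests, temporal series."""

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nichedyn as nd
from nichedyn.dynamics import _shift_surface
from nichedyn.envspace import build_density_grid, shared_bounds

from .conftest import schoener_d_oracle


class TestSchoenerD:
    def test_identity_is_one(self):
        z = np.random.default_rng(0).uniform(size=(10, 10))
        assert nd.schoener_d(z, z) == pytest.approx(1.0)

    def test_disjoint_supports_zero(self):
        z1 = np.zeros((10, 10)); z1[:5] = 1.0
        z2 = np.zeros((10, 10)); z2[5:] = 1.0
        assert nd.schoener_d(z1, z2) == pytest.approx(0.0)

    def test_two_cell_formula(self):
        z1 = np.array([[1.0, 0.0]])
        z2 = np.array([[0.5, 0.5]])
        assert nd.schoener_d(z1, z2) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1),
           st.floats(min_value=0.1, max_value=50.0))
    def test_symmetry_and_scale_invariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        z1 = rng.uniform(size=(8, 8))
        z2 = rng.uniform(size=(8, 8))
        d = nd.schoener_d(z1, z2)
        assert 0.0 <= d <= 1.0
        assert nd.schoener_d(z2, z1) == pytest.approx(d)
        assert nd.schoener_d(scale * z1, z2) == pytest.approx(d)

    def test_all_zero_surface_in_mask_raises(self):
        z = np.ones((5, 5))
        zero = np.zeros((5, 5))
        with pytest.raises(ValueError):
            nd.schoener_d(z, zero)


class TestEsuIndices:
    def test_identical_niches(self):
        z = np.zeros((6, 6)); z[2:4, 2:4] = 1.0
        e, s, u = nd.esu_indices(z, z.copy())
        assert (e, s, u) == (0.0, 1.0, 0.0)

    def test_disjoint_niches_full_shift_pattern(self):
        # the all-expansion / all-unfilling signature of a fresh invasion
        # into conditions the native population never uses
        z_nat = np.zeros((6, 6)); z_nat[:2] = 1.0
        z_inv = np.zeros((6, 6)); z_inv[4:] = 1.0
        e, s, u = nd.esu_indices(z_nat, z_inv)
        assert (e, s, u) == (1.0, 0.0, 1.0)
        assert nd.schoener_d(z_nat, z_inv) == pytest.approx(0.0, abs=1e-12)

    def test_three_cell_hand_computation(self):
        z_nat = np.array([[0.5, 1.0, 0.0]])
        z_inv = np.array([[0.0, 1.0, 0.25]])
        e, s, u = nd.esu_indices(z_nat, z_inv)
        assert e == pytest.approx(0.25 / 1.25)
        assert s == pytest.approx(0.8)
        assert u == pytest.approx(0.5 / 1.5)

    def test_expansion_stability_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            z1 = rng.uniform(size=(8, 8)) * (rng.uniform(size=(8, 8)) > 0.4)
            z2 = rng.uniform(size=(8, 8)) * (rng.uniform(size=(8, 8)) > 0.4)
            mask = rng.uniform(size=(8, 8)) > 0.2
            if not ((z1 > 0) & mask).any() or not ((z2 > 0) & mask).any():
                continue
            e, s, _ = nd.esu_indices(z1, z2, mask)
            assert e + s == pytest.approx(1.0)

    def test_invasive_outside_mask_convention(self):
        z_nat = np.zeros((4, 4)); z_nat[0, 0] = 1.0
        z_inv = np.zeros((4, 4)); z_inv[3, 3] = 1.0
        mask = np.zeros((4, 4), dtype=bool); mask[0, :2] = True
        with pytest.warns(UserWarning, match="convention"):
            e, s, u = nd.esu_indices(z_nat, z_inv, mask)
        assert (e, s, u) == (1.0, 0.0, 1.0)

    def test_empty_mask_and_missing_native_raise(self):
        z = np.ones((4, 4))
        with pytest.raises(ValueError, match="empty"):
            nd.esu_indices(z, z, np.zeros((4, 4), dtype=bool))
        z_nat = np.zeros((4, 4)); z_nat[0, 0] = 1.0
        mask = np.zeros((4, 4), dtype=bool); mask[3, 3] = True
        with pytest.raises(ValueError, match="native"):
            nd.esu_indices(z_nat, np.ones((4, 4)), mask)


class TestEquivalencyTest:
    def test_identical_singletons_degenerate(self):
        occ = np.array([[0.3, 0.4]])
        bg = np.random.default_rng(2).normal(size=(50, 2))
        res = nd.equivalency_test(occ, occ.copy(), bg, n_perm=19, R=20, seed=0)
        assert np.allclose(res.null_Ds, res.observed_D)
        assert res.p_value == 1.0

    def test_exhaustive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        o1, o2 = rng.normal(size=(2, 2)), rng.normal(1.0, 1.0, size=(2, 2))
        bg = rng.normal(0.5, 1.5, size=(60, 2))
        res = nd.equivalency_test(o1, o2, bg, R=15, n_perm=19,
                                  method="exhaustive")
        # independent enumeration of all C(4, 2) reallocations
        pooled = np.vstack([o1, o2])
        bounds = shared_bounds(bg, pooled)
        def d_of(i1):
            i2 = [i for i in range(4) if i not in i1]
            g1 = build_density_grid(pooled[list(i1)], bg, 15, None, bounds)
            g2 = build_density_grid(pooled[i2], bg, 15, None, bounds)
            return nd.schoener_d(g1.z, g2.z)
        null = np.array([d_of(c) for c in combinations(range(4), 2)])
        assert len(res.null_Ds) == 6
        np.testing.assert_allclose(np.sort(res.null_Ds), np.sort(null),
                                   atol=1e-12)
        p_oracle = (1 + (null <= res.observed_D).sum()) / 7
        assert res.p_value == pytest.approx(p_oracle)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(4)
        o1, o2 = rng.normal(size=(8, 2)), rng.normal(size=(10, 2))
        bg = rng.normal(size=(80, 2))
        a = nd.equivalency_test(o1, o2, bg, R=20, n_perm=29, seed=7)
        b = nd.equivalency_test(o1, o2, bg, R=20, n_perm=29, seed=7)
        np.testing.assert_array_equal(a.null_Ds, b.null_Ds)
        assert a.p_value == b.p_value

    def test_p_value_in_unit_interval(self):
        rng = np.random.default_rng(5)
        res = nd.equivalency_test(rng.normal(size=(6, 2)),
                                  rng.normal(2, 1, size=(6, 2)),
                                  rng.normal(1, 2, size=(60, 2)),
                                  R=20, n_perm=19, seed=1)
        assert 0 < res.p_value <= 1


class TestSimilarityTest:
    @staticmethod
    def _grids(seed=6, R=30, sep=0.0):
        rng = np.random.default_rng(seed)
        bg = rng.normal(0, 1.5, size=(400, 2))
        o1 = rng.normal(0, 0.3, size=(40, 2))
        o2 = rng.normal(sep, 0.3, size=(40, 2))
        bounds = shared_bounds(bg, o1, o2)
        g1 = build_density_grid(o1, bg, R, None, bounds)
        g2 = build_density_grid(o2, bg, R, None, bounds)
        return g1, g2

    def test_overlapping_niches_detected_as_similar(self):
        hits = 0
        for seed in range(10):
            g1, g2 = self._grids(seed)
            res = nd.similarity_test(g1, g2, n_perm=49, seed=seed)
            hits += res.p_value <= 0.05
        assert hits >= 8

    def test_single_cell_available_space_rejected(self):
        e = np.zeros((10, 10)); e[5, 5] = 1.0
        z = e.copy()
        g = nd.EntityDensityGrid(((0.0, 1.0), (0.0, 1.0)), 10, o=z, e=e, z=z)
        with pytest.raises(ValueError):
            nd.similarity_test(g, g, n_perm=19)

    def test_shift_surface_preserves_mass_within_window(self):
        z = np.zeros((6, 6)); z[2, 3] = 2.0
        out = _shift_surface(z, (1, -2))
        assert out[3, 1] == 2.0
        assert out.sum() == 2.0
        # shifting out of the window truncates
        assert _shift_surface(z, (10, 0)).sum() == 0.0


class TestTemporalDynamics:
    def test_single_year_single_row(self):
        rng = np.random.default_rng(7)
        bg = rng.normal(size=(100, 2))
        occ = rng.normal(size=(20, 2))
        nat = build_density_grid(occ, bg, 25, None, shared_bounds(bg, occ))
        series = nd.temporal_dynamics(nat, occ, [2015] * 20, bg)
        assert len(series) == 1
        assert series.loc[0, "n_records_cumulative"] == 20

    def test_year_without_new_records_repeats_previous_row(self):
        rng = np.random.default_rng(8)
        bg = rng.normal(size=(100, 2))
        occ = rng.normal(size=(30, 2))
        years = [2014] * 15 + [2016] * 15
        nat = build_density_grid(occ, bg, 25, None, shared_bounds(bg, occ))
        series = nd.temporal_dynamics(nat, occ, years, bg,
                                      years_grid=[2014, 2015, 2016])
        r14 = series[series.year == 2014].drop(columns="year").iloc[0]
        r15 = series[series.year == 2015].drop(columns="year").iloc[0]
        pd.testing.assert_series_equal(r14, r15, check_names=False)

    def test_cumulative_counts_nondecreasing_years_increasing(self, noshift_scenario):
        scen = nd.make_invasion_scenario({
            "seed": 5, "n_rows": 32, "n_cols": 32, "n_native": 200,
            "n_invaded": 300, "introduction_cell": (16, 16),
            "spread_rate": 2.0, "years": list(range(2010, 2016))})
        res = nd.NicheShiftModel.from_scenario(scen, grid_resolution=40).fit(
            equivalency=False, similarity=False)
        t = res.temporal
        assert (np.diff(t["year"]) > 0).all()
        assert (np.diff(t["n_records_cumulative"]) >= 0).all()

    def test_no_records_at_first_year_raises(self):
        rng = np.random.default_rng(9)
        bg = rng.normal(size=(100, 2))
        occ = rng.normal(size=(10, 2))
        nat = build_density_grid(occ, bg, 25, None, shared_bounds(bg, occ))
        with pytest.raises(ValueError, match="first year"):
            nd.temporal_dynamics(nat, occ, [2015] * 10, bg,
                                 years_grid=[2014, 2015])


class TestMarginalitySweep:
    def test_single_zero_quantile_matches_direct_indices(self, noshift_scenario):
        res = nd.NicheShiftModel.from_scenario(
            noshift_scenario, grid_resolution=40).fit(
            equivalency=False, similarity=False)
        sweep = nd.marginality_sweep(res.native_grid, res.invasive_grid, [0.0])
        mask = nd.analogue_mask(res.native_grid, res.invasive_grid, 0.0)
        e, s, u = nd.esu_indices(res.native_grid.z, res.invasive_grid.z, mask)
        assert sweep.loc[0, "expansion"] == pytest.approx(e)
        assert sweep.loc[0, "unfilling"] == pytest.approx(u)

    def test_core_niche_insensitive_to_marginal_trimming(self, noshift_scenario):
        res = nd.NicheShiftModel.from_scenario(
            noshift_scenario, grid_resolution=40).fit(
            equivalency=False, similarity=False)
        sweep = nd.marginality_sweep(res.native_grid, res.invasive_grid,
                                     [0.0, 0.1, 0.2])
        assert sweep["expansion"].max() - sweep["expansion"].min() < 0.05

    def test_empty_mask_row_flagged_not_fabricated(self):
        e1 = np.zeros((10, 10)); e1[:3] = 1.0
        e2 = np.zeros((10, 10)); e2[7:] = 1.0
        g1 = nd.EntityDensityGrid(((0.0, 1.0), (0.0, 1.0)), 10, o=e1, e=e1, z=e1)
        g2 = nd.EntityDensityGrid(((0.0, 1.0), (0.0, 1.0)), 10, o=e2, e=e2, z=e2)
        sweep = nd.marginality_sweep(g1, g2, [0.0])
        assert sweep.loc[0, "flagged"]
        assert np.isnan(sweep.loc[0, "expansion"])

    def test_unordered_quantiles_rejected(self, noshift_scenario):
        res = nd.NicheShiftModel.from_scenario(
            noshift_scenario, grid_resolution=40).fit(
            equivalency=False, similarity=False)
        with pytest.raises(ValueError):
            nd.marginality_sweep(res.native_grid, res.invasive_grid, [0.2, 0.1])
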