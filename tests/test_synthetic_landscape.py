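"""Synthetic landscape and virtual-species generators."""

import numpy as np
import pytest

from disjunctsdm.synthetic_landscape import (
    CapacityError, GridGeometry, generate_climate_stack,
    generate_collinear_stack, generate_future_stack,
    future_halving_true_range, make_virtual_species, sample_occurrences,
)


class TestClimateStack:
    def test_same_seed_gives_bit_identical_stacks(self):
        a = generate_climate_stack(4, (40, 40), seed=5)
        b = generate_climate_stack(4, (40, 40), seed=5)
        assert np.array_equal(a.data, b.data)

    def test_zero_cross_correlation_is_empirically_near_zero(self):
        # short autocorrelation range so the grid holds many effective samples
        s = generate_climate_stack(4, (200, 200), autocorr_range=2.0,
                                   cross_corr=0.0, seed=7)
        env = s.env_table()
        c = np.corrcoef(env, rowvar=False)
        off = c[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.1)

    def test_requested_cross_correlation_is_recovered(self):
        s = generate_climate_stack(3, (200, 200), autocorr_range=2.0,
                                   cross_corr=0.5, seed=8)
        c = np.corrcoef(s.env_table(), rowvar=False)
        off = c[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.5, atol=0.1)

    def test_huge_autocorrelation_range_flattens_layers(self):
        smooth = generate_climate_stack(2, (50, 50), autocorr_range=500.0,
                                        seed=3, layer_means=[0, 0], layer_sds=[1, 1])
        # over-smoothed limit: layer variance far below white-noise variance 1
        assert smooth.data[0].var() < 0.05

    @pytest.mark.parametrize("kwargs", [
        dict(n_layers=1), dict(n_layers=3, shape=(0, 10)),
        dict(n_layers=3, autocorr_range=-1.0),
        dict(n_layers=3, cross_corr=-0.9),
    ])
    def test_invalid_parameters_are_rejected(self, kwargs):
        args = {"n_layers": 3, "shape": (10, 10), "seed": 0}
        args.update(kwargs)
        with pytest.raises(ValueError):
            generate_climate_stack(**args)

    def test_nodata_mask_propagates(self):
        mask = np.zeros((20, 20), bool)
        mask[:5] = True
        s = generate_climate_stack(2, (20, 20), seed=1, nodata_mask=mask)
        assert np.all(np.isnan(s.data[:, mask]))
        assert np.all(np.isfinite(s.data[:, ~mask]))


class TestFutureStack:
    def test_identity_perturbation_returns_current(self, stack):
        fut = generate_future_stack(stack, noise_sd=0.0)
        assert np.array_equal(fut.data, stack.data, equal_nan=True)
        assert fut.scenario_id == "GCM1_rcp26"

    def test_additive_offset_shifts_the_layer_mean(self, stack):
        fut = generate_future_stack(stack, offsets={"bio1": 2.0}, noise_sd=0.0)
        assert np.nanmean(fut.layer("bio1")) == pytest.approx(
            np.nanmean(stack.layer("bio1")) + 2.0)
        assert np.array_equal(fut.layer("bio2"), stack.layer("bio2"), equal_nan=True)

    def test_multiplicative_factor_scales_the_layer(self, stack):
        fut = generate_future_stack(stack, factors={"bio2": 1.1}, noise_sd=0.0)
        assert np.allclose(fut.layer("bio2"), 1.1 * stack.layer("bio2"))

    def test_two_seeds_differ_only_in_noise(self, stack):
        f1 = generate_future_stack(stack, noise_sd=0.5, seed=1)
        f2 = generate_future_stack(stack, noise_sd=0.5, seed=2)
        diff = f1.layer("bio1") - f2.layer("bio1")
        assert abs(diff.mean()) < 0.1
        assert diff.std() == pytest.approx(np.sqrt(2) * 0.5, rel=0.25)

    def test_unknown_layer_name_raises(self, stack):
        with pytest.raises(KeyError):
            generate_future_stack(stack, offsets={"bio99": 1.0})


class TestVirtualSpecies:
    def test_suitability_bounded_and_regions_disjoint(self, truth, stack):
        suit = truth.suitability(stack)
        v = suit[np.isfinite(suit)]
        assert v.min() >= 0 and v.max() <= 1
        assert not np.any(truth.region_masks["core"] & truth.region_masks["disjunct"])

    def test_regions_separated_by_the_stated_gap(self, truth, stack):
        X, _ = stack.geometry.cell_centers()
        xmax_core = X[truth.region_masks["core"]].max()
        xmin_disj = X[truth.region_masks["disjunct"]].min()
        assert xmin_disj - xmax_core >= truth.gap_km

    def test_zero_core_request_yields_only_disjunct_records(self, truth, stack):
        occ = sample_occurrences(truth, stack, 0, 20, seed=1)
        assert set(occ.df["group"]) == {"disjunct"}
        assert len(occ) == 20

    def test_occurrences_lie_inside_their_region(self, occurrences, truth, stack):
        for group in ("core", "disjunct"):
            sub = occurrences.subset(group)
            r, c = sub.rowcols(stack.geometry)
            assert truth.region_masks[group][r, c].all()
            assert not stack.nodata_mask[r, c].any()

    def test_sampling_is_suitability_biased(self, truth, stack):
        occ = sample_occurrences(truth, stack, 300, 0, seed=4)
        suit = truth.suitability(stack)
        r, c = occ.subset("core").rowcols(stack.geometry)
        region_mean = suit[truth.region_masks["core"]].mean()
        assert suit[r, c].mean() > region_mean

    def test_near_uniform_truth_samples_uniformly(self, stack):
        # effectively flat suitability: occupancy matches a uniform draw
        truth = make_virtual_species(stack, breadth_scale=1e6)
        occ = sample_occurrences(truth, stack, 2000, 0, seed=9)
        r, c = occ.subset("core").rowcols(stack.geometry)
        # chi-square GOF over column quartiles of the core region
        core_cols = np.flatnonzero(truth.region_masks["core"].any(axis=0))
        edges = np.quantile(core_cols, [0, .25, .5, .75, 1.0])
        obs, _ = np.histogram(c, bins=edges)
        from scipy.stats import chisquare
        # expected proportional to the number of region columns in each bin
        width, _ = np.histogram(core_cols, bins=edges)
        p = chisquare(obs, f_exp=width / width.sum() * obs.sum()).pvalue
        assert p > 0.01

    def test_core_mean_environment_converges_to_truth_weighted_mean(self, truth, stack):
        suit = truth.suitability(stack)
        sel = truth.region_masks["core"]
        w = np.nan_to_num(suit)[sel]
        env = stack.data[:, sel]
        target = (env * w).sum(axis=1) / w.sum()
        # modest sampling fraction: without-replacement draws stay close to
        # suitability-proportional inclusion probabilities
        occ = sample_occurrences(truth, stack, 300, 0, seed=5)
        r, c = occ.subset("core").rowcols(stack.geometry)
        sample = stack.env_at_cells(r, c)
        se = sample.std(axis=0, ddof=1) / np.sqrt(len(sample))
        assert np.all(np.abs(sample.mean(axis=0) - target) < 3 * se + 1e-9)

    def test_capacity_error_when_region_is_too_small(self, truth, stack):
        with pytest.raises(CapacityError):
            sample_occurrences(truth, stack, 10**7, 0, seed=1)


class TestCollinearStack:
    def test_two_components_explain_almost_all_variance(self):
        from disjunctsdm.env_space import pooled_pca
        s = generate_collinear_stack(6, (60, 60), seed=4)
        proj = pooled_pca([s])
        assert proj.explained_var[:2].sum() > 0.98

    def test_noise_breaks_perfect_collinearity(self):
        s = generate_collinear_stack(5, (40, 40), noise_sd=0.5, seed=4)
        corr = np.corrcoef(s.env_table().T)
        off = corr[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(off) < 0.999)

    def test_layer_units_match_requested_means_and_sds(self):
        s = generate_collinear_stack(3, (50, 50), seed=2,
                                     layer_means=[10, 20, 30],
                                     layer_sds=[1, 2, 3])
        env = s.env_table()
        assert np.allclose(env.mean(axis=0), [10, 20, 30], atol=0.5)
        assert np.allclose(env.std(axis=0), [1, 2, 3], rtol=0.05)

    def test_deterministic_and_validated(self):
        a = generate_collinear_stack(4, (30, 30), seed=7)
        b = generate_collinear_stack(4, (30, 30), seed=7)
        assert np.array_equal(a.data, b.data)
        with pytest.raises(ValueError):
            generate_collinear_stack(4, (30, 30), n_factors=5)
        with pytest.raises(ValueError):
            generate_collinear_stack(4, (30, 30), noise_sd=-0.1)


class TestThresholdSampling:
    def test_all_points_fall_inside_the_true_range(self, stack):
        wide = make_virtual_species(stack, breadth_scale=1.0,
                                    threshold_fraction=0.1)
        occ = sample_occurrences(wide, stack, 100, 20, seed=8,
                                 method="threshold")
        r, c = occ.rowcols(stack.geometry)
        assert np.all(wide.suitability(stack)[r, c] >= wide.true_threshold)

    def test_unknown_method_rejected(self, stack, truth):
        with pytest.raises(ValueError, match="method"):
            sample_occurrences(truth, stack, 10, 10, seed=1, method="bogus")


class TestOptimumPlacement:
    def test_region_anchored_optimum_is_that_regions_quantile(self, stack):
        t = make_virtual_species(stack, optimum_region="disjunct")
        sel = t.region_masks["disjunct"] & ~stack.nodata_mask
        expected = np.quantile(stack.data[:, sel].T, 0.2, axis=0)
        assert np.allclose(t.optimum, expected)

    def test_snapped_optimum_is_a_realized_cell_climate(self, stack):
        t = make_virtual_species(stack, snap_optimum=True)
        env = stack.env_table()
        match = np.all(np.isclose(env, t.optimum), axis=1)
        assert match.any()
        # and it attains (near-)maximal suitability on the landscape
        assert np.nanmax(t.suitability(stack)) == pytest.approx(1.0, abs=1e-9)

    def test_unknown_region_rejected(self, stack):
        with pytest.raises(ValueError, match="edge"):
            make_virtual_species(stack, optimum_region="edge")


class TestRangeHalvingOracle:
    def test_constructed_future_halves_the_true_range(self, stack, truth):
        fut, frac = future_halving_true_range(stack, truth)
        assert frac == pytest.approx(0.5, abs=0.01)
        cur_n = truth.true_range(stack).sum()
        assert truth.true_range(fut).sum() == pytest.approx(0.5 * cur_n, rel=0.02)

    def test_multi_layer_direction_shift_halves_the_range_too(self, stack, truth):
        env_mean = stack.env_table().mean(axis=0)
        direction = {name: float(env_mean[i] - truth.optimum[i])
                     for i, name in enumerate(stack.layer_names)}
        fut, frac = future_halving_true_range(stack, truth, direction=direction)
        assert frac == pytest.approx(0.5, abs=0.01)
        # the shift moves every layer, not just the first
        for i in range(len(stack.layer_names)):
            delta = fut.data[i] - stack.data[i]
            assert np.nanstd(delta) < 1e-9  # uniform additive shift per layer
            assert abs(np.nanmean(delta)) > 0

    def test_direction_with_unknown_layer_rejected(self, stack, truth):
        with pytest.raises(ValueError, match="unknown layers"):
            future_halving_true_range(stack, truth, direction={"bio99": 1.0})


def test_point_to_rowcol_roundtrip():
    g = GridGeometry(10, 15, 2.0, xll=100.0, yll=-50.0)
    X, Y = g.cell_centers()
    r, c = g.point_to_rowcol(X.ravel(), Y.ravel())
    assert np.array_equal(X[r, c], X.ravel())
    with pytest.raises(ValueError):
        g.point_to_rowcol(np.array([99.0]), np.array([0.0]))
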