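"""Presence-background model fitting, prediction, and cross-validation."""

import numpy as np
import pytest

from disjunctsdm.evaluation import roc_auc
from disjunctsdm.sdm_core import (DEFAULT_FEATURES, build_features,
                                  cross_validate, fit_presence_background,
                                  predict_suitability, sample_pseudoabsences)


def _niche_sample(rng, n, optimum=(0.5, -0.3), scale=0.4, extent=2.5):
    """Presences from a sharp Gaussian niche inside a uniform environment."""
    pts = rng.uniform(-extent, extent, size=(n * 40, 2))
    w = np.exp(-0.5 * (((pts - optimum) / scale) ** 2).sum(axis=1))
    idx = rng.choice(len(pts), size=n, replace=False, p=w / w.sum())
    return pts[idx]


class TestPseudoAbsences:
    def test_zero_request_gives_empty_set(self, stack):
        assert len(sample_pseudoabsences(stack, 0, seed=1)) == 0

    def test_full_request_exhausts_all_valid_cells(self):
        import disjunctsdm as d
        mask = np.zeros((20, 20), bool)
        mask[0] = True
        s = d.generate_climate_stack(2, (20, 20), seed=1, nodata_mask=mask)
        pa = sample_pseudoabsences(s, 380, seed=2)
        assert len(pa) == 380
        assert not mask[pa["row"], pa["col"]].any()
        assert len(pa.drop_duplicates(["row", "col"])) == 380

    def test_same_seed_same_cells(self, stack):
        a = sample_pseudoabsences(stack, 500, seed=3)
        b = sample_pseudoabsences(stack, 500, seed=3)
        assert a.equals(b)

    def test_overdraw_raises_with_guidance(self, stack):
        with pytest.raises(ValueError, match="reduce"):
            sample_pseudoabsences(stack, 10**7, seed=1)


class TestFit:
    def test_no_signal_data_gives_chance_discrimination(self, rng):
        pres = rng.uniform(-2, 2, size=(400, 2))
        bg = rng.uniform(-2, 2, size=(4000, 2))
        model = fit_presence_background(pres[:300], bg[:3000])
        test_scores = np.concatenate([model.predict(pres[300:]),
                                      model.predict(bg[3000:])])
        labels = np.concatenate([np.ones(100), np.zeros(1000)])
        assert roc_auc(test_scores, labels) == pytest.approx(0.5, abs=0.05)

    def test_sharp_niche_gives_high_heldout_auc(self, rng):
        pres = _niche_sample(rng, 400)
        bg = rng.uniform(-2.5, 2.5, size=(4000, 2))
        model = fit_presence_background(pres[:300], bg[:3000])
        scores = np.concatenate([model.predict(pres[300:]), model.predict(bg[3000:])])
        labels = np.concatenate([np.ones(100), np.zeros(1000)])
        assert roc_auc(scores, labels) > 0.9

    def test_huge_penalty_shrinks_to_a_flat_map(self, rng):
        pres = _niche_sample(rng, 100)
        bg = rng.uniform(-2.5, 2.5, size=(1000, 2))
        model = fit_presence_background(pres, bg, l1=1e3)
        assert np.allclose(model.coefficients[1:], 0.0, atol=1e-8)
        p = model.predict(bg)
        assert p.std() < 1e-8

    def test_duplicated_background_leaves_fit_invariant(self, rng):
        pres = _niche_sample(rng, 80)
        bg = rng.uniform(-2.5, 2.5, size=(500, 2))
        m1 = fit_presence_background(pres, bg, l1=0.05)
        m2 = fit_presence_background(pres, np.vstack([bg, bg]), l1=0.05)
        assert np.allclose(m1.coefficients, m2.coefficients, atol=1e-4)

    def test_objective_trace_is_monotone_nonincreasing(self, rng):
        pres = _niche_sample(rng, 150)
        bg = rng.uniform(-2.5, 2.5, size=(1500, 2))
        model = fit_presence_background(pres, bg)
        trace = model.training_meta["objective_trace"]
        assert np.all(np.diff(trace) <= 1e-12)
        assert model.training_meta["converged"]

    def test_implied_optimum_recovers_truth(self, rng):
        """Log-quadratic truth: the fitted vertex sits near the true optimum."""
        opt = np.array([0.6, -0.4])
        pres = _niche_sample(rng, 500, optimum=opt, scale=0.5)
        bg = rng.uniform(-2.5, 2.5, size=(5000, 2))
        model = fit_presence_background(pres, bg)
        axis_sd = bg.std(axis=0)
        assert np.all(np.abs(model.implied_optimum() - opt) < 0.3 * axis_sd)

    def test_nonconvergence_is_flagged_not_silent(self, rng):
        pres = _niche_sample(rng, 50)
        bg = rng.uniform(-2.5, 2.5, size=(500, 2))
        model = fit_presence_background(pres, bg, max_iter=3)
        assert model.training_meta["converged"] is False

    def test_too_few_presences_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_presence_background(rng.normal(size=(5, 2)),
                                    rng.normal(size=(100, 2)))

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            build_features(np.zeros((3, 2)), ["pc1", "pc3^5"])


class TestPredict:
    def test_zero_coefficients_give_constant_map(self, rng):
        from disjunctsdm.sdm_core import SDMModel
        model = SDMModel(DEFAULT_FEATURES, np.array([0.7, 0, 0, 0, 0, 0.0]),
                         0.1, np.zeros(5), np.ones(5))
        scores = rng.normal(size=(2, 8, 9))
        out = predict_suitability(model, scores, "s")
        assert np.allclose(out.values, 1 / (1 + np.exp(-0.7)))

    def test_logistic_link_is_monotone_in_the_linear_predictor(self, rng):
        pres = _niche_sample(rng, 100)
        bg = rng.uniform(-2.5, 2.5, size=(1000, 2))
        model = fit_presence_background(pres, bg)
        eta = model.linear_predictor(bg)
        p = model.predict(bg)
        order = np.argsort(eta)
        assert np.all(np.diff(p[order]) >= 0)

    def test_nodata_cells_propagate(self, rng):
        pres = _niche_sample(rng, 60)
        bg = rng.uniform(-2.5, 2.5, size=(600, 2))
        model = fit_presence_background(pres, bg)
        scores = rng.normal(size=(2, 5, 5))
        scores[:, 0, 0] = np.nan
        out = predict_suitability(model, scores, "s")
        assert np.isnan(out.values[0, 0])
        assert np.isfinite(out.values[1:]).all()

    def test_presence_centroid_outscores_median_background(self, rng):
        pres = _niche_sample(rng, 300)
        bg = rng.uniform(-2.5, 2.5, size=(3000, 2))
        model = fit_presence_background(pres, bg)
        at_centroid = model.predict(pres.mean(axis=0)[None, :])[0]
        assert at_centroid >= np.median(model.predict(bg))


class TestCrossValidate:
    def test_split_sizes_match_the_holdout_fraction(self, rng):
        pres = _niche_sample(rng, 100)
        bg = rng.uniform(-2.5, 2.5, size=(1000, 2))
        runs = cross_validate(pres, bg, n_rep=10, test_frac=0.3, seed=1)
        assert len(runs) == 10
        for run in runs:
            assert len(run.test_presences) == 30
            assert len(run.test_background) == 300
            assert run.model.training_meta["n_presence"] == 70

    def test_each_split_partitions_the_presences(self, rng):
        pres = _niche_sample(rng, 60)
        bg = rng.uniform(-2.5, 2.5, size=(600, 2))
        runs = cross_validate(pres, bg, n_rep=3, seed=2)
        all_rows = {tuple(p) for p in pres}
        for run in runs:
            test_rows = {tuple(p) for p in run.test_presences}
            assert test_rows <= all_rows
            assert len(test_rows) == len(run.test_presences)

    def test_same_seed_reproduces_the_split_sequence(self, rng):
        pres = _niche_sample(rng, 60)
        bg = rng.uniform(-2.5, 2.5, size=(600, 2))
        r1 = cross_validate(pres, bg, n_rep=3, seed=3)
        r2 = cross_validate(pres, bg, n_rep=3, seed=3)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.test_presences, b.test_presences)
            assert np.array_equal(a.model.coefficients, b.model.coefficients)

    def test_too_few_presences_named_in_error(self, rng):
        with pytest.raises(ValueError, match="10"):
            cross_validate(rng.normal(size=(12, 2)), rng.normal(size=(100, 2)),
                           n_rep=2, test_frac=0.3, seed=1)
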