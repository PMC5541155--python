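"""Subspace LK search, MAP shape fusion, and the alternating explicit fit."""

import numpy as np
import pytest
from scipy.optimize import minimize

import dap
from dap.appearance import Shape
from dap.explicit import (
    ExplicitFitter,
    LandmarkPrediction,
    fit_explicit,
    lk_search,
    map_energy,
    map_shape,
    project_orthogonal,
)
from dap.priors import ShapeModel

from conftest import translate_periodic


class TestProjectOrthogonal:
    @pytest.fixture()
    def model(self, wavelet_model):
        return wavelet_model.appearance_model

    def test_span_maps_to_zero(self, model):
        a = model.components @ np.arange(1.0, model.n_components + 1)
        assert np.linalg.norm(project_orthogonal(model, a)) < 1e-9

    def test_orthogonal_vector_unchanged(self, model):
        rng = np.random.default_rng(0)
        a = rng.normal(size=model.dim)
        a_perp = project_orthogonal(model, a)
        assert np.allclose(project_orthogonal(model, a_perp), a_perp, atol=1e-10)

    def test_idempotent(self, model):
        rng = np.random.default_rng(1)
        a = rng.normal(size=model.dim)
        once = project_orthogonal(model, a)
        assert np.abs(project_orthogonal(model, once) - once).max() < 1e-10

    def test_length_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            project_orthogonal(model, np.zeros(3))


class TestLKSearch:
    def test_zero_residual_stays_put(self, shift_fixture):
        # searching the very image the template was built from, starting at
        # the true landmark: first step below tolerance, prediction = x0
        base, pts, model = shift_fixture
        pyr = model.geometry.build_pyramid(base)
        pred = lk_search(pyr, model, pts[4], 4, 1, max_iter=30, tol=1e-3)
        assert pred.converged and pred.iterations == 1
        assert np.allclose(pred.x, pts[4], atol=1e-6)

    def test_known_subpixel_shift_recovered(self, shift_fixture):
        base, pts, model = shift_fixture
        shift = np.array([1.2, -0.7])
        pyr = model.geometry.build_pyramid(translate_periodic(base, shift))
        pred = lk_search(pyr, model, pts[4], 4, 1, max_iter=60, tol=1e-4)
        assert np.linalg.norm(pred.x - (pts[4] + shift)) < 0.1

    def test_quarter_patch_shifts_recovered(self, shift_fixture):
        # shifts up to 25% of the patch width, noise-free: < 0.2 px error
        base, pts, model = shift_fixture
        rng = np.random.default_rng(11)
        fitter = ExplicitFitter(model)
        errs = []
        for _ in range(20):
            shift = rng.uniform(-4.25, 4.25, size=2)
            pyr = model.geometry.build_pyramid(translate_periodic(base, shift))
            n = int(rng.integers(0, len(pts)))
            pred = fitter.search(pyr, pts[n], n, 1, max_iter=60, tol=1e-4)
            errs.append(np.linalg.norm(pred.x - (pts[n] + shift)))
        assert np.mean(np.array(errs) < 0.2) >= 0.95

    def test_flat_patch_keeps_position_with_high_variance(self, shift_fixture):
        # a textureless observation has no gradient signal: the template
        # pseudo-inverse yields no update and the residual flags no salience
        base, pts, model = shift_fixture
        flat = np.full_like(base, 0.5)
        pyr = model.geometry.build_pyramid(flat)
        pred = lk_search(pyr, model, pts[4], 4, 1, max_iter=30, tol=1e-3)
        assert np.allclose(pred.x, pts[4], atol=1e-6)
        assert pred.sigma2 > 0.1  # far above the 1e-6 floor


def _random_instance(rng, N=5, t=3, levels=(1, 2), full_rank=False):
    dim = 2 * N
    t_eff = dim if full_rank else t
    Q, _ = np.linalg.qr(rng.normal(size=(dim, t_eff)))
    sm = ShapeModel(
        mean=rng.normal(size=dim) * 5,
        components=Q,
        eigenvalues=np.sort(rng.uniform(0.5, 4.0, t_eff))[::-1],
        mean_centroid=np.zeros(2),
    )
    preds = {
        (n, l): LandmarkPrediction(
            x=rng.normal(size=2) * 3,
            sigma2=float(rng.uniform(0.1, 2.0)),
            converged=True,
            iterations=1,
        )
        for n in range(N)
        for l in levels
    }
    return sm, preds


class TestMapShape:
    def test_prior_dominates_with_huge_variances(self):
        rng = np.random.default_rng(2)
        sm, preds = _random_instance(rng, full_rank=True)
        for p in preds.values():
            p.sigma2 = 1e12
        s = map_shape(sm, preds)
        assert np.allclose(s.as_vector(), sm.mean, atol=1e-5)

    def test_observation_dominates_without_prior(self):
        rng = np.random.default_rng(3)
        _, preds = _random_instance(rng, levels=(1,))
        s = map_shape(None, preds)
        for n in range(5):
            assert np.allclose(s.points[n], preds[(n, 1)].x, atol=1e-12)

    def test_matches_numerical_minimizer(self):
        rng = np.random.default_rng(4)
        for _ in range(8):
            sm, preds = _random_instance(rng)
            s_map = map_shape(sm, preds)
            res = minimize(
                lambda v: map_energy(sm, preds, Shape.from_vector(v)),
                sm.mean,
                method="BFGS",
                options={"gtol": 1e-12, "maxiter": 5000},
            )
            assert np.abs(s_map.as_vector() - res.x).max() < 1e-6

    def test_variance_rescaling_invariance_without_prior(self):
        rng = np.random.default_rng(5)
        _, preds = _random_instance(rng)
        s1 = map_shape(None, preds)
        for p in preds.values():
            p.sigma2 *= 37.5
        s2 = map_shape(None, preds)
        assert np.allclose(s1.as_vector(), s2.as_vector(), atol=1e-9)

    def test_fused_energy_below_single_scale_shapes(self):
        rng = np.random.default_rng(6)
        sm, preds = _random_instance(rng)
        fused = map_shape(sm, preds)
        e_fused = map_energy(sm, preds, fused)
        for l in (1, 2):
            s_l = Shape(np.array([preds[(n, l)].x for n in range(5)]))
            assert e_fused <= map_energy(sm, preds, s_l) + 1e-12

    def test_trimmed_levels_contribute_nothing(self):
        rng = np.random.default_rng(7)
        sm, preds = _random_instance(rng)
        full = map_shape(sm, preds)
        # adding a dummy prediction with infinite variance changes nothing
        preds[(0, 3)] = LandmarkPrediction(
            x=np.array([1e3, 1e3]), sigma2=1e15, converged=True, iterations=1
        )
        almost = map_shape(sm, preds)
        assert np.allclose(full.as_vector(), almost.as_vector(), atol=1e-6)


class TestFitExplicit:
    def test_zero_outer_iterations_returns_init(self, gaussian_model, population):
        img = population.images[0]
        pyr = gaussian_model.geometry.build_pyramid(img)
        s0 = gaussian_model.shape_model.mean_shape()
        s, state = fit_explicit(pyr, gaussian_model, s0, outer_iters=0)
        assert np.array_equal(s.points, s0.points)
        assert state.energies == []

    def test_truth_is_near_fixed_point_on_training_image(
        self, gaussian_model, population
    ):
        i = 3  # a training image
        pyr = gaussian_model.geometry.build_pyramid(population.images[i])
        truth = population.shapes[i]
        s, _ = fit_explicit(pyr, gaussian_model, truth, outer_iters=2)
        drift = np.mean(np.linalg.norm(s.points - truth.points, axis=1))
        assert drift < 0.5

    def test_recovery_improves_on_mean_shape_init(
        self, gaussian_model, population, test_indices
    ):
        s0 = gaussian_model.shape_model.mean_shape()
        wins = 0
        subset = test_indices[:10]
        for i in subset:
            pyr = gaussian_model.geometry.build_pyramid(population.images[i])
            s, _ = fit_explicit(pyr, gaussian_model, s0, outer_iters=8)
            t = population.shapes[i].points
            e0 = np.mean(np.linalg.norm(s0.points - t, axis=1))
            e1 = np.mean(np.linalg.norm(s.points - t, axis=1))
            wins += e1 < e0
        assert wins >= 9
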