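"""Stage-2 linear parameter evolution and surface reconstruction."""

import numpy as np
import pytest

from underice import (
    CTypeParams,
    DegenerateDesignError,
    LinearLaw,
    ParamEvolution,
    ValidationError,
    evaluate_profile,
    fit_linear_evolution,
    fit_param_evolution,
    predict_params,
    reconstruct_surface,
)


def brute_force_line(times, values, span=2.0, resolution=1e-4):
    """Independent OLS oracle: nested grid search over (alpha, beta).

    Starts from a coarse grid spanning the pairwise-slope range and
    refines around the incumbent until the requested resolution.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    slopes = [
        (y[j] - y[i]) / (t[j] - t[i])
        for i in range(len(t))
        for j in range(i + 1, len(t))
        if t[j] != t[i]
    ]
    a_lo, a_hi = min(slopes) - span, max(slopes) + span
    b_lo, b_hi = y.min() - span * (1 + abs(t).max()), y.max() + span * (1 + abs(t).max())

    def rss(alpha, beta):
        r = y[None, None, :] - (alpha[:, :, None] * t[None, None, :] + beta[:, :, None])
        return np.sum(r**2, axis=-1)

    best = None
    while True:
        alphas = np.linspace(a_lo, a_hi, 41)
        betas = np.linspace(b_lo, b_hi, 41)
        A, B = np.meshgrid(alphas, betas, indexing="ij")
        cost = rss(A, B)
        i, j = np.unravel_index(np.argmin(cost), cost.shape)
        best = (alphas[i], betas[j])
        da, db = alphas[1] - alphas[0], betas[1] - betas[0]
        if da <= resolution and db <= resolution:
            return best
        a_lo, a_hi = best[0] - 2 * da, best[0] + 2 * da
        b_lo, b_hi = best[1] - 2 * db, best[1] + 2 * db


class TestFitLinearEvolution:
    @pytest.mark.parametrize(
        "times, values, alpha, beta",
        [
            ((10, 20, 30), (21, 41, 61), 2.0, 1.0),
            ((10, 20, 30), (5, 5, 5), 0.0, 5.0),
            ((0, 1, 2), (0, 1, 1), 0.5, 1.0 / 6.0),
        ],
    )
    def test_closed_form_cases(self, times, values, alpha, beta):
        law = fit_linear_evolution(times, values)
        assert law.alpha == pytest.approx(alpha, abs=1e-12)
        assert law.beta == pytest.approx(beta, abs=1e-12)

    def test_matches_brute_force_grid(self, rng):
        for _ in range(10):
            n = rng.integers(3, 9)
            t = np.sort(rng.uniform(0, 10, n))
            y = rng.uniform(-2, 2) * t + rng.uniform(-2, 2) + rng.normal(0, 0.3, n)
            law = fit_linear_evolution(t, y)
            alpha, beta = brute_force_line(t, y)
            assert law.alpha == pytest.approx(alpha, abs=5e-4)
            assert law.beta == pytest.approx(beta, abs=5e-4)

    def test_identical_times_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            fit_linear_evolution([5, 5, 5], [1, 2, 3])

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            fit_linear_evolution([1, 2, 3], [1, 2])


def constant_evolution(a=4.0, b=-0.02, c=1.0, d=0.01, metal=None):
    return ParamEvolution(
        LinearLaw(0.0, a), LinearLaw(0.0, b), LinearLaw(0.0, c), LinearLaw(0.0, d),
        metal=metal,
    )


class TestPredictParams:
    def test_zero_slopes_give_intercepts_everywhere(self):
        evo = constant_evolution()
        for t in (0.0, 31.0, 130.0):
            p = predict_params(evo, t)
            assert (p.a, p.b, p.c, p.d) == (4.0, -0.02, 1.0, 0.01)

    def test_origin_returns_intercepts(self):
        evo = ParamEvolution(
            LinearLaw(0.01, 4.0), LinearLaw(1e-4, -0.02),
            LinearLaw(0.002, 1.0), LinearLaw(1e-5, 0.01),
        )
        p = predict_params(evo, 0.0)
        assert (p.a, p.b, p.c, p.d) == (4.0, -0.02, 1.0, 0.01)

    def test_linear_arithmetic(self):
        evo = ParamEvolution(
            LinearLaw(0.01, 4.0), LinearLaw(0.0, -0.02),
            LinearLaw(0.0, 1.0), LinearLaw(0.0, 0.01),
        )
        assert predict_params(evo, 50.0).a == pytest.approx(4.5)

    def test_enforces_canonical_ordering(self):
        # lines that cross: by t=100 the 'b' line exceeds the 'd' line,
        # so the prediction must come back swapped
        evo = ParamEvolution(
            LinearLaw(0.0, 4.0), LinearLaw(1e-3, -0.02),
            LinearLaw(0.0, 1.0), LinearLaw(0.0, 0.01),
        )
        p = predict_params(evo, 100.0)
        assert p.b <= p.d

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            predict_params(constant_evolution(), -1.0)


class TestReconstructSurface:
    def test_cell_is_direct_composition(self):
        evo = ParamEvolution(
            LinearLaw(0.01, 4.0), LinearLaw(-1e-5, -0.02),
            LinearLaw(0.002, 1.0), LinearLaw(1e-5, 0.01),
        )
        depth_axis = [2.5, 50.0, 147.5]
        time_axis = [64.0, 100.0]
        surface = reconstruct_surface(evo, depth_axis, time_axis)
        expected = evaluate_profile(predict_params(evo, 100.0), 50.0)
        assert surface.value_at(50.0, 100.0) == pytest.approx(expected, rel=1e-14)

    def test_zero_slope_evolution_is_time_invariant(self):
        surface = reconstruct_surface(
            constant_evolution(), np.arange(2.5, 150, 5.0), [10.0, 50.0, 90.0]
        )
        assert np.allclose(surface.values[:, 0], surface.values[:, 1])
        assert np.allclose(surface.values[:, 0], surface.values[:, 2])

    def test_default_axes_cell_count(self):
        surface = reconstruct_surface(
            constant_evolution(),
            np.arange(2.5, 150, 5.0),
            np.arange(64.0, 131.0, 1.0),
        )
        assert surface.values.size == 30 * 67 == 2010

    def test_amplitude_intercept_shift_is_exact(self):
        """With the b-evolution frozen at zero, raising beta_a by delta
        raises every surface cell by exactly delta (e^{0 h} = 1)."""
        delta = 0.37
        base = ParamEvolution(
            LinearLaw(0.01, 4.0), LinearLaw(0.0, 0.0),
            LinearLaw(0.0, 1.0), LinearLaw(0.0, 0.01),
        )
        shifted = ParamEvolution(
            LinearLaw(0.01, 4.0 + delta), LinearLaw(0.0, 0.0),
            LinearLaw(0.0, 1.0), LinearLaw(0.0, 0.01),
        )
        h = np.arange(2.5, 150, 5.0)
        t = [64.0, 100.0, 130.0]
        s0 = reconstruct_surface(base, h, t)
        s1 = reconstruct_surface(shifted, h, t)
        assert np.allclose(s1.values - s0.values, delta, rtol=0, atol=1e-12)

    @pytest.mark.parametrize(
        "depths, times",
        [([], [1.0]), ([1.0], []), ([2.0, 1.0], [1.0]), ([1.0], [2.0, 1.0])],
    )
    def test_axis_validation(self, depths, times):
        with pytest.raises(ValidationError):
            reconstruct_surface(constant_evolution(), depths, times)


class TestTwoStageRecovery:
    def test_zero_noise_recovers_true_evolutions(self, small_zero_noise,
                                                 small_zero_noise_result):
        """Fit per date then regress per parameter: on noiseless data the
        whole two-stage pipeline must return the generating coefficients."""
        cfg, _ = small_zero_noise
        res = small_zero_noise_result
        for metal, evo in res.evolutions.items():
            truth = cfg.true_evolutions[metal]
            for name in "abcd":
                for attr in ("alpha", "beta"):
                    est = getattr(evo.law(name), attr)
                    tru = getattr(truth.law(name), attr)
                    assert est == pytest.approx(tru, rel=1e-3), (metal, name, attr)

    def test_stage2_ordering_is_consistent(self, small_zero_noise_result):
        fits = small_zero_noise_result.fits
        assert (fits["b"] <= fits["d"]).all()


def test_fit_param_evolution_canonicalises_before_regression():
    # one date reported with swapped terms must not corrupt the lines
    times = [10.0, 20.0, 30.0]
    canon = [CTypeParams(5.0, -0.05, 0.5, 0.02)] * 3
    mixed = [canon[0], CTypeParams(0.5, 0.02, 5.0, -0.05), canon[2]]
    evo_c = fit_param_evolution(times, canon)
    evo_m = fit_param_evolution(times, mixed)
    for name in "abcd":
        assert evo_m.law(name) == evo_c.law(name)
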