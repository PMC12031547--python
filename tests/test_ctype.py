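"""Biexponential profile model: evaluation, minimum, and identification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from underice import (
    CTypeParams,
    NonConvergenceError,
    Profile,
    ValidationError,
    evaluate_profile,
    fit_profile,
    profile_minimum,
)

DEPTHS_30 = np.arange(2.5, 150.0, 5.0)


def make_profile(params: CTypeParams, depths=DEPTHS_30, metal="As", time=64.0):
    return Profile(
        metal=metal,
        time=time,
        depths=depths,
        concentrations=evaluate_profile(params, depths),
    )


class TestEvaluateProfile:
    @pytest.mark.parametrize(
        "params, h, expected",
        [
            (CTypeParams(1, 0, 1, 0), 37.0, 2.0),
            (CTypeParams(0, -0.3, 0, 0.4), 12.0, 0.0),
            (CTypeParams(5.0, -0.05, 0.5, 0.02), 10.0, 3.6434),
        ],
    )
    def test_point_values(self, params, h, expected):
        assert evaluate_profile(params, h) == pytest.approx(expected, abs=1e-4)

    def test_vectorised_over_depth(self):
        p = CTypeParams(2.0, -0.01, 1.0, 0.02)
        h = np.array([0.0, 10.0, 20.0])
        out = evaluate_profile(p, h)
        assert out.shape == h.shape
        assert out[0] == pytest.approx(p.a + p.c)

    @given(
        a=st.floats(0, 50),
        b=st.floats(-0.5, 0.5),
        c=st.floats(0, 50),
        d=st.floats(-0.5, 0.5),
    )
    def test_surface_value_is_sum_of_amplitudes(self, a, b, c, d):
        # at the ice-water interface the exponentials are 1, so HM(0) = a + c
        assert evaluate_profile(CTypeParams(a, b, c, d), 0.0) == pytest.approx(a + c)


class TestCanonicalOrdering:
    def test_swaps_terms_when_b_exceeds_d(self):
        p = CTypeParams(0.5, 0.02, 5.0, -0.05).canonical()
        assert (p.a, p.b, p.c, p.d) == (5.0, -0.05, 0.5, 0.02)

    def test_idempotent(self):
        p = CTypeParams(5.0, -0.05, 0.5, 0.02)
        assert p.canonical() == p

    @given(
        a=st.floats(0, 10), b=st.floats(-0.4, 0.4),
        c=st.floats(0, 10), d=st.floats(-0.4, 0.4),
        h=st.floats(0, 150),
    )
    def test_preserves_profile_values(self, a, b, c, d, h):
        p = CTypeParams(a, b, c, d)
        assert evaluate_profile(p.canonical(), h) == pytest.approx(
            evaluate_profile(p, h), rel=1e-12, abs=1e-12
        )


class TestProfileMinimum:
    def test_symmetric_terms_put_minimum_at_origin(self):
        h_star, value = profile_minimum(CTypeParams(1.0, -0.07, 1.0, 0.07))
        assert h_star == pytest.approx(0.0, abs=1e-12)
        assert value == pytest.approx(2.0)

    def test_closed_form_interior_minimum(self):
        h_star, value = profile_minimum(CTypeParams(5.0, -0.05, 0.5, 0.02))
        assert h_star == pytest.approx(45.98, abs=0.01)
        assert value == pytest.approx(
            evaluate_profile(CTypeParams(5.0, -0.05, 0.5, 0.02), h_star)
        )

    @pytest.mark.parametrize(
        "params",
        [
            CTypeParams(1.0, 0.01, 1.0, 0.02),   # both terms increasing
            CTypeParams(1.0, -0.02, 1.0, -0.01),  # both terms decreasing
            CTypeParams(0.0, -0.05, 1.0, 0.02),   # vanished first amplitude
        ],
    )
    def test_no_interior_minimum(self, params):
        assert profile_minimum(params) is None

    def test_agrees_with_grid_search(self, rng):
        """Convexity makes the stationary point the unique minimum; a
        0.001 cm brute-force grid over the column must agree."""
        grid = np.arange(0.0, 300.0, 0.001)
        for _ in range(100):
            params = CTypeParams(
                a=rng.uniform(0.1, 10),
                b=rng.uniform(-0.3, 0.3),
                c=rng.uniform(0.1, 10),
                d=rng.uniform(-0.3, 0.3),
            )
            values = evaluate_profile(params, grid)
            k = int(np.argmin(values))
            result = profile_minimum(params)
            if result is None:
                # minimum must sit on the domain boundary
                assert k in (0, grid.size - 1)
            else:
                h_star, v_star = result
                if h_star < 299.0:
                    assert abs(grid[k] - h_star) <= 0.001
                    assert v_star == pytest.approx(values[k], rel=1e-6)


class TestFitProfile:
    def test_recovers_noiseless_parameters(self):
        truth = CTypeParams(5.0, -0.05, 0.5, 0.02)
        params, diag = fit_profile(make_profile(truth))
        assert diag.converged
        for name in "abcd":
            est, tru = getattr(params, name), getattr(truth, name)
            assert est == pytest.approx(tru, rel=1e-3)

    def test_constant_profile_is_representable(self):
        v = 3.7
        profile = Profile("Fe", 80.0, DEPTHS_30, np.full(DEPTHS_30.size, v))
        params, diag = fit_profile(profile)
        assert diag.residual_sum_of_squares <= 1e-6
        assert evaluate_profile(params, 0.0) == pytest.approx(v, abs=1e-3)

    def test_term_permutation_gives_canonical_result(self):
        # data generated with the terms written in swapped order is the
        # same curve; the fit must come back in canonical ordering
        swapped = CTypeParams(0.5, 0.02, 5.0, -0.05)
        params, _ = fit_profile(make_profile(swapped))
        assert params.b <= params.d
        assert params.a == pytest.approx(5.0, rel=1e-3)
        assert params.b == pytest.approx(-0.05, rel=1e-3)
        assert params.c == pytest.approx(0.5, rel=1e-3)
        assert params.d == pytest.approx(0.02, rel=1e-3)

    def test_invariant_to_sample_order(self, rng):
        truth = CTypeParams(4.0, -0.03, 1.0, 0.01)
        conc = evaluate_profile(truth, DEPTHS_30) * (
            1 + 0.05 * rng.standard_normal(DEPTHS_30.size)
        )
        order = rng.permutation(DEPTHS_30.size)
        p1 = Profile("Cu", 90.0, DEPTHS_30, conc)
        p2 = Profile("Cu", 90.0, DEPTHS_30[order], conc[order])
        r1, _ = fit_profile(p1)
        r2, _ = fit_profile(p2)
        assert r1 == r2

    def test_no_worse_than_generating_truth(self, rng):
        """The multi-start optimizer must match or beat the true
        parameters' residual on noisy synthetic profiles."""
        truth = CTypeParams(5.0, -0.02, 1.5, 0.01)
        for _ in range(10):
            conc = evaluate_profile(truth, DEPTHS_30) * (
                1 + 0.05 * rng.standard_normal(DEPTHS_30.size)
            )
            profile = Profile("As", 100.0, DEPTHS_30, conc)
            _, diag = fit_profile(profile)
            rss_truth = float(
                np.sum((evaluate_profile(truth, DEPTHS_30) - conc) ** 2)
            )
            assert diag.residual_sum_of_squares <= rss_truth + 1e-12

    def test_rejects_short_profiles(self):
        profile = Profile("As", 64.0, DEPTHS_30[:5],
                          np.ones(5))
        with pytest.raises(ValidationError, match="at least 6"):
            fit_profile(profile)


class TestProfileValidation:
    def test_normalises_sample_order(self):
        p = Profile("As", 64.0, [10.0, 5.0, 20.0], [1.0, 2.0, 3.0])
        assert list(p.depths) == [5.0, 10.0, 20.0]
        assert list(p.concentrations) == [2.0, 1.0, 3.0]

    @pytest.mark.parametrize(
        "depths, conc, match",
        [
            ([5.0, 5.0, 10.0], [1, 1, 1], "duplicate"),
            ([-5.0, 5.0, 10.0], [1, 1, 1], "> 0 cm"),
            ([5.0, 10.0, 15.0], [1, -1, 1], ">= 0"),
        ],
    )
    def test_rejects_bad_samples(self, depths, conc, match):
        with pytest.raises(ValidationError, match=match):
            Profile("As", 64.0, depths, conc)
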