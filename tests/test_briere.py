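"""Analytic identities and invariants of the modified Briere curve."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thermoniche.briere import (
    CanonicalBriereParams,
    DegenerateShapeError,
    NaturalBriereParams,
    ParameterDomainError,
    briere_modified,
    briere_original,
    canonical_evaluate,
    half_max_temperatures,
    niche_summary,
    optimal_temperature,
    to_canonical,
    to_natural,
)

from conftest import random_natural_params


def natural_params_strategy():
    return st.builds(
        lambda t_min, span, log_c, a, b: NaturalBriereParams(
            c=10.0**log_c, t_min=t_min, t_max=t_min + span, a=a, b=b
        ),
        t_min=st.floats(-5.0, 20.0),
        span=st.floats(15.0, 40.0),
        log_c=st.floats(-5.0, -1.0),
        a=st.floats(0.2, 5.0),
        b=st.floats(0.2, 5.0),
    )


class TestOriginalBriere:
    def test_boundary_zeros(self):
        assert briere_original(10.0, c=1e-4, t_min=10, t_max=40) == 0.0
        assert briere_original(40.0, c=1e-4, t_min=10, t_max=40) == 0.0

    def test_arithmetic_value(self):
        # 1e-4 * 30 * 20 * sqrt(10)
        expected = 1e-4 * 30 * 20 * np.sqrt(10.0)
        assert briere_original(30.0, c=1e-4, t_min=10, t_max=40) == pytest.approx(
            expected, rel=1e-12
        )

    def test_outside_range_is_zero(self):
        assert briere_original(5.0, c=1e-4, t_min=10, t_max=40) == 0.0
        assert briere_original(45.0, c=1e-4, t_min=10, t_max=40) == 0.0

    def test_invalid_parameters_raise(self):
        with pytest.raises(ParameterDomainError):
            briere_original(30.0, c=1e-4, t_min=40, t_max=10)
        with pytest.raises(ParameterDomainError):
            briere_original(30.0, c=-1.0, t_min=10, t_max=40)


class TestModifiedBriere:
    def test_boundary_and_outside_zeros(self):
        p = NaturalBriereParams(c=2e-3, t_min=5, t_max=45, a=2, b=1)
        assert briere_modified(5.0, p) == 0.0
        assert briere_modified(45.0, p) == 0.0
        assert briere_modified(-10.0, p) == 0.0
        assert briere_modified(60.0, p) == 0.0

    def test_arithmetic_value(self):
        p = NaturalBriereParams(c=2e-3, t_min=5, t_max=45, a=2, b=1)
        assert briere_modified(30.0, p) == pytest.approx(2e-3 * 25**2 * 15, rel=1e-12)

    def test_equal_exponents_peak_at_midpoint(self):
        p = NaturalBriereParams(c=1e-3, t_min=10, t_max=40, a=1, b=1)
        assert optimal_temperature(p) == pytest.approx(25.0)
        grid = np.linspace(10, 40, 1001)
        assert grid[np.argmax(briere_modified(grid, p))] == pytest.approx(25.0, abs=0.05)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(DegenerateShapeError):
            NaturalBriereParams(c=1e-3, t_min=10, t_max=40, a=0, b=0)

    def test_one_sided_shape_allowed(self):
        p = NaturalBriereParams(c=1e-3, t_min=10, t_max=40, a=0, b=2)
        # a=0: the curve stays positive arbitrarily close to the cold limit
        assert briere_modified(10.0 + 1e-9, p) == pytest.approx(1e-3 * 30**2, rel=1e-6)
        assert briere_modified(10.0, p) == 0.0  # boundary convention
        assert briere_modified(40.0, p) == 0.0


class TestParametrizations:
    def test_alpha_s_formulas(self):
        p = NaturalBriereParams(c=1e-3, t_min=10, t_max=45, a=2, b=1)
        cp = to_canonical(p)
        assert cp.alpha == pytest.approx(2.0 / 3.0, rel=1e-12)
        assert cp.s == pytest.approx(3.0, rel=1e-12)

    def test_topt_closed_form(self):
        p = NaturalBriereParams(c=1e-3, t_min=10, t_max=45, a=2, b=1)
        assert optimal_temperature(p) == pytest.approx((2 / 3) * 45 + (1 / 3) * 10)

    def test_topt_alpha_limit(self):
        p = CanonicalBriereParams(g_max=1.0, alpha=0.999999, s=3, t_min=10, t_max=45)
        assert optimal_temperature(p) == pytest.approx(45.0, abs=1e-3)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=natural_params_strategy())
    def test_round_trip_identity(self, p):
        q = to_natural(to_canonical(p))
        assert q.c == pytest.approx(p.c, rel=1e-10)
        assert q.a == pytest.approx(p.a, rel=1e-10)
        assert q.b == pytest.approx(p.b, rel=1e-10)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=natural_params_strategy())
    def test_forms_agree_pointwise(self, p):
        cp = to_canonical(p)
        grid = np.linspace(p.t_min, p.t_max, 101)
        np.testing.assert_allclose(
            canonical_evaluate(grid, cp), briere_modified(grid, p), rtol=1e-10, atol=1e-300
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=natural_params_strategy())
    def test_peak_identity(self, p):
        cp = to_canonical(p)
        assert canonical_evaluate(optimal_temperature(cp), cp) == pytest.approx(
            cp.g_max, rel=1e-12
        )


class TestNiche:
    def test_topt_matches_grid_argmax_on_random_draws(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = random_natural_params(rng)
            grid = np.linspace(p.t_min, p.t_max, 4001)
            step = grid[1] - grid[0]
            assert abs(optimal_temperature(p) - grid[np.argmax(briere_modified(grid, p))]) <= step

    def test_half_max_roots_hit_target(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = to_canonical(random_natural_params(rng))
            lo, hi = half_max_temperatures(p, 0.5)
            assert canonical_evaluate(lo, p) == pytest.approx(0.5 * p.g_max, rel=1e-5)
            assert canonical_evaluate(hi, p) == pytest.approx(0.5 * p.g_max, rel=1e-5)

    def test_half_max_agrees_with_grid_scan(self):
        p = CanonicalBriereParams(g_max=0.5, alpha=0.7, s=4.0, t_min=10, t_max=47)
        grid = np.linspace(10, 47, 10**6)
        vals = canonical_evaluate(grid, p)
        above = grid[vals >= 0.5 * p.g_max]
        lo, hi = half_max_temperatures(p, 0.5)
        res = grid[1] - grid[0]
        assert abs(lo - above[0]) <= 2 * res
        assert abs(hi - above[-1]) <= 2 * res

    def test_fraction_one_collapses_to_peak(self):
        p = CanonicalBriereParams(g_max=1.0, alpha=0.6, s=3, t_min=0, t_max=40)
        lo, hi = half_max_temperatures(p, 1.0)
        assert lo == hi == pytest.approx(optimal_temperature(p))

    def test_symmetric_curve_symmetric_roots(self):
        p = CanonicalBriereParams(g_max=1.0, alpha=0.5, s=3, t_min=10, t_max=40)
        lo, hi = half_max_temperatures(p, 0.5)
        t_opt = optimal_temperature(p)
        assert t_opt - lo == pytest.approx(hi - t_opt, abs=1e-4)

    def test_fraction_domain_error(self):
        p = CanonicalBriereParams(g_max=1.0, alpha=0.5, s=3, t_min=10, t_max=40)
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                half_max_temperatures(p, bad)

    def test_breadth_decreases_with_steepness(self):
        breadths = []
        for s in (1.0, 2.0, 4.0, 8.0, 16.0):
            p = CanonicalBriereParams(g_max=0.5, alpha=0.7, s=s, t_min=10, t_max=47)
            breadths.append(niche_summary(p).breadth)
        assert all(b1 > b2 for b1, b2 in zip(breadths, breadths[1:]))

    def test_niche_invariants_on_random_params(self):
        rng = np.random.default_rng(13)
        for _ in range(1000):
            p = random_natural_params(rng)
            ns = niche_summary(p)
            assert p.t_min <= ns.t_half_low < ns.t_opt < ns.t_half_high <= p.t_max
            assert ns.breadth > 0

    def test_unimodality_at_grid_resolution(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            p = random_natural_params(rng)
            t_opt = optimal_temperature(p)
            up = briere_modified(np.linspace(p.t_min + 1e-6, t_opt, 300), p)
            down = briere_modified(np.linspace(t_opt, p.t_max - 1e-6, 300), p)
            assert np.all(np.diff(up) >= -1e-12 * np.max(up))
            assert np.all(np.diff(down) <= 1e-12 * np.max(down))
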