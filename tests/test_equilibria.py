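"""1:1 mass-balance root, generalized m:n equilibrium, and Job analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hostguest.equilibria import (
    bound_fraction,
    complex_concentration,
    job_curve,
    job_maximum,
    solve_equilibrium_1to1,
    solve_equilibrium_general,
)
from hostguest.errors import DomainError, NoMaximumError, UndefinedFractionError


def bisect_complex(h0, g0, ka):
    """Independent oracle: bisection on f(c) = Ka*(H0-c)*(G0-c) - c.

    200 halvings collapse the bracket to adjacent floats, so the returned
    root is exact to machine precision."""
    if h0 == 0 or g0 == 0 or ka == 0:
        return 0.0
    lo, hi = 0.0, min(h0, g0)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if ka * (h0 - mid) * (g0 - mid) - mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestSolve1to1:
    def test_no_association(self):
        st_ = solve_equilibrium_1to1(1e-4, 1e-4, 0.0)
        assert st_.complex_conc == 0.0
        assert st_.free_host == 1e-4 and st_.free_guest == 1e-4

    def test_no_host(self):
        st_ = solve_equilibrium_1to1(0.0, 5e-5, 1e4)
        assert st_.complex_conc == 0.0
        assert st_.free_guest == 5e-5

    def test_equimolar_root_matches_bisection(self):
        st_ = solve_equilibrium_1to1(1e-4, 1e-4, 1e4)
        assert st_.complex_conc == pytest.approx(3.8197e-5, rel=1e-4)
        assert st_.complex_conc == pytest.approx(bisect_complex(1e-4, 1e-4, 1e4), rel=1e-12)

    def test_infinite_ka_limit(self):
        st_ = solve_equilibrium_1to1(2e-4, 1e-4, math.inf)
        assert st_.complex_conc == 1e-4

    @pytest.mark.parametrize("bad", ["total_host", "total_guest", "ka"])
    def test_negative_inputs_name_parameter(self, bad):
        kwargs = {"total_host": 1e-4, "total_guest": 1e-4, "ka": 1e4, bad: -1.0}
        with pytest.raises(DomainError, match=bad):
            solve_equilibrium_1to1(**kwargs)

    def test_closed_form_vs_bisection_on_grid(self):
        """Stable conjugate root agrees with bisection to <=1e-10 relative
        over Ka in 1e1..1e8 and totals in 1e-6..1e-2 (log-spaced)."""
        kas = np.logspace(1, 8, 5)
        concs = np.logspace(-6, -2, 5)
        checked = 0
        for ka in kas:
            for h0 in concs:
                for g0 in concs:
                    c = complex_concentration(h0, g0, ka)
                    ref = bisect_complex(h0, g0, ka)
                    assert c == pytest.approx(ref, rel=1e-10, abs=1e-22)
                    checked += 1
        assert checked >= 100

    def test_mass_balance_and_action_invariants(self):
        for ka, h0, g0 in [(1e2, 3e-4, 7e-5), (1e6, 1e-5, 1e-5), (5e4, 2e-3, 1e-6)]:
            s = solve_equilibrium_1to1(h0, g0, ka)
            assert 0.0 <= s.complex_conc <= min(h0, g0)
            assert s.free_host + s.complex_conc == pytest.approx(h0, rel=1e-12)
            assert s.free_guest + s.complex_conc == pytest.approx(g0, rel=1e-12)
            assert ka * s.free_host * s.free_guest == pytest.approx(
                s.complex_conc, rel=1e-9
            )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        ka=st.floats(1e1, 1e8), h0=st.floats(1e-6, 1e-2), g0=st.floats(1e-6, 1e-2),
        factor=st.floats(1.01, 10.0),
    )
    def test_monotone_in_each_argument(self, ka, h0, g0, factor):
        c = complex_concentration(h0, g0, ka)
        assert complex_concentration(h0 * factor, g0, ka) >= c
        assert complex_concentration(h0, g0 * factor, ka) >= c
        assert complex_concentration(h0, g0, ka * factor) >= c

    def test_bound_fraction_depends_only_on_ka_times_conc_when_equimolar(self):
        # scaling totals by s and Ka by 1/s preserves Ka*C, hence the fraction
        for s in (0.1, 3.0, 40.0):
            a = bound_fraction(solve_equilibrium_1to1(1e-4, 1e-4, 1e4))
            b = bound_fraction(solve_equilibrium_1to1(1e-4 * s, 1e-4 * s, 1e4 / s))
            assert a == pytest.approx(b, rel=1e-12)


class TestBoundFraction:
    def test_zero_ka_gives_zero(self):
        assert bound_fraction(solve_equilibrium_1to1(1e-4, 1e-4, 0.0)) == 0.0

    def test_saturation_limit(self):
        assert bound_fraction(solve_equilibrium_1to1(2e-4, 1e-4, math.inf)) == 1.0

    def test_equimolar_value(self):
        f = bound_fraction(solve_equilibrium_1to1(1e-4, 1e-4, 1e4))
        assert f == pytest.approx(0.38197, rel=1e-4)

    def test_zero_guest_is_undefined(self):
        st_ = solve_equilibrium_1to1(1e-4, 0.0, 1e4)
        with pytest.raises(UndefinedFractionError):
            bound_fraction(st_)


class TestGeneralEquilibrium:
    def test_reduces_to_1to1(self):
        c = solve_equilibrium_general(1e-4, 1e-4, 1e4, 1, 1)
        assert c == pytest.approx(complex_concentration(1e-4, 1e-4, 1e4), rel=1e-9)

    def test_stoichiometry_bounds(self):
        with pytest.raises(DomainError):
            solve_equilibrium_general(1e-4, 1e-4, 1e4, 4, 1)

    def test_complex_cannot_exceed_limiting_species(self):
        c = solve_equilibrium_general(1e-4, 1e-4, 1e12, 1, 2)
        assert c <= 1e-4 / 2 + 1e-18


class TestJobCurve:
    def test_endpoints_are_zero(self):
        curve = job_curve(1e-4, [0.0, 0.5, 1.0], ka=1e4)
        assert curve.complex_concs[0] == 0.0
        assert curve.complex_concs[-1] == 0.0

    def test_midpoint_value_matches_bisection(self):
        curve = job_curve(1e-4, [0.25, 0.5, 0.75], ka=1e4)
        assert curve.complex_concs[1] == pytest.approx(1.3397e-5, rel=1e-4)
        assert curve.complex_concs[1] == pytest.approx(
            bisect_complex(5e-5, 5e-5, 1e4), rel=1e-10
        )

    def test_exchange_symmetry(self):
        xs = np.arange(0.1, 0.95, 0.1)
        curve = job_curve(1e-4, xs, ka=3e4)
        assert np.allclose(curve.complex_concs, curve.complex_concs[::-1], rtol=1e-10)

    def test_mole_fraction_domain(self):
        with pytest.raises(DomainError):
            job_curve(1e-4, [0.0, 1.2], ka=1e4)

    def test_default_grid_is_11_points(self):
        assert job_curve(1e-4, ka=1e4).mole_fractions.size == 11


class TestJobMaximum:
    @pytest.mark.parametrize("ctot,ka", [(1e-4, 1.30e4), (8e-5, 1.05e5)])
    def test_one_to_one_peaks_at_half(self, ctot, ka):
        assert job_maximum(job_curve(ctot, ka=ka)) == pytest.approx(0.5, abs=1e-6)

    def test_half_for_random_designs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            ka = 10 ** rng.uniform(2, 7)
            ctot = 10 ** rng.uniform(-5, -3)
            assert job_maximum(job_curve(ctot, ka=ka)) == pytest.approx(0.5, abs=1e-6)

    def test_one_to_two_peaks_at_third(self):
        curve = job_curve(1e-4, ka=1e10, stoichiometry=(1, 2))
        assert job_maximum(curve) == pytest.approx(1.0 / 3.0, abs=1e-3)

    def test_flat_curve_has_no_maximum(self):
        with pytest.raises(NoMaximumError):
            job_maximum(job_curve(1e-4, ka=0.0))
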