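"""Pore model: creation ODE fixed point, energy-gradient consistency,
tension closure, pore current, and the sub-stepped integrator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nspefsim as ns
from nspefsim import pores


@pytest.fixture(scope="module")
def ep():
    return ns.default_params().ep


# ---------------------------------------------------------------------------
# pore_density_rate / equilibrium
# ---------------------------------------------------------------------------

def test_density_rate_rest_equilibrium(ep):
    assert pores.pore_density_rate(0.0, ep.N0, ep) == 0.0


def test_density_rate_bare_membrane_equals_alpha(ep):
    assert pores.pore_density_rate(0.0, 0.0, ep) == pytest.approx(1.0e9)


def test_density_rate_symmetric_in_vm(ep):
    for v in (0.1, 0.5, 1.0):
        assert pores.pore_density_rate(v, 5e9, ep) == pores.pore_density_rate(-v, 5e9, ep)


@pytest.mark.parametrize("V", [0.0, 0.1, 0.17, 0.3])
def test_integrated_density_reaches_closed_form_fixed_point(V, ep):
    """N integrated to steady state matches N0 exp(q (V/U)^2) to 0.1%."""
    N_eq = pores.equilibrium_density(V, ep)
    b = (ep.alpha / ep.N0) * np.exp((1 - ep.q) * (V / ep.U_ep) ** 2)
    st_ = pores.rest_state(1, ep)
    horizon = 9.0 / b
    for _ in range(60):
        st_ = pores.advance_pores(st_, np.array([V]), horizon / 60, ep)
    assert st_.N[0] == pytest.approx(N_eq, rel=1e-3)


def test_vm_guard_warns_and_caps(ep):
    with pytest.warns(RuntimeWarning, match="clamped"):
        r = pores.pore_density_rate(3.0, 0.0, ep)
    assert np.isfinite(r)


# ---------------------------------------------------------------------------
# pore energy / radius rate
# ---------------------------------------------------------------------------

def test_energy_large_r_dominated_by_surface_term(ep):
    r = 100e-9
    W = pores.pore_energy(r, 0.0, ep.sigma0, ep)
    approx = 2 * np.pi * ep.gamma * r - np.pi * ep.sigma0 * r**2
    assert W == pytest.approx(approx, rel=1e-3)


def test_energy_decreases_with_vm_at_fixed_r(ep):
    r = 2e-9
    Ws = [pores.pore_energy(r, v, ep.sigma0, ep) for v in (0.0, 0.5, 1.0)]
    assert Ws[0] > Ws[1] > Ws[2]


def test_radius_rate_vanishes_at_brute_force_energy_minimum(ep):
    """1D minimization of W locates the stationary radius; the ODE rate is
    zero there (within the discrete minimizer's resolution)."""
    delta = ep.sigma0
    rs = np.linspace(0.6e-9, 30e-9, 200_000)
    W = pores.pore_energy(rs, 0.0, delta, ep)
    r_min = rs[np.argmin(W)]
    rate = pores.pore_radius_rate(r_min, 0.0, delta, ep)
    scale = abs(pores.pore_radius_rate(2 * r_min, 0.0, delta, ep))
    assert abs(rate) < 1e-2 * scale


def test_radius_rate_signs(ep):
    # high TMV expands pores
    assert pores.pore_radius_rate(ep.r_star, 1.0, ep.sigma0, ep) > 0
    # line tension shrinks large pores at rest
    assert pores.pore_radius_rate(10 * ep.r_star, 0.0, ep.sigma0, ep) < 0


@settings(deadline=None, derandomize=True, max_examples=60)
@given(r=st.floats(0.7e-9, 20e-9), V=st.floats(0.0, 1.0))
def test_radius_rate_is_negative_energy_gradient(r, V):
    """pore_radius_rate == -(D/kT) dW/dr by central differences, < 1e-3."""
    ep = ns.default_params().ep
    h = r * 1e-6
    dW = (pores.pore_energy(r + h, V, ep.sigma0, ep)
          - pores.pore_energy(r - h, V, ep.sigma0, ep)) / (2 * h)
    rate = pores.pore_radius_rate(r, V, ep.sigma0, ep)
    pred = -(ep.D_pore / (ep.k_B * ep.T)) * dW
    assert rate == pytest.approx(pred, rel=1e-3, abs=1e-12)


def test_radius_rate_rejects_nonpositive_radius(ep):
    with pytest.raises(ValueError):
        pores.pore_radius_rate(0.0, 0.0, ep.sigma0, ep)
    with pytest.raises(ValueError):
        pores.pore_energy(-1e-9, 0.0, ep.sigma0, ep)


# ---------------------------------------------------------------------------
# effective tension
# ---------------------------------------------------------------------------

def test_effective_tension_zero_area_gives_bare_tension(ep):
    assert pores.effective_tension(0.0, ep) == pytest.approx(1e-6)


def test_effective_tension_root_matches_bisection(ep):
    closed = 1.0 - np.sqrt((2 * ep.sigma_prime - ep.sigma0) / (2 * ep.sigma_prime))
    lo, hi = 0.0, 0.5
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if pores.effective_tension(mid, ep) > 0:
            lo = mid
        else:
            hi = mid
    assert closed == pytest.approx(0.5 * (lo + hi), abs=1e-12)
    assert pores.effective_tension(closed, ep) == pytest.approx(0.0, abs=1e-12)


def test_effective_tension_monotone_decreasing(ep):
    a = np.linspace(0, 0.5, 200)
    d = pores.effective_tension(a, ep)
    assert np.all(np.diff(d) < 0)


def test_effective_tension_domain_error(ep):
    with pytest.raises(ValueError):
        pores.effective_tension(1.0, ep)


# ---------------------------------------------------------------------------
# electroporation current
# ---------------------------------------------------------------------------

def test_ep_current_zero_voltage(ep):
    assert pores.ep_current_density(0.0, ep.N0, ep.r_star, ep, 5e-9, 0.65) == 0.0


def test_ep_current_matches_hand_computed_series_resistance(ep):
    V, N, r, d, sb = 0.5, ep.N0, ep.r_star, 5e-9, 0.65
    R_int = d / (0.22 * np.pi * r**2)
    R_acc = 1.0 / (2 * sb * r)
    expect = N * V / (R_int + R_acc)
    assert pores.ep_current_density(V, N, r, ep, d, sb) == pytest.approx(expect)
    # ohmic model drops the access term
    expect_ohmic = N * V / R_int
    assert pores.ep_current_density(V, N, r, ep, d, model="ohmic") == \
        pytest.approx(expect_ohmic)


def test_ep_current_monotone_in_each_argument(ep):
    base = pores.ep_current_density(0.5, 1e14, 1e-9, ep, 5e-9, 0.65)
    assert pores.ep_current_density(0.6, 1e14, 1e-9, ep, 5e-9, 0.65) > base
    assert pores.ep_current_density(0.5, 2e14, 1e-9, ep, 5e-9, 0.65) > base
    assert pores.ep_current_density(0.5, 1e14, 2e-9, ep, 5e-9, 0.65) > base


# ---------------------------------------------------------------------------
# advance_pores
# ---------------------------------------------------------------------------

def test_rest_state_is_fixed_point(ep):
    st_ = pores.rest_state(3, ep)
    out = pores.advance_pores(st_, np.zeros(3), 1e-8, ep)
    assert np.allclose(out.N, st_.N)
    assert np.allclose(out.r_pore, st_.r_pore, rtol=1e-6)


def test_constant_vm_matches_tiny_step_reference(ep):
    """100 ns at V = 1 V vs a 1000x finer reference integration, 0.5%."""
    V = np.array([1.0])
    coarse = pores.rest_state(1, ep)
    for _ in range(100):
        coarse = pores.advance_pores(coarse, V, 1e-9, ep)
    fine = pores.rest_state(1, ep)
    for _ in range(10_000):
        fine = pores.advance_pores(fine, V, 1e-11, ep, max_rel_change=0.005)
    assert coarse.N[0] == pytest.approx(fine.N[0], rel=5e-3)
    assert coarse.r_pore[0] == pytest.approx(fine.r_pore[0], rel=5e-3)


def test_pulse_removal_reseals_radius_and_area(ep):
    st_ = pores.rest_state(1, ep)
    for _ in range(100):
        st_ = pores.advance_pores(st_, np.array([1.0]), 1e-9, ep)
    peak_r, peak_A = st_.r_pore[0], st_.A_frac[0]
    for _ in range(200):
        st_ = pores.advance_pores(st_, np.array([0.0]), 1e-9, ep)
    assert st_.r_pore[0] < peak_r
    assert st_.A_frac[0] < peak_A
    assert st_.r_pore[0] > 0.99 * pores.R_FLOOR_FRAC * ep.r_star
    # settles onto the stationary radius self-consistent with the surviving
    # pore density (tension is relaxed by A = pi r^2 N, so it sits below the
    # N0-based rest radius)
    delta = pores.effective_tension(st_.A_frac[0], ep)
    rate = pores.pore_radius_rate(st_.r_pore[0], 0.0, delta, ep)
    peak_rate = abs(pores.pore_radius_rate(peak_r, 0.0, delta, ep))
    assert abs(rate) < 0.05 * peak_rate


def test_floors_preserved_under_odd_dt_schedules(ep):
    rng = np.random.default_rng(5)
    st_ = pores.rest_state(4, ep)
    for k in range(50):
        V = rng.uniform(-1.2, 1.2, 4)
        dt = 10 ** rng.uniform(-12, -8.5)
        st_ = pores.advance_pores(st_, V, dt, ep)
        assert np.all(st_.N >= 0)
        assert np.all(st_.r_pore >= pores.R_FLOOR_FRAC * ep.r_star * (1 - 1e-12))
        assert np.all(st_.A_frac < 1.0)
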