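"""Field solver: analytic oracles (uniform field, concentric disk, 2D
induced-TMV), symmetry, stability, convergence, determinism, conservation."""

import numpy as np
import pytest

import nspefsim as ns
from nspefsim import geometry, solver
from nspefsim.geometry import Capsule, Scene
from nspefsim.meshing import REGION_MEDIUM, build_mesh


def _boundary_nodes(mesh, side):
    x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
    return np.flatnonzero((np.abs(x) < 1e-12) | (np.abs(x - side) < 1e-12)
                          | (np.abs(y) < 1e-12) | (np.abs(y - side) < 1e-12))


def test_homogeneous_scene_reproduces_uniform_field():
    p = ns.default_params()
    sc = geometry.build_scene(p, [], include_cell=False)
    m = build_mesh(sc, h_far=12e-6, h_membrane=12e-6, min_angle_deg=0.5)
    ctx = solver.assemble(m, p)
    E0 = p.pulse.E_applied
    psi = solver.solve_static(ctx, E0 * p.geometry.domain_side)
    E, mx = solver.field_magnitude(ctx, psi)
    assert np.abs(E - E0).max() / E0 < 1e-6


def test_concentric_disk_matches_closed_form_to_point1_percent():
    """Two-conductivity disk vs the classical series solution; the exact
    solution is imposed on the walls so only discretization error remains."""
    p = ns.default_params()
    R = 4e-6
    p.geometry.r_c = R
    p.geometry.r_n = 2e-6
    sc = geometry.build_scene(p, [])
    sc.include_nucleus = False
    E0, side = 6e5, p.geometry.domain_side
    s0, s1 = p.medium.sigma, p.cytoplasm.sigma
    c = np.array(sc.center)

    def closed_form(nodes):
        xy = nodes - c
        r = np.hypot(xy[:, 0], xy[:, 1])
        x = xy[:, 0]
        return np.where(
            r < R, -(2 * s0 / (s0 + s1)) * E0 * x,
            -E0 * x * (1.0 - ((s1 - s0) / (s1 + s0)) * R**2 / np.maximum(r, 1e-12)**2))

    m = build_mesh(sc, h_far=2e-6, h_membrane=0.2e-6, min_angle_deg=0.5,
                   slit_membranes=False, grade=0.2)
    ctx = solver.assemble(m, p)
    bnd = _boundary_nodes(m, side)
    psi = solver.solve_static(ctx, dirichlet=(bnd, closed_form(m.nodes[bnd])))
    ana = closed_form(m.nodes)
    r = np.hypot(*(m.nodes - c).T)
    sel = r < 3 * R
    err = np.abs(psi[sel] - ana[sel]).max() / np.abs(ana[sel]).max()
    assert err < 1e-3


def test_cnt_regions_are_equipotential(matched_pair):
    arm = matched_pair["cnt"]
    p = matched_pair["params"]
    V = p.pulse.E_applied * p.geometry.domain_side
    psi = solver.solve_static(arm["ctx"], V)
    for tag in np.unique(arm["mesh"].region):
        if tag < 10:
            continue
        nid = np.unique(arm["mesh"].triangles[arm["mesh"].region == tag])
        spread = psi[nid].max() - psi[nid].min()
        assert spread < 1e-3 * V


def test_rest_state_is_stationary():
    p = ns.default_params()
    sc = geometry.build_scene(p, [])
    m = build_mesh(sc, h_far=12e-6, h_membrane=1.5e-6, min_angle_deg=0.5)
    ctx = solver.assemble(m, p)
    psi = np.zeros(m.n_nodes)
    g0 = np.zeros(ctx.S_int.shape[1])
    out = solver.step(ctx, psi, g0, 0.0, 1e-9)
    assert np.abs(out).max() < 1e-12
    vm = solver.transmembrane_voltage(ctx, out)
    assert all(np.abs(v).max() < 1e-12 for v in vm.values())


def test_backward_euler_first_order_in_dt():
    """Richardson self-convergence of V_m at the pole during passive charging."""
    p = ns.default_params()
    sc = geometry.build_scene(p, [])
    sc.include_nucleus = False
    m = build_mesh(sc, h_far=12e-6, h_membrane=1.5e-6, min_angle_deg=0.5)
    ctx = solver.assemble(m, p)
    V = p.pulse.E_applied * p.geometry.domain_side
    g0 = np.zeros(ctx.S_int.shape[1])
    T = 40e-9
    pole = np.argmin(np.abs(m.interfaces["outer_membrane"].theta))

    def vm_pole(dt):
        psi = np.zeros(m.n_nodes)
        for _ in range(int(round(T / dt))):
            psi = solver.step(ctx, psi, g0, V, dt)
        return solver.transmembrane_voltage(ctx, psi)["outer_membrane"][pole]

    v1, v2, v4 = vm_pole(4e-9), vm_pole(2e-9), vm_pole(1e-9)
    ratio = (v1 - v2) / (v2 - v4)
    assert 1.5 < ratio < 3.0  # ~2 for a first-order scheme


def test_passive_membrane_reaches_2d_schwan_steady_state(passive_charged):
    """Insulating cylindrical shell: V_m -> 2 r_c E cos(theta) within 2%."""
    d = passive_charged
    vm = solver.transmembrane_voltage(d["ctx"], d["psi"])["outer_membrane"]
    th = d["mesh"].interfaces["outer_membrane"].theta
    ana = 2 * d["R"] * d["E0"] * np.cos(th)
    assert np.abs(vm - ana).max() / np.abs(ana).max() < 0.02


def test_passive_charging_time_constant(passive_charged):
    """Half-rise time of the pole TMV matches the analytic tau ln 2 within 5%."""
    d = passive_charged
    ctx, mesh, tau = d["ctx"], d["mesh"], d["tau"]
    p = d["params"]
    V = d["E0"] * p.geometry.domain_side
    pole = np.argmin(np.abs(mesh.interfaces["outer_membrane"].theta))
    v_inf = solver.transmembrane_voltage(ctx, d["psi"])["outer_membrane"][pole]
    psi = np.zeros(mesh.n_nodes)
    g0 = np.zeros(ctx.S_int.shape[1])
    dt = tau / 80
    t, t_half = 0.0, None
    for _ in range(200):
        psi = solver.step(ctx, psi, g0, V, dt)
        t += dt
        v = solver.transmembrane_voltage(ctx, psi)["outer_membrane"][pole]
        if v >= 0.5 * v_inf:
            t_half = t
            break
    assert t_half is not None
    assert t_half == pytest.approx(tau * np.log(2), rel=0.05)


def test_tmv_antisymmetric_and_zero_at_equator(cnt_free_run):
    res = cnt_free_run["result"]
    i = np.argmin(np.abs(res.times - 150e-9))
    mem = res.membranes["outer_membrane"]
    th, vm = mem["theta"], mem["V_m"][i]
    order = np.argsort(th)
    th_s, vm_s = th[order], vm[order]
    vm_mirror = np.interp(np.pi - th_s, th_s, vm_s, period=2 * np.pi)
    peak = np.abs(vm_s).max()
    assert np.abs(vm_s + vm_mirror).max() < 0.01 * peak
    vm_equator = np.interp(np.pi / 2, th_s, vm_s)
    assert abs(vm_equator) < 0.05 * peak


def test_cnt_free_medium_max_sits_on_outer_membrane(cnt_free_run):
    """The strongest field outside the cell concentrates on the outer
    membrane contour. (In this 2D model at the plateau the hottest exterior
    spot is the narrow band near the equator that has not electroporated;
    the porated polar caps pass current and carry a lower exterior field.)"""
    res, ctx, mesh = (cnt_free_run[k] for k in ("result", "ctx", "mesh"))
    snap = res.snapshots[0]
    E, _ = solver.field_magnitude(ctx, snap.psi)
    med = mesh.region == REGION_MEDIUM
    k = np.flatnonzero(med)[np.argmax(E[med])]
    c = np.array(mesh.scene.center)
    rel = mesh.centroids()[k] - c
    r = np.hypot(*rel)
    r_c = mesh.scene.r_c
    assert abs(r - r_c) < 0.1 * r_c  # on the membrane contour
    assert E[med].max() > 1.2 * res.max_E_domain[0]  # concentrated above E0


def test_single_high_aspect_capsule_max_at_tip():
    p = ns.default_params()
    side = 8e-6
    cap = Capsule((side / 2, side / 2), 0.0, 1e-6, 10e-9)  # L/D = 100
    sc = Scene(side=side, center=(side / 2, side / 2), r_c=1e-6, r_n=0.5e-6,
               d_mem=5e-9, d_ne=40e-9, include_cell=False, cnts=[cap])
    m = build_mesh(sc, h_far=0.8e-6, h_membrane=0.8e-6, min_angle_deg=0.5)
    ctx = solver.assemble(m, p)
    E0 = 1e4
    psi = solver.solve_static(ctx, E0 * side)
    E, _ = solver.field_magnitude(ctx, psi)
    outside = m.region < 10
    k = np.flatnonzero(outside)[np.argmax(E[outside])]
    a, b = cap.endpoints
    d_tip = min(np.linalg.norm(m.centroids()[k] - a),
                np.linalg.norm(m.centroids()[k] - b))
    assert d_tip < cap.D
    assert E[outside].max() > 5 * E0  # strong tip enhancement


def test_simulation_rerun_is_bit_identical():
    p = ns.default_params()
    p.pulse.t_width = 20e-9
    p.pulse.t_end = 30e-9
    sc = geometry.build_scene(p, [])
    m = build_mesh(sc, h_far=15e-6, h_membrane=2e-6, min_angle_deg=0.5)
    a = solver.run_simulation(p, m, snapshot_times=(10e-9,))
    b = solver.run_simulation(p, m, snapshot_times=(10e-9,))
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.max_E_domain, b.max_E_domain)
    assert np.array_equal(a.membranes["outer_membrane"]["N"],
                          b.membranes["outer_membrane"]["N"])
    assert np.array_equal(a.snapshots[0].psi, b.snapshots[0].psi)


def test_zero_amplitude_pulse_changes_nothing():
    p = ns.default_params()
    p.pulse.E_applied = 0.0
    p.pulse.t_width = 20e-9
    p.pulse.t_end = 30e-9
    sc = geometry.build_scene(p, [])
    m = build_mesh(sc, h_far=15e-6, h_membrane=2e-6, min_angle_deg=0.5)
    res = solver.run_simulation(p, m)
    assert res.max_E_domain.max() < 1e-9
    mem = res.membranes["outer_membrane"]
    assert np.allclose(mem["N"], p.ep.N0)
    assert np.allclose(mem["r_pore"], mem["r_pore"][0])
    assert np.abs(mem["V_m"]).max() < 1e-12


def test_discrete_current_conservation():
    """Net current into the driven electrode equals the net current out of
    the ground electrode within 0.5% at every step."""
    p = ns.default_params()
    sc = geometry.build_scene(p, [])
    m = build_mesh(sc, h_far=12e-6, h_membrane=1.5e-6, min_angle_deg=0.5)
    ctx = solver.assemble(m, p)
    V = p.pulse.E_applied * p.geometry.domain_side
    g0 = np.zeros(ctx.S_int.shape[1])
    psi = np.zeros(m.n_nodes)
    dt = 1e-9
    for _ in range(5):
        new = solver.step(ctx, psi, g0, V, dt)
        i_l, i_r = solver.electrode_currents(ctx, new, psi, g0, dt)
        assert abs(i_l + i_r) < 0.005 * abs(i_l)
        psi = new


@pytest.mark.parametrize("dt", [0.1e-9, 1e-9, 10e-9])
def test_unconditional_stability(dt):
    """Backward Euler stays bounded for any dt at fixed drive."""
    p = ns.default_params()
    sc = geometry.build_scene(p, [])
    m = build_mesh(sc, h_far=15e-6, h_membrane=2e-6, min_angle_deg=0.5)
    ctx = solver.assemble(m, p)
    V = p.pulse.E_applied * p.geometry.domain_side
    g0 = np.zeros(ctx.S_int.shape[1])
    psi = np.zeros(m.n_nodes)
    for _ in range(30):
        psi = solver.step(ctx, psi, g0, V, dt)
        assert np.abs(psi).max() <= 1.0001 * V
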