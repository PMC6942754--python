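"""Shared fixtures: coarse-mesh simulation runs reused across the suite.

Oracle and property tests run on deliberately coarse meshes and shortened
time grids; the heavy mesh-converged runs live only in the acceptance tests.
"""

import warnings

import numpy as np
import pytest

import nspefsim as ns
from nspefsim import geometry, solver


def make_params(**mesh_overrides):
    p = ns.default_params()
    p.mesh.h_far = mesh_overrides.get("h_far", 10e-6)
    p.mesh.h_membrane = mesh_overrides.get("h_membrane", 1e-6)
    p.mesh.min_angle_deg = 0.5
    return p


@pytest.fixture(scope="session")
def params():
    return make_params()


@pytest.fixture(scope="session")
def cnt_free_run():
    """Full-pulse CNT-free run on a coarse mesh (shared, read-only)."""
    p = make_params(h_membrane=0.5e-6, h_far=8e-6)
    sc = geometry.build_scene(p, [])
    mesh = ns.build_mesh(sc, h_far=p.mesh.h_far, h_membrane=p.mesh.h_membrane,
                         min_angle_deg=p.mesh.min_angle_deg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = solver.run_simulation(p, mesh, snapshot_times=(152e-9,))
    ctx = solver.assemble(mesh, p)
    return {"params": p, "scene": sc, "mesh": mesh, "result": res, "ctx": ctx}


@pytest.fixture(scope="session")
def matched_pair():
    """CNT-free vs 5-CNT runs on matched mesh settings, full pulse window."""
    p = make_params(h_membrane=1e-6, h_far=10e-6)
    out = {}
    for label, cnts in (("free", []), ("cnt", ns.sample_cnts(p, seed=1))):
        sc = geometry.build_scene(p, cnts, seed=1)
        mesh = ns.build_mesh(sc, h_far=p.mesh.h_far, h_membrane=p.mesh.h_membrane,
                             min_angle_deg=p.mesh.min_angle_deg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = solver.run_simulation(p, mesh, snapshot_times=(152e-9,))
        out[label] = {"mesh": mesh, "result": res, "ctx": solver.assemble(mesh, p)}
    out["params"] = p
    return out


@pytest.fixture(scope="session")
def passive_charged():
    """Passive (electroporation off) membrane charged to steady state at
    constant field: the 2D induced-TMV oracle. Single membrane, no nucleus."""
    p = make_params(h_membrane=0.5e-6, h_far=8e-6)
    sc = geometry.build_scene(p, [])
    sc.include_nucleus = False
    mesh = ns.build_mesh(sc, h_far=8e-6, h_membrane=0.5e-6, min_angle_deg=0.5)
    ctx = solver.assemble(mesh, p)
    from nspefsim.params import EPS0
    R = p.geometry.r_c
    s_i, s_e = p.cytoplasm.sigma, p.medium.sigma
    C_m = EPS0 * p.membrane.eps_r / p.geometry.d_mem
    g_m = p.membrane.sigma / p.geometry.d_mem
    tau = C_m / (s_i * s_e / (R * (s_i + s_e)) + g_m)
    E0 = p.pulse.E_applied
    psi = np.zeros(mesh.n_nodes)
    g0 = np.zeros(ctx.S_int.shape[1])
    dt = tau / 40
    for _ in range(int(np.ceil(8 * tau / dt))):
        psi = solver.step(ctx, psi, g0, E0 * p.geometry.domain_side, dt)
    return {"params": p, "mesh": mesh, "ctx": ctx, "psi": psi,
            "tau": tau, "E0": E0, "R": R}
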