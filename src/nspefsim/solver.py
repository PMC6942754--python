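"""Quasi-static time-domain FEM solve of the conduction + displacement
current equation

    -div(sigma grad psi) - div(eps0 eps_r d/dt grad psi) = 0

on the bulk regions, with both membranes as zero-thickness
distributed-impedance interfaces. Each membrane contour exists twice in the
mesh (inner and outer node traces at identical coordinates); the normal
current density crossing the interface is

    J = g_m V_m + c_m dV_m/dt + g_ep V_m,

with V_m = psi_inner - psi_outer the transmembrane voltage relative to rest
(the resting offset is absorbed into the conduction term, so the rest state
is stationary), g_m = sigma_mem0/d, c_m = eps0 eps_mem/d, and g_ep the areal
electroporation conductance supplied by the pore model. Time stepping is
implicit backward Euler in both the bulk displacement term and the membrane
charging term, hence unconditionally stable; the electrodes are Dirichlet
boundaries driven by the trapezoidal pulse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import pores
from .meshing import (REGION_CNT_BASE, REGION_CYTOPLASM, REGION_MEDIUM,
                      REGION_NUCLEOPLASM, SimMesh)
from .params import EPS0, ModelParams, pulse_value


class SolverError(RuntimeError):
    pass


@dataclass
class MembraneState:
    """State carried by one membrane contour (vectors over contour nodes)."""

    theta: np.ndarray
    V_m: np.ndarray      # transmembrane voltage relative to rest, V
    pore: pores.PoreModelState
    g_ep: np.ndarray     # areal electroporation conductance, S m^-2

    def copy(self) -> "MembraneState":
        return MembraneState(self.theta, self.V_m.copy(), self.pore.copy(),
                             self.g_ep.copy())


@dataclass
class FieldState:
    t: float
    psi: np.ndarray      # potential at mesh nodes (duplicated traces), V


@dataclass
class SimResult:
    """Time series produced by :func:`run_simulation`."""

    times: np.ndarray
    max_E_domain: np.ndarray
    max_E_cell: np.ndarray
    membranes: dict[str, dict[str, np.ndarray]]  # name -> {theta, V_m, N, r_pore, g_ep, A_frac}
    snapshots: list[FieldState]
    mesh: SimMesh
    n_steps: int = 0
    n_rejected: int = 0


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def region_properties(mesh: SimMesh, params: ModelParams):
    """Per-triangle (sigma, eps_r) arrays from region tags."""
    lut = {REGION_MEDIUM: params.medium, REGION_CYTOPLASM: params.cytoplasm,
           REGION_NUCLEOPLASM: params.nucleoplasm}
    sigma = np.empty(mesh.n_triangles)
    eps = np.empty(mesh.n_triangles)
    for tag in np.unique(mesh.region):
        props = lut.get(tag)
        if props is None:
            if tag >= REGION_CNT_BASE:
                props = params.cnt
            else:
                raise SolverError(f"region tag {tag} has no dielectric properties")
        m = mesh.region == tag
        sigma[m] = props.sigma
        eps[m] = props.eps_r
    return sigma, eps


def _p1_gradients(mesh: SimMesh):
    """P1 shape-function gradients: (M, 3, 2) array and triangle areas."""
    p = mesh.nodes[mesh.triangles]
    v0 = p[:, 1] - p[:, 0]
    v1 = p[:, 2] - p[:, 0]
    det = v0[:, 0] * v1[:, 1] - v0[:, 1] * v1[:, 0]
    area = 0.5 * np.abs(det)
    # grad of barycentric coordinates
    g = np.empty((len(p), 3, 2))
    g[:, 1, 0] = v1[:, 1] / det
    g[:, 1, 1] = -v1[:, 0] / det
    g[:, 2, 0] = -v0[:, 1] / det
    g[:, 2, 1] = v0[:, 0] / det
    g[:, 0] = -g[:, 1] - g[:, 2]
    return g, area


def _stiffness(mesh: SimMesh, coeff: np.ndarray, grads, area) -> sp.csr_matrix:
    """Assemble sum_T coeff_T (grad u, grad v)_T."""
    t = mesh.triangles
    n = mesh.n_nodes
    rows, cols, vals = [], [], []
    w = coeff * area
    for i in range(3):
        for j in range(3):
            rows.append(t[:, i])
            cols.append(t[:, j])
            vals.append(w * np.einsum("kd,kd->k", grads[:, i], grads[:, j]))
    A = sp.coo_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(n, n))
    return A.tocsr()


@dataclass
class SolverContext:
    mesh: SimMesh
    params: ModelParams
    K_sigma: sp.csr_matrix
    K_eps: sp.csr_matrix
    S_int: sp.csr_matrix          # (n x K_total) trace incidence: +inner, -outer
    lumped: np.ndarray            # (K_total,) interface lumped lengths
    g_m: np.ndarray               # (K_total,) background membrane conductance, S/m^2
    c_m: np.ndarray               # (K_total,) membrane capacitance, F/m^2
    iface_order: list[str]        # interface names in S_int column order
    iface_slices: dict[str, slice]
    dirichlet: np.ndarray         # node ids
    dirichlet_scale: np.ndarray   # psi = scale * V_drive
    free: np.ndarray
    grads: np.ndarray
    area: np.ndarray
    sigma_tri: np.ndarray
    eps_tri: np.ndarray


def assemble(mesh: SimMesh, params: ModelParams) -> SolverContext:
    """Build the discrete operators for implicit stepping."""
    sigma_tri, eps_tri = region_properties(mesh, params)
    grads, area = _p1_gradients(mesh)
    K_sigma = _stiffness(mesh, sigma_tri, grads, area)
    K_eps = _stiffness(mesh, EPS0 * eps_tri, grads, area)

    rows, cols, vals = [], [], []
    lumped, g_m, c_m = [], [], []
    iface_order, iface_slices = [], {}
    col = 0
    for name, iface in mesh.interfaces.items():
        k = iface.n_nodes
        if name == "outer_membrane":
            d, props = params.geometry.d_mem, params.membrane
        elif name == "nuclear_envelope":
            d, props = params.geometry.d_ne, params.nuclear_envelope
        else:
            raise SolverError(f"unknown interface {name!r}")
        cols_k = np.arange(col, col + k)
        rows.extend([iface.inner_nodes, iface.outer_nodes])
        cols.extend([cols_k, cols_k])
        vals.extend([np.ones(k), -np.ones(k)])
        lumped.append(iface.lumped_len)
        g_m.append(np.full(k, props.sigma / d))
        c_m.append(np.full(k, EPS0 * props.eps_r / d))
        iface_order.append(name)
        iface_slices[name] = slice(col, col + k)
        col += k
    n = mesh.n_nodes
    if col:
        S_int = sp.coo_matrix((np.concatenate(vals),
                               (np.concatenate(rows), np.concatenate(cols))),
                              shape=(n, col)).tocsr()
        lumped = np.concatenate(lumped)
        g_m = np.concatenate(g_m)
        c_m = np.concatenate(c_m)
    else:
        S_int = sp.csr_matrix((n, 0))
        lumped = np.empty(0)
        g_m = np.empty(0)
        c_m = np.empty(0)

    dirichlet = np.concatenate([mesh.left_nodes, mesh.right_nodes])
    scale = np.concatenate([np.ones(len(mesh.left_nodes)),
                            np.zeros(len(mesh.right_nodes))])
    free_mask = np.ones(n, dtype=bool)
    free_mask[dirichlet] = False
    return SolverContext(mesh=mesh, params=params, K_sigma=K_sigma, K_eps=K_eps,
                         S_int=S_int, lumped=lumped, g_m=g_m, c_m=c_m,
                         iface_order=iface_order, iface_slices=iface_slices,
                         dirichlet=dirichlet, dirichlet_scale=scale,
                         free=np.flatnonzero(free_mask), grads=grads, area=area,
                         sigma_tri=sigma_tri, eps_tri=eps_tri)


# ---------------------------------------------------------------------------
# stepping
# ---------------------------------------------------------------------------

def interface_g_ep(ctx: SolverContext) -> np.ndarray:
    """Concatenated g_ep vector in interface column order (starts at zero)."""
    return np.zeros(ctx.S_int.shape[1])


def step(ctx: SolverContext, psi_old: np.ndarray, g_ep_all: np.ndarray,
         V_drive: float, dt: float) -> np.ndarray:
    """One backward-Euler step at fixed pore state.

    Solves (K_sigma + K_eps/dt + S diag(l (g_m+g_ep+c_m/dt)) S^T) psi =
    K_eps/dt psi_old + S diag(l c_m/dt) S^T psi_old with Dirichlet electrode
    values psi = V_drive (left) / 0 (right).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    G = ctx.lumped * (ctx.g_m + g_ep_all + ctx.c_m / dt)
    C = ctx.lumped * (ctx.c_m / dt)
    S = ctx.S_int
    A = ctx.K_sigma + ctx.K_eps / dt + S @ sp.diags(G) @ S.T
    b = ctx.K_eps @ psi_old / dt + S @ (C * (S.T @ psi_old))

    psi = np.empty_like(psi_old)
    psi[ctx.dirichlet] = V_drive * ctx.dirichlet_scale
    f = ctx.free
    A = A.tocsr()
    rhs = b[f] - A[f][:, ctx.dirichlet] @ psi[ctx.dirichlet]
    try:
        lu = splu(A[f][:, f].tocsc())
        psi[f] = lu.solve(rhs)
    except RuntimeError as exc:  # pragma: no cover - singular systems
        raise SolverError(f"linear solve failed: {exc}") from exc
    return psi


def transmembrane_voltage(ctx: SolverContext, psi: np.ndarray) -> dict[str, np.ndarray]:
    """V_m = inner trace - outer trace per interface node (relative to rest)."""
    vm_all = ctx.S_int.T @ psi
    return {name: vm_all[ctx.iface_slices[name]] for name in ctx.iface_order}


def field_magnitude(ctx: SolverContext, psi: np.ndarray,
                    region_filter=None) -> tuple[np.ndarray, float]:
    """Per-triangle |grad psi| (V/m) and its maximum over the filter.

    ``region_filter``: None (whole domain), an explicit boolean mask, or a
    sequence of region tags.
    """
    u = psi[ctx.mesh.triangles]
    Ex = -np.einsum("ki,ki->k", u, ctx.grads[:, :, 0])
    Ey = -np.einsum("ki,ki->k", u, ctx.grads[:, :, 1])
    E = np.hypot(Ex, Ey)
    if region_filter is None:
        mask = np.ones(len(E), dtype=bool)
    elif isinstance(region_filter, np.ndarray) and region_filter.dtype == bool:
        mask = region_filter
    else:
        mask = np.isin(ctx.mesh.region, np.asarray(region_filter))
    if not mask.any():
        raise SolverError("empty region filter")
    return E, float(E[mask].max())


def cell_interior_mask(mesh: SimMesh) -> np.ndarray:
    return np.isin(mesh.region, [REGION_CYTOPLASM, REGION_NUCLEOPLASM])


def electrode_currents(ctx: SolverContext, psi_new: np.ndarray,
                       psi_old: np.ndarray, g_ep_all: np.ndarray,
                       dt: float) -> tuple[float, float]:
    """Net current (per unit depth, A/m) through each electrode, from the
    discrete residual at the Dirichlet nodes; equal magnitudes express
    discrete current conservation."""
    G = ctx.lumped * (ctx.g_m + g_ep_all + ctx.c_m / dt)
    C = ctx.lumped * (ctx.c_m / dt)
    S = ctx.S_int
    A = ctx.K_sigma + ctx.K_eps / dt + S @ sp.diags(G) @ S.T
    b = ctx.K_eps @ psi_old / dt + S @ (C * (S.T @ psi_old))
    res = A @ psi_new - b
    i_left = float(res[ctx.mesh.left_nodes].sum())
    i_right = float(res[ctx.mesh.right_nodes].sum())
    return i_left, i_right


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _membrane_sigma_bulk(name: str, params: ModelParams) -> float:
    if name == "outer_membrane":
        return 0.5 * (params.medium.sigma + params.cytoplasm.sigma)
    return 0.5 * (params.cytoplasm.sigma + params.nucleoplasm.sigma)


def _membrane_thickness(name: str, params: ModelParams) -> float:
    return params.geometry.d_mem if name == "outer_membrane" else params.geometry.d_ne


def _membrane_ep(name: str, params: ModelParams):
    return params.ep if name == "outer_membrane" else params.ep_inner


def run_simulation(params: ModelParams, mesh: SimMesh,
                   t_end: float | None = None,
                   dt_fine: float = 0.1e-9, dt_coarse: float = 1.0e-9,
                   dV_max: float = 0.1, dA_max: float = 0.01,
                   snapshot_times: tuple[float, ...] = (),
                   electroporation: bool = True,
                   record_every: int = 1) -> SimResult:
    """Run the coupled field + electroporation simulation from rest to t_end.

    Operator splitting per accepted step: an implicit field+membrane-charging
    solve at frozen pore state, then the pore update at frozen V_m. The step
    size tracks the pulse (dt_fine during rise/fall, dt_coarse elsewhere) and
    a step is rejected and halved whenever any membrane node's V_m changes by
    more than ``dV_max`` or its pore area fraction by more than ``dA_max`` —
    the creation ODE is stiff in V_m near the poration threshold.
    """
    pulse = params.pulse
    if t_end is None:
        t_end = pulse.t_end
    ctx = assemble(mesh, params)
    side = params.geometry.domain_side

    mem: dict[str, MembraneState] = {}
    for name in ctx.iface_order:
        iface = mesh.interfaces[name]
        ep = _membrane_ep(name, params)
        st = pores.rest_state(iface.n_nodes, ep, steric=params.steric)
        mem[name] = MembraneState(theta=iface.theta,
                                  V_m=np.zeros(iface.n_nodes),
                                  pore=st,
                                  g_ep=_g_ep_of(st, name, params,
                                                electroporation))
    psi = np.zeros(mesh.n_nodes)

    cell_mask = cell_interior_mask(mesh) if mesh.interfaces else None
    rec_t, rec_maxE, rec_maxEc = [], [], []
    rec_mem: dict[str, dict[str, list]] = {
        name: {"V_m": [], "N": [], "r_pore": [], "g_ep": [], "A_frac": []}
        for name in ctx.iface_order}
    snapshots: list[FieldState] = []
    snap_left = sorted(snapshot_times)

    def record(t, psi):
        E, mx = field_magnitude(ctx, psi)
        rec_t.append(t)
        rec_maxE.append(mx)
        if cell_mask is not None and cell_mask.any():
            rec_maxEc.append(float(E[cell_mask].max()))
        else:
            rec_maxEc.append(np.nan)
        for name, ms in mem.items():
            rec_mem[name]["V_m"].append(ms.V_m.copy())
            rec_mem[name]["N"].append(ms.pore.N.copy())
            rec_mem[name]["r_pore"].append(ms.pore.r_pore.copy())
            rec_mem[name]["g_ep"].append(ms.g_ep.copy())
            rec_mem[name]["A_frac"].append(ms.pore.A_frac.copy())

    record(0.0, psi)
    t = 0.0
    dt = dt_fine
    n_steps = n_rejected = 0
    fall_start = pulse.t_rise + pulse.t_width - pulse.t_fall
    fall_end = pulse.t_rise + pulse.t_width
    step_idx = 0
    while t < t_end - 1e-15:
        in_ramp = (t < pulse.t_rise + 2 * dt_fine) or \
                  (fall_start - 2 * dt_fine <= t < fall_end + 2 * dt_fine)
        dt_max = dt_fine if in_ramp else dt_coarse
        dt = min(dt, dt_max, t_end - t)
        if snap_left and t < snap_left[0] <= t + dt:
            dt = snap_left[0] - t  # land exactly on the snapshot time
        accepted = False
        for _ in range(60):
            V_drive = pulse_value(pulse, t + dt) * side
            g_all = _gather_g_ep(ctx, mem)
            psi_new = step(ctx, psi, g_all, V_drive, dt)
            vm_new = transmembrane_voltage(ctx, psi_new)
            dV = max((np.max(np.abs(vm_new[name] - mem[name].V_m))
                      for name in ctx.iface_order), default=0.0)
            if dV > dV_max and dt > 1e-13:
                dt *= 0.5
                n_rejected += 1
                continue
            new_mem = {}
            dA = 0.0
            if electroporation:
                for name, ms in mem.items():
                    ep = _membrane_ep(name, params)
                    p_new = pores.advance_pores(ms.pore, vm_new[name], dt, ep,
                                                steric=params.steric)
                    dA = max(dA, float(np.max(np.abs(p_new.A_frac - ms.pore.A_frac))))
                    new_mem[name] = (p_new, vm_new[name])
            else:
                for name, ms in mem.items():
                    new_mem[name] = (ms.pore, vm_new[name])
            if dA > dA_max and dt > 1e-13:
                dt *= 0.5
                n_rejected += 1
                continue
            accepted = True
            break
        if not accepted:
            raise SolverError(f"time step rejected 60 times at t = {t:.3e} s")
        t += dt
        psi = psi_new
        for name, (p_new, vm) in new_mem.items():
            mem[name].pore = p_new
            mem[name].V_m = vm
            mem[name].g_ep = _g_ep_of(p_new, name, params, electroporation)
        n_steps += 1
        step_idx += 1
        if snap_left and t >= snap_left[0] - 1e-15:
            snapshots.append(FieldState(t=t, psi=psi.copy()))
            snap_left.pop(0)
        if step_idx % record_every == 0 or t >= t_end - 1e-15:
            record(t, psi)
        dt = min(dt * 1.3, dt_max)

    membranes = {}
    for name in ctx.iface_order:
        membranes[name] = {"theta": mesh.interfaces[name].theta,
                           "lumped_len": mesh.interfaces[name].lumped_len}
        for key, lst in rec_mem[name].items():
            membranes[name][key] = np.array(lst)
    return SimResult(times=np.array(rec_t), max_E_domain=np.array(rec_maxE),
                     max_E_cell=np.array(rec_maxEc), membranes=membranes,
                     snapshots=snapshots, mesh=mesh,
                     n_steps=n_steps, n_rejected=n_rejected)


def _g_ep_of(pore_state: pores.PoreModelState, name: str, params: ModelParams,
             electroporation: bool) -> np.ndarray:
    if not electroporation:
        return np.zeros_like(pore_state.N)
    ep = _membrane_ep(name, params)
    return pores.areal_pore_conductance(
        pore_state.N, pore_state.r_pore, ep, _membrane_thickness(name, params),
        sigma_bulk=_membrane_sigma_bulk(name, params),
        model=params.pore_current_model)


def _gather_g_ep(ctx: SolverContext, mem: dict[str, MembraneState]) -> np.ndarray:
    if not ctx.iface_order:
        return np.zeros(0)
    return np.concatenate([mem[name].g_ep for name in ctx.iface_order])


def solve_static(ctx: SolverContext, V_drive: float = 0.0,
                 dirichlet: tuple[np.ndarray, np.ndarray] | None = None) -> np.ndarray:
    """Steady conduction solve (no displacement current, membranes passive):
    the DC limit used by the analytic oracles and the tip-field diagnostic.

    By default the electrodes are driven at ``V_drive``/0; passing
    ``dirichlet=(node_ids, values)`` instead imposes arbitrary boundary
    values (used to test against closed-form solutions without domain
    truncation error)."""
    G = ctx.lumped * ctx.g_m
    S = ctx.S_int
    A = (ctx.K_sigma + S @ sp.diags(G) @ S.T).tocsr()
    psi = np.zeros(ctx.mesh.n_nodes)
    if dirichlet is None:
        fixed = ctx.dirichlet
        psi[fixed] = V_drive * ctx.dirichlet_scale
        f = ctx.free
    else:
        fixed, values = dirichlet
        psi[fixed] = values
        mask = np.ones(ctx.mesh.n_nodes, dtype=bool)
        mask[fixed] = False
        f = np.flatnonzero(mask)
    rhs = -(A[f][:, fixed] @ psi[fixed])
    psi[f] = splu(A[f][:, f].tocsc()).solve(rhs)
    return psi
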