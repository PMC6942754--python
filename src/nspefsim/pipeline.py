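"""High-level orchestration shared by the command line and scripts:
scene -> mesh -> coupled simulation -> scalar summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import geometry, meshing, postprocess, solver
from .params import ModelParams, _KEYS, _set_path, ParamError


@dataclass
class CaseResult:
    scene: geometry.Scene
    mesh: meshing.SimMesh
    ctx: solver.SolverContext
    result: solver.SimResult
    summaries: dict
    scalars: dict


def run_case(params: ModelParams, seed: int | None = None,
             with_cnts: bool = True, t_end: float | None = None,
             snapshot_times: tuple[float, ...] | None = None,
             record_every: int = 1) -> CaseResult:
    """Run one full case: sample CNTs (if any), mesh, simulate, postprocess.

    The plateau snapshot defaults to the mid-pulse time
    t_rise + t_width/2. Scalars: plateau max |E| over the domain and over the
    cell interior, the end-time electroporated areas and fluxes, and the
    maximum pore density per membrane.
    """
    n_cnts = params.cnt_config.n if with_cnts else 0
    if n_cnts > 0:
        if seed is None:
            raise ParamError("a seed is required when sampling CNTs")
        cnts = geometry.sample_cnts(params, seed)
    else:
        cnts = []
    scene = geometry.build_scene(params, cnts, seed=seed)
    mesh = meshing.build_mesh(scene, h_far=params.mesh.h_far,
                              h_membrane=params.mesh.h_membrane,
                              h_tip_frac=params.mesh.h_tip_frac,
                              min_angle_deg=params.mesh.min_angle_deg)
    pulse = params.pulse
    t_plateau = pulse.t_rise + 0.5 * pulse.t_width
    if snapshot_times is None:
        snapshot_times = (t_plateau,)
    result = solver.run_simulation(params, mesh, t_end=t_end,
                                   snapshot_times=snapshot_times,
                                   record_every=record_every)
    ctx = solver.assemble(mesh, params)

    summaries = {name: postprocess.electroporated_area(result, name)
                 for name in result.membranes}
    scalars = plateau_scalars(ctx, result, t_plateau)
    for name, summ in summaries.items():
        short = "outer" if name == "outer_membrane" else "inner"
        scalars[f"S_end_{short}"] = float(summ.S[-1])
        scalars[f"flux_end_{short}"] = float(summ.flux[-1])
        scalars[f"max_N_{short}"] = float(result.membranes[name]["N"].max())
    return CaseResult(scene=scene, mesh=mesh, ctx=ctx, result=result,
                      summaries=summaries, scalars=scalars)


def plateau_scalars(ctx, result, t_plateau: float) -> dict:
    """Max field magnitudes at the snapshot closest to the plateau time."""
    scal = {}
    if result.snapshots:
        snap = min(result.snapshots, key=lambda s: abs(s.t - t_plateau))
        E, mx = solver.field_magnitude(ctx, snap.psi)
        scal["t_snapshot"] = snap.t
        scal["max_E_domain"] = mx
        mask = solver.cell_interior_mask(ctx.mesh)
        if mask.any():
            scal["max_E_cell"] = float(E[mask].max())
    return scal


def plateau_maxima(params: ModelParams, cnts: list, t_snap: float = 152e-9,
                   t_end: float = 155e-9) -> dict:
    """Run the coupled simulation to just past the plateau snapshot and
    return the per-element field maxima (kV/cm) over the whole domain and
    over the cell interior, plus the mesh size."""
    import warnings

    scene = geometry.build_scene(params, cnts)
    mesh = meshing.build_mesh(scene, h_far=params.mesh.h_far,
                              h_membrane=params.mesh.h_membrane,
                              h_tip_frac=params.mesh.h_tip_frac,
                              min_angle_deg=params.mesh.min_angle_deg)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = solver.run_simulation(params, mesh, t_end=t_end,
                                       snapshot_times=(t_snap,))
    ctx = solver.assemble(mesh, params)
    snap = result.snapshots[0]
    E, mx = solver.field_magnitude(ctx, snap.psi)
    cell = solver.cell_interior_mask(mesh)
    return {"max_E_domain_kVcm": mx / 1e5,
            "max_E_cell_kVcm": float(E[cell].max()) / 1e5,
            "n_triangles": mesh.n_triangles, "mesh": mesh, "result": result,
            "ctx": ctx}


def cnt_free_reference(h_membrane: float = 0.2e-6, h_far: float = 4e-6) -> dict:
    """The CNT-free five-layer scene at the 6 kV/cm pulse plateau, on a mesh
    fine enough that halving h changes the maxima by < 2% (verified in the
    test suite)."""
    params = _default()
    params.mesh.h_membrane = h_membrane
    params.mesh.h_far = h_far
    params.mesh.min_angle_deg = 0.5
    return plateau_maxima(params, [])


def cnt_ensemble(seed: int, n_seeds: int = 20,
                 h_membrane: float = 1e-6, h_far: float = 10e-6) -> dict:
    """Plateau maxima for ``n_seeds`` random 5-capsule configurations.

    Child seeds are spawned deterministically from ``seed``; the mesh density
    is reduced relative to the CNT-free reference so the ensemble stays
    desk-scale."""
    child_seeds = (np.random.SeedSequence(seed).generate_state(n_seeds)
                   % np.uint32(2**31)).astype(int)
    domain, cell = [], []
    for s in child_seeds:
        params = _default()
        params.mesh.h_membrane = h_membrane
        params.mesh.h_far = h_far
        params.mesh.min_angle_deg = 0.5
        cnts = geometry.sample_cnts(params, int(s))
        out = plateau_maxima(params, cnts)
        domain.append(out["max_E_domain_kVcm"])
        cell.append(out["max_E_cell_kVcm"])
    return {"seeds": child_seeds.tolist(),
            "max_E_domain_kVcm": domain, "max_E_cell_kVcm": cell}


def single_capsule_tip_field(E0: float = 1e4, L: float = 1e-6, D: float = 10e-9,
                             side: float = 8e-6, h_tip_frac: float = 0.25) -> float:
    """Solved max field (V/m) outside a lone conductive capsule in a uniform
    background field E0: the lightning-rod worked example."""
    params = _default()
    cap = geometry.Capsule((side / 2, side / 2), 0.0, L, D)
    scene = geometry.Scene(side=side, center=(side / 2, side / 2),
                           r_c=1e-6, r_n=0.5e-6, d_mem=5e-9, d_ne=40e-9,
                           include_cell=False, cnts=[cap])
    mesh = meshing.build_mesh(scene, h_far=side / 10, h_membrane=side / 10,
                              h_tip_frac=h_tip_frac, min_angle_deg=0.5)
    ctx = solver.assemble(mesh, params)
    psi = solver.solve_static(ctx, E0 * side)
    E, _ = solver.field_magnitude(ctx, psi)
    return float(E[mesh.region < meshing.REGION_CNT_BASE].max())


def _default() -> ModelParams:
    from .params import default_params
    return default_params()


def apply_sweep_key(params: ModelParams, key: str, value) -> None:
    """Set one sweep parameter. Besides the flat config keys, the synthetic
    key ``cnt_aspect`` fixes D at the current range midpoint and sets
    L = aspect * D (degenerate ranges), so aspect-ratio sweeps are one key."""
    if key == "cnt_aspect":
        cfg = params.cnt_config
        D = 0.5 * (cfg.D_min + cfg.D_max)
        cfg.D_min = cfg.D_max = D
        cfg.L_min = cfg.L_max = float(value) * D
        return
    if key not in _KEYS:
        raise ParamError(f"unknown sweep key {key!r}; valid keys: "
                         + ", ".join(sorted(list(_KEYS) + ["cnt_aspect"])))
    _set_path(params, _KEYS[key][0], float(value))
    params.validate()
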