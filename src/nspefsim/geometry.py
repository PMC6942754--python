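"""Scene construction: the five-layer cell in its square domain plus
Monte Carlo placement of conductive CNT capsules.

A capsule (stadium) is the 2D cross-section of a cylindrical CNT: a rectangle
of length L - D with two semicircular caps of radius D/2, so L is the
tip-to-tip length. Capsules are placed by rejection sampling: centers uniform
over a radial band around the cell, orientations uniform, L and D uniform in
their ranges; candidates that touch the cell membrane, another capsule, an
electrode, or the domain boundary are rejected. Identical seeds give
identical configurations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import LineString, Point, Polygon, box

from .params import ModelParams, ParamError


class PackingError(RuntimeError):
    """Raised when the rejection-sampling budget is exhausted."""

    def __init__(self, placed: int, requested: int, budget: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could not place capsule {placed + 1} of {requested} within "
            f"{budget} attempts; {placed} capsules placed")


@dataclass
class Capsule:
    """CNT cross-section: stadium of tip-to-tip length L and diameter D."""

    center: tuple[float, float]  # m, domain coordinates
    angle: float                 # orientation to the field (x) axis, rad
    L: float                     # tip-to-tip length, m
    D: float                     # diameter, m

    def __post_init__(self) -> None:
        if not (self.L > self.D > 0):
            raise ParamError(f"capsule: need L > D > 0, got L={self.L}, D={self.D}")

    @property
    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Centers of the two semicircular caps."""
        half = 0.5 * (self.L - self.D)
        d = np.array([np.cos(self.angle), np.sin(self.angle)])
        c = np.asarray(self.center)
        return c - half * d, c + half * d

    def polygon(self, quad_segs: int = 32) -> Polygon:
        a, b = self.endpoints
        return LineString([a, b]).buffer(self.D / 2, quad_segs=quad_segs)


@dataclass
class Scene:
    """Cell layers + electrodes + accepted CNT capsules, domain coordinates.

    The domain is the square [0, side] x [0, side]; the cell is centered at
    (side/2, side/2). The left edge (x = 0) is the driven electrode, the
    right edge (x = side) is grounded.
    """

    side: float
    center: tuple[float, float]
    r_c: float
    r_n: float
    d_mem: float
    d_ne: float
    cnts: list[Capsule] = field(default_factory=list)
    seed: int | None = None
    include_cell: bool = True
    include_nucleus: bool = True

    def cell_circle(self) -> Polygon:
        return Point(self.center).buffer(self.r_c, quad_segs=64)

    def nucleus_circle(self) -> Polygon:
        return Point(self.center).buffer(self.r_n, quad_segs=64)

    def domain_box(self) -> Polygon:
        return box(0.0, 0.0, self.side, self.side)


def _check_capsule(cap: Capsule, scene: Scene, clearance: float) -> bool:
    """Exact stadium-geometry admissibility test for one candidate capsule."""
    poly = cap.polygon()
    inset = scene.domain_box().buffer(-clearance)
    if not poly.within(inset):
        return False  # leaves the domain or touches an electrode/boundary
    if scene.include_cell and poly.distance(Point(scene.center)) < scene.r_c + clearance:
        return False  # overlaps the outer membrane annulus
    for other in scene.cnts:
        if poly.distance(other.polygon()) < clearance:
            return False
    return True


def sample_cnts(params: ModelParams, seed: int,
                scene: Scene | None = None) -> list[Capsule]:
    """Sample ``params.cnt_config.n`` admissible capsules by rejection.

    Centers are uniform over the annulus band ``[band_min, band_max]`` around
    the cell center, orientations uniform on [0, pi), L and D uniform in
    their ranges. Raises :class:`PackingError` if a capsule cannot be placed
    within the attempt budget.
    """
    cfg = params.cnt_config
    cfg.validate()
    if scene is None:
        scene = build_scene(params, [])
    else:
        scene = Scene(**{**scene.__dict__, "cnts": []})
    rng = np.random.default_rng(seed)
    placed: list[Capsule] = []
    for k in range(cfg.n):
        for _ in range(cfg.max_attempts):
            # area-uniform radius in the annulus band
            u = rng.uniform(cfg.band_min ** 2, cfg.band_max ** 2)
            rad = np.sqrt(u)
            phi = rng.uniform(0.0, 2 * np.pi)
            cx = scene.center[0] + rad * np.cos(phi)
            cy = scene.center[1] + rad * np.sin(phi)
            ang = rng.uniform(0.0, np.pi)
            L = rng.uniform(cfg.L_min, cfg.L_max)
            D = rng.uniform(cfg.D_min, cfg.D_max)
            if L <= D:
                continue
            cand = Capsule((cx, cy), ang, L, D)
            if _check_capsule(cand, scene, cfg.clearance):
                placed.append(cand)
                scene.cnts.append(cand)
                break
        else:
            raise PackingError(k, cfg.n, cfg.max_attempts)
    return placed


def build_scene(params: ModelParams, cnts: list[Capsule],
                include_cell: bool = True, seed: int | None = None) -> Scene:
    """Assemble a :class:`Scene`, validating every capsule against the cell,
    the electrodes, the domain, and the other capsules."""
    g = params.geometry
    g.validate()
    scene = Scene(side=g.domain_side,
                  center=(g.domain_side / 2, g.domain_side / 2),
                  r_c=g.r_c, r_n=g.r_n, d_mem=g.d_mem, d_ne=g.d_ne,
                  cnts=[], seed=seed, include_cell=include_cell)
    for idx, cap in enumerate(cnts):
        if not _check_capsule(cap, scene, params.cnt_config.clearance):
            raise ParamError(f"capsule {idx} violates scene invariants "
                             f"(overlap or out of domain)")
        scene.cnts.append(cap)
    return scene


def scene_to_json(scene: Scene, path) -> None:
    """Serialize the scene (coordinates in micrometers) to JSON."""
    um = 1e6
    doc = {
        "side_um": scene.side * um,
        "center_um": [c * um for c in scene.center],
        "r_c_um": scene.r_c * um, "r_n_um": scene.r_n * um,
        "d_mem_um": scene.d_mem * um, "d_ne_um": scene.d_ne * um,
        "seed": scene.seed,
        "include_cell": scene.include_cell,
        "cnts": [
            {"center_um": [c * um for c in cap.center], "angle_rad": cap.angle,
             "L_um": cap.L * um, "D_um": cap.D * um}
            for cap in scene.cnts
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def scene_from_json(path) -> Scene:
    with open(path) as fh:
        doc = json.load(fh)
    m = 1e-6
    return Scene(
        side=doc["side_um"] * m,
        center=tuple(c * m for c in doc["center_um"]),
        r_c=doc["r_c_um"] * m, r_n=doc["r_n_um"] * m,
        d_mem=doc["d_mem_um"] * m, d_ne=doc["d_ne_um"] * m,
        seed=doc.get("seed"), include_cell=doc.get("include_cell", True),
        cnts=[Capsule(tuple(c * m for c in d["center_um"]), d["angle_rad"],
                      d["L_um"] * m, d["D_um"] * m) for d in doc["cnts"]],
    )
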