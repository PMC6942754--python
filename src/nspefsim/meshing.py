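"""Region-tagged triangulation of a :class:`~nspefsim.geometry.Scene`.

The mesher is built on ``scipy.spatial.Delaunay``:

1. boundary nodes are laid out along the square boundary, the two membrane
   circles, and every capsule outline, with spacing taken from a Lipschitz
   size field (fine at capsule caps, ``h_membrane`` on the membrane contours,
   ``h_far`` in the bulk);
2. interior nodes come from a graded quadtree (cell centers with a small
   deterministic jitter), filtered so no interior node invades the diametral
   circle of a boundary segment — this is what guarantees Delaunay recovers
   every interface edge, which is verified explicitly;
3. triangles are tagged by point-in-region tests of their centroids;
4. the membranes are *not* meshed as thin layers: each membrane circle is
   slit into an inner and an outer node trace (duplicated coordinates), and
   the field solver couples the traces through the distributed-impedance
   membrane current law.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .geometry import Scene

REGION_MEDIUM = 0
REGION_CYTOPLASM = 1
REGION_NUCLEOPLASM = 2
REGION_CNT_BASE = 10  # capsule k -> REGION_CNT_BASE + k

REGION_NAMES = {REGION_MEDIUM: "medium", REGION_CYTOPLASM: "cytoplasm",
                REGION_NUCLEOPLASM: "nucleoplasm"}


class MeshError(RuntimeError):
    """Mesh generation failed; the message carries scene diagnostics."""


@dataclass
class Interface:
    """One slit membrane contour.

    ``outer_nodes[i]`` and ``inner_nodes[i]`` sit at identical coordinates;
    the outer ids belong to triangles outside the circle, the inner ids to
    triangles inside. Consecutive indices are adjacent along the contour.
    """

    name: str
    outer_nodes: np.ndarray   # (K,) node ids, ordered by theta
    inner_nodes: np.ndarray   # (K,) duplicated node ids
    theta: np.ndarray         # (K,) polar angle from the field (+x) axis, rad
    normal: np.ndarray        # (K, 2) outward unit normal
    lumped_len: np.ndarray    # (K,) half-sum of adjacent contour edge lengths, m
    radius: float

    @property
    def n_nodes(self) -> int:
        return len(self.outer_nodes)

    @property
    def circumference(self) -> float:
        return float(self.lumped_len.sum())


@dataclass
class SimMesh:
    nodes: np.ndarray                  # (N, 2) coordinates, m
    triangles: np.ndarray              # (M, 3) node ids
    region: np.ndarray                 # (M,) region tag per triangle
    interfaces: dict[str, Interface] = field(default_factory=dict)
    left_nodes: np.ndarray = None      # driven electrode (x = 0)
    right_nodes: np.ndarray = None     # ground electrode (x = side)
    scene: Scene = None
    h_far: float = 0.0
    h_membrane: float = 0.0
    min_angle_deg: float = 0.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        u = p[:, 1] - p[:, 0]
        v = p[:, 2] - p[:, 0]
        return 0.5 * np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])

    def centroids(self) -> np.ndarray:
        return self.nodes[self.triangles].mean(axis=1)


# ---------------------------------------------------------------------------
# size field
# ---------------------------------------------------------------------------

_GRADE = 0.5  # default Lipschitz constant of the size field


class _SizeField:
    def __init__(self, scene: Scene, h_far: float, h_mem: float, h_tips: list[float],
                 grade: float = _GRADE):
        self.scene = scene
        self.h_far = h_far
        self.h_mem = h_mem
        self.h_tips = h_tips
        self.grade = grade
        self.center = np.asarray(scene.center)
        self.segs = []  # capsule skeleton segments (a, b, radius)
        for cap in scene.cnts:
            a, b = cap.endpoints
            self.segs.append((a, b, cap.D / 2))

    def _dist_segment(self, pts, a, b):
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
        proj = a + np.outer(t, ab) if denom > 0 else np.broadcast_to(a, pts.shape)
        return np.linalg.norm(pts - proj, axis=1)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        h = np.full(len(pts), self.h_far)
        if self.scene.include_cell:
            r = np.linalg.norm(pts - self.center, axis=1)
            h = np.minimum(h, self.h_mem + self.grade * np.abs(r - self.scene.r_c))
            if getattr(self.scene, "include_nucleus", True):
                h = np.minimum(h, self.h_mem + self.grade * np.abs(r - self.scene.r_n))
        for (a, b, rad), h_tip in zip(self.segs, self.h_tips):
            d = np.abs(self._dist_segment(pts, a, b) - rad)
            h = np.minimum(h, h_tip + self.grade * d)
        return h


# ---------------------------------------------------------------------------
# boundary node layout
# ---------------------------------------------------------------------------

def _walk_circle(center, radius, size_fn) -> np.ndarray:
    """Sample a circle with locally adaptive arc spacing; returns (K,2) points
    ordered by increasing theta starting at theta = 0."""
    thetas = [0.0]
    while True:
        th = thetas[-1]
        x = center + radius * np.array([np.cos(th), np.sin(th)])
        step = float(size_fn(x[None, :])[0]) / radius
        if th + step >= 2 * np.pi:
            break
        thetas.append(th + step)
    th = np.array(thetas)
    # rescale uniformly so the loop closes with a full-size final segment
    th = th * (2 * np.pi) / (th[-1] + step)
    th = th[th < 2 * np.pi - 1e-12]
    pts = center + radius * np.stack([np.cos(th), np.sin(th)], axis=1)
    return pts


def _capsule_outline(cap, h_tip: float) -> np.ndarray:
    """Closed stadium outline with fine caps and geometrically graded sides."""
    a, b = cap.endpoints
    rho = cap.D / 2
    direction = (b - a) / np.linalg.norm(b - a)
    nrm = np.array([-direction[1], direction[0]])
    ang0 = np.arctan2(nrm[1], nrm[0])

    n_cap = max(6, int(np.ceil(np.pi * rho / h_tip)))
    # graded spacing along a straight side of length Ls
    Ls = float(np.linalg.norm(b - a))
    s_vals = [0.0]
    h_max = 4.0 * rho
    s = 0.0
    while True:
        step = min(h_max, h_tip + _GRADE * min(s, Ls - s))
        if s + step >= Ls - 0.5 * h_tip:
            break
        s += step
        s_vals.append(s)
    s_vals.append(Ls)
    s_arr = np.array(s_vals)

    pts = []
    # side 1: from a+rho*nrm to b+rho*nrm
    for s in s_arr[:-1]:
        pts.append(a + direction * s + rho * nrm)
    # cap at b: angle from ang0 to ang0 - pi (turning through the +direction tip)
    for i in range(n_cap):
        th = ang0 - np.pi * i / n_cap
        pts.append(b + rho * np.array([np.cos(th), np.sin(th)]))
    # side 2: back along -nrm
    for s in s_arr[::-1][:-1]:
        pts.append(a + direction * s - rho * nrm)
    # cap at a
    for i in range(n_cap):
        th = ang0 - np.pi - np.pi * i / n_cap
        pts.append(a + rho * np.array([np.cos(th), np.sin(th)]))
    return np.array(pts)


def _square_boundary(side: float, size_fn) -> np.ndarray:
    corners = np.array([[0, 0], [side, 0], [side, side], [0, side]], float)
    pts = []
    for i in range(4):
        a, c = corners[i], corners[(i + 1) % 4]
        direction = (c - a) / side
        s = 0.0
        edge_pts = [a.copy()]
        while True:
            x = a + s * direction
            step = float(size_fn(x[None, :])[0])
            if s + step >= side - 1e-12:
                break
            s += step
            edge_pts.append(a + s * direction)
        pts.extend(edge_pts)
    return np.array(pts)


# ---------------------------------------------------------------------------
# interior nodes: graded quadtree
# ---------------------------------------------------------------------------

def _quadtree_points(side: float, size_fn, h_min: float) -> np.ndarray:
    """Centers of graded quadtree leaves, with small deterministic jitter."""
    n0 = 8
    size = side / n0
    xs = (np.arange(n0) + 0.5) * size
    cx, cy = np.meshgrid(xs, xs)
    centers = np.stack([cx.ravel(), cy.ravel()], axis=1)
    sizes = np.full(len(centers), size)
    out_pts = []
    rng = np.random.default_rng(987654321)  # fixed: mesh is a pure function of inputs
    for _ in range(40):
        h = size_fn(centers)
        refine = sizes > np.maximum(0.9 * h, 1.5 * h_min)
        done = ~refine
        if done.any():
            keep = centers[done]
            jitter = (rng.random(keep.shape) - 0.5) * 0.4 * sizes[done, None]
            out_pts.append(keep + jitter)
        if not refine.any():
            break
        c = centers[refine]
        s = sizes[refine]
        off = 0.25 * s
        centers = np.concatenate([
            c + np.stack([off, off], axis=1) * d
            for d in ([1, 1], [1, -1], [-1, 1], [-1, -1])
        ])
        sizes = np.concatenate([s / 2] * 4)
    return np.concatenate(out_pts) if out_pts else np.empty((0, 2))


# ---------------------------------------------------------------------------
# main entry
# ---------------------------------------------------------------------------

def _local_spacing(pts: np.ndarray, closed: bool = True) -> np.ndarray:
    """Per-node spacing of an ordered closed polyline: the max adjacent edge,
    so the interior-point filter keeps every boundary edge's diametral circle
    empty even across grading transitions."""
    nxt = np.roll(pts, -1, axis=0)
    d_next = np.linalg.norm(nxt - pts, axis=1)
    d_prev = np.roll(d_next, 1)
    if not closed:
        d_next[-1] = d_prev[-1]
        d_prev[0] = d_next[0]
    return np.maximum(d_next, d_prev)


def build_mesh(scene: Scene, h_far: float = 8e-6, h_membrane: float = 0.4e-6,
               h_tip_frac: float = 0.35, min_angle_deg: float = 5.0,
               n_smooth: int = 1, slit_membranes: bool = True,
               grade: float = _GRADE) -> SimMesh:
    """Build the region-tagged, membrane-slit triangulation of ``scene``.

    ``h_tip_frac`` sets the cap element size as a fraction of each capsule's
    radius, so thin capsules are meshed proportionally finer. Raises
    :class:`MeshError` if interface recovery or the quality floor fails.
    """
    if not (0 < h_membrane <= h_far):
        raise MeshError("need 0 < h_membrane <= h_far")
    h_tips = [h_tip_frac * cap.D / 2 for cap in scene.cnts]
    size_fn = _SizeField(scene, h_far, h_membrane, h_tips, grade=grade)
    center = np.asarray(scene.center)

    fixed_groups: list[np.ndarray] = []   # each: ordered closed polyline
    group_kind: list[str] = []
    sq = _square_boundary(scene.side, size_fn)
    fixed_groups.append(sq)
    group_kind.append("square")
    include_nucleus = getattr(scene, "include_nucleus", True)
    if scene.include_cell:
        fixed_groups.append(_walk_circle(center, scene.r_c, size_fn))
        group_kind.append("outer_membrane")
        if include_nucleus:
            fixed_groups.append(_walk_circle(center, scene.r_n, size_fn))
            group_kind.append("nuclear_envelope")
    for cap, h_tip in zip(scene.cnts, h_tips):
        fixed_groups.append(_capsule_outline(cap, h_tip))
        group_kind.append("cnt")

    fixed = np.concatenate(fixed_groups)
    spacing = np.concatenate([_local_spacing(g) for g in fixed_groups])

    h_min = min(h_tips) if h_tips else h_membrane
    interior = _quadtree_points(scene.side, size_fn, h_min)
    # keep interior nodes out of the diametral circles of boundary segments
    tree = cKDTree(fixed)
    d, idx = tree.query(interior, k=1)
    interior = interior[d > 0.75 * spacing[idx]]
    inside_dom = ((interior[:, 0] > 1e-12) & (interior[:, 0] < scene.side - 1e-12)
                  & (interior[:, 1] > 1e-12) & (interior[:, 1] < scene.side - 1e-12))
    interior = interior[inside_dom]

    points = np.concatenate([fixed, interior])
    n_fixed = len(fixed)

    tri = Delaunay(points)
    for _ in range(max(0, n_smooth)):
        points = _smooth(points, tri, n_fixed)
        tri = Delaunay(points)

    triangles = tri.simplices.copy()
    nodes = points.copy()

    # region tagging by centroid
    cent = nodes[triangles].mean(axis=1)
    region = np.full(len(triangles), REGION_MEDIUM, dtype=int)
    if scene.include_cell:
        r = np.linalg.norm(cent - center, axis=1)
        region[r < scene.r_c] = REGION_CYTOPLASM
        if include_nucleus:
            region[r < scene.r_n] = REGION_NUCLEOPLASM
    for k, cap in enumerate(scene.cnts):
        a, b = cap.endpoints
        ab = b - a
        t = np.clip(((cent - a) @ ab) / float(ab @ ab), 0.0, 1.0)
        dseg = np.linalg.norm(cent - (a + np.outer(t, ab)), axis=1)
        region[dseg < cap.D / 2] = REGION_CNT_BASE + k

    # locate the ordered contour node ids of each group
    offsets = np.cumsum([0] + [len(g) for g in fixed_groups])
    interfaces: dict[str, Interface] = {}
    mesh = SimMesh(nodes=nodes, triangles=triangles, region=region,
                   interfaces=interfaces, scene=scene, h_far=h_far,
                   h_membrane=h_membrane)
    edge_set = _edge_set(triangles)
    for gi, kind in enumerate(group_kind):
        ids = np.arange(offsets[gi], offsets[gi + 1])
        if kind in ("outer_membrane", "nuclear_envelope", "cnt"):
            _check_contour_recovery(ids, edge_set, kind)
        if slit_membranes and kind in ("outer_membrane", "nuclear_envelope"):
            radius = scene.r_c if kind == "outer_membrane" else scene.r_n
            interfaces[kind] = _insert_slit(mesh, ids, center, radius, kind)

    # electrode node sets (post-slit node array)
    x = mesh.nodes[:, 0]
    mesh.left_nodes = np.flatnonzero(np.abs(x) < 1e-12)
    mesh.right_nodes = np.flatnonzero(np.abs(x - scene.side) < 1e-12)

    mesh.min_angle_deg = float(_min_angle_deg(mesh.nodes, mesh.triangles))
    if mesh.min_angle_deg < min_angle_deg:
        raise MeshError(
            f"mesh quality below floor: min angle {mesh.min_angle_deg:.2f} deg "
            f"< {min_angle_deg} deg (scene: {len(scene.cnts)} capsules, "
            f"h_far={h_far}, h_membrane={h_membrane})")
    return mesh


def _smooth(points: np.ndarray, tri: Delaunay, n_fixed: int) -> np.ndarray:
    """One Laplacian smoothing pass on interior (non-fixed) nodes."""
    n = len(points)
    t = tri.simplices
    nbr_sum = np.zeros((n, 2))
    nbr_cnt = np.zeros(n)
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            np.add.at(nbr_sum, t[:, i], points[t[:, j]])
            np.add.at(nbr_cnt, t[:, i], 1.0)
    out = points.copy()
    free = np.arange(n_fixed, n)
    out[free] = nbr_sum[free] / np.maximum(nbr_cnt[free, None], 1.0)
    return out


def _edge_set(triangles: np.ndarray) -> set:
    e = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    e.sort(axis=1)
    return set(map(tuple, e.tolist()))


def _check_contour_recovery(ids: np.ndarray, edge_set: set, kind: str) -> None:
    k = len(ids)
    missing = [(int(ids[i]), int(ids[(i + 1) % k]))
               for i in range(k)
               if tuple(sorted((ids[i], ids[(i + 1) % k]))) not in edge_set]
    if missing:
        raise MeshError(f"{kind} contour not recovered by the triangulation: "
                        f"{len(missing)} of {k} edges missing (first: {missing[0]})")


def _insert_slit(mesh: SimMesh, ids: np.ndarray, center: np.ndarray,
                 radius: float, name: str) -> Interface:
    """Duplicate contour nodes; interior triangles rebind to the duplicates."""
    nodes, triangles = mesh.nodes, mesh.triangles
    k = len(ids)
    dup = np.arange(len(nodes), len(nodes) + k)
    mesh.nodes = np.concatenate([nodes, nodes[ids]])
    remap = -np.ones(len(mesh.nodes), dtype=int)
    remap[ids] = dup
    cent = nodes[triangles].mean(axis=1)
    inside = np.linalg.norm(cent - center, axis=1) < radius
    tin = triangles[inside]
    mask = remap[tin] >= 0
    tin[mask] = remap[tin][mask]
    triangles[inside] = tin
    mesh.triangles = triangles

    pts = mesh.nodes[ids]
    rel = pts - center
    theta = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
    normal = rel / np.linalg.norm(rel, axis=1, keepdims=True)
    nxt = np.roll(pts, -1, axis=0)
    d_next = np.linalg.norm(nxt - pts, axis=1)
    lumped = 0.5 * (d_next + np.roll(d_next, 1))
    return Interface(name=name, outer_nodes=ids.copy(), inner_nodes=dup,
                     theta=theta, normal=normal, lumped_len=lumped, radius=radius)


def _min_angle_deg(nodes: np.ndarray, triangles: np.ndarray) -> float:
    p = nodes[triangles]
    angles = []
    for i in range(3):
        a = p[:, (i + 1) % 3] - p[:, i]
        b = p[:, (i + 2) % 3] - p[:, i]
        cosang = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
        angles.append(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
    return float(np.min(angles))
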