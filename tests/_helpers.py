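"""Shared test geometry: primitive meshes and an independent volume oracle.

The column (voxelization) oracle rasterises each solid into vertical
columns over an XY grid and measures enclosed z-extent per column, using
nothing but the raw vertex/face arrays. It shares no code with the
package's Boolean kernel, so agreement between the two is meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull

from dentofacial.mesh_core import TriangleMesh

# ---------------------------------------------------------------------------
# Primitive solids
# ---------------------------------------------------------------------------

_CUBE_FACES = np.array(
    [
        (0, 2, 1), (0, 3, 2),  # z = 0
        (4, 5, 6), (4, 6, 7),  # z = 1
        (0, 1, 5), (0, 5, 4),  # y = 0
        (2, 3, 7), (2, 7, 6),  # y = 1
        (0, 4, 7), (0, 7, 3),  # x = 0
        (1, 2, 6), (1, 6, 5),  # x = 1
    ],
    dtype=np.int64,
)


def cube(origin=(0.0, 0.0, 0.0), size=1.0) -> TriangleMesh:
    """Axis-aligned unit-topology cube, outward oriented."""
    o = np.asarray(origin, float)
    v = np.array(
        [
            (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
            (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
        ],
        dtype=float,
    )
    return TriangleMesh(o + v * float(size), _CUBE_FACES.copy())


def box(lo, hi) -> TriangleMesh:
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    v = np.array(
        [
            (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
            (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
        ],
        dtype=float,
    )
    return TriangleMesh(lo + v * (hi - lo), _CUBE_FACES.copy())


def regular_tetrahedron(a: float = 1.0) -> TriangleMesh:
    """Regular tetrahedron with edge length ``a``; volume a^3 / (6 sqrt 2)."""
    v = np.array(
        [(1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1)], dtype=float
    ) * (a / (2.0 * np.sqrt(2.0)))
    f = np.array([(0, 1, 2), (0, 2, 3), (0, 3, 1), (1, 3, 2)], dtype=np.int64)
    m = TriangleMesh(v, f)
    tri = m.triangles()
    vol = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()
    if vol < 0:
        m = TriangleMesh(v, f[:, ::-1])
    return m


def icosphere(radius: float = 1.0, subdivisions: int = 3, center=(0, 0, 0)) -> TriangleMesh:
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(tm.vertices) + np.asarray(center, float),
                        np.asarray(tm.faces))


def hull_mesh(points: np.ndarray) -> tuple[TriangleMesh, float]:
    """Convex hull as an outward-oriented TriangleMesh plus its exact volume."""
    h = ConvexHull(points)
    faces = h.simplices.copy()
    c = points[h.vertices].mean(axis=0)
    tri = points[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    flip = np.einsum("ij,ij->i", n, tri.mean(axis=1) - c) < 0
    faces[flip] = faces[flip][:, ::-1]
    return TriangleMesh(points, faces), float(h.volume)


def random_blended_hull(rng: np.random.Generator, n_clusters: int, size: float):
    """Hull of a blend of anisotropic, rotated point clusters (seeded)."""
    pts = []
    for _ in range(n_clusters):
        c = rng.uniform(-0.4, 0.4, 3) * size
        scale = rng.uniform(0.3, 0.8, 3) * size
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        pts.append(c + (rng.standard_normal((30, 3)) * scale) @ q.T)
    return hull_mesh(np.vstack(pts))


def random_overlapping_pair(seed: int):
    """Deterministic convex/blended solid pair with guaranteed bbox overlap."""
    rng = np.random.default_rng(1000 + seed)
    a, va = random_blended_hull(rng, 1 + seed % 3, 20.0)
    shift = rng.uniform(-0.3, 0.3, 3) * 20.0
    b, vb = random_blended_hull(rng, 1 + (seed + 1) % 3, 18.0)
    b = TriangleMesh(b.vertices + shift, b.faces)
    return a, va, b, vb


# ---------------------------------------------------------------------------
# Column (voxelization) volume oracle — independent of the package kernel
# ---------------------------------------------------------------------------


def column_bounds(mesh: TriangleMesh, xs: np.ndarray, ys: np.ndarray):
    """Per-column lower (enter) and upper (exit) z of the enclosed interval.

    Valid for solids whose vertical cross-section is a single interval
    (convex bodies and the battery's blended hulls). Columns that miss the
    solid report enter = +inf / exit = -inf.
    """
    enter = np.full((len(xs), len(ys)), np.inf)
    exit_ = np.full((len(xs), len(ys)), -np.inf)
    tri = mesh.triangles()
    nrm = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    dx = xs[1] - xs[0]
    dy = ys[1] - ys[0]
    for t, n in zip(tri, nrm):
        if abs(n[2]) < 1e-12:
            continue
        i0 = max(0, int(np.ceil((t[:, 0].min() - xs[0]) / dx)))
        i1 = min(len(xs) - 1, int(np.floor((t[:, 0].max() - xs[0]) / dx)))
        j0 = max(0, int(np.ceil((t[:, 1].min() - ys[0]) / dy)))
        j1 = min(len(ys) - 1, int(np.floor((t[:, 1].max() - ys[0]) / dy)))
        if i1 < i0 or j1 < j0:
            continue
        X, Y = np.meshgrid(xs[i0:i1 + 1], ys[j0:j1 + 1], indexing="ij")
        x1, y1 = t[0, 0], t[0, 1]
        x2, y2 = t[1, 0], t[1, 1]
        x3, y3 = t[2, 0], t[2, 1]
        det = (y2 - y3) * (x1 - x3) + (x3 - x2) * (y1 - y3)
        if abs(det) < 1e-15:
            continue
        l1 = ((y2 - y3) * (X - x3) + (x3 - x2) * (Y - y3)) / det
        l2 = ((y3 - y1) * (X - x3) + (x1 - x3) * (Y - y3)) / det
        l3 = 1.0 - l1 - l2
        inside = (l1 >= -1e-12) & (l2 >= -1e-12) & (l3 >= -1e-12)
        if not inside.any():
            continue
        Z = l1 * t[0, 2] + l2 * t[1, 2] + l3 * t[2, 2]
        sub_e = enter[i0:i1 + 1, j0:j1 + 1]
        sub_x = exit_[i0:i1 + 1, j0:j1 + 1]
        if n[2] < 0:
            np.minimum(sub_e, np.where(inside, Z, np.inf), out=sub_e)
        else:
            np.maximum(sub_x, np.where(inside, Z, -np.inf), out=sub_x)
    return enter, exit_


def oracle_volume(mesh: TriangleMesh, n: int = 240) -> float:
    """Column-oracle volume of one solid."""
    lo, hi = mesh.bounds()
    xs = np.linspace(lo[0] - 1e-9, hi[0] + 1e-9, n)
    ys = np.linspace(lo[1] - 1e-9, hi[1] + 1e-9, n)
    enter, exit_ = column_bounds(mesh, xs, ys)
    length = np.clip(exit_ - enter, 0.0, None)
    length[~np.isfinite(length)] = 0.0
    return float(length.sum() * (xs[1] - xs[0]) * (ys[1] - ys[0]))


def oracle_intersection_volume(a: TriangleMesh, b: TriangleMesh, n: int = 240) -> float:
    """Column-oracle volume of A intersect B, straight from the operands."""
    lo = np.maximum(a.bounds()[0], b.bounds()[0]) - 1e-9
    hi = np.minimum(a.bounds()[1], b.bounds()[1]) + 1e-9
    if (hi <= lo).any():
        return 0.0
    xs = np.linspace(lo[0], hi[0], n)
    ys = np.linspace(lo[1], hi[1], n)
    ea, xa = column_bounds(a, xs, ys)
    eb, xb = column_bounds(b, xs, ys)
    length = np.clip(np.minimum(xa, xb) - np.maximum(ea, eb), 0.0, None)
    length[~np.isfinite(length)] = 0.0
    return float(length.sum() * (xs[1] - xs[0]) * (ys[1] - ys[0]))


def planar_grid_patch(nx: int = 9, ny: int = 7, w: float = 4.0, h: float = 3.0,
                      z: float = 0.0) -> TriangleMesh:
    """Open planar rectangle patch in the z = const plane, +Z oriented."""
    xs = np.linspace(0.0, w, nx)
    ys = np.linspace(0.0, h, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    verts = np.column_stack([X.ravel(), Y.ravel(), np.full(X.size, float(z))])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append((a, b, b + 1))
            faces.append((a, b + 1, a + 1))
    return TriangleMesh(verts, np.asarray(faces, dtype=np.int64))
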