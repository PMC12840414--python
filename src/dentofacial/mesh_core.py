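"""Triangle-mesh substrate: STL I/O, signed volume, centroid, rigid motion.

All geometry is in millimetres; volumes in mm^3. STL carries no units, so
``unit == mm`` is asserted by contract. Meshes used for volumetry must be
watertight: every edge shared by exactly two faces with opposite traversal
directions. Watertightness is *enforced* by the volume operations, never
assumed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

from .errors import (
    DomainError,
    EmptyMeshError,
    MeshFormatError,
    NotWatertightError,
)

WELD_TOL = 1e-6  # vertex weld tolerance, mm


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class TriangleMesh:
    """Vertices (n, 3) in mm and faces (m, 3) with outward CCW orientation."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (
            self.faces.min() < 0 or self.faces.max() >= len(self.vertices)
        ):
            raise DomainError("face indices out of range")

    # -- convenience -------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy())

    def bounds(self) -> np.ndarray:
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def triangles(self) -> np.ndarray:
        return self.vertices[self.faces]

    def face_normals(self) -> np.ndarray:
        tri = self.triangles()
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        return n  # unnormalised (2x area weighted)

    def area(self) -> float:
        return float(np.linalg.norm(self.face_normals(), axis=1).sum() / 2.0)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriangleMesh":
        return cls(np.asarray(tm.vertices, float), np.asarray(tm.faces, int))

    # -- topology ----------------------------------------------------------
    def boundary_edges(self) -> np.ndarray:
        """Directed edges that lack an opposite partner. Empty <=> watertight."""
        if self.n_faces == 0:
            return np.empty((0, 2), dtype=np.int64)
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        # An edge (a,b) is matched if (b,a) occurs exactly as often.
        key = e[:, 0] * (self.n_vertices + 1) + e[:, 1]
        rkey = e[:, 1] * (self.n_vertices + 1) + e[:, 0]
        order = np.argsort(key)
        skey = key[order]
        # count occurrences of each directed edge
        uniq, counts = np.unique(skey, return_counts=True)
        fwd = dict(zip(uniq.tolist(), counts.tolist()))
        bad = []
        seen = set()
        for i, (k, rk) in enumerate(zip(key.tolist(), rkey.tolist())):
            if k in seen:
                continue
            seen.add(k)
            if fwd.get(k, 0) != fwd.get(rk, 0) or fwd[k] != 1:
                bad.append(e[i])
        return np.array(bad, dtype=np.int64).reshape(-1, 2)

    def is_watertight(self) -> bool:
        if self.n_faces == 0:
            return False
        f = self.faces
        e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        key = e[:, 0].astype(np.int64) * (self.n_vertices + 1) + e[:, 1]
        rkey = e[:, 1].astype(np.int64) * (self.n_vertices + 1) + e[:, 0]
        u1, c1 = np.unique(key, return_counts=True)
        if (c1 != 1).any():
            return False
        u2 = np.sort(rkey)
        return bool(np.array_equal(np.sort(key), u2))


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation orthonormal, det +1)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = np.asarray(self.translation, dtype=np.float64).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
            np.linalg.det(R), 1.0, atol=1e-8
        ):
            raise DomainError("rotation must be orthonormal with determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(np.eye(3), np.asarray(t, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass
class MeshDiagnostics:
    """Cleaning report returned alongside meshes read from disk."""

    duplicate_vertices_merged: int = 0
    degenerate_faces_removed: int = 0
    notes: list = field(default_factory=list)

    def as_dict(self):
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# Cleaning helpers
# ---------------------------------------------------------------------------


def weld_vertices(mesh: TriangleMesh, tol: float = WELD_TOL) -> tuple[TriangleMesh, int]:
    """Merge vertices closer than ``tol`` (eps-ball clustering); returns merge count.

    Uses kd-tree pair queries with union-find so that every pair within
    ``tol`` is merged regardless of how the points fall relative to any
    grid; chains of near pairs collapse to a single representative.
    """
    if mesh.n_vertices == 0:
        return mesh, 0
    from scipy.spatial import cKDTree

    verts_in = mesh.vertices
    pairs = cKDTree(verts_in).query_pairs(tol, output_type="ndarray")
    parent = np.arange(mesh.n_vertices)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    for i, j in pairs:
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
    roots = np.array([find(i) for i in range(mesh.n_vertices)])
    reps, inverse = np.unique(roots, return_inverse=True)
    merged = mesh.n_vertices - len(reps)
    verts = verts_in[reps]
    faces = inverse[mesh.faces]
    return TriangleMesh(verts, faces), int(merged)


def drop_degenerate_faces(
    mesh: TriangleMesh, area_tol: float = 1e-12
) -> tuple[TriangleMesh, int]:
    """Remove faces with repeated indices or (near-)zero area."""
    f = mesh.faces
    if len(f) == 0:
        return mesh, 0
    distinct = (f[:, 0] != f[:, 1]) & (f[:, 1] != f[:, 2]) & (f[:, 0] != f[:, 2])
    areas = np.linalg.norm(mesh.face_normals(), axis=1) / 2.0
    keep = distinct & (areas > area_tol)
    removed = int((~keep).sum())
    return TriangleMesh(mesh.vertices, f[keep]), removed


def _require_watertight(mesh: TriangleMesh, op: str) -> None:
    if mesh.n_faces == 0:
        raise EmptyMeshError(f"{op}: mesh has no faces")
    if not mesh.is_watertight():
        edges = mesh.boundary_edges()
        raise NotWatertightError(
            f"{op}: mesh is not watertight ({len(edges)} unmatched edges, "
            f"first few: {edges[:5].tolist()})",
            boundary_edges=edges,
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def read_mesh(path) -> tuple[TriangleMesh, MeshDiagnostics]:
    """Read a binary or ASCII STL (or OFF) file into a cleaned TriangleMesh.

    Vertices are deduplicated within 1e-6 mm, degenerate faces removed, and
    face orientation made consistent where possible.
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    try:
        tm = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # pragma: no cover - backend specific messages
        raise MeshFormatError(f"cannot read mesh file {path}: {exc}") from exc
    if tm is None or not hasattr(tm, "faces") or len(tm.faces) == 0:
        raise EmptyMeshError(f"{path}: no facets")
    mesh = TriangleMesh.from_trimesh(tm)
    mesh, merged = weld_vertices(mesh)
    mesh, removed = drop_degenerate_faces(mesh)
    if mesh.n_faces == 0:
        raise EmptyMeshError(f"{path}: all facets degenerate")
    # make winding consistent where the surface allows it
    tm2 = mesh.as_trimesh()
    trimesh.repair.fix_normals(tm2, multibody=True)
    mesh = TriangleMesh.from_trimesh(tm2)
    diag = MeshDiagnostics(duplicate_vertices_merged=merged, degenerate_faces_removed=removed)
    return mesh, diag


def write_mesh(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    """Write STL (``binary`` or ``ascii``) or OFF (by ``.off`` extension)."""
    path = Path(path)
    tm = mesh.as_trimesh()
    if path.suffix.lower() == ".off":
        tm.export(str(path), file_type="off")
        return
    if dialect == "binary":
        tm.export(str(path), file_type="stl")
    elif dialect == "ascii":
        path.write_text(trimesh.exchange.stl.export_stl_ascii(tm))
    else:
        raise DomainError(f"unknown STL dialect {dialect!r}")


def signed_volume(mesh: TriangleMesh) -> float:
    """Enclosed volume via the divergence theorem (signed tetrahedra).

    Positive for outward orientation; invariant under rigid motion.
    Requires a watertight mesh.
    """
    _require_watertight(mesh, "signed_volume")
    return _signed_volume_raw(mesh)


def _signed_volume_raw(mesh: TriangleMesh) -> float:
    """Divergence-theorem volume without the watertightness gate.

    Valid for any geometrically closed oriented surface (used internally on
    Boolean outputs before topological healing).
    """
    if mesh.n_faces == 0:
        return 0.0
    tri = mesh.triangles()
    return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


def center_of_volume(mesh: TriangleMesh) -> np.ndarray:
    """Volume centroid via signed-tetrahedron first moments."""
    _require_watertight(mesh, "center_of_volume")
    tri = mesh.triangles()
    d6 = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))
    vol = d6.sum() / 6.0
    if vol <= 0:
        raise DomainError("center_of_volume requires positive volume")
    centroids = tri.sum(axis=1) / 4.0  # tetra centroid against the origin
    return np.asarray((centroids * d6[:, None]).sum(axis=0) / (6.0 * vol))


def uniform_scale(mesh: TriangleMesh, s: float, center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    """Scale all vertices about ``center`` by s > 0 (volume scales by s^3)."""
    if not np.isfinite(s) or s <= 0:
        raise DomainError(f"scale factor must be positive, got {s}")
    c = np.asarray(center, float).reshape(3)
    return TriangleMesh(c + (mesh.vertices - c) * float(s), mesh.faces.copy())


def apply_transform(mesh: TriangleMesh, t: RigidTransform) -> TriangleMesh:
    """Apply a proper rigid motion; preserves volume and all distances."""
    return TriangleMesh(t.apply(mesh.vertices), mesh.faces.copy())
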