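"""Patch extraction, extrusion, face closure, Boolean volumetry and metrics.

The pipeline builds the extruded buccal-patch solid, scales it by the
bizygomatic ratio, aligns tooth and face to the common frame, places the
tooth by translation, closes the facial shell into a solid, intersects the
two solids, and reports

    RTV  = V_total - V_superimposed
    %SI  = (V_superimposed / V_total) x 100

with V_superimposed = volume(tooth solid  intersect  face solid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .csg import (
    coincidence_eps,
    drop_redundant_flaps,
    excise_nonmanifold,
    fill_small_holes,
    heal_tjunctions,
    mesh_intersection,
    peel_flaps,
    weld_boundary_vertices,
)
from .errors import (
    ClosureError,
    DentofacialError,
    DomainError,
    ExtrusionError,
    InvalidSelectionError,
)
from .landmark_align import (
    FaceLandmarks,
    ToothLandmarks,
    align_face,
    align_tooth,
    place_for_superimposition,
)
from .mesh_core import (
    TriangleMesh,
    _require_watertight,
    _signed_volume_raw,
    apply_transform,
    drop_degenerate_faces,
    signed_volume,
    uniform_scale,
    weld_vertices,
)

# ---------------------------------------------------------------------------
# Patch selection
# ---------------------------------------------------------------------------


@dataclass
class PatchSelection:
    """Face indices of the source mesh forming the buccal patch."""

    face_indices: np.ndarray

    def __post_init__(self):
        idx = np.unique(np.asarray(self.face_indices, dtype=np.int64).reshape(-1))
        if len(idx) == 0:
            raise InvalidSelectionError("empty selection")
        self.face_indices = idx

    def validate(self, mesh: TriangleMesh) -> None:
        idx = self.face_indices
        if idx.min() < 0 or idx.max() >= mesh.n_faces:
            raise InvalidSelectionError("selection indices out of range")
        sub = _submesh(mesh, idx)
        comp = _edge_connected_components(sub.faces)
        if comp > 1:
            raise InvalidSelectionError(
                f"selection has {comp} edge-connected components, expected 1"
            )
        loops = _boundary_loops(sub)
        if len(loops) != 1:
            raise InvalidSelectionError(
                f"selection boundary has {len(loops)} loops, expected 1"
            )


def _submesh(mesh: TriangleMesh, face_idx: np.ndarray) -> TriangleMesh:
    faces = mesh.faces[face_idx]
    used = np.unique(faces)
    remap = np.full(mesh.n_vertices, -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return TriangleMesh(mesh.vertices[used], remap[faces])


def _edge_connected_components(faces: np.ndarray) -> int:
    """Components of faces connected through shared (undirected) edges."""
    nf = len(faces)
    parent = np.arange(nf)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edge_to_face: dict = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (min(u, v), max(u, v))
            other = edge_to_face.get(key)
            if other is None:
                edge_to_face[key] = fi
            else:
                ra, rb = find(fi), find(other)
                if ra != rb:
                    parent[ra] = rb
    return len({find(i) for i in range(nf)})


def _boundary_loops(mesh: TriangleMesh) -> list[list[int]]:
    """Directed boundary edges chained into closed loops (vertex index lists)."""
    f = mesh.faces
    edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    seen = {}
    for a, b in edges:
        seen[(int(a), int(b))] = seen.get((int(a), int(b)), 0) + 1
    boundary = [
        (a, b) for (a, b), c in seen.items() if c == 1 and seen.get((b, a), 0) == 0
    ]
    nxt = {}
    for a, b in boundary:
        if a in nxt:
            raise InvalidSelectionError(
                "non-manifold boundary: vertex on more than one boundary edge pair"
            )
        nxt[a] = b
    loops = []
    remaining = set(nxt)
    while remaining:
        start = min(remaining)
        loop = [start]
        remaining.discard(start)
        cur = nxt[start]
        while cur != start:
            loop.append(cur)
            if cur not in remaining:
                raise InvalidSelectionError("open boundary chain: not a closed loop")
            remaining.discard(cur)
            cur = nxt[cur]
        loops.append(loop)
    return loops


# ---------------------------------------------------------------------------
# Patch extraction with boundary smoothing
# ---------------------------------------------------------------------------


def extract_patch(
    mesh: TriangleMesh, sel: PatchSelection, smoothing_iters: int = 5
) -> TriangleMesh:
    """Extract the selected sub-mesh, Laplacian-smoothing the boundary loop.

    Only boundary vertices move (toward the midpoint of their loop
    neighbours); interior vertices are untouched. The relaxation factor is
    halved whenever a pass would change the patch area by 5% or more.
    """
    sel.validate(mesh)
    patch = _submesh(mesh, sel.face_indices)
    if smoothing_iters <= 0:
        return patch
    loop = _boundary_loops(patch)[0]
    verts = patch.vertices.copy()
    n = len(loop)
    idx = np.asarray(loop)
    prv = np.roll(idx, 1)
    nxt = np.roll(idx, -1)
    for _ in range(smoothing_iters):
        lam = 0.5
        area_before = TriangleMesh(verts, patch.faces).area()
        while True:
            trial = verts.copy()
            trial[idx] = (1 - lam) * verts[idx] + lam * 0.5 * (verts[prv] + verts[nxt])
            area_after = TriangleMesh(trial, patch.faces).area()
            if area_before == 0 or abs(area_after - area_before) / area_before < 0.05:
                verts = trial
                break
            lam *= 0.5
            if lam < 1e-6:
                verts = trial
                break
    return TriangleMesh(verts, patch.faces)


# ---------------------------------------------------------------------------
# Solid construction
# ---------------------------------------------------------------------------


def _vertex_normals(mesh: TriangleMesh, smooth_passes: int = 4) -> np.ndarray:
    """Area-weighted vertex normals, unit length.

    The normal field is relaxed over vertex neighbourhoods before use so
    that boundary kinks (e.g. from boundary-loop smoothing) do not fold the
    offset surface; for a planar patch the relaxation is an exact no-op.
    """
    fn = mesh.face_normals()  # area-weighted
    vn = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(vn, mesh.faces[:, k], fn)
    ln = np.linalg.norm(vn, axis=1)
    ln[ln == 0] = 1.0
    vn = vn / ln[:, None]
    if smooth_passes > 0:
        f = mesh.faces
        edges = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        for _ in range(smooth_passes):
            acc = vn.copy()
            np.add.at(acc, edges[:, 0], vn[edges[:, 1]])
            np.add.at(acc, edges[:, 1], vn[edges[:, 0]])
            ln = np.linalg.norm(acc, axis=1)
            ln[ln == 0] = 1.0
            vn = acc / ln[:, None]
    return vn


def extrude_to_solid(patch: TriangleMesh, h: float) -> TriangleMesh:
    """Extrude the open patch by ``h`` mm along the inward vertex normals.

    Solid = patch (top)  U  offset copy (bottom, flipped)  U  boundary wall.
    For a planar patch the volume is exactly area x h.
    """
    if not (h > 0):
        raise DomainError(f"extrusion height must be positive, got {h}")
    loops = _boundary_loops(patch)
    if len(loops) != 1:
        raise ExtrusionError(f"patch has {len(loops)} boundary loops, expected 1")
    vn = _vertex_normals(patch)
    nv = patch.n_vertices
    offset = patch.vertices - h * vn  # inward
    verts = np.vstack([patch.vertices, offset])
    top = patch.faces
    bottom = patch.faces[:, ::-1] + nv
    # Reject folded offsets (h too large for the local curvature). Individual
    # sliver facets at sharp boundary corners may invert even under a smooth
    # normal field; their volume contribution is O(h x folded area), so the
    # hard failure is scoped to folded area above 0.1% of the patch area.
    top_n = patch.face_normals()
    bot_n = TriangleMesh(offset, patch.faces).face_normals()
    dots = np.einsum("ij,ij->i", top_n, bot_n)
    folded = dots <= 0
    top_areas = 0.5 * np.linalg.norm(top_n, axis=1)
    if top_areas[folded].sum() > 1e-3 * top_areas.sum():
        raise ExtrusionError(
            f"offset by h={h} folds {int(folded.sum())} faces "
            f"({top_areas[folded].sum():.4g} of {top_areas.sum():.4g} patch area; "
            "self-intersecting extrusion; reduce h or refine the patch)"
        )
    # wall: for each directed boundary edge (a, b) of the top, quad (b,a,a'),(b,a',b')
    loop = loops[0]
    wall = []
    for i in range(len(loop)):
        a, b = loop[i], loop[(i + 1) % len(loop)]
        wall.append((b, a, a + nv))
        wall.append((b, a + nv, b + nv))
    faces = np.vstack([top, bottom, np.asarray(wall, dtype=np.int64)])
    solid = TriangleMesh(verts, faces)
    solid, _ = weld_vertices(solid, tol=1e-9)
    solid, _ = drop_degenerate_faces(solid, area_tol=1e-14)
    if not solid.is_watertight():
        raise ExtrusionError("extruded solid is not watertight")
    if signed_volume(solid) <= 0:
        raise ExtrusionError("extruded solid has non-positive volume")
    return solid


def face_to_solid(shell: TriangleMesh, cap_depth: float) -> TriangleMesh:
    """Close an open facial shell by sweeping its boundary to Z = -cap_depth.

    The anterior surface geometry is unmodified; the boundary loop is swept
    straight back to the cap plane and the cap is fan-triangulated.
    """
    loops = _boundary_loops(shell)
    if len(loops) != 1:
        raise ClosureError(
            f"shell has {len(loops)} boundary loops after cleaning, expected 1"
        )
    zmin = float(shell.vertices[:, 2].min())
    if -cap_depth > zmin - 1e-12 and not np.isclose(-cap_depth, zmin):
        raise ClosureError(
            f"cap plane Z={-cap_depth} is anterior to the shell (min Z {zmin})"
        )
    loop = loops[0]
    nv = shell.n_vertices
    ring = shell.vertices[np.asarray(loop)].copy()
    ring[:, 2] = -cap_depth
    centroid = ring.mean(axis=0)
    verts = np.vstack([shell.vertices, ring, centroid[None, :]])
    cidx = nv + len(loop)
    faces = [tuple(f) for f in shell.faces]
    n = len(loop)
    for i in range(n):
        a, b = loop[i], loop[(i + 1) % n]
        ap, bp = nv + i, nv + (i + 1) % n
        # wall paired against the shell's directed edge (a, b)
        faces.append((b, a, ap))
        faces.append((b, ap, bp))
        # cap paired against the wall's (ap, bp)
        faces.append((bp, ap, cidx))
    solid = TriangleMesh(verts, np.asarray(faces, dtype=np.int64))
    solid, _ = weld_vertices(solid, tol=1e-9)
    solid, _ = drop_degenerate_faces(solid, area_tol=1e-14)
    if not solid.is_watertight():
        raise ClosureError("closed facial solid is not watertight")
    vol = signed_volume(solid)
    if vol < 0:
        solid = TriangleMesh(solid.vertices, solid.faces[:, ::-1])
    return solid


# ---------------------------------------------------------------------------
# Boolean intersection and metrics
# ---------------------------------------------------------------------------


def boolean_intersection(a: TriangleMesh, b: TriangleMesh) -> TriangleMesh:
    """Watertight A intersect B; empty mesh (volume 0) when disjoint."""
    _require_watertight(a, "boolean_intersection operand A")
    _require_watertight(b, "boolean_intersection operand B")
    raw = mesh_intersection(a, b)
    if raw.n_faces == 0:
        return raw
    healed = heal_tjunctions(raw)
    if not healed.is_watertight():
        # Seam defects come from tangent or grazing contact, where kept/dropped
        # decisions are ambiguous at the coincidence-band scale and either
        # answer is volumetrically negligible. The repair ladder is strictly
        # local to the defects: probe away redundant overlapped strips, peel
        # dangling flaps, fan-fill rims (small ones freely, arbitrary ones
        # under a cumulative 1% surface-area budget), then excise stubborn
        # non-manifold tangles and collapse sub-band rim micro-clusters.
        eps_c = coincidence_eps(a, b)
        lo = np.minimum(a.bounds()[0], b.bounds()[0])
        hi = np.maximum(a.bounds()[1], b.bounds()[1])
        diag = float(np.linalg.norm(hi - lo))
        delta0 = max(1e-9, 1e-7 * diag)
        healed = drop_redundant_flaps(healed, a, b, delta0)
        area_budget = 0.01 * healed.area()
        added = 0.0
        for it in range(8):
            if healed.is_watertight():
                break
            healed = peel_flaps(healed)
            healed = fill_small_holes(
                healed, max_perimeter=0.02 * diag, width_tol=eps_c
            )
            area_before = healed.area()
            capped = fill_small_holes(healed, max_perimeter=np.inf)
            grown = capped.area() - area_before
            if added + grown <= area_budget:
                added += grown
                healed = capped
            if healed.is_watertight():
                break
            healed = excise_nonmanifold(healed)
            # escalate the rim-weld radius while defects persist: stubborn
            # tangles (odd directed-boundary structures no cycle fill can
            # close) are collapsed once the radius reaches their diameter
            healed = weld_boundary_vertices(
                healed, min(eps_c * 4.0**it, 100.0 * eps_c)
            )
        if not healed.is_watertight():
            raise ClosureError(
                "Boolean intersection could not be healed to watertight topology"
            )
    return healed


@dataclass
class SuperimpositionResult:
    """Outcome record for one subject."""

    V_total: float
    V_superimposed: float
    RTV: float
    pct_SI: float
    placement_residual: float = 0.0
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.V_total > 0):
            raise DomainError(f"V_total must be positive, got {self.V_total}")
        if not (0.0 <= self.V_superimposed <= self.V_total):
            raise DomainError(
                f"V_superimposed {self.V_superimposed} outside [0, V_total={self.V_total}]"
            )

    def as_dict(self) -> dict:
        return {
            "V_total": self.V_total,
            "V_superimposed": self.V_superimposed,
            "RTV": self.RTV,
            "pct_SI": self.pct_SI,
            "placement_residual": self.placement_residual,
            "config": dict(self.config),
        }


def compute_metrics(
    v_total: float,
    v_superimposed: float,
    placement_residual: float = 0.0,
    config: dict | None = None,
) -> SuperimpositionResult:
    """RTV = V_total - V_superimposed; %SI = V_superimposed / V_total x 100."""
    if not (v_total > 0):
        raise DomainError(f"V_total must be positive, got {v_total}")
    if v_superimposed < 0 or v_superimposed > v_total:
        raise DomainError(
            f"V_superimposed={v_superimposed} inconsistent with V_total={v_total}"
        )
    rtv = v_total - v_superimposed
    pct = v_superimposed / v_total * 100.0
    return SuperimpositionResult(
        V_total=float(v_total),
        V_superimposed=float(v_superimposed),
        RTV=float(rtv),
        pct_SI=float(pct),
        placement_residual=float(placement_residual),
        config=dict(config or {}),
    )


def _stage(name, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except DentofacialError as exc:
        exc.args = (f"[{name}] {exc.args[0] if exc.args else ''}",) + exc.args[1:]
        raise


def run_superimposition(
    tooth_scan: TriangleMesh,
    tooth_lm: ToothLandmarks,
    face_shell: TriangleMesh,
    face_lm: FaceLandmarks,
    selection: PatchSelection,
    config: PipelineConfig | None = None,
) -> SuperimpositionResult:
    """Full protocol for one subject; deterministic for identical inputs.

    extract_patch -> extrude_to_solid(h) -> uniform_scale(s) -> align_tooth
    -> align_face -> place_for_superimposition -> face_to_solid ->
    boolean_intersection -> compute_metrics.
    """
    cfg = config or PipelineConfig()

    patch = _stage("extract_patch", extract_patch, tooth_scan, selection, cfg.smoothing_iters)
    solid = _stage("extrude_to_solid", extrude_to_solid, patch, cfg.extrusion_mm)

    def scale_tooth(mesh, lm):
        scaled = uniform_scale(mesh, cfg.scale)
        scaled_lm = ToothLandmarks(
            **{k: np.asarray(v) * cfg.scale for k, v in lm.as_dict().items()}
        )
        return scaled, scaled_lm

    if cfg.scale_after_alignment:
        _, solid_a, lm_a = _stage("align_tooth", align_tooth, solid, tooth_lm)
        # scaling about the origin (= centre of volume after alignment)
        tooth_solid, tooth_lm_a = scale_tooth(solid_a, lm_a)
    else:
        scaled, scaled_lm = scale_tooth(solid, tooth_lm)
        _, tooth_solid, tooth_lm_a = _stage("align_tooth", align_tooth, scaled, scaled_lm)

    _, face_a, face_lm_a = _stage("align_face", align_face, face_shell, face_lm)

    placement, residual = _stage(
        "place_for_superimposition",
        place_for_superimposition,
        face_a,
        face_lm_a,
        tooth_solid,
        tooth_lm_a,
        cfg.mode,
    )
    tooth_placed = apply_transform(tooth_solid, placement)

    tooth_depth = float(
        tooth_placed.vertices[:, 2].max() - tooth_placed.vertices[:, 2].min()
    )
    cap_depth = cfg.cap_depth if cfg.cap_depth is not None else (
        2.0 * tooth_depth - float(face_a.vertices[:, 2].min().clip(max=0.0))
    )
    face_solid = _stage("face_to_solid", face_to_solid, face_a, cap_depth)

    v_total = _stage("signed_volume", signed_volume, tooth_placed)
    inter = _stage("boolean_intersection", boolean_intersection, tooth_placed, face_solid)
    v_sup = _signed_volume_raw(inter) if inter.n_faces else 0.0
    # guard against 1-ulp numerical overshoot of the containment bound
    if v_sup > v_total and (v_sup - v_total) <= 1e-9 * v_total:
        v_sup = v_total
    v_sup = max(v_sup, 0.0)

    return _stage(
        "compute_metrics",
        compute_metrics,
        v_total,
        v_sup,
        placement_residual=residual,
        config={
            "scale": cfg.scale,
            "extrusion_mm": cfg.extrusion_mm,
            "mode": cfg.mode,
            "smoothing_iters": cfg.smoothing_iters,
            "cap_depth": cap_depth,
            "scale_after_alignment": cfg.scale_after_alignment,
        },
    )
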