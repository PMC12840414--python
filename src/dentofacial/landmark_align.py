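"""Anatomical landmark sets and the three alignment steps of the protocol.

Frame convention (right-handed, mm):
  X = transverse (mesio-distal), Y = vertical (cervico-incisal / facial
  midline, up positive), Z = anteroposterior (anterior positive).

The protocol text assigns the incisal midpoint "along the Z axis" in one step
and aligns the tooth "cervico-incisally along the Y axis" in the next; a
single frame cannot honour both literally. This package fixes the frame by
the placement-stage requirements, which are the ones the metrics depend on:

  * ``align_tooth``: cervical->incisal axis maps to -Y (incisal down, like
    the face), the mesio-distal direction to X, the buccal normal to +Z,
    origin at the solid's centre of volume. The incisal midpoint then lies
    in the X = 0 midline plane.
  * ``align_face``: glabella->pogonion parallel to -Y, glabella and labiale
    superius in the X = 0 midsagittal plane, origin at the shell's
    area-weighted surface centroid.
  * ``place_for_superimposition``: pure translation of the tooth; vertical
    level by least squares over the menton/glabella tangency pair,
    transverse centring on the selected landmark span, anterior tangency
    along Z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

from .errors import (
    DegenerateConfigurationError,
    MissingLandmarkError,
    SchemaError,
)
from .mesh_core import (
    RigidTransform,
    TriangleMesh,
    apply_transform,
    center_of_volume,
)

_TOL = 1e-9


def _pt(v, name):
    a = np.asarray(v, dtype=np.float64).reshape(-1)
    if a.shape != (3,) or not np.isfinite(a).all():
        raise SchemaError(f"landmark {name!r} must be a finite 3-D point, got {v!r}")
    return a


@dataclass
class ToothLandmarks:
    """Named points on the buccal patch boundary, in the tooth's frame (mm)."""

    incisal_midpoint: np.ndarray
    mesial_edge_midpoint: np.ndarray
    distal_edge_midpoint: np.ndarray
    cervical_midpoint: np.ndarray

    def __post_init__(self):
        for f in fields(self):
            setattr(self, f.name, _pt(getattr(self, f.name), f.name))
        if np.allclose(self.mesial_edge_midpoint, self.distal_edge_midpoint):
            raise DegenerateConfigurationError("mesial and distal midpoints coincide")
        if np.linalg.norm(self.incisal_midpoint - self.cervical_midpoint) <= 0:
            raise DegenerateConfigurationError("incisal and cervical midpoints coincide")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name).tolist() for f in fields(self)}

    def transformed(self, t: RigidTransform) -> "ToothLandmarks":
        return ToothLandmarks(
            **{f.name: t.apply(getattr(self, f.name)) for f in fields(self)}
        )


_FACE_REQUIRED = (
    "glabella",
    "pogonion",
    "menton",
    "labiale_superius",
    "zygion_left",
    "zygion_right",
    "alare_left",
    "alare_right",
)
_FACE_OPTIONAL = (
    "nasion",
    "exocanthion_left",
    "exocanthion_right",
    "endocanthion_left",
    "endocanthion_right",
    "cheilion_left",
    "cheilion_right",
)


@dataclass
class FaceLandmarks:
    """Facial anthropometric landmarks in the face scan's frame (mm)."""

    glabella: np.ndarray
    pogonion: np.ndarray
    menton: np.ndarray
    labiale_superius: np.ndarray
    zygion_left: np.ndarray
    zygion_right: np.ndarray
    alare_left: np.ndarray
    alare_right: np.ndarray
    optional: dict = None

    def __post_init__(self):
        for name in _FACE_REQUIRED:
            setattr(self, name, _pt(getattr(self, name), name))
        opt = dict(self.optional or {})
        for name in opt:
            if name not in _FACE_OPTIONAL:
                raise SchemaError(f"unknown face landmark {name!r}")
            opt[name] = _pt(opt[name], name)
        self.optional = opt
        if np.allclose(self.glabella, self.pogonion):
            raise DegenerateConfigurationError(
                "glabella and pogonion coincide; vertical facial line undefined"
            )
        for left, right in (
            ("zygion_left", "zygion_right"),
            ("alare_left", "alare_right"),
        ):
            if np.allclose(getattr(self, left), getattr(self, right)):
                raise DegenerateConfigurationError(f"{left} and {right} coincide")

    def as_dict(self) -> dict:
        d = {name: getattr(self, name).tolist() for name in _FACE_REQUIRED}
        d.update({k: v.tolist() for k, v in self.optional.items()})
        return d

    def transformed(self, t: RigidTransform) -> "FaceLandmarks":
        return FaceLandmarks(
            **{name: t.apply(getattr(self, name)) for name in _FACE_REQUIRED},
            optional={k: t.apply(v) for k, v in self.optional.items()},
        )


# ---------------------------------------------------------------------------
# Sidecar I/O (JSON: landmark name -> [x, y, z] in mm)
# ---------------------------------------------------------------------------


def _load_json(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise MissingLandmarkError(f"landmark file not found: {path}")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON ({exc})") from exc
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: expected an object mapping name -> [x, y, z]")
    return data


def load_tooth_landmarks(path) -> ToothLandmarks:
    data = _load_json(path)
    known = {f.name for f in fields(ToothLandmarks)}
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"{path}: unknown tooth landmark names {sorted(unknown)}")
    missing = known - set(data)
    if missing:
        raise MissingLandmarkError(f"{path}: missing tooth landmarks {sorted(missing)}")
    return ToothLandmarks(**data)


def load_face_landmarks(path) -> FaceLandmarks:
    data = _load_json(path)
    known = set(_FACE_REQUIRED) | set(_FACE_OPTIONAL)
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"{path}: unknown face landmark names {sorted(unknown)}")
    missing = set(_FACE_REQUIRED) - set(data)
    if missing:
        raise MissingLandmarkError(f"{path}: missing face landmarks {sorted(missing)}")
    required = {k: data[k] for k in _FACE_REQUIRED}
    optional = {k: data[k] for k in data if k in _FACE_OPTIONAL}
    return FaceLandmarks(**required, optional=optional)


def save_landmarks(lm, path) -> None:
    Path(path).write_text(json.dumps(lm.as_dict(), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Alignment operations
# ---------------------------------------------------------------------------


def _orthonormal_frame(y_dir: np.ndarray, x_hint: np.ndarray):
    """Right-handed frame with Y along ``y_dir`` and X along the projected hint."""
    ny = np.linalg.norm(y_dir)
    if ny < _TOL:
        raise DegenerateConfigurationError("vertical landmark axis has zero length")
    y = y_dir / ny
    x = x_hint - (x_hint @ y) * y
    nx = np.linalg.norm(x)
    if nx < 1e-8 * max(1.0, np.linalg.norm(x_hint)):
        raise DegenerateConfigurationError(
            "landmarks are collinear: transverse direction undefined"
        )
    x = x / nx
    z = np.cross(x, y)
    return x, y, z


def align_tooth(
    solid: TriangleMesh, lm: ToothLandmarks
) -> tuple[RigidTransform, TriangleMesh, ToothLandmarks]:
    """Move the tooth solid into the standard tooth frame.

    Cervical->incisal maps to -Y (incisal down), mesial->distal to +X,
    buccal to +Z (right-handedness), origin at the centre of volume.
    """
    y_dir = lm.cervical_midpoint - lm.incisal_midpoint
    x_hint = lm.distal_edge_midpoint - lm.mesial_edge_midpoint
    x, y, z = _orthonormal_frame(y_dir, x_hint)
    # rows of R are the frame axes: world point p maps to (p.x, p.y, p.z)
    rot = np.vstack([x, y, z])
    centroid = center_of_volume(solid)
    t = RigidTransform(rot, -rot @ centroid)
    aligned = apply_transform(solid, t)
    return t, aligned, lm.transformed(t)


def _area_centroid(mesh: TriangleMesh) -> np.ndarray:
    tri = mesh.triangles()
    areas = np.linalg.norm(mesh.face_normals(), axis=1) / 2.0
    total = areas.sum()
    if total <= 0:
        raise DegenerateConfigurationError("face shell has zero area")
    return np.asarray((tri.mean(axis=1) * areas[:, None]).sum(axis=0) / total)


def align_face(
    face: TriangleMesh, lm: FaceLandmarks
) -> tuple[RigidTransform, TriangleMesh, FaceLandmarks]:
    """Move the face shell into the standard face frame.

    Glabella->pogonion maps to -Y; a final yaw about Y puts glabella and
    labiale superius into the X = 0 midsagittal plane (least squares over
    their X offsets); origin at the area-weighted surface centroid.
    """
    y_dir = lm.glabella - lm.pogonion
    ny = np.linalg.norm(y_dir)
    if ny < _TOL:
        raise DegenerateConfigurationError("glabella and pogonion coincide")
    y = y_dir / ny
    # provisional transverse hint: right->left zygion span
    x_hint = lm.zygion_left - lm.zygion_right
    x, y, z = _orthonormal_frame(y_dir, x_hint)
    rot1 = np.vstack([x, y, z])
    # yaw about Y minimising sum of squared X offsets of the two midline
    # points, measured about the area centroid (the eventual origin) so the
    # fit is invariant to the input's arbitrary world pose
    centroid = _area_centroid(face)
    mid = (np.vstack([lm.glabella, lm.labiale_superius]) - centroid) @ rot1.T
    sx = float((mid[:, 0] ** 2).sum())
    sz = float((mid[:, 2] ** 2).sum())
    sxz = float((mid[:, 0] * mid[:, 2]).sum())
    # f(phi) = sum (x cos phi - z sin phi)^2
    #        = (sx + sz)/2 + (sx - sz)/2 cos 2phi - sxz sin 2phi,
    # so the critical points satisfy tan 2phi = -2 sxz / (sx - sz)
    phi = 0.5 * np.arctan2(-2.0 * sxz, sx - sz)
    cands = []
    for cand in (phi, phi + np.pi / 2.0, phi + np.pi, phi - np.pi / 2.0):
        c, s = np.cos(cand), np.sin(cand)
        cost = sx * c * c - 2 * sxz * s * c + sz * s * s
        zmean = float((mid[:, 0] * s + mid[:, 2] * c).mean())  # z after yaw
        cands.append((cost, zmean, cand))
    # prefer minimal cost; the two minima phi and phi + pi are mathematically
    # tied, so treat costs equal within fp noise of the inputs as ties and
    # break them toward the anterior (+Z) glabella
    cmin = min(c for c, _, _ in cands)
    tol = 1e-9 * (sx + sz) + 1e-12
    phi = max((zm, cand) for c, zm, cand in cands if c <= cmin + tol)[1]
    c, s = np.cos(phi), np.sin(phi)
    yaw = np.array([[c, 0.0, -s], [0.0, 1.0, 0.0], [s, 0.0, c]])
    rot = yaw @ rot1
    t = RigidTransform(rot, -rot @ centroid)
    aligned = apply_transform(face, t)
    return t, aligned, lm.transformed(t)


def place_for_superimposition(
    face: TriangleMesh,
    face_lm: FaceLandmarks,
    tooth: TriangleMesh,
    tooth_lm: ToothLandmarks,
    mode: str = "zygion",
) -> tuple[RigidTransform, float]:
    """Translate the aligned, scaled tooth onto the aligned face.

    Vertical: least-squares translation over the two tangency constraints
    (incisal midpoint at the menton level, cervical midpoint at the glabella
    level); the residual (mm) of that fit is returned. Transverse: the
    tooth's X extremes are centred on the selected landmark span (zygion or
    alare pair). Anteroposterior: the tooth's anterior-most vertex is placed
    at the face's anterior-most Z (tangent, never behind).
    """
    if mode not in ("zygion", "alare"):
        raise MissingLandmarkError(f"unknown tangency mode {mode!r}")
    left = getattr(face_lm, f"{mode}_left", None)
    right = getattr(face_lm, f"{mode}_right", None)
    if left is None or right is None:
        raise MissingLandmarkError(f"mode {mode!r} landmarks missing")

    # vertical: two constraints, one unknown ty -> least squares is the mean
    c1 = float(face_lm.menton[1] - tooth_lm.incisal_midpoint[1])
    c2 = float(face_lm.glabella[1] - tooth_lm.cervical_midpoint[1])
    ty = 0.5 * (c1 + c2)
    residual = abs(c1 - c2) / 2.0

    # transverse: centre tooth X extremes on the landmark span midpoint
    span_mid = 0.5 * (left[0] + right[0])
    tooth_mid = 0.5 * (tooth.vertices[:, 0].min() + tooth.vertices[:, 0].max())
    tx = float(span_mid - tooth_mid)

    # anteroposterior: anterior tangency
    tz = float(face.vertices[:, 2].max() - tooth.vertices[:, 2].max())

    return RigidTransform.from_translation([tx, ty, tz]), float(residual)
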