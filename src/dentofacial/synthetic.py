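"""Synthetic tooth patches, faces with landmarks, and cohort tables.

Geometry construction
---------------------
The tooth buccal patch is a rounded-corner rectangular grid with a
*cylindrical* buccal sag, z = sag x (1 - (2x/w)^2): the surface depends on x
only. The synthetic face is a heightfield z = F(x, y) whose anterior
mid-face is blended toward the scaled tooth surface with weight kappa
through an x-only mask m(x) that equals 1 across the whole tooth footprint.
Because both the tooth top and the mask depend on x alone, at kappa = 1 the
face surface coincides exactly with the placed tooth's top surface over the
entire footprint, so the pipeline's %SI approaches 100.

The face's base profile  B(x, y) = -a x^2 - b (y - y_mid)^2  is symmetric
about the glabella/pogonion mid-level, so those two landmarks share the same
z at every kappa and the glabella->pogonion segment stays parallel to Y;
x-symmetry puts the area centroid on the midline. The generator subtracts
the area centroid, so generated faces are exactly pre-aligned
(``align_face`` returns the identity).

With  a >= s*sag / (s*w/2)^2  the face surface, measured relative to its own
anterior maximum (where the placement snaps the tooth), rises pointwise in
kappa everywhere under the tooth footprint, which makes %SI monotone
non-decreasing in kappa by construction.

A disjoint fixture is produced by a symmetric pair of tall, thin anterior
spikes placed outside the tooth footprint: the placement snaps the tooth
apex to the spike tips, leaving the tooth solid strictly anterior of the
rest of the face while the shell keeps its midline symmetry.

Cohort simulation
-----------------
V_total is Normal per sex; %SI follows a left-skewed truncated skew-normal
(shape a = -4) calibrated by moment matching to the target mean/SD; RTV =
V_total x (1 - %SI/100) is therefore right-skewed. The rank correlation
between V_total and RTV is induced by a Gaussian copula between the V and
%SI driver normals, with the copula parameter calibrated by root finding on
a large common-random-number simulation of the resulting Spearman rho.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .config import DEFAULT_EXTRUSION_MM, DEFAULT_SCALE
from .errors import DomainError, FeasibilityError
from .landmark_align import FaceLandmarks, ToothLandmarks, save_landmarks
from .mesh_core import TriangleMesh, write_mesh

# ---------------------------------------------------------------------------
# Shape parameter types
# ---------------------------------------------------------------------------


@dataclass
class ToothShapeParams:
    """Buccal-patch shape: ~8.5 x 11 mm with ~0.8 mm buccal convexity."""

    width: float = 8.5  # mesio-distal, mm
    height: float = 11.0  # cervico-incisal, mm
    sag: float = 0.8  # buccal convexity depth, mm
    rounding: float = 1.2  # corner rounding radius, mm
    nx: int = 17  # grid vertices across the width (odd -> midline column)

    def __post_init__(self):
        if not (self.width > 0 and self.height > 0):
            raise DomainError("tooth width and height must be positive")
        if self.sag < 0:
            raise DomainError("sag must be >= 0")
        if not (0 <= self.rounding < min(self.width, self.height) / 2):
            raise DomainError("rounding must lie in [0, min(width, height)/2)")
        if self.nx < 5 or self.nx % 2 == 0:
            raise DomainError("nx must be an odd integer >= 5")
        pitch = self.width / (self.nx - 1)
        if self.rounding > 0 and pitch > self.rounding:
            raise DomainError(
                f"grid pitch {pitch:.3f} mm cannot resolve rounding "
                f"radius {self.rounding} mm; increase nx"
            )

    @property
    def ny(self) -> int:
        n = int(round((self.nx - 1) * self.height / self.width)) + 1
        return n if n % 2 == 1 else n + 1  # odd -> mid-height row


@dataclass
class FaceShapeParams:
    """Synthetic facial shell parameters, tied to the scaled tooth."""

    scale: float = DEFAULT_SCALE
    tooth_width: float = 8.5
    tooth_height: float = 11.0
    tooth_sag: float = 0.8
    transverse_curvature: float = 0.006  # a, 1/mm
    vertical_curvature: float = 0.004  # b, 1/mm
    anterior_offset: float = 5.0  # A, mm: plateau advance over the base apex
    margin_frac: float = 0.2  # mesh half-width = (1 + margin) x footprint
    transition_frac: float = 0.1  # mask rolloff width as fraction of footprint
    pogonion_frac: float = 0.15  # midline landmark heights as fractions of
    labiale_superius_frac: float = 0.45  # the menton->glabella span
    zygion_height_frac: float = 0.62
    alare_height_frac: float = 0.50
    alare_halfspan_frac: float = 0.25  # of the footprint half-width
    spike_height: float = 0.0  # anterior spike apex z (mm); 0 = no spike
    nx: int = 49  # odd; target grid across the full mesh width
    ny: int = 41
    tooth_nx: int = 17  # x-lattice of the matching tooth patch; the crown
    # plateau is the chordal (piecewise-linear) sag sampled on that lattice
    # and the footprint grid nests it, so at kappa = 1 the facial surface
    # coincides with the scaled tooth facets instead of interpenetrating
    # them at the chordal-sagitta scale

    def __post_init__(self):
        if self.scale <= 0:
            raise DomainError("scale must be positive")
        if self.nx % 2 == 0 or self.ny < 5 or self.nx < 9:
            raise DomainError("nx must be odd >= 9 and ny >= 5")
        if self.tooth_nx < 5 or self.tooth_nx % 2 == 0:
            raise DomainError("tooth_nx must be an odd integer >= 5")
        # monotonicity of %SI in kappa requires a >= s*sag / (s*w/2)^2
        a_min = (self.scale * self.tooth_sag) / (self.scale * self.tooth_width / 2) ** 2
        if self.transverse_curvature < a_min:
            raise DomainError(
                f"transverse_curvature must be >= {a_min:.5f} for kappa-monotone %SI"
            )
        if not (0 < self.transition_frac <= self.margin_frac):
            raise DomainError("need 0 < transition_frac <= margin_frac")

    @property
    def bizygomatic_width(self) -> float:
        return self.scale * self.tooth_width

    @property
    def facial_height(self) -> float:
        return self.scale * self.tooth_height


# ---------------------------------------------------------------------------
# Tooth patch
# ---------------------------------------------------------------------------


def _grid_mesh(xs: np.ndarray, ys: np.ndarray, z_of_xy) -> TriangleMesh:
    """Regular heightfield grid, CCW seen from +Z."""
    nx, ny = len(xs), len(ys)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = z_of_xy(X, Y)
    verts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    faces = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            faces.append((a, b, b + 1))
            faces.append((a, b + 1, a + 1))
    return TriangleMesh(verts, np.asarray(faces, dtype=np.int64))


def gen_tooth(
    params: ToothShapeParams | None = None, seed: int = 0
) -> tuple[TriangleMesh, ToothLandmarks, float]:
    """Curved rounded-rectangle buccal patch with boundary landmarks.

    Returns (patch, landmarks, analytic planform area). The construction is
    fully deterministic; ``seed`` is accepted for interface uniformity.
    """
    p = params or ToothShapeParams()
    w, ht, r = p.width, p.height, p.rounding
    xs = np.linspace(-w / 2, w / 2, p.nx)
    ys = np.linspace(0.0, ht, p.ny)

    def sag_z(x):
        return p.sag * (1.0 - (2.0 * x / w) ** 2)

    mesh = _grid_mesh(xs, ys, lambda X, Y: sag_z(X))
    if r > 0:
        v = mesh.vertices.copy()
        for cx, cy in ((w / 2 - r, r), (w / 2 - r, ht - r),
                       (-w / 2 + r, r), (-w / 2 + r, ht - r)):
            dx = v[:, 0] - cx
            dy = v[:, 1] - cy
            sel = (np.sign(dx) == np.sign(cx)) & (
                (dy > 0) if cy > ht / 2 else (dy < 0)
            )
            d = np.hypot(dx, dy)
            out = sel & (d > r)
            if out.any():
                f = r / d[out]
                v[out, 0] = cx + dx[out] * f
                v[out, 1] = cy + dy[out] * f
                v[out, 2] = sag_z(v[out, 0])
        mesh = TriangleMesh(v, mesh.faces)

    lm = ToothLandmarks(
        incisal_midpoint=np.array([0.0, 0.0, sag_z(0.0)]),
        mesial_edge_midpoint=np.array([-w / 2, ht / 2, sag_z(-w / 2)]),
        distal_edge_midpoint=np.array([w / 2, ht / 2, sag_z(w / 2)]),
        cervical_midpoint=np.array([0.0, ht, sag_z(0.0)]),
    )
    return mesh, lm, _planform_area(mesh)


def _planform_area(patch: TriangleMesh) -> float:
    """Exact XY-plane area enclosed by the patch boundary loop (shoelace)."""
    f = patch.faces
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    count: dict = {}
    for a, b in e:
        count[(int(a), int(b))] = count.get((int(a), int(b)), 0) + 1
    s = 0.0
    for (a, b), c in count.items():
        if c == 1 and count.get((b, a), 0) == 0:
            pa, pb = patch.vertices[a], patch.vertices[b]
            s += pa[0] * pb[1] - pb[0] * pa[1]
    return abs(s) / 2.0


# ---------------------------------------------------------------------------
# Face shell
# ---------------------------------------------------------------------------


def _mask(x: np.ndarray, half: float, trans: float) -> np.ndarray:
    """1 on |x| <= half, cosine rolloff to 0 over [half, half + trans]."""
    ax = np.abs(x)
    m = np.zeros_like(ax)
    m[ax <= half] = 1.0
    ring = (ax > half) & (ax < half + trans)
    m[ring] = 0.5 * (1.0 + np.cos(np.pi * (ax[ring] - half) / trans))
    return m


def gen_face(
    params: FaceShapeParams | None = None,
    tooth_scaled: TriangleMesh | None = None,
    kappa: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[TriangleMesh, FaceLandmarks]:
    """Facial shell blended toward the scaled tooth surface with weight kappa.

    ``tooth_scaled`` (the scaled buccal patch) is cross-checked against the
    parameters when given. The returned shell is exactly pre-aligned: its
    area centroid is the origin, glabella->pogonion is parallel to -Y, and
    the midline landmarks lie in X = 0.
    """
    p = params or FaceShapeParams()
    if not (0.0 <= kappa <= 1.0):
        raise DomainError(f"kappa must lie in [0, 1], got {kappa}")
    if noise_sd < 0:
        raise DomainError("noise_sd must be >= 0")
    s = p.scale
    X_half = s * p.tooth_width / 2.0  # footprint half-width
    sA = s * p.tooth_sag  # scaled sag amplitude
    Hf = s * p.tooth_height  # menton -> glabella span
    if tooth_scaled is not None:
        b = tooth_scaled.bounds()
        if not np.isclose(b[1, 0] - b[0, 0], 2 * X_half, rtol=1e-6):
            raise DomainError("tooth_scaled width inconsistent with FaceShapeParams")
        if not np.isclose(b[1, 1] - b[0, 1], Hf, rtol=1e-6):
            raise DomainError("tooth_scaled height inconsistent with FaceShapeParams")

    W_half = (1.0 + p.margin_frac) * X_half
    trans = p.transition_frac * X_half
    y_men, y_gla = -Hf / 2.0, Hf / 2.0

    # x grid with exact lattice lines at +-X_half (zygions, mask edge);
    # the footprint segment nests the scaled tooth x-lattice so that facial
    # grid cells lie inside tooth facet planes (surface is linear in y)
    n_out = max(3, (p.nx - 1) // 8)
    n_target = max(p.tooth_nx, p.nx - 2 * n_out)
    k_ref = max(1, int(round((n_target - 1) / (p.tooth_nx - 1))))
    n_in = k_ref * (p.tooth_nx - 1) + 1
    xs = np.concatenate(
        [
            np.linspace(-W_half, -X_half, n_out + 1)[:-1],
            np.linspace(-X_half, X_half, n_in),
            np.linspace(X_half, W_half, n_out + 1)[1:],
        ]
    )
    # chordal crown profile: the sag parabola sampled on the tooth lattice
    xt_lattice = np.linspace(-X_half, X_half, p.tooth_nx)
    sag_nodes = sA * (1.0 - (xt_lattice / X_half) ** 2)
    ys = np.linspace(y_men, y_gla, p.ny)

    def snap_y(frac):
        return ys[int(np.argmin(np.abs(ys - (y_men + frac * Hf))))]

    y_pog = snap_y(p.pogonion_frac)
    y_ls = snap_y(p.labiale_superius_frac)
    y_zyg = snap_y(p.zygion_height_frac)
    y_ala = snap_y(p.alare_height_frac)
    x_ala = xs[int(np.argmin(np.abs(xs - p.alare_halfspan_frac * X_half)))]
    y_mid = 0.5 * (y_gla + y_pog)  # base profile symmetric about this level

    a, b_, A = p.transverse_curvature, p.vertical_curvature, p.anterior_offset

    def surface(Xg, Yg):
        base = -a * Xg**2 - b_ * (Yg - y_mid) ** 2
        plateau = A + np.interp(Xg, xt_lattice, sag_nodes)
        m = kappa * _mask(Xg, X_half, trans)
        return (1.0 - m) * base + m * plateau

    mesh = _grid_mesh(xs, ys, surface)
    nx, ny = len(xs), len(ys)

    def vid(xv, yv):
        i = int(np.argmin(np.abs(xs - xv)))
        j = int(np.argmin(np.abs(ys - yv)))
        return i * ny + j

    lm_ids = {
        "glabella": vid(0.0, y_gla),
        "pogonion": vid(0.0, y_pog),
        "menton": vid(0.0, y_men),
        "labiale_superius": vid(0.0, y_ls),
        "zygion_left": vid(+X_half, y_zyg),
        "zygion_right": vid(-X_half, y_zyg),
        "alare_left": vid(+x_ala, y_ala),
        "alare_right": vid(-x_ala, y_ala),
    }
    verts = mesh.vertices.copy()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        jitter = rng.normal(0.0, noise_sd, len(verts))
        jitter[list(lm_ids.values())] = 0.0  # landmarks stay exact
        verts[:, 2] += jitter
    if p.spike_height > 0:
        # symmetric spike pair outside the crown footprint: keeps the shell's
        # midline symmetry (area centroid, yaw criterion) intact while making
        # the anterior-most surface point clear of the footprint laterally
        j_spike = ny // 2
        x_spike = X_half + 0.5 * (W_half - X_half)
        for xt in (+x_spike, -x_spike):
            i_spike = int(np.argmin(np.abs(xs - xt)))
            verts[i_spike * ny + j_spike, 2] = p.spike_height
    mesh = TriangleMesh(verts, mesh.faces)

    # exact pre-alignment: area centroid to the origin
    tri = mesh.triangles()
    areas = np.linalg.norm(mesh.face_normals(), axis=1) / 2.0
    centroid = (tri.mean(axis=1) * areas[:, None]).sum(axis=0) / areas.sum()
    verts = mesh.vertices - centroid
    mesh = TriangleMesh(verts, mesh.faces)
    lm = FaceLandmarks(**{k: verts[i] for k, i in lm_ids.items()})
    return mesh, lm


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class CohortSimConfig:
    """Ground-truth parameters of the simulated cohort (study defaults)."""

    n: int = 98
    sex_ratio_female: float = 64.0 / 98.0
    female_vtotal_mean: float = 1_583_561.0
    female_vtotal_sd: float = 225_978.0
    male_vtotal_mean: float = 1_706_232.0
    male_vtotal_sd: float = 151_086.0
    si_mean: float = 82.64
    si_sd: float = 7.36
    si_skew_shape: float = -4.0  # left-skewed %SI -> right-skewed RTV
    rho_female: float = 0.515  # target Spearman(V_total, RTV) per sex
    rho_male: float = 0.142
    age_mean: float = 20.56
    age_sd: float = 1.29
    age_min: int = 18
    age_max: int = 27
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise FeasibilityError(f"cohort size must be >= 1, got {self.n}")
        if not (0.0 <= self.sex_ratio_female <= 1.0):
            raise DomainError("sex_ratio_female must lie in [0, 1]")
        for nm in ("female_vtotal_sd", "male_vtotal_sd", "si_sd", "age_sd"):
            if getattr(self, nm) <= 0:
                raise DomainError(f"{nm} must be positive")
        for nm in ("rho_female", "rho_male"):
            if not (-1.0 < getattr(self, nm) < 1.0):
                raise DomainError(f"{nm} must lie in (-1, 1)")
        if not (0 < self.si_mean < 100):
            raise DomainError("si_mean must lie in (0, 100)")

    def as_dict(self) -> dict:
        return asdict(self)


@lru_cache(maxsize=32)
def _si_marginal(mean: float, sd: float, shape: float) -> tuple[float, float]:
    """(loc, scale) of the [0, 100]-truncated skew-normal matching mean/SD."""

    def moments(loc, scale):
        dist = stats.skewnorm(shape, loc=loc, scale=scale)
        f0, f1 = dist.cdf(0.0), dist.cdf(100.0)
        z = f1 - f0
        if z <= 1e-12:
            return np.nan, np.nan
        m1 = integrate.quad(lambda x: x * dist.pdf(x), 0, 100, limit=200)[0] / z
        m2 = integrate.quad(lambda x: x * x * dist.pdf(x), 0, 100, limit=200)[0] / z
        return m1, np.sqrt(max(m2 - m1 * m1, 0.0))

    def f(theta):
        m, s_ = moments(theta[0], np.exp(theta[1]))
        return [m - mean, s_ - sd]

    delta = shape / np.sqrt(1 + shape * shape)
    scale0 = sd / np.sqrt(max(1 - 2 * delta * delta / np.pi, 1e-6))
    loc0 = mean - scale0 * delta * np.sqrt(2 / np.pi)
    sol = optimize.root(f, x0=[loc0, np.log(scale0)], method="hybr", tol=1e-12)
    if not sol.success:
        raise FeasibilityError(
            f"cannot match %SI mean {mean} / SD {sd} with skew shape {shape}"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _si_from_uniform(u: np.ndarray, mean: float, sd: float, shape: float) -> np.ndarray:
    loc, scale = _si_marginal(mean, sd, shape)
    dist = stats.skewnorm(shape, loc=loc, scale=scale)
    f0, f1 = dist.cdf(0.0), dist.cdf(100.0)
    return np.clip(dist.ppf(f0 + u * (f1 - f0)), 0.0, 100.0)


@lru_cache(maxsize=64)
def _calibrate_copula(
    rho_target: float,
    v_mean: float,
    v_sd: float,
    si_mean: float,
    si_sd: float,
    si_shape: float,
    n_sim: int = 40_000,
) -> float:
    """Copula parameter r giving Spearman(V_total, RTV) = rho_target."""
    rng = np.random.default_rng(20_240_001)
    e1 = rng.standard_normal(n_sim)
    e2 = rng.standard_normal(n_sim)

    def spearman_at(r):
        z2 = r * e1 + np.sqrt(1.0 - r * r) * e2
        v = v_mean + v_sd * e1
        si = _si_from_uniform(stats.norm.cdf(z2), si_mean, si_sd, si_shape)
        rtv = v * (1.0 - si / 100.0)
        return stats.spearmanr(v, rtv).statistic

    lo, hi = -0.999, 0.999
    f_lo = spearman_at(lo) - rho_target
    f_hi = spearman_at(hi) - rho_target
    if f_lo * f_hi > 0:
        raise FeasibilityError(
            f"target Spearman {rho_target} outside achievable range "
            f"[{f_lo + rho_target:.3f}, {f_hi + rho_target:.3f}] for this "
            "%SI skew configuration"
        )
    return float(optimize.brentq(lambda r: spearman_at(r) - rho_target, lo, hi, xtol=1e-4))


def gen_cohort_table(config: CohortSimConfig | None = None) -> tuple[pd.DataFrame, dict]:
    """Simulate the per-subject cohort table with known ground truth."""
    cfg = config or CohortSimConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    female = rng.random(n) < cfg.sex_ratio_female
    # ages: discretised truncated normal on [age_min, age_max]
    a_lo = (cfg.age_min - cfg.age_mean) / cfg.age_sd
    a_hi = (cfg.age_max + 0.999 - cfg.age_mean) / cfg.age_sd
    ages = np.floor(
        stats.truncnorm.ppf(rng.random(n), a_lo, a_hi, loc=cfg.age_mean, scale=cfg.age_sd)
    ).astype(int)

    params = {
        True: (cfg.female_vtotal_mean, cfg.female_vtotal_sd, cfg.rho_female),
        False: (cfg.male_vtotal_mean, cfg.male_vtotal_sd, cfg.rho_male),
    }
    calibrated = {}
    v_total = np.empty(n)
    si = np.empty(n)
    z1 = rng.standard_normal(n)
    e2 = rng.standard_normal(n)
    for is_f, (mu, sd, rho) in params.items():
        r = _calibrate_copula(
            rho, mu, sd, cfg.si_mean, cfg.si_sd, cfg.si_skew_shape
        )
        calibrated["female" if is_f else "male"] = r
        sel = female == is_f
        z2 = r * z1[sel] + np.sqrt(1.0 - r * r) * e2[sel]
        v_total[sel] = mu + sd * z1[sel]
        si[sel] = _si_from_uniform(
            stats.norm.cdf(z2), cfg.si_mean, cfg.si_sd, cfg.si_skew_shape
        )
    v_total = np.maximum(v_total, 1.0)
    v_sup = v_total * si / 100.0
    rtv = v_total - v_sup

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i + 1:03d}" for i in range(n)],
            "sex": np.where(female, "female", "male"),
            "age": ages,
            "v_total": v_total,
            "v_superimposed": v_sup,
            "rtv": rtv,
            "pct_si": si,
        }
    )
    loc, scale = _si_marginal(cfg.si_mean, cfg.si_sd, cfg.si_skew_shape)
    truth = {
        "config": cfg.as_dict(),
        "copula_r": calibrated,
        "si_marginal": {"loc": loc, "scale": scale, "shape": cfg.si_skew_shape},
    }
    return table, truth


# ---------------------------------------------------------------------------
# End-to-end mesh fixtures
# ---------------------------------------------------------------------------


@dataclass
class SubjectMeshConfig:
    """One-subject geometry fixture parameters."""

    tooth: ToothShapeParams = field(default_factory=ToothShapeParams)
    face: FaceShapeParams = field(default_factory=FaceShapeParams)
    kappa: float = 1.0
    noise_sd: float = 1e-3
    disjoint: bool = False


def gen_subject_meshes(
    config: SubjectMeshConfig | None = None, seed: int = 0, out_dir=None
) -> dict:
    """Generate one subject's tooth scan, face shell, landmarks and %SI band.

    When ``out_dir`` is given, writes tooth.stl / face.stl / tooth_landmarks
    .json / face_landmarks.json / expected.json there (deterministic bytes
    for a fixed seed).
    """
    cfg = config or SubjectMeshConfig()
    patch, tooth_lm, area = gen_tooth(cfg.tooth, seed=seed)
    face_params = cfg.face
    if cfg.disjoint:
        face_params = FaceShapeParams(
            **{**asdict(cfg.face), "spike_height": 120.0}
        )
        kappa = 0.0
    else:
        kappa = cfg.kappa
    scaled_patch = TriangleMesh(patch.vertices * face_params.scale, patch.faces)
    face, face_lm = gen_face(
        face_params, scaled_patch, kappa=kappa, noise_sd=cfg.noise_sd, seed=seed + 1
    )
    if cfg.disjoint:
        band = (0.0, 0.0)
    elif kappa == 1.0:
        band = (99.0, 100.0)
    else:
        band = (0.0, 100.0)
    out = {
        "tooth_mesh": patch,
        "tooth_landmarks": tooth_lm,
        "face_mesh": face,
        "face_landmarks": face_lm,
        "expected_si_band": band,
        "analytic_patch_area": area,
        "kappa": kappa,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_mesh(patch, out_dir / "tooth.stl")
        write_mesh(face, out_dir / "face.stl")
        save_landmarks(tooth_lm, out_dir / "tooth_landmarks.json")
        save_landmarks(face_lm, out_dir / "face_landmarks.json")
        (out_dir / "expected.json").write_text(
            json.dumps(
                {
                    "expected_si_band": list(band),
                    "kappa": kappa,
                    "disjoint": cfg.disjoint,
                    "scale": face_params.scale,
                    "extrusion_mm": DEFAULT_EXTRUSION_MM,
                },
                indent=2,
            )
            + "\n"
        )
        out["paths"] = {
            "tooth": str(out_dir / "tooth.stl"),
            "face": str(out_dir / "face.stl"),
            "tooth_landmarks": str(out_dir / "tooth_landmarks.json"),
            "face_landmarks": str(out_dir / "face_landmarks.json"),
        }
    return out
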