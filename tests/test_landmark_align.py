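"""Landmark schemas, sidecar I/O, and the three alignment operations."""

import numpy as np
import pytest

from dentofacial.errors import (
    DegenerateConfigurationError,
    MissingLandmarkError,
    SchemaError,
)
from dentofacial.landmark_align import (
    FaceLandmarks,
    ToothLandmarks,
    align_face,
    align_tooth,
    load_face_landmarks,
    load_tooth_landmarks,
    place_for_superimposition,
    save_landmarks,
)
from dentofacial.mesh_core import RigidTransform, apply_transform, center_of_volume
from dentofacial.superimposition import extrude_to_solid
from dentofacial.synthetic import gen_face, gen_tooth


def _tooth_fixture():
    patch, lm, _ = gen_tooth()
    return extrude_to_solid(patch, 6.0), lm


def _random_rigid(seed):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    return RigidTransform(q.T, rng.uniform(-40, 40, 3))


# ---------------------------------------------------------------------------
# Schemas and sidecar I/O
# ---------------------------------------------------------------------------


def test_tooth_landmarks_coincident_points_rejected():
    p = np.zeros(3)
    with pytest.raises(DegenerateConfigurationError):
        ToothLandmarks(p, [1, 0, 0], [1, 0, 0], [0, 1, 0])
    with pytest.raises(DegenerateConfigurationError):
        ToothLandmarks(p, [-1, 0, 0], [1, 0, 0], p)


def test_landmark_point_validation():
    with pytest.raises(SchemaError):
        ToothLandmarks([0, 0], [1, 0, 0], [-1, 0, 0], [0, 1, 0])
    with pytest.raises(SchemaError):
        ToothLandmarks([0, 0, np.nan], [1, 0, 0], [-1, 0, 0], [0, 1, 0])


def test_tooth_landmark_json_round_trip(tmp_path):
    _, lm = _tooth_fixture()
    path = tmp_path / "tooth.json"
    save_landmarks(lm, path)
    back = load_tooth_landmarks(path)
    for name, v in lm.as_dict().items():
        assert getattr(back, name) == pytest.approx(v)


def test_face_landmark_json_round_trip(tmp_path):
    _, lm = gen_face()
    path = tmp_path / "face.json"
    save_landmarks(lm, path)
    back = load_face_landmarks(path)
    for name, v in lm.as_dict().items():
        assert getattr(back, name, None) is not None or name in back.optional


def test_unknown_and_missing_landmark_names(tmp_path):
    path = tmp_path / "bad.json"
    path.write_text('{"incisal_midpoint": [0,0,0], "weird": [1,1,1]}')
    with pytest.raises(SchemaError):
        load_tooth_landmarks(path)
    path.write_text('{"incisal_midpoint": [0,0,0]}')
    with pytest.raises(MissingLandmarkError):
        load_tooth_landmarks(path)
    with pytest.raises(MissingLandmarkError):
        load_tooth_landmarks(tmp_path / "nope.json")
    path.write_text("not json")
    with pytest.raises(SchemaError):
        load_tooth_landmarks(path)


def test_face_landmarks_optional_validation():
    _, lm = gen_face()
    with pytest.raises(SchemaError):
        FaceLandmarks(**{k: np.asarray(v) for k, v in lm.as_dict().items()},
                      optional={"made_up": [0, 0, 0]})


# ---------------------------------------------------------------------------
# align_tooth
# ---------------------------------------------------------------------------


def test_align_tooth_postconditions():
    solid, lm = _tooth_fixture()
    _, aligned, alm = align_tooth(solid, lm)
    # origin at the centre of volume
    assert center_of_volume(aligned) == pytest.approx(np.zeros(3), abs=1e-9)
    # cervical -> incisal along -Y: incisal below cervical, both on the midline
    assert alm.incisal_midpoint[1] < alm.cervical_midpoint[1]
    assert alm.incisal_midpoint[0] == pytest.approx(0.0, abs=1e-9)
    assert alm.cervical_midpoint[0] == pytest.approx(0.0, abs=1e-9)
    # mesial -> distal along +X
    assert alm.distal_edge_midpoint[0] > alm.mesial_edge_midpoint[0]


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_align_tooth_recovers_from_rigid_motion(seed):
    solid, lm = _tooth_fixture()
    t = _random_rigid(seed)
    moved = apply_transform(solid, t)
    _, a0, _ = align_tooth(solid, lm)
    _, a1, _ = align_tooth(moved, lm.transformed(t))
    assert a1.vertices == pytest.approx(a0.vertices, abs=1e-6)


def test_align_tooth_collinear_landmarks_rejected():
    solid, _ = _tooth_fixture()
    lm = ToothLandmarks([0, 0, 0], [0, 1, 0], [0, 3, 0], [0, 2, 0])
    with pytest.raises(DegenerateConfigurationError):
        align_tooth(solid, lm)


# ---------------------------------------------------------------------------
# align_face
# ---------------------------------------------------------------------------


def test_align_face_identity_on_prealigned_shell():
    # the generated shell is pre-aligned up to the ~1e-3 mm midline offset of
    # its area centroid (diagonal triangulation of a curved surface), so
    # align_face must be a near-identity at that scale
    face, lm = gen_face()
    t, aligned, alm = align_face(face, lm)
    assert t.rotation == pytest.approx(np.eye(3), abs=1e-4)
    assert t.translation == pytest.approx(np.zeros(3), abs=1e-2)
    assert aligned.vertices == pytest.approx(face.vertices, abs=0.05)


def test_align_face_postconditions_and_recovery():
    face, lm = gen_face()
    _, a0, _ = align_face(face, lm)
    for seed in (11, 12):
        t = _random_rigid(seed)
        moved = apply_transform(face, t)
        _, a1, alm1 = align_face(moved, lm.transformed(t))
        assert a1.vertices == pytest.approx(a0.vertices, abs=1e-5)
        # glabella -> pogonion parallel to -Y, midline points near X = 0
        # (the yaw is a least-squares fit over two points, so their residual
        # X offsets stay at the centroid-offset scale, not exactly zero)
        seg = alm1.pogonion - alm1.glabella
        assert seg[0] == pytest.approx(0.0, abs=1e-9)
        assert seg[2] == pytest.approx(0.0, abs=1e-9)
        assert seg[1] < 0
        assert alm1.labiale_superius[0] == pytest.approx(0.0, abs=5e-3)
        # glabella anterior (+Z half-space choice of the yaw)
        assert alm1.glabella[2] >= -1e-6


def test_align_face_is_idempotent():
    face, lm = gen_face()
    _, a1, alm1 = align_face(face, lm)
    _, a2, _ = align_face(a1, alm1)
    assert a2.vertices == pytest.approx(a1.vertices, abs=1e-9)


# ---------------------------------------------------------------------------
# place_for_superimposition
# ---------------------------------------------------------------------------


def _placement_fixture():
    face, face_lm = gen_face()
    patch, tooth_lm, _ = gen_tooth()
    solid = extrude_to_solid(patch, 6.0)
    from dentofacial.mesh_core import uniform_scale

    scaled = uniform_scale(solid, 15.56)
    scaled_lm = ToothLandmarks(
        **{k: np.asarray(v) * 15.56 for k, v in tooth_lm.as_dict().items()}
    )
    _, tooth_a, lm_a = align_tooth(scaled, scaled_lm)
    return face, face_lm, tooth_a, lm_a


def test_place_residual_zero_for_matched_span():
    face, face_lm, tooth, lm = _placement_fixture()
    t, residual = place_for_superimposition(face, face_lm, tooth, lm)
    # the generator builds menton->glabella exactly 15.56 x tooth height, so
    # the two vertical constraints agree and the least-squares residual is 0
    assert residual == pytest.approx(0.0, abs=1e-6)
    placed = apply_transform(tooth, t)
    # anterior tangency and transverse centring
    assert placed.vertices[:, 2].max() == pytest.approx(
        face.vertices[:, 2].max(), abs=1e-9
    )
    mid = 0.5 * (placed.vertices[:, 0].min() + placed.vertices[:, 0].max())
    span_mid = 0.5 * (face_lm.zygion_left[0] + face_lm.zygion_right[0])
    assert mid == pytest.approx(span_mid, abs=1e-9)


def test_place_translation_cancels_face_shift():
    face, face_lm, tooth, lm = _placement_fixture()
    t0, _ = place_for_superimposition(face, face_lm, tooth, lm)
    from dentofacial.mesh_core import TriangleMesh

    shift = np.array([5.0, 0.0, 0.0])
    face2 = TriangleMesh(face.vertices + shift, face.faces)
    lm2 = face_lm.transformed(RigidTransform.from_translation(shift))
    t1, _ = place_for_superimposition(face2, lm2, tooth, lm)
    assert t1.translation - t0.translation == pytest.approx(shift, abs=1e-9)


def test_place_modes_and_errors():
    face, face_lm, tooth, lm = _placement_fixture()
    t_z, _ = place_for_superimposition(face, face_lm, tooth, lm, mode="zygion")
    t_a, _ = place_for_superimposition(face, face_lm, tooth, lm, mode="alare")
    # both landmark pairs are x-symmetric on the synthetic face
    assert t_a.translation == pytest.approx(t_z.translation, abs=1e-9)
    with pytest.raises(MissingLandmarkError):
        place_for_superimposition(face, face_lm, tooth, lm, mode="nasion")


def test_place_residual_reflects_vertical_mismatch():
    face, face_lm, tooth, lm = _placement_fixture()
    # stretch the tooth's landmark span by 2 mm: constraints now disagree
    lm2 = ToothLandmarks(
        incisal_midpoint=lm.incisal_midpoint - [0.0, 2.0, 0.0],
        mesial_edge_midpoint=lm.mesial_edge_midpoint,
        distal_edge_midpoint=lm.distal_edge_midpoint,
        cervical_midpoint=lm.cervical_midpoint,
    )
    _, residual = place_for_superimposition(face, face_lm, tooth, lm2)
    assert residual == pytest.approx(1.0, abs=1e-9)
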