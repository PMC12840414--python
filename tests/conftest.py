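"""Shared fixtures: seeded hypothesis profile and cached pipeline runs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dentofacial.config import PipelineConfig
from dentofacial.superimposition import PatchSelection, run_superimposition
from dentofacial.synthetic import SubjectMeshConfig, gen_subject_meshes

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

_FIXTURE_SEED = 3


def _run(kappa=None, disjoint=False, config=None, seed=_FIXTURE_SEED):
    cfg_mesh = SubjectMeshConfig(disjoint=True) if disjoint else SubjectMeshConfig(kappa=kappa)
    fx = gen_subject_meshes(cfg_mesh, seed=seed)
    sel = PatchSelection(np.arange(fx["tooth_mesh"].n_faces))
    result = run_superimposition(
        fx["tooth_mesh"],
        fx["tooth_landmarks"],
        fx["face_mesh"],
        fx["face_landmarks"],
        sel,
        config or PipelineConfig(),
    )
    return fx, result


@pytest.fixture(scope="session")
def pipeline_runs():
    """One full pipeline run per scenario, computed once per session.

    Keys: kappa sweep ('k02', 'k06', 'k085', 'k1'), a bitwise repeat of
    'k085', the same subject with scaling applied after alignment and with a
    deeper cap plane, and the disjoint fixture. Values are (fixture dict,
    SuperimpositionResult).
    """
    runs = {}
    for key, kappa in (("k02", 0.2), ("k06", 0.6), ("k085", 0.85), ("k1", 1.0)):
        runs[key] = _run(kappa=kappa)
    runs["k085_repeat"] = _run(kappa=0.85)
    runs["k085_scale_after"] = _run(
        kappa=0.85, config=PipelineConfig(scale_after_alignment=True)
    )
    cap = runs["k085"][1].config["cap_depth"]
    runs["k085_cap_deeper"] = _run(
        kappa=0.85, config=PipelineConfig(cap_depth=cap + 60.0)
    )
    runs["disjoint"] = _run(disjoint=True)
    return runs


@pytest.fixture(scope="session")
def subject_fixture_dir(tmp_path_factory):
    """On-disk kappa = 1 subject fixture (STL + landmark JSON + expected)."""
    out = tmp_path_factory.mktemp("subject_k1")
    gen_subject_meshes(SubjectMeshConfig(kappa=1.0), seed=_FIXTURE_SEED, out_dir=out)
    return out
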