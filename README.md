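# dentofacial

Volumetric tooth–face superimposition and cohort statistics.

The package implements a 3-D protocol that quantifies how much of a scaled
anterior tooth form is "absorbed" by a facial surface:

1. the buccal patch of a maxillary central incisor scan is extracted,
   extruded 6 mm along its mean normal into a closed solid, and uniformly
   scaled ×15.56;
2. the scaled tooth solid and the face shell are moved into a common
   landmark-defined frame and the tooth is placed tangent to the face
   (anterior tangency, transverse centring on the zygion span, vertical
   least-squares over the incisal–menton and cervical–glabella constraints);
3. the face shell is closed into a solid and Boolean-intersected with the
   tooth solid;
4. per subject, `V_superimposed` is the intersection volume,
   `RTV = V_total − V_superimposed` (remaining tooth volume) and
   `%SI = V_superimposed / V_total × 100` (percentage superimposition).

Cohort-level analysis (descriptives, normality gating, paired and two-sample
tests, Spearman correlation, achieved power) and synthetic generators for
meshes and cohort tables round out the pipeline.

## Layout

| Module | Contents |
| --- | --- |
| `dentofacial.mesh_core` | `TriangleMesh`, watertightness checks, signed volume, centre of volume, rigid transforms, uniform scaling, STL/OFF I/O |
| `dentofacial.csg` | authored Boolean intersection kernel (local corefinement + ray-parity classification) |
| `dentofacial.landmark_align` | landmark schemas and JSON sidecars, `align_tooth`, `align_face`, `place_for_superimposition` |
| `dentofacial.superimposition` | `extract_patch`, `extrude_to_solid`, `face_to_solid`, `boolean_intersection`, `compute_metrics`, `run_superimposition` |
| `dentofacial.cohort_stats` | cohort schema validation, descriptives, tests, effect sizes, power, `analysis_report` |
| `dentofacial.synthetic` | deterministic tooth/face/subject mesh generators and the copula-based cohort simulator |
| `dentofacial.reference` | bundled reference-cohort summary inputs and `recompute_reference_battery` |
| `dentofacial.config` | `PipelineConfig` protocol presets (scale 15.56, extrusion 6 mm, zygion mode, …) |
| `dentofacial.cli` | `dentofacial superimpose | cohort | simulate | power` |

## CLI

```bash
# one subject end to end
dentofacial superimpose tooth.stl face.stl \
    --tooth-landmarks tooth_landmarks.json \
    --face-landmarks face_landmarks.json --out-dir results/

# simulate a 98-subject cohort, then analyse it
dentofacial simulate --out-dir sim --seed 7
dentofacial cohort sim/cohort.csv --out-dir report/

# achieved power from summary statistics
dentofacial power --mean-diff 285052.34 --sd-diff 137012.73 --n 98
```

## Tests

```bash
python -m pytest tests
```

`tests/test_acceptance.py` holds one test per acceptance criterion; the
geometry suite checks the authored Boolean kernel against an independent
column-sampling volume oracle, and the statistics suite cross-checks the
authored power functions against `statsmodels`.

Design notes and the rationale for frame choices, kernel tolerances and the
calibration experiments are in `docs/methods.md`.
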