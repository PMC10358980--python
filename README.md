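# mapeval

Pre-clinical evaluation of cardiac electro-anatomical mapping systems against
simulated "silver standard" tissue activity.

Clinical mapping systems infer tissue activation from intracardiac
electrograms, but in patients the true transmembrane activity is unknown, so
their accuracy cannot be measured directly. `mapeval` closes that gap in
silico: it simulates transmembrane potentials (Vm) on atrial tissue
geometries, synthesizes the unipolar electrograms a catheter would record at
user-supplied electrode positions, and scores a mapping system's reported
activation times and activation patterns against the simulated ground truth —
without ever revealing the Vm data to the system under test.

## What it does

1. **Simulate** — monodomain reaction–diffusion on triangulated sheets and
   shells, with a 28-state human atrial membrane model (or a fast two-variable
   surrogate), paced / S1–S2 reentry / focal stimulation protocols, and a
   tissue conductivity calibrated so a plane wave travels at 55 cm/s.
2. **Synthesize** — unipolar extracellular electrograms from the lead-field
   integral φe = ∫ −σe ∇Vm · ∇(1/r) dV over the tissue, evaluated with
   Gaussian quadrature, plus bounded uniform noise at a declared level.
3. **Detect** — activation times from extremal dV/dt episodes with a
   refractory constraint; phase maps, phase-singularity tracking with
   topological charge, and k-means localization of reentrant sources.
4. **Classify** — per-beat activation patterns on 3×3 electrode
   neighbourhoods: focal/planar (F), clockwise reentry (R+),
   counterclockwise reentry (R−).
5. **Score** — optimal one-to-one matching of reported vs. true activation
   times within a tolerance, then
   `AcTPM = fC · (1 − fS) · 100` for timing and
   `AcPPM = fC · (1 − fS) · (1 − fM) · 100` for patterns
   (fractions of correct, spurious, and misclassified detections).

The blinded workflow (`mapeval.workflow.EvaluationSession`) enforces the
evaluation protocol: the system under test sees only a surface point cloud and
its own noisy electrograms; master-seed-derived per-entry noise seeds make
every issued dataset bit-reproducible.

## Quick start

```python
from mapeval.geometry import build_sheet_geometry, place_uniform_array
from mapeval.simulator import TissueParams, protocol_paced, run_monodomain
from mapeval.electrograms import compute_electrograms
from mapeval.activation import DetectorParams, detect_activations

geom = build_sheet_geometry(81, 81, 0.025)          # 2 cm x 2 cm sheet
protocol = protocol_paced(geom, [0.0, 1.0, 0.0], radius=0.15, onset=2.0)
record = run_monodomain(geom, TissueParams(duration=90.0), protocol, "nygren")

array = place_uniform_array(geom, [1.0, 1.0, 0.0])  # 6x6 contact array
egms = compute_electrograms(record, array)
acts = detect_activations(egms.phi_e[0], DetectorParams(alpha=1.0,
                                                        polarity="negative"))
```

Runnable walk-throughs live in `examples/`:

- `01_paced_beat_electrograms.py` — paced beat, electrogram synthesis, and
  electrogram-vs-Vm activation-time agreement (prints 0.000 ms average RMS).
- `02_figure_of_eight_reentry.py` — S1–S2 induction of figure-of-eight
  reentry, phase-singularity tracking, R+/R− source clustering (~2 min).
- `03_blinded_evaluation.py` — the full blinded administrator/user protocol
  ending in an AcTPM/AcPPM report and tolerance sweep.

## Command-line interface

The `mapeval` entry point drives the same workflow from the shell:

```
mapeval simulate            run one simulation config and persist the entry
mapeval library             build / list / inspect a simulation library
mapeval export-surface      blinded surface point cloud for one entry
mapeval register-electrodes register the user electrode table and noise level
mapeval issue-egms          issue blinded noisy electrograms
mapeval evaluate            score user predictions, write the JSON report
mapeval sweep-tol           AcTPM / %spurious / RMS-SD vs. matching tolerance
```

## Verification

Run the test suite (~6 min; builds a small simulation library once per
session):

```sh
python -m pytest -o addopts= -p no:cacheprovider -q tests/
```

Reproduce the acceptance targets:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

Measured values:

| target | quantity | value |
|---|---|---|
| t1 | plane-wave conduction velocity | 55.6 cm/s (target 55 ± 10%) |
| t2 | electrogram-vs-Vm activation-time RMS, 36 electrodes | 0.000 ms (< 1 ms) |
| t3–t6 | AcPPM for 4/6, 5/6, 2/6, 1/6 correct beats | 67, 83, 33, 17 |

## Documentation

`docs/methods.md` describes the numerical methods, detector and classifier
parameters, metric definitions, conventions (chirality, noise seeding), and
known limitations.
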