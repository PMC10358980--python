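# Methods

This document records the numerical methods, default parameters, and
conventions implemented in `mapeval`. All lengths are in cm, times in ms,
potentials in mV, and conductivities in mS/cm unless stated otherwise.

## 1. Tissue geometry

`mapeval.geometry` builds triangulated surfaces:

- **Sheets** — regular nx × ny node grids with two triangles per cell;
  `build_sheet_geometry(81, 81, 0.025)` is the standard 2 cm × 2 cm sheet.
- **Spherical shells** — subdivided icosahedra projected to radius R with
  outward normals (verified against the Euler characteristic and area 4πR²).
- **Tetrahedral meshes** — supported by the FEM assembly for volumetric
  problems; surface extraction yields the boundary triangulation.

Electrode containers (`ElectrodeArray`) carry labels, 3-D positions, a grid
shape when the array is regular, and for each electrode the nearest tissue
surface node and its distance. `place_uniform_array` places a 6×6 grid with
0.4 cm pitch 0.05 cm above a sheet; `place_basket_array` wraps an 8×8
A1–H8 basket around a shell.

## 2. Monodomain simulation

`mapeval.simulator.run_monodomain` solves

  χ (Cm ∂Vm/∂t + I_ion(Vm, s)) = ∇·(σ ∇Vm)

with surface-to-volume ratio χ = 1400 cm⁻¹, membrane capacitance
Cm = 1 µF/cm², and isotropic conductivity σ. Discretization:

- linear P1 finite elements (stiffness K, lumped mass M) on the surface,
  scaled by an effective sheet thickness of 0.03 cm;
- operator splitting per step Δt = 0.1 ms: an explicit reaction update
  (Rush–Larsen for Hodgkin–Huxley gates) followed by backward-Euler
  diffusion, whose sparse system is factorized once and reused;
- states saved every 1 ms (1 kHz), matching clinical amplifier rates.

### Membrane models

- `"nygren"` — a 28-state human atrial action-potential model (resting
  potential ≈ −74 mV, overshoot > 0 mV, Rush–Larsen gate integration).
- `"twovar"` — a two-variable excitable surrogate (Aliev–Panfilov form),
  rescaled to mV and ms with a `time_scale` factor; `time_scale = 6.0`
  gives an action-potential duration of roughly 240 ms and sustains
  figure-of-eight reentry with a ~160 ms cycle length on a 4 cm sheet. It
  runs ~50× faster than the atrial model and is used for the reentry
  fixtures and most tests.

### Conduction-velocity calibration

The default conductivity is **σ = 3.7 mS/cm**, calibrated so that a plane
wave of the atrial model on the standard sheet propagates at 55 cm/s
(measured 55.6 cm/s between interior sites 1 cm apart). CV scales as √σ, a
property verified in the tests. `measure_cv` computes distance over
activation-time difference between two sites and validates propagation
direction.

### Stimulation protocols

`protocol_paced` (single onset in a radius around a point), `protocol_s1s2`
(cross-gradient S1 then delayed S2 in an overlapping region — the standard
reentry induction), and `protocol_focal` (repeated firing at a site with a
fixed interval). Stimulation is applied as a suprathreshold current for the
cell model's diastolic threshold.

## 3. Electrogram synthesis

Unipolar extracellular potentials use the infinite-volume-conductor lead
field

  φe(x) = (1 / 4π σe) ∫ −σi ∇Vm · ∇(1/‖x − y‖) dV(y)

with extracellular conductivity σe = 7 mS/cm, evaluated per element with
symmetric Gaussian quadrature (default order 2; higher orders refine by
subdivision and serve as a convergence oracle in the tests). The operator is
assembled once as a dense lead-field matrix L so that Φe = L · Vm for every
frame; it is linear, exact for the far-field dipole decay of a wavefront
source (amplitude ratio 4 per distance doubling), and rejects electrodes
placed on the tissue surface itself.

Additive noise is uniform in [−a, a] on the temporal derivative scale, where
`a` is the declared noise level in mV/ms; each electrode draws from an
independent substream of a seeded generator, so noise is reproducible and
scales exactly linearly with the level.

## 4. Activation detection

`detect_activations` marks activation times at the extremal temporal
derivative within super-threshold episodes of dV/dt:

- threshold α = 0.2 mV/ms on the **positive** derivative for Vm traces;
- threshold α = 1.0 mV/ms on the **negative** derivative for electrograms
  (steepest negative deflection);
- a greedy refractory constraint β = 100 ms suppresses secondary episodes;
- times are reported on the record's sample grid.

A brute-force reference detector in the tests checks the implementation on
randomized signals.

## 5. Phase mapping and reentry sources

The phase signal is a delay embedding,

  θ(t) = atan2(Vm(t + τ) + 30, Vm(t − τ) + 30), τ = 2 ms,

NaN-padded at the record boundaries. Phase singularities (PSs) are detected
per surface node by summing wrapped phase differences around the node's
one-ring, ordered counterclockwise as seen from the outward normal; a winding
of ±2π (tolerance π) marks a PS with topological charge ±1, and connected
same-charge nodes are de-duplicated. Border nodes with open rings are
skipped. `ps_density` accumulates PS occurrences per node over a time window.

`cluster_reentry_sources` runs k-means with k = 2 on the PS occurrence
locations and assigns chirality by mean charge: **the negative-charge cluster
is labelled R+ (clockwise as seen from the electrode side), the positive one
R− (counterclockwise)**. This sign convention follows from the outward-normal
orientation of the winding ring.

## 6. Pattern classification

`classify_pattern` inspects one beat on a 3×3 electrode neighbourhood, using
the centre electrode's activation time as reference:

- **F (focal/planar)** — all eight neighbour AcT differences lie in
  [−δ, γ + δ] with slack δ = 2 ms and window γ = 100 ms;
- **R+ / R− (reentry)** — the eight border electrodes, traversed clockwise
  (R+) or counterclockwise (R−) from some anchor, show a monotone AcT
  progression, allowing a wrap onto the next beat at each electrode; an
  exhaustive-path oracle in the tests certifies the greedy search;
- R takes precedence over F when both match.

`extract_patterns` applies the classifier per interior electrode and beat
over the full record.

## 7. Performance metrics

`compare_act` matches reported to true activation times per electrode by
maximum-cardinality, minimum-cost one-to-one assignment within a tolerance
Tol (linear sum assignment; match count is monotone in Tol). From the
fractions of correct (fC) and spurious (fS) detections:

  AcTPM = fC · (1 − fS) · 100.

Timing error is summarized as the average per-electrode RMS of matched
differences and its standard deviation (RMS-SD). `sweep_tolerance` reports
AcTPM, %spurious, and RMS-SD over a tolerance grid.

`compare_patterns` matches pattern detections of each type within 100 ms and
1 cm of a true event; with the misclassified fraction fM:

  AcPPM = fC · (1 − fS) · (1 − fM) · 100.

Paced/focal truth events are scored as F only; duplicates of an already
matched event are neither correct nor spurious; spurious detections are
attributed to the nearest-in-time event type. The published worked values —
AcPPM = 67, 83, 33, 17 for 4/6, 5/6, 2/6, 1/6 correct beats with no spurious
or misclassified detections — are reproduced exactly.

## 8. Blinded evaluation workflow

`build_standard_library` creates the reference entry set:

- **reentry-f8** — 4 cm × 4 cm sheet (81×81, 0.05 cm), two-variable model
  with `time_scale = 6.0`, σ = 0.8 mS/cm, S1 at (0, 2, 0) radius 0.5 cm, S2
  at (2, 1, 0) radius 1.0 cm delayed 350 ms, analysis window 1000–1998 ms;
  yields one paced beat plus six R+ and six R− reentrant beats from a stable
  figure-of-eight pair;
- a **focal** entry contributing six F+ and six F− beats,

for 25 ground-truth events total. `EvaluationSession` enforces the protocol
order (register electrodes → declare noise → issue electrograms → ingest
predictions → evaluate) and derives the per-entry noise seed as

  noise_seed = (master_seed · 1000003 + crc32(entry_id)) mod 2³¹,

so re-issued datasets are bit-identical while entries remain decorrelated.
Issued artifacts contain only electrode labels, times, signals, and the
declared noise level — never Vm, geometry, or seeds. Reports are validated
against `mapeval/schemas/report.schema.json`.

## 9. Limitations

- The volume conductor is infinite and homogeneous; no torso boundary or
  blood-pool inhomogeneity.
- Conductivity is isotropic; fiber anisotropy is not modelled.
- The surface FEM uses a constant effective thickness rather than a true
  bidomain or volumetric formulation.
- The two-variable surrogate reproduces wave dynamics, not ionic detail;
  restitution-driven phenomena need the atrial model.
- Pattern classification is limited to 3×3 neighbourhoods of regular grids;
  irregular catheter layouts are only supported through nearest-node
  projection.
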