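# Methods

This note describes the models and algorithms implemented in `mwdetect`, a
simulation study of microwave-based detection of intracranial bleeding.
The study question is whether the complex microwave transmission
coefficients measured between antennas of a helmet-like array around the
head carry enough information to separate patients with an intracranial
bleeding from healthy subjects, and how detection performance scales with
training-set size and measurement noise.

## Measurement model

A measurement is the complex transmission coefficient S_mn between every
unordered pair of 16 antennas (12 in a ring around the head, 4 on top),
sampled at 267 frequencies uniformly spanning 0.5–1.5 GHz. That is
16·15/2 = 120 pairs and 267 × 120 = 32 040 complex features per subject
(`records.antenna_pairs`, `records.default_frequency_grid`).

## Dielectric tissue models (`dielectric`)

Tissues are modeled as single-pole Debye media with a static-conductivity
term,

    eps(w) = eps_inf + (eps_s − eps_inf)/(1 + j w tau) + sigma/(j w eps0),

using the engineering convention e^{+jwt}, so lossy media have
Im(eps) ≤ 0. Literature tissue data are given as multi-pole Cole–Cole
models; `TissueLibrary` fits an equivalent Debye model to each tissue by
bounded least squares over the 0.5–1.5 GHz operating band
(`fit_debye`: modulus-of-difference cost, multi-start over relaxation
times of 1/10/100 ps to escape the shallow tau valley). The Debye form is
what the FDTD time stepping can integrate with a single auxiliary
differential equation per cell. Deionized water (the antenna-matching
medium) is a fixed Debye model with static permittivity 77.5.

## Head phantoms (`phantom`)

The reference head is a synthetic voxel phantom of nested ellipsoidal
shells — skin, fat, muscle, skull, CSF, grey matter — around a
white-matter core, with two ellipsoidal CSF ventricles, on a 1 mm grid.
Its three governing measures (ear-to-ear breadth, forehead-to-neck length,
top-to-below-eye height) define the outer ellipsoid.

A randomized subject is derived from the reference by:

1. **Bleeding insertion** (patients only). A sphere of blood is placed
   fully inside the cranial cavity (everything enclosed by the skull,
   found by binary hole-filling, so CSF, ventricles, grey and white matter
   are all admissible). The radius is drawn uniformly between the radii
   of the 0 and 105 mL spheres, which makes the induced volume density
   proportional to V^(−2/3): small bleedings dominate, making the
   detection task realistically hard. The upper radius is capped so the
   voxelized sphere never exceeds 105 mL. The center is uniform over
   cavity voxels whose distance to the cavity boundary is at least the
   radius.
2. **Anthropometric rescaling.** Per-gender (p1, p50, p99) percentiles of
   the three head measures are combined into an all-adult population by
   the rule (female p1, mean of medians, male p99); each subject's
   measures are drawn from independent truncated normals matching the
   combined percentiles, and the phantom is resampled
   (nearest-neighbor) by the target/original ratios per axis.
3. **Hair layer.** A uniformly drawn 0–4 mm hair shell is grown outward
   from the skin surface by iterated binary dilation.

Every transform appends a provenance record to the phantom.

## Forward solver (`fdtd`)

Transmission spectra are computed with a 3D Yee-grid FDTD solver:

- **Media.** Dispersive Debye media enter through an auxiliary
  differential equation (ADE) for the polarization current, one update per
  E component per cell; the update coefficients are exact discretizations
  of the single-pole kernel. Static conductivity is handled
  semi-implicitly in the E update.
- **Boundaries.** Convolutional PML (CPML) on all faces, graded
  polynomially and matched to the dominant background medium.
- **Antennas.** Center-fed thin-wire dipoles: arm cells are perfect
  conductors, and the feed edge carries a resistive voltage source (50 Ω)
  injected curl-consistently into the E update — the same load acts as the
  matched termination on receiving ports. Port voltage is −E·dx at the
  feed. Each antenna sits in an elliptic-cylinder bolus of deionized
  water that couples it to the head.
- **Time step** is 0.98 of the 3D CFL limit; runs stop after a fixed step
  count or when trailing port energy has decayed 50 dB below its peak.
  The spectra at the 267 operating frequencies are extracted by direct
  DFT of the port voltages, and S_mn is the ratio to the incident-wave
  spectrum obtained from a calibration run in homogeneous water.
- The inner loops are numba-compiled; a full 16-antenna head scene is
  nevertheless expensive, which motivates the surrogate below for
  cohort-scale statistics.

The solver is verified against physics oracles rather than reference
snapshots: free-space arrival delay within one time step of distance/c
(differencing two receivers on 1/r-compensated traces with a common
threshold, which cancels the source rise time), reciprocity of the
transmission matrix to 1e−6, and plane-wave attenuation in a lossy medium
within 10% of the closed-form attenuation constant.

## Measurement noise (`noise`)

Instrument noise is applied per frequency/pair sample as independent
complex Gaussian perturbations scaled by the noise floor: sigma =
10^(nf/20) for a noise floor of nf dB. The study conditions use
nf = −100 dB (laboratory-grade) and −70 dB (degraded).

## Classifier (`classifier`)

The detector is an SVD subspace classifier on the raw complex feature
vectors (no centering or normalization). For each class, the leading d
left singular vectors of the training matrix span a class subspace; a test
vector x is scored by the Euclidean norm of its projection residual
‖x − U Uᴴ x‖, and the decision value is the bleeding-distance minus the
healthy-distance (negative favors bleeding). Residuals for every
truncation d of one fitted basis are obtained from a single SVD via the
cumulative captured energy, which makes the dimension sweep in
cross-validation cheap.

## Evaluation (`evaluation`)

- **ROC/AUC.** The ROC is swept over all decision thresholds; its area
  equals the Mann–Whitney U statistic (probability that a random
  bleeding case scores more bleeding-like than a random healthy case,
  ties counted half), and both are implemented and cross-checked.
- **Nested cross-validation.** Stratified 10-fold outer CV; within each
  outer training set, a stratified 10-fold inner CV selects the subspace
  dimension from a default grid (ties resolved toward the smallest
  dimension; infeasible dimensions are skipped with a warning). Outer
  decision values are pooled into one ROC.
- **Learning curve.** For each subset size n, stratified random subsets
  (n/2 per class) are drawn repeatedly from the pool and evaluated with
  nested CV. The repetition AUCs at each size are tested against chance
  with a one-sample, one-tailed t-test of the mean against 0.5, preceded
  by an Anderson–Darling normality check.

## Surrogate cohorts (`surrogate`)

Cohort-scale statistics (hundreds of subjects) are out of reach for the
full FDTD pipeline, so a statistically matched surrogate generator
produces transmission-like records directly: healthy records are a shared
mean spectrum plus a low-rank background of anatomical variability plus
VNA noise at the configured floor; patient records additionally carry a
bleeding signature whose amplitude scales with the lesion volume drawn
from the same V^(−2/3) law as the voxel sampler. Its defaults are the
study conditions (1000 subjects, 267 × 120 features, −100 dB floor,
0–105 mL volumes); a reduced "toy" feature size (20 × 6) supports fast
statistical experiments. The healthy half of a cohort is bit-identical
across effect amplitudes at a fixed seed, enabling paired comparisons.

`calibrate_effect` bisects the effect amplitude until the mean nested-CV
AUC over several independently seeded cohorts hits a target operating
point, so experiments can be run at a controlled difficulty instead of an
arbitrary effect size.

## Study orchestration (`experiment`, `cli`)

`ExperimentConfig` is a frozen, YAML-round-trippable configuration with a
content hash; `run_study` derives all stage seeds from one master seed via
`numpy.random.SeedSequence`, generates a cohort per noise floor, runs the
learning curve, and writes per-repeat and summary tables, figures, and a
provenance manifest (config hash, seeds, timings, package versions).
Reruns of the same configuration are byte-identical. The `mwdetect` CLI
exposes the pipeline stages (phantom, forward, cohort, noise, classify,
evaluate, study) as thin wrappers over the library.
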