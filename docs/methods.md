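# Methods

This note documents the models, defaults and design choices behind
`strokedti`, and what the synthetic phantoms do and do not establish about
real data.

## Phantom model

The generator emulates the structure of a unilateral rodent-stroke MRI
study rather than rodent anatomy. One animal is an ellipsoidal "brain"
(default semiaxes 4.6 × 4.3 × 5.2 mm) on the study acquisition grid —
64 × 64 × 16 voxels of 0.156 × 0.156 × 0.75 mm — containing:

- a straight cylindrical white-matter bundle (radius 0.9 mm) running
  left–right through both hemispheres, with coherent prolate tensors;
- two mirrored ellipsoidal lateral ventricles (CSF) whose volume may scale
  up over time (hydrocephalus ex vacuo after infarction);
- a spherical lesion confined to the right hemisphere whose radius shrinks
  from day 1 to week 5, consistent with acute edema resolving.

All shapes are evaluated on voxel-center offsets from the grid midplanes,
and the midsagittal plane is a voxel boundary (even first dimension), so a
lesion-free phantom is *bit-exactly* mirror symmetric under an index flip.
This is what makes the null tests sharp: with no lesion and no noise, every
ipsilesional/contralesional quantity is exactly 1, not approximately.

Simple closed-form shapes were chosen deliberately: sphere, shell and
ellipsoid volumes have analytic values, so volumetry and ROI construction
are tested against arithmetic, not against the code's own output.

**Diffusivities and T2 intensities.** The study tabulates neither, so
defaults are literature-typical for rodent brain and config-exposed, not
claims about any particular dataset: white matter λ = (1.7, 0.3, 0.3)×10⁻³
mm²/s (FA ≈ 0.80), gray matter isotropic 0.8×10⁻³ (FA = 0 exactly, which
makes sub-threshold tracking tests clean), CSF 3.0×10⁻³. T2-weighted
means (arbitrary units): gray 100 ± 5, white 95 ± 5, CSF 180 ± 6, lesion
130 ± 5 — the lesion sits 6 SD above gray so the mean + 2·SD rule detects
it with probability ≈ Φ(4), while leaving a measurable ~2.3% false-positive
tail on normal tissue for calibration tests.

**Signal and noise.** DWI follows the monoexponential tensor model
`S = S0·exp(−b gᵀDg)` with the acquisition's 1 b=0 + 30 directions at
b = 1000 s/mm² (directions from a deterministic golden-spiral half-sphere).
Noise is Rician — `sqrt((S+n₁)² + n₂²)`, `n ~ N(0, σ²)` — the physical
model for magnitude MRI, with σ = (white-matter b0 signal)/SNR and default
SNR 30. There is no pulse-sequence physics beyond this, no partial-volume
mixing, and no motion or eddy artifacts (phantoms are motion-free, so the
preprocessing a real study would run before this pipeline is out of scope).

**Lesion microstructure.** Inside the lesion all eigenvalues of the
underlying tissue are scaled by a per-timepoint factor (default 0.6 → 0.75
→ 0.9, acute diffusion restriction relaxing over weeks). Uniform scaling
moves AD/RD/MD but leaves FA invariant — a deliberate property used by a
discriminating test that each relative metric reads its own map.

**Cohort effects.** Three arms (PBS-only, FBS-hMSCs, SS-hMSCs) with
planted week-5 severity ordering SS < FBS < PBS on lesion radius,
ventricular enlargement and mNSS; all arms start alike on day 1. Default
trajectories: lesion radius (2.0, 1.6, 1.3), (2.0, 1.4, 1.0),
(2.0, 1.2, 0.8) mm; mNSS means (12, 10.5, 9.5), (12, 9, 7.5),
(12, 7.5, 5.5) with SD 1.2 — magnitudes chosen to resemble a moderate
tMCAo cohort where the treated-vs-control gap emerges over weeks. Per-animal
trajectories jitter around the group means and are monotonized (lesions
never regrow, ventricles never shrink). Item-level mNSS records are
allocated randomly across the rubric items under each subscale's bound, so
scoring always reproduces the drawn total. The enrollment ledger mirrors
the published exclusion structure (45 randomized; 4 early deaths, 4
without deficits, 2 subarachnoid hemorrhages; 35 analyzed).

## Analysis stages: numerical choices

**Tensor fit.** Log-linear OLS on the 7-column design — the default
behavior of the standard DTI toolboxes and fully specified; weighted or
nonlinear fits are a possible extension, not implemented. Signals are
floored at `1e-6 × S0̂` before the log so Rician noise cannot produce
−∞. A rank check on the design rejects collinear schemes with an explicit
message. Negative fitted eigenvalues are clamped to 0 for the scalar maps
(preserving FA ∈ [0, 1]) but retained raw with a per-voxel flag.
Eigenvector sign is fixed (first non-zero component positive) so outputs
are deterministic.

**Tracking.** Fixed-step Euler (default step = half the smallest voxel
dimension), bidirectional from each seed with the halves merged; stopping
at FA < 0.15, turning angle > 45° between consecutive steps, volume exit,
or the step cap. The eigenvector is looked up nearest-neighbor — averaging
eigenvectors across voxels is sign-ambiguous — while FA is interpolated
trilinearly so the FA stop acts smoothly. Streamlines shorter than two
voxel widths are discarded as stubs. One seed per voxel at the voxel
center by default; extra seeds use seeded uniform jitter. FD is normalized
by seed-voxel count, which keeps values comparable across seeding choices.
Seeding is ROI-based (the analysis ROI ipsilesionally, its mirror
contralesionally), which makes the rFD numerator and denominator
structurally symmetric; whole-brain seeding with ROI filtering is a
different convention and would change absolute FD values.

**Segmentation.** "T2 value" is read as T2-weighted signal intensity (the
acquisition a study like this reports is single-TE, so no T2 mapping is
possible). The contralateral reference excludes the ventricle prior —
including CSF would inflate the threshold; the exclusion is configurable.
Segmentation runs in 3-D over the slab; ventricle delineation is
prior-guided thresholding because manual atlas tracing is not algorithmic
(the prior is ground truth in phantoms, user-supplied for real data).

**ROI metrics.** The recovery ROI is defined once from the day-1 and
5-week lesion masks and applied to all timepoints without registration —
this assumes cross-session voxel correspondence, which holds exactly for
phantoms and is a documented usage requirement for real data. The ROI
aggregate is the mean (median behind a flag). The mirror requires an even
left–right dimension; real data would need midline alignment first.

**Statistics.** Gaussian identity-link GEE with subjects as clusters;
working correlation exchangeable by default (independence available). The
covariance default is the Mancl–DeRouen bias-reduced sandwich: the plain
robust sandwich is markedly anti-conservative at animal-study cluster
counts (measured type-I error ~0.25 at 6 clusters/arm for the 4-df
interaction Wald test). Even bias-reduced, the Wald chi-square is an
asymptotic test, so the type-I calibration Monte-Carlo runs at 50
clusters/arm, where the measured rejection rate is ~0.05; small-cohort
gate p-values should be read as liberal. Tukey HSD uses
studentized-range quantiles (Tukey–Kramer SE for unequal n), reducing
exactly to the pooled t-test for two groups; quantiles come from the
numerically integrated range distribution and are verified against
published q-table entries. The post-hoc layer runs only when the GEE
interaction p < 0.05 (threshold in config, override flag available), and
no correction is applied across outcomes. Degenerate inputs (zero
within-group variance) are flagged with a warning rather than raising.

**mNSS.** The rubric's printed subscale bounds are 3 (tail raise) + 12
(sensory) + 6 (beam) = 21, while the composite is described as a 0–18
scale; the scorer returns the arithmetic sum and warns above 18 rather
than silently rescaling — the discrepancy is in the source rubric and
cannot be resolved from its text. The scorer consumes pre-judged item
values; it measures nothing.

## Problem sizes

Default grid 64 × 64 × 16 keeps one animal-timepoint (simulate, fit,
segment, track) under ~2 s and a full 18-animal three-timepoint cohort
around two minutes on one CPU. Monte-Carlo sizes: 1000 replicates for GEE
null calibration, 200 for the effect-ordering and family-wise-error
checks, 8–10 noise realizations for segmentation calibration — sizes at
which the binomial confidence bounds used by the tests are meaningful.

## What passing tests do and do not show

The phantoms establish internal correctness: round-trip parameter
recovery, exact null behavior under symmetry, threshold calibration
against Gaussian tails, analytic-volume agreement, and recovery of planted
group orderings through the full inference chain. They do not establish
performance on real rodent data — real brains have curved, crossing and
branching tracts (the single-tensor model is known to be unreliable in
crossing-fiber voxels), spatially varying coil sensitivity and noise,
imperfect midline symmetry, and inter-session motion, none of which the
generator emulates. Group-level DTI differences enter the phantom chiefly
through lesion geometry; the biological signal in which treated animals'
recovering tissue regains anisotropy faster is not planted, so tests
validate the measurement chain, not that effect's magnitude.
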