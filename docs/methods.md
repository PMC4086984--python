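# Methods

## The correction model

Knee joint motion is expressed as intrinsic Cardan rotations about the
femoral mediolateral (flexion/extension, α), anterior (ab/adduction, β)
and longitudinal (axial rotation, γ) axes — coordinate sequence Y–X–Z
in this package's frame mapping. The method rests on one anatomical
constraint: the healthy knee articulates essentially about a single
dominant axis, and physiological frontal-plane motion is small (≲ 7°
range) and uncoupled from flexion. Any strong flexion–ab/adduction
correlation is therefore interpreted as measurement artifact — a
malrotated joint coordinate system — rather than physiology.

Per subject and side, the n time-normalized cycles are stacked into an
(n·101)×3 matrix. Its 3×3 covariance is eigendecomposed; eigenvalues
are sorted descending and reported with variance fractions
δ_j = λ_j/Σλ. The transfer matrix P holds the eigenvectors as columns,
with

* **column assignment**: of the 6 permutations, the one maximizing
  Σ|P_ii| is chosen by exhaustive enumeration, so each principal axis
  is paired with the anatomical channel it is most collinear with.
  Score ties below 1e-12 resolve to the lexicographically smallest
  permutation (logged); ties only arise on contrived input, since gait
  data always has dominant flexion variance.
* **sign fix**: columns are negated until diag(P) ≥ 0, so corrected
  flexion increases with raw flexion.

Corrected angles are Pᵀx applied to **uncentered** triples. Centering
is used only inside the covariance; offsets must pass through P so that
a fixed varus/valgus deformity survives correction and the same P can
be transferred to the static posture trial. The covariance divisor is
1/(n−1) by default (`ddof` configurable); the divisor affects neither
the eigenvectors nor δ_j.

Two subject-level guarantees follow algebraically and are enforced as
tests: the corrected stacked channels are exactly uncorrelated, and the
total centered variance is invariant (orthonormal transform). Note the
zero-correlation guarantee concerns the *stacked samples*; the
correlation between corrected *mean profiles* is exactly zero only when
cycles are identical (no stride-to-stride noise), and otherwise of
order noise²/√n — both modes are available in the evaluation metrics
(`r2_mode="profile"` default, `"stacked"` for the algebraic quantity).

## What the synthetic generator emulates

`SyntheticConfig` defaults define the simulated study:

| parameter | default | rationale |
|---|---|---|
| flexion waveform | baseline 5° + periodic bumps: stance 12° at 12 % (width 25), swing 55° at 72 % (width 10) | double-bump shape with stance peak ≈ 17°, swing peak ≈ 60°, inside the physiological 50–70° band |
| ab/adduction | offset (deformity, default 0) + 1.5°·sin(4πt+0.8) | biphasic frontal wobble, 3° range, well below the ≈ 7° physiological bound; deliberately near-uncorrelated with flexion |
| axial rotation | 5° offset + 4°·sin(2πt+2.0) + 0.1·(flexion−mean) | transverse-plane offset and flexion coupling are physiologic; the 4° amplitude separates the two minor principal variances so the 2nd/3rd axes are identifiable (near-equal minor variances make the eigenplane degenerate) |
| stride noise | SD 1°/channel, Gaussian low-pass filtered (σ = 5 samples, periodic) | smooth stride-to-stride variability rather than white noise |
| misalignment | rotation about the femoral **longitudinal** axis; per-side magnitude uniform [8°, 15°] (cohort) or fixed 10° (patient experiments) | a malrotated thigh/knee marker tilts the flexion axis in the transverse plane, converting flexion into spurious ab/adduction — the classic cross-talk mechanism; axis and magnitude configurable |
| posture trial | (10°, deformity, 5°) through the same misalignment | standing radiological position with a mild flexion contracture; noise-free (static trials are averaged over many frames) |
| cohort | 20 subjects × 2 sides × 40 cycles | cohort size of a typical validation study; ≈ 40 cycles per side is a realistic session yield |

Observed angles are the Cardan decomposition of M·R·Mᵀ, where R is the
true joint rotation and M the misalignment: a misplaced lateral knee
marker enters the construction of femoral *and* tibial frames, so both
are rotated together. This conjugation acts on rotation vectors as an
exact orthogonal map, which is precisely the error structure a linear
orthonormal Pᵀ can invert; rotating only the proximal frame
(`apply_misalignment(..., frame="proximal")`, also available) injects
Euler-angle offsets that no post-hoc orthonormal transform can remove.

What the generator does **not** emulate: soft-tissue artifact,
marker-level trajectories, time-warping between strides, asymmetric
left/right waveforms, and any true flexion-coupled frontal-plane
motion. Passing tests therefore show that the estimator inverts the
modelled misalignment mechanism under realistic amplitudes and noise —
not that every clinical cross-talk pattern is removable; in real data,
genuine flexion-coupled varus/valgus (e.g. some pathologies) would be
removed along with the artifact, a known limitation of
correlation-based corrections.

## Preprocessing

Raw angle streams are cleaned per the usual laboratory rules: interior
missing runs of ≤ 9 frames are filled by a not-a-knot cubic spline
through the valid samples (exact on cubic polynomials); runs of ≥ 10
frames — and runs touching the stream boundary — stay missing, and any
stride containing them is rejected with a logged reason. Smoothing uses
a cubic smoothing spline with penalty chosen by generalized
cross-validation (`roughness=None`), or a fixed penalty (0 = identity).
Heel strikes are local maxima of the heel−sacrum anterior-posterior
distance, toe-offs local minima of toe−sacrum; strides are resampled to
101 points by cubic splines over normalized time (idempotent on the
grid).

## Numerical choices

* Gimbal tolerance: decomposition raises a typed error when the middle
  Cardan angle is within 1e-6 rad of ±90°; the knee's physiological
  band never approaches this.
* Orthonormality checks at 1e-9; covariance symmetrized before
  eigendecomposition (`(C+Cᵀ)/2`); eigenvalues clipped at 0.
* Rank guard: fitting raises a typed error when the second eigenvalue
  falls below 1e-10 × trace — fewer than two channels carrying variance
  leave nothing to correct.
* Repeated-eigenvalue flag at gaps < 1e-10 × trace (principal axes not
  unique); correction still proceeds with the tie-broken assignment.
* Determinism: all randomness flows from `numpy` SeedSequences derived
  from `(seed, subject index, side)`, so cohorts are bit-identical
  across runs and machines.

## Problem sizes in tests and the acceptance script

The default cohort (20 × 2 × 40 cycles) is used wherever a criterion
concerns the cohort; the seed-robustness check of pre-correction
cross-talk averages 20 cohorts re-generated at 10 cycles per side,
since the mean-profile correlation is insensitive to cycle count; the
noise-free checks use 2–3 cycles because identical cycles add no
information. The eigenvalue cross-check runs 1000 random PSD matrices
against the closed-form characteristic-cubic roots.

## Open design points, resolved

* The Cardan sequence is not uniquely fixed by the marker-model
  description; the standard gait order (flexion → ab/adduction → axial
  rotation) is the default and the `SequenceConvention` object makes it
  swappable.
* The posture triple is passed through P raw, with no re-referencing to
  the gait mean — required for deformity offsets to be preserved, and
  consistent with corrected posture angles changing sign under
  correction.
* Left and right sides never share a P: the misalignment is a per-side
  marker-placement error.
* Group tables report profile SD in degrees alongside variance in
  degrees²: published variability values for flexion (≈ 16–17) are only
  compatible with a 60° range of motion on the SD scale.
* SD over subjects uses 1/(n−1); with a single subject it is reported
  as 0 and flagged undefined.
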