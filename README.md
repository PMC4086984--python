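# kneepca

PCA-based post-hoc correction of kinematic **cross-talk** in knee joint
Euler angles, for gait analysts and biomechanics researchers.

In 3-D gait analysis the knee is described by three sequential (Cardan)
rotations: flexion/extension (α), ab/adduction (β, varus/valgus) and
axial rotation (γ). The segment coordinate systems behind these angles
are built from palpated skin markers, and small marker-placement errors
tilt the flexion axis. Because the knee moves overwhelmingly about that
one axis, the tilt leaks the large flexion waveform into the small
frontal- and transverse-plane channels — spurious, flexion-correlated
ab/adduction and rotation known as cross-talk.

## Method

For one subject and side, all *n* time-normalized gait cycles are
stacked into an (n·101)×3 matrix **X** of angle triples. The correction

1. computes the covariance **C** of the three angle channels and its
   eigendecomposition **C** w<sub>j</sub> = λ<sub>j</sub> w<sub>j</sub>,
   with variance fractions δ<sub>j</sub> = λ<sub>j</sub> / Σλ;
2. assembles the eigenvectors into an orthonormal **transfer matrix P**,
   permuting its columns so the sum of absolute diagonal entries is
   maximal and flipping signs so the diagonal is non-negative — each
   principal axis is thereby matched to the anatomical channel it most
   resembles;
3. re-expresses every *uncentered* angle triple in the principal basis,
   (ψ, ξ, ρ)ᵀ = **P**ᵀ (α, β, γ)ᵀ, giving corrected flexion ψ,
   ab/adduction ξ and rotation ρ whose pairwise correlations over the
   stacked samples vanish by construction.

Because offsets pass through **P**, the same matrix transfers to a
static posture trial, where the corrected varus/valgus angle can be
compared with a radiographic deformity measurement.

The core is the scikit-learn style transformer
`kneepca.CrosstalkCorrector` (`fit` on stacked samples, `transform` any
angle triples); `correct_subject` wraps it per subject/side. A seeded
synthetic-gait generator (`kneepca.simulate`) provides ground-truth
data: realistic flexion/abduction/rotation waveforms, smooth
stride-to-stride noise, and cross-talk injected by a known rigid
malrotation of the joint coordinate system, so the whole method is
verifiable without any motion-capture recording.

## Worked example

```python
import numpy as np
from kneepca import (SyntheticConfig, generate_subject,
                     correct_subject, evaluate_subject)

# an osteoarthritis-style subject: +5 deg varus deformity observed
# through a 10 deg misaligned coordinate system
cfg = SyntheticConfig(misalignment_range=None, misalignment_deg=10.0,
                      abduction_offset=5.0, seed=0)
subject, truth = generate_subject(cfg, index=0, side="right")
result = correct_subject(subject)
metrics = evaluate_subject(subject, result, truth=truth.deformity)

print(f"cross-talk r2   before: {metrics.r2_before:.3f}   after: {metrics.r2_after:.2e}")
print(f"abduction SD    before: {np.sqrt(metrics.delta2_abd_before):.2f} deg"
      f"  after: {np.sqrt(metrics.delta2_abd_after):.2f} deg")
print(f"posture varus   raw: {metrics.posture_before:+.2f} deg"
      f"  corrected: {metrics.posture_after:+.2f} deg  (x-ray truth {truth.deformity:+.1f} deg)")
print("transfer matrix P:")
print(np.round(result.transfer.P, 3))
```

prints

```text
cross-talk r2   before: 0.802   after: 1.23e-05
abduction SD    before: 2.69 deg  after: 1.18 deg
posture varus   raw: +3.20 deg  corrected: +5.11 deg  (x-ray truth +5.0 deg)
transfer matrix P:
[[ 0.985  0.163 -0.062]
 [-0.165  0.986 -0.035]
 [ 0.055  0.044  0.997]]
```

Before correction, 80 % of the ab/adduction profile variance is
explained by flexion (r² = 0.80) and the standing varus angle is biased
by 1.8°; after re-expressing the angles in the principal basis the
coupling is annihilated, the frontal-plane variability shrinks to its
physiological level, and the posture-trial varus angle lands within
0.11° of the ground-truth deformity. `P` is close to the (transposed)
misalignment rotation the generator injected.

A command-line pipeline chains the stages on CSV/JSON datasets:

```bash
kneepca pipeline --seed 1 --out run/
# or stage by stage: kneepca simulate / correct / evaluate / report
```

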