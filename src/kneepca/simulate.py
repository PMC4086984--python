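"""Seeded synthetic gait-kinematics generator with known ground truth.

Emulates per-subject knee Cardan-angle recordings with the features
that matter for validating the cross-talk correction:

* a dominant double-bump flexion/extension waveform (stance peak around
  15-17 deg, swing peak around 60 deg);
* physiologically small ab/adduction (oscillation bounded well below
  7 deg peak-to-peak) plus an optional fixed varus/valgus deformity;
* axial rotation with a constant offset, an oscillation larger than the
  frontal-plane one, and an optional flexion-coupled term;
* smooth, seeded stride-to-stride noise (spline-like low-pass filtered
  Gaussian perturbations rather than white noise);
* cross-talk injected by a known rigid malrotation of the joint
  coordinate system, applied to both segment frames
  (``observed = M @ R @ M.T``), the effect of a misplaced lateral knee
  marker.

Every dataset carries its ground truth (true cycles, misalignment
matrix, deformity) so downstream modules are testable without any real
motion-capture recording.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .euler import (
    DEFAULT_CONVENTION,
    SequenceConvention,
    apply_misalignment,
    misalignment_about,
)
from .processing import AngleCycle, N_POINTS
from .correction import SubjectSide

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_true_cycle",
    "induce_crosstalk",
    "generate_subject",
    "generate_cohort",
]


def _bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    """Periodic unit bump: exp(width * (cos(2 pi (t - center)) - 1))."""
    return np.exp(width * (np.cos(2.0 * np.pi * (t - center)) - 1.0))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; defaults define the simulated study.

    Angles in degrees, cycle time in fractions of the gait cycle.
    ``abduction_offset`` is the fixed varus/valgus deformity (positive =
    varus).  Per-subject misalignment magnitudes are drawn uniformly
    from ``misalignment_range``; set it to ``None`` to use the fixed
    ``misalignment_deg`` for every subject (as for the osteoarthritis
    posture experiments).
    """

    n_subjects: int = 20
    n_cycles: int = 40
    sides: tuple[str, ...] = ("left", "right")
    # flexion/extension: baseline + stance and swing bumps
    flexion_baseline: float = 5.0
    stance_amplitude: float = 12.0
    stance_center: float = 0.12
    stance_width: float = 25.0
    swing_amplitude: float = 55.0
    swing_center: float = 0.72
    swing_width: float = 10.0
    # ab/adduction: deformity offset + small biphasic oscillation
    abduction_offset: float = 0.0
    abduction_amplitude: float = 1.5
    abduction_phase: float = 0.8
    abduction_bound: float = 7.0
    # axial rotation: offset + oscillation + flexion coupling
    rotation_offset: float = 5.0
    rotation_amplitude: float = 4.0
    rotation_phase: float = 2.0
    flexion_rotation_coupling: float = 0.1
    # coordinate-system misalignment
    misalignment_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    misalignment_deg: float = 10.0
    misalignment_range: tuple[float, float] | None = (8.0, 15.0)
    # stride-to-stride noise
    noise_sd: float = 1.0
    noise_smoothness: float = 5.0
    # static posture trial (radiological position)
    posture_flexion: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "stance_amplitude",
            "swing_amplitude",
            "abduction_amplitude",
            "rotation_amplitude",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.misalignment_deg) >= 45.0:
            raise ValueError("misalignment magnitude must stay below 45 deg")
        if self.misalignment_range is not None:
            lo, hi = self.misalignment_range
            if not (0 <= lo <= hi < 45):
                raise ValueError("misalignment_range must satisfy 0 <= lo <= hi < 45")
        if 2.0 * self.abduction_amplitude > self.abduction_bound:
            raise ValueError(
                "abduction oscillation range exceeds the physiological bound"
            )

    @property
    def posture_true(self) -> np.ndarray:
        """True static-posture triple (degrees)."""
        return np.array(
            [self.posture_flexion, self.abduction_offset, self.rotation_offset]
        )


@dataclass
class GroundTruth:
    """What the generator knows and an experimenter would not."""

    true_cycles: list[AngleCycle]
    misalignment: np.ndarray
    misalignment_deg: float
    deformity: float
    posture_true: np.ndarray


def true_waveforms(cfg: SyntheticConfig) -> np.ndarray:
    """Noise-free (101, 3) waveform defined by the configuration."""
    t = np.linspace(0.0, 1.0, N_POINTS)
    flex = (
        cfg.flexion_baseline
        + cfg.stance_amplitude * _bump(t, cfg.stance_center, cfg.stance_width)
        + cfg.swing_amplitude * _bump(t, cfg.swing_center, cfg.swing_width)
    )
    abd = cfg.abduction_offset + cfg.abduction_amplitude * np.sin(
        4.0 * np.pi * t + cfg.abduction_phase
    )
    rot = (
        cfg.rotation_offset
        + cfg.flexion_rotation_coupling * (flex - flex.mean())
        + cfg.rotation_amplitude * np.sin(2.0 * np.pi * t + cfg.rotation_phase)
    )
    return np.column_stack([flex, abd, rot])


def _smooth_noise(rng: np.random.Generator, cfg: SyntheticConfig) -> np.ndarray:
    """Low-pass filtered Gaussian perturbation, SD-calibrated per channel."""
    e = gaussian_filter1d(
        rng.standard_normal((N_POINTS, 3)),
        cfg.noise_smoothness,
        axis=0,
        mode="wrap",
    )
    sd = e.std(axis=0)
    sd[sd == 0] = 1.0
    return e * (cfg.noise_sd / sd)


def generate_true_cycle(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    side: str = "right",
    cycle_id: int = 0,
) -> AngleCycle:
    """One true (misalignment-free) gait cycle with seeded smooth noise."""
    samples = true_waveforms(cfg)
    if cfg.noise_sd > 0:
        samples = samples + _smooth_noise(rng, cfg)
    return AngleCycle(samples, side=side, cycle_id=cycle_id)


def induce_crosstalk(
    cycle: AngleCycle,
    mis: np.ndarray,
    conv: SequenceConvention = DEFAULT_CONVENTION,
) -> AngleCycle:
    """Observe a cycle through a malpositioned coordinate system.

    Samplewise misalignment of both segment frames; an identity
    misalignment is the identity map.
    """
    observed = apply_misalignment(cycle.samples, mis, conv, frame="both")
    return AngleCycle(observed, side=cycle.side, cycle_id=cycle.cycle_id)


def _subject_rng(cfg: SyntheticConfig, index: int, side: str) -> np.random.Generator:
    side_code = 0 if side == "left" else 1
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(cfg.seed, index, side_code))
    )


def generate_subject(
    cfg: SyntheticConfig,
    index: int = 0,
    side: str = "right",
    conv: SequenceConvention = DEFAULT_CONVENTION,
    rng: np.random.Generator | None = None,
) -> tuple[SubjectSide, GroundTruth]:
    """One subject/side: noisy true cycles observed through one fixed
    misalignment, plus the misaligned static posture trial.

    The misalignment magnitude is drawn from ``cfg.misalignment_range``
    (or fixed at ``cfg.misalignment_deg`` when the range is ``None``);
    its axis is ``cfg.misalignment_axis`` in the femoral frame.
    Reproducible: the per-subject stream derives from
    ``(cfg.seed, index, side)``.
    """
    if rng is None:
        rng = _subject_rng(cfg, index, side)
    if cfg.misalignment_range is None:
        theta = cfg.misalignment_deg
    else:
        theta = rng.uniform(*cfg.misalignment_range)
    mis = misalignment_about(np.array(cfg.misalignment_axis), theta)

    true_cycles = [
        generate_true_cycle(cfg, rng, side=side, cycle_id=k)
        for k in range(cfg.n_cycles)
    ]
    observed = [induce_crosstalk(c, mis, conv) for c in true_cycles]
    posture_true = cfg.posture_true
    posture_obs = apply_misalignment(posture_true, mis, conv, frame="both")

    subject = SubjectSide(
        subject=f"S{index:02d}",
        side=side,
        cycles=observed,
        posture=posture_obs,
    )
    truth = GroundTruth(
        true_cycles=true_cycles,
        misalignment=mis,
        misalignment_deg=float(theta),
        deformity=cfg.abduction_offset,
        posture_true=posture_true,
    )
    return subject, truth


def generate_cohort(
    cfg: SyntheticConfig,
    conv: SequenceConvention = DEFAULT_CONVENTION,
) -> list[tuple[SubjectSide, GroundTruth]]:
    """Independent subjects x sides, fully reproducible from the seed."""
    cohort: list[tuple[SubjectSide, GroundTruth]] = []
    for index in range(cfg.n_subjects):
        for side in cfg.sides:
            cohort.append(generate_subject(cfg, index, side, conv))
    return cohort
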