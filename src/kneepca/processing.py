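"""Raw-stream preprocessing: gap filling, smoothing, gait events,
stride segmentation and 101-point time normalization.

The pipeline mirrors standard motion-capture practice: cubic-spline
interpolation of short marker dropouts, smoothing-spline filtering,
coordinate-based gait-event detection from heel/toe/sacrum trajectories,
and per-stride resampling onto a 0-100 % grid of 101 equally spaced
points.  Strides containing gaps of ``max_gap + 1`` frames or more are
rejected rather than filled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline, make_smoothing_spline
from scipy.signal import find_peaks

from .exceptions import NoCompleteCycleError, UnusableTrialError

__all__ = [
    "RawTrial",
    "GaitEvents",
    "AngleCycle",
    "interpolate_gaps",
    "smooth",
    "detect_events",
    "segment_and_normalize",
    "normalize_segment",
    "N_POINTS",
]

logger = logging.getLogger(__name__)

#: Samples per time-normalized gait cycle (0..100 % inclusive).
N_POINTS = 101

#: Longest missing run (frames) that is still spline-filled; runs of
#: ``DEFAULT_MAX_GAP + 1`` or more frames stay missing and the stride is
#: later rejected.
DEFAULT_MAX_GAP = 9

COMPONENTS = ("flexion", "abduction", "rotation")


@dataclass
class AngleCycle:
    """One time-normalized gait cycle of knee Cardan angles.

    ``samples`` is a (101, 3) array in degrees with columns flexion,
    ab/adduction, axial rotation, indexed 0..100 % of the cycle.
    """

    samples: np.ndarray
    side: str = "right"
    cycle_id: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.shape != (N_POINTS, 3):
            raise ValueError(
                f"cycle must be ({N_POINTS}, 3), got {self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("cycle contains missing samples")

    def component(self, name: str) -> np.ndarray:
        """Return one angle channel by name or column index."""
        idx = COMPONENTS.index(name) if isinstance(name, str) else int(name)
        return self.samples[:, idx]


@dataclass
class RawTrial:
    """Frame-rate angle stream with optional event-marker tracks.

    ``angles`` is (T, 3) degrees with missing samples encoded as NaN;
    ``heel``/``toe``/``sacrum`` are anterior-posterior marker
    coordinates (mm) used for event detection.
    """

    sample_rate: float
    angles: np.ndarray
    heel: np.ndarray | None = None
    toe: np.ndarray | None = None
    sacrum: np.ndarray | None = None
    side: str = "right"

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 2 or self.angles.shape[1] != 3:
            raise ValueError("angles must be a (T, 3) array")
        if self.angles.shape[0] < 2:
            raise ValueError("trial must hold at least 2 samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")


@dataclass
class GaitEvents:
    """Heel-strike and toe-off frame indices for one side."""

    heel_strikes: np.ndarray
    toe_offs: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=int)
        self.toe_offs = np.asarray(self.toe_offs, dtype=int)
        for name, ev in (("heel_strikes", self.heel_strikes),
                         ("toe_offs", self.toe_offs)):
            if ev.size > 1 and np.any(np.diff(ev) <= 0):
                raise ValueError(f"{name} must be strictly increasing")


def _missing_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of True in ``mask`` as (start, stop) slices."""
    runs: list[tuple[int, int]] = []
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    stops = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts, stops))


def _fill_channel(y: np.ndarray, max_gap: int) -> np.ndarray:
    """Spline-fill interior missing runs of length <= max_gap."""
    y = y.copy()
    missing = ~np.isfinite(y)
    if not missing.any():
        return y
    if missing.all():
        raise UnusableTrialError("channel is entirely missing")
    valid = np.flatnonzero(~missing)
    spline = CubicSpline(valid, y[valid])  # not-a-knot: exact on cubics
    for start, stop in _missing_runs(missing):
        if stop - start > max_gap:
            logger.info("gap of %d frames at %d left unfilled", stop - start, start)
            continue
        if start == 0 or stop == len(y):
            logger.info("edge gap at %d left unfilled (extrapolation)", start)
            continue
        idx = np.arange(start, stop)
        y[idx] = spline(idx)
    return y


def interpolate_gaps(trial: RawTrial, max_gap: int = DEFAULT_MAX_GAP) -> RawTrial:
    """Fill short missing runs in every angle channel by cubic splines.

    Runs of at most ``max_gap`` consecutive missing frames are filled
    from a cubic spline through the valid samples of that channel;
    longer runs (and runs touching the stream boundary) remain missing
    and are logged, so the strides containing them are rejected later.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    filled = np.column_stack(
        [_fill_channel(trial.angles[:, j], max_gap) for j in range(3)]
    )
    return replace(trial, angles=filled)


def smooth(trial: RawTrial, roughness: float | None = None) -> RawTrial:
    """Smoothing-spline filter of each angle channel.

    ``roughness`` is the spline penalty weight ``lam``; ``None`` selects
    it per channel by generalized cross-validation, ``0`` reproduces the
    input (interpolating limit).  Requires a gap-free stream.
    """
    if not np.all(np.isfinite(trial.angles)):
        raise UnusableTrialError("smoothing requires a gap-free stream")
    t = np.arange(trial.angles.shape[0], dtype=float)
    out = np.column_stack(
        [
            make_smoothing_spline(t, trial.angles[:, j], lam=roughness)(t)
            for j in range(3)
        ]
    )
    return replace(trial, angles=out)


def detect_events(trial: RawTrial) -> GaitEvents:
    """Coordinate-based gait events from heel/toe/sacrum trajectories.

    Heel strikes are the local maxima of the heel-sacrum
    anterior-posterior distance, toe offs the local minima of the
    toe-sacrum distance.  Plateau ties resolve to the earliest frame.

    Raises :class:`NoCompleteCycleError` with fewer than two heel
    strikes.
    """
    if trial.heel is None or trial.toe is None or trial.sacrum is None:
        raise UnusableTrialError("event detection needs heel, toe and sacrum tracks")
    heel_rel = np.asarray(trial.heel, dtype=float) - np.asarray(trial.sacrum, dtype=float)
    toe_rel = np.asarray(trial.toe, dtype=float) - np.asarray(trial.sacrum, dtype=float)
    hs, _ = find_peaks(heel_rel)
    to, _ = find_peaks(-toe_rel)
    if hs.size < 2:
        raise NoCompleteCycleError("fewer than two heel strikes detected")
    return GaitEvents(heel_strikes=hs, toe_offs=to)


def normalize_segment(segment: np.ndarray) -> np.ndarray:
    """Resample one stride to 101 equally spaced points per channel.

    Cubic-spline interpolation over normalized time; a segment already
    on the 101-point grid is reproduced exactly at the grid points.
    """
    segment = np.asarray(segment, dtype=float)
    n = segment.shape[0]
    if n < 2:
        raise ValueError("segment too short to resample")
    t = np.linspace(0.0, 1.0, n)
    tq = np.linspace(0.0, 1.0, N_POINTS)
    return np.column_stack(
        [CubicSpline(t, segment[:, j])(tq) for j in range(segment.shape[1])]
    )


def segment_and_normalize(
    trial: RawTrial,
    events: GaitEvents,
) -> list[AngleCycle]:
    """Cut heel-strike-to-heel-strike strides and time-normalize them.

    One :class:`AngleCycle` per consecutive heel-strike pair; strides
    still containing unfilled gaps are dropped with a logged reason, so
    strides in = cycles out + rejections.
    """
    hs = events.heel_strikes
    if hs.size < 2:
        raise NoCompleteCycleError("need at least two heel strikes")
    cycles: list[AngleCycle] = []
    for k, (a, b) in enumerate(zip(hs[:-1], hs[1:])):
        segment = trial.angles[a : b + 1]
        if not np.all(np.isfinite(segment)):
            logger.info("cycle %d rejected: unfilled gap between frames %d-%d", k, a, b)
            continue
        cycles.append(
            AngleCycle(normalize_segment(segment), side=trial.side, cycle_id=k)
        )
    return cycles
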