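"""Cardan-angle rotation algebra for the knee joint.

Knee motion is described by three sequential rotations (Cardan/Euler
angles) about anatomical axes: flexion/extension about the mediolateral
axis, ab/adduction (varus/valgus) about the anterior axis, and axial
(internal/external) rotation about the longitudinal axis.  The axes of
the femoral frame are mapped to coordinate axes as

=============  ====  ==========================
anatomical     axis  rotation carried
=============  ====  ==========================
mediolateral   Y     flexion/extension (alpha)
anterior       X     ab/adduction      (beta)
longitudinal   Z     axial rotation    (gamma)
=============  ====  ==========================

so the default Cardan sequence is intrinsic Y-X-Z.  All public
interfaces use degrees; radians appear only inside the trigonometric
kernels (delegated to :mod:`scipy.spatial.transform`).

A malpositioned joint coordinate system is modelled by composing a fixed
misalignment rotation with the true joint rotation before decomposing it
back into angles; this is the generative mechanism behind kinematic
cross-talk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Mapping, NamedTuple

import numpy as np
from scipy.spatial.transform import Rotation

from .exceptions import GimbalLockError

__all__ = [
    "CardanAngles",
    "SequenceConvention",
    "angles_to_rotation",
    "rotation_to_angles",
    "apply_misalignment",
    "misalignment_about",
    "check_rotation_matrix",
]

#: Tolerance for orthonormality / unit-determinant checks.
ORTHO_TOL = 1e-9

#: Distance (radians) from +/-90 deg below which the Cardan
#: decomposition of the middle angle is treated as gimbal-locked.
GIMBAL_TOL = 1e-6


class CardanAngles(NamedTuple):
    """One Cardan triple in degrees.

    ``abduction`` is signed so that positive means varus on either side
    (see :class:`SequenceConvention.abduction_sign`).
    """

    flexion: float
    abduction: float
    rotation: float


@dataclass(frozen=True)
class SequenceConvention:
    """Ordered Cardan sequence and per-side sign convention.

    Parameters
    ----------
    axes:
        scipy-style intrinsic rotation sequence; the three letters are
        the coordinate axes carrying flexion, ab/adduction and axial
        rotation, in that order.  Must be a permutation of ``X``, ``Y``
        and ``Z``.
    abduction_sign:
        Sign applied to the ab/adduction channel per side so that
        positive abduction always means varus.  The raw marker model
        directs the flexion axis towards the subject's left on both
        knees, so a side-dependent flip may be required for real
        recordings; synthetic data uses +1 on both sides.
    """

    axes: str = "YXZ"
    abduction_sign: Mapping[str, float] = field(
        default_factory=lambda: {"left": 1.0, "right": 1.0}
    )

    def __post_init__(self) -> None:
        if sorted(self.axes.upper()) != ["X", "Y", "Z"]:
            raise ValueError(
                f"axes must be a permutation of XYZ, got {self.axes!r}"
            )
        object.__setattr__(self, "axes", self.axes.upper())


DEFAULT_CONVENTION = SequenceConvention()


def check_rotation_matrix(R: np.ndarray, tol: float = ORTHO_TOL) -> np.ndarray:
    """Validate that ``R`` is a proper rotation matrix.

    Raises ``ValueError`` when ``R`` is not orthonormal with determinant
    +1 within ``tol``.
    """
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise ValueError(f"expected trailing shape (3, 3), got {R.shape}")
    err = np.max(np.abs(np.swapaxes(R, -1, -2) @ R - np.eye(3)))
    if err > tol:
        raise ValueError(f"matrix not orthonormal: ||R'R - I|| = {err:.3g}")
    if np.max(np.abs(np.linalg.det(R) - 1.0)) > tol:
        raise ValueError("matrix determinant differs from +1")
    return R


def angles_to_rotation(
    angles: CardanAngles | np.ndarray,
    conv: SequenceConvention = DEFAULT_CONVENTION,
) -> np.ndarray:
    """Compose the rotation matrix of one or more Cardan triples.

    ``angles`` is a length-3 triple or an ``(..., 3)`` array in degrees;
    the result has shape ``(..., 3, 3)`` and is the product of the three
    elementary rotations in the order of ``conv.axes`` (intrinsic).
    """
    a = np.asarray(angles, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError("expected a length-3 Cardan triple")
    if not np.all(np.isfinite(a)):
        raise ValueError("angles must be finite")
    return Rotation.from_euler(conv.axes, a, degrees=True).as_matrix()


def _middle_angle_margin(R: np.ndarray, conv: SequenceConvention) -> np.ndarray:
    """Radians separating the middle Cardan angle from +/-90 degrees."""
    mid = np.deg2rad(
        Rotation.from_matrix(R).as_euler(conv.axes, degrees=True)[..., 1]
    )
    return np.pi / 2 - np.abs(mid)


def rotation_to_angles(
    R: np.ndarray,
    conv: SequenceConvention = DEFAULT_CONVENTION,
) -> np.ndarray:
    """Decompose rotation matrices into Cardan triples (degrees).

    Inverse of :func:`angles_to_rotation` away from gimbal lock.

    Raises
    ------
    GimbalLockError
        When the middle angle lies within ``GIMBAL_TOL`` radians of
        +/-90 degrees, where the decomposition is not unique.  The
        physiological knee operates far from this band.
    """
    R = check_rotation_matrix(R)
    with warnings.catch_warnings():
        # scipy warns at gimbal lock; we raise a typed error below
        warnings.simplefilter("ignore", UserWarning)
        ang = Rotation.from_matrix(R).as_euler(conv.axes, degrees=True)
    margin = np.pi / 2 - np.abs(np.deg2rad(ang[..., 1]))
    if np.any(margin <= GIMBAL_TOL):
        raise GimbalLockError(
            "middle Cardan angle within tolerance of +/-90 degrees"
        )
    return ang


def misalignment_about(
    axis: np.ndarray | str,
    magnitude_deg: float,
) -> np.ndarray:
    """Rotation matrix for a coordinate-system misalignment.

    ``axis`` is a coordinate-axis letter (``"X"``/``"Y"``/``"Z"``) or an
    arbitrary 3-vector (normalized internally); ``magnitude_deg`` is the
    malrotation in degrees.
    """
    if isinstance(axis, str):
        return Rotation.from_euler(axis.upper(), magnitude_deg, degrees=True).as_matrix()
    v = np.asarray(axis, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("misalignment axis must be nonzero")
    return Rotation.from_rotvec(v / n * np.deg2rad(magnitude_deg)).as_matrix()


def apply_misalignment(
    true_angles: CardanAngles | np.ndarray,
    mis: np.ndarray,
    conv: SequenceConvention = DEFAULT_CONVENTION,
    frame: Literal["proximal", "both"] = "proximal",
) -> np.ndarray:
    """Cardan angles observed through a malpositioned coordinate system.

    Parameters
    ----------
    true_angles:
        True joint angles, triple or ``(..., 3)`` array, degrees.
    mis:
        3x3 misalignment rotation of the segment frame(s).
    frame:
        ``"proximal"`` rotates only the proximal (femoral) frame: the
        observed rotation matrix is ``mis @ R``.  ``"both"`` rotates
        both segment frames identically, ``mis @ R @ mis.T`` — the
        situation created by a misplaced lateral knee marker, which
        enters the construction of femoral and tibial frames alike.  In
        either case an identity misalignment is the identity map.

    Returns the Cardan decomposition of the composed rotation; gimbal
    degeneracy propagates as :class:`GimbalLockError`.
    """
    mis = check_rotation_matrix(mis)
    R = angles_to_rotation(true_angles, conv)
    if frame == "proximal":
        observed = mis @ R
    elif frame == "both":
        observed = mis @ R @ mis.T
    else:
        raise ValueError(f"unknown frame {frame!r}")
    return rotation_to_angles(observed, conv)
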