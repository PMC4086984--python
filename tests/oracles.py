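"""Independent closed-form oracles used by the test suite.

Deliberately hand-rolled and kept independent of the package's own code
paths (which delegate to scipy): elementary rotation matrices composed
term by term, and the trigonometric (Cardano) closed form for the
eigenvalues of a symmetric 3x3 matrix.
"""

import math

import numpy as np


def rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rot_y(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


_ELEMENTARY = {"X": rot_x, "Y": rot_y, "Z": rot_z}


def cardan_product(angles, axes: str = "YXZ") -> np.ndarray:
    """Intrinsic Cardan composition as an explicit elementary product."""
    R = np.eye(3)
    for axis, angle in zip(axes.upper(), angles):
        R = R @ _ELEMENTARY[axis](angle)
    return R


def symmetric_eigenvalues_closed_form(C: np.ndarray) -> np.ndarray:
    """Descending eigenvalues of a symmetric 3x3 matrix via the
    trigonometric solution of the characteristic cubic."""
    C = np.asarray(C, dtype=float)
    p1 = C[0, 1] ** 2 + C[0, 2] ** 2 + C[1, 2] ** 2
    q = np.trace(C) / 3.0
    if p1 == 0.0:
        return np.sort(np.diag(C))[::-1]
    p2 = (C[0, 0] - q) ** 2 + (C[1, 1] - q) ** 2 + (C[2, 2] - q) ** 2 + 2.0 * p1
    p = math.sqrt(p2 / 6.0)
    B = (C - q * np.eye(3)) / p
    r = np.linalg.det(B) / 2.0
    r = min(1.0, max(-1.0, r))
    phi = math.acos(r) / 3.0
    eig1 = q + 2.0 * p * math.cos(phi)
    eig3 = q + 2.0 * p * math.cos(phi + 2.0 * math.pi / 3.0)
    eig2 = 3.0 * q - eig1 - eig3
    return np.array([eig1, eig2, eig3])


def random_psd_3x3(rng: np.random.Generator) -> np.ndarray:
    A = rng.standard_normal((3, 3))
    return A @ A.T
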