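"""PCA realignment of knee Cardan angles — the cross-talk correction.

A malpositioned joint coordinate system mixes the dominant
flexion/extension motion into the ab/adduction and axial-rotation
channels.  Because that mixing is (to first order) a fixed rotation of
the angle triple, it can be undone post hoc: stack all gait cycles of
one subject/side into an ``(n*101, 3)`` matrix, diagonalize its
covariance, and re-express every angle triple in the principal basis.

The eigenvector columns are permuted so the diagonal of the transfer
matrix ``P`` is maximal and sign-flipped so every diagonal entry is
nonnegative; each principal component is then identified with one
anatomical angle (``psi`` corrected flexion, ``xi`` corrected
ab/adduction, ``rho`` corrected axial rotation).  Corrected angles are
``P.T @ x`` applied to the *uncentered* triples, so constant offsets —
in particular a fixed varus/valgus deformity — are carried through the
rotation, and the same ``P`` transfers to a static posture trial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import DegenerateCovarianceError
from .processing import AngleCycle, N_POINTS

__all__ = [
    "CrosstalkCorrector",
    "SubjectSide",
    "StackedObservations",
    "EigenResult",
    "TransferMatrix",
    "CorrectionResult",
    "stack_cycles",
    "covariance",
    "eigendecompose",
    "sort_eigenvectors",
    "apply_correction",
    "correct_subject",
    "transfer_to_posture",
]

logger = logging.getLogger(__name__)

#: Permutation scores closer than this are tied (lexicographic tie-break).
TIE_TOL = 1e-12

#: Eigenvalue gaps below this fraction of the trace are flagged degenerate.
DEGENERACY_TOL = 1e-10


# ---------------------------------------------------------------------------
# containers


@dataclass
class SubjectSide:
    """All gait cycles of one subject and side, plus optional posture.

    The unit on which a single PCA is fitted; left and right sides of
    one subject are corrected independently.
    """

    subject: str
    side: str
    cycles: list[AngleCycle]
    posture: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.cycles:
            raise ValueError("SubjectSide needs at least one cycle")
        if any(c.side != self.side for c in self.cycles):
            raise ValueError("all cycles must share the SubjectSide's side")
        if self.posture is not None:
            self.posture = np.asarray(self.posture, dtype=float).reshape(3)

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


@dataclass
class StackedObservations:
    """Row-stacked angle samples of one subject/side.

    ``X`` is ``(n*101, 3)`` degrees, columns flexion, ab/adduction,
    rotation; ``mean`` the per-column mean.
    """

    X: np.ndarray
    mean: np.ndarray


@dataclass
class EigenResult:
    """Eigendecomposition of the 3x3 angle covariance.

    ``eigenvalues`` descending (degrees^2), ``eigenvectors`` as unit
    columns, ``variance_ratio`` the per-axis variance fractions
    (eigenvalue over trace).  ``degenerate`` flags (near-)repeated
    eigenvalues or an all-zero covariance, where the principal axes are
    not unique.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    variance_ratio: np.ndarray
    degenerate: bool = False


@dataclass
class TransferMatrix:
    """Sorted, sign-fixed eigenvector basis.

    ``P`` columns are the eigenvectors after applying permutation
    ``permutation`` (column ``i`` of ``P`` is eigenvector
    ``permutation[i]``) and sign flips ``signs``; corrected angles are
    ``P.T @ x``.
    """

    P: np.ndarray
    permutation: tuple[int, int, int]
    signs: np.ndarray

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        err = np.max(np.abs(self.P.T @ self.P - np.eye(3)))
        if err > 1e-9:
            raise ValueError("transfer matrix is not orthonormal")
        if np.any(np.diag(self.P) < 0):
            raise ValueError("transfer matrix diagonal must be nonnegative")


@dataclass
class CorrectionResult:
    """Corrected cycles and fitted transform for one subject/side."""

    corrected_cycles: list[AngleCycle]
    transfer: TransferMatrix
    eigen: EigenResult
    corrected_posture: np.ndarray | None = None


# ---------------------------------------------------------------------------
# primitives


def stack_cycles(s: SubjectSide) -> StackedObservations:
    """Concatenate all cycles row-wise and record the column means."""
    X = np.vstack([c.samples for c in s.cycles])
    return StackedObservations(X=X, mean=X.mean(axis=0))


def covariance(obs: StackedObservations | np.ndarray, ddof: int = 1) -> np.ndarray:
    """Covariance of the mean-centered angle columns (degrees^2).

    ``ddof=1`` gives the unbiased estimator; the divisor does not affect
    eigenvectors or variance fractions.
    """
    X = obs.X if isinstance(obs, StackedObservations) else np.asarray(obs, float)
    if X.shape[0] < 2:
        raise ValueError("covariance needs at least two rows")
    C = np.cov(X, rowvar=False, ddof=ddof)
    return (C + C.T) / 2.0


def eigendecompose(C: np.ndarray, degeneracy_tol: float = DEGENERACY_TOL) -> EigenResult:
    """Eigenvalues/vectors of a symmetric PSD 3x3 matrix, descending.

    Variance fractions are eigenvalues over their sum; a zero trace
    (all-constant input) or a near-repeated eigenvalue pair is flagged
    degenerate.
    """
    C = np.asarray(C, dtype=float)
    if C.shape != (3, 3):
        raise ValueError("expected a 3x3 matrix")
    if np.max(np.abs(C - C.T)) > 1e-9:
        raise ValueError("covariance must be symmetric")
    lam, W = np.linalg.eigh(C)
    lam, W = lam[::-1], W[:, ::-1]
    lam = np.clip(lam, 0.0, None)
    total = lam.sum()
    if total <= 0.0:
        return EigenResult(lam, W, np.full(3, np.nan), degenerate=True)
    degenerate = bool(np.min(np.abs(np.diff(lam))) < degeneracy_tol * total)
    return EigenResult(lam, W, lam / total, degenerate=degenerate)


def sort_eigenvectors(eig: EigenResult, tie_tol: float = TIE_TOL) -> TransferMatrix:
    """Permute and sign-fix eigenvector columns into the transfer matrix.

    Among the 6 column permutations the one maximizing the sum of
    absolute diagonal entries wins, so each principal axis is assigned
    to the anatomical channel it most resembles; exact ties resolve to
    the lexicographically smallest permutation (logged).  Column signs
    are then flipped so every diagonal entry is nonnegative — corrected
    flexion increases with raw flexion.
    """
    W = eig.eigenvectors
    scored = [
        (sum(abs(W[i, p[i]]) for i in range(3)), p)
        for p in permutations(range(3))
    ]
    best_score = max(s for s, _ in scored)
    candidates = sorted(p for s, p in scored if best_score - s < tie_tol)
    if len(candidates) > 1:
        logger.info("permutation tie broken lexicographically: %s", candidates)
    perm = candidates[0]
    P = W[:, perm].copy()
    signs = np.where(np.diag(P) < 0, -1.0, 1.0)
    P *= signs
    return TransferMatrix(P=P, permutation=tuple(perm), signs=signs)


# ---------------------------------------------------------------------------
# estimator


class CrosstalkCorrector(TransformerMixin, BaseEstimator):
    """Remove kinematic cross-talk from Cardan angle triples by PCA.

    Fit on the stacked ``(n_samples, 3)`` angle observations of one
    subject/side (columns flexion, ab/adduction, axial rotation,
    degrees).  ``transform`` re-expresses raw, uncentered triples in the
    sorted principal basis, yielding corrected angles whose pairwise
    correlations over the training samples vanish.

    Parameters
    ----------
    ddof:
        Covariance divisor ``1/(n - ddof)``; irrelevant to the fitted
        axes, kept for reporting.
    tie_tol, degeneracy_tol:
        Tolerances for the permutation tie-break and the repeated-
        eigenvalue flag.

    Attributes
    ----------
    mean_ : (3,) column means of the training samples (degrees).
    covariance_ : (3, 3) angle covariance (degrees^2).
    eigenvalues_ : (3,) descending principal variances (degrees^2).
    variance_ratio_ : (3,) per-axis variance fractions.
    transfer_matrix_ : (3, 3) sorted, sign-fixed eigenvector basis P;
        corrected = X @ P.
    permutation_, signs_ : column bookkeeping of the sorting step.
    degenerate_ : True when the principal axes were not unique.

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> flex = 30 + 25 * np.sin(np.linspace(0, 2 * np.pi, 101))
    >>> X = np.column_stack([flex, 0.2 * flex, rng.normal(5, 2, 101)])
    >>> corr = CrosstalkCorrector().fit(X)
    >>> Xc = corr.transform(X)
    >>> abs(np.corrcoef(Xc[:, 0], Xc[:, 1])[0, 1]) < 1e-8
    True
    """

    def __init__(
        self,
        ddof: int = 1,
        tie_tol: float = TIE_TOL,
        degeneracy_tol: float = DEGENERACY_TOL,
    ) -> None:
        self.ddof = ddof
        self.tie_tol = tie_tol
        self.degeneracy_tol = degeneracy_tol

    def fit(self, X, y=None) -> "CrosstalkCorrector":
        """Fit principal angle axes on stacked observations ``X``."""
        X = check_array(X, dtype=float)
        if X.shape[1] != 3:
            raise ValueError("expected exactly 3 angle columns")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        self.mean_ = X.mean(axis=0)
        self.covariance_ = covariance(X, ddof=self.ddof)
        eig = eigendecompose(self.covariance_, self.degeneracy_tol)
        total = eig.eigenvalues.sum()
        if total <= 0.0 or eig.eigenvalues[1] <= self.degeneracy_tol * max(total, 1.0):
            raise DegenerateCovarianceError(
                "angle covariance has rank < 2; nothing to correct"
            )
        tm = sort_eigenvectors(eig, self.tie_tol)
        self.eigen_result_ = eig
        self.eigenvalues_ = eig.eigenvalues
        self.variance_ratio_ = eig.variance_ratio
        self.degenerate_ = eig.degenerate
        self.transfer_ = tm
        self.transfer_matrix_ = tm.P
        self.permutation_ = tm.permutation
        self.signs_ = tm.signs
        self.n_features_in_ = 3
        return self

    def transform(self, X) -> np.ndarray:
        """Corrected angles: each raw triple mapped through ``P.T``."""
        check_is_fitted(self, "transfer_matrix_")
        X = check_array(X, dtype=float)
        return X @ self.transfer_matrix_

    def inverse_transform(self, X) -> np.ndarray:
        """Map corrected angles back to the observational basis."""
        check_is_fitted(self, "transfer_matrix_")
        X = check_array(X, dtype=float)
        return X @ self.transfer_matrix_.T


# ---------------------------------------------------------------------------
# subject-level wrappers


def apply_correction(cycle: AngleCycle, tm: TransferMatrix) -> AngleCycle:
    """Correct one cycle: every uncentered sample mapped through P.T."""
    return AngleCycle(
        cycle.samples @ tm.P, side=cycle.side, cycle_id=cycle.cycle_id
    )


def transfer_to_posture(posture: np.ndarray, tm: TransferMatrix) -> np.ndarray:
    """Correct a static posture triple with the gait-fitted transform."""
    return np.asarray(posture, dtype=float).reshape(3) @ tm.P


def correct_subject(s: SubjectSide, ddof: int = 1) -> CorrectionResult:
    """Fit one transfer matrix per subject/side and correct everything.

    A single PCA is fitted on all stacked cycles; every cycle — and the
    posture trial, when present — is corrected with that one ``P``.

    Raises :class:`DegenerateCovarianceError` when fewer than two angle
    columns carry variance.
    """
    obs = stack_cycles(s)
    corr = CrosstalkCorrector(ddof=ddof).fit(obs.X)
    tm = corr.transfer_
    corrected = [apply_correction(c, tm) for c in s.cycles]
    posture = (
        transfer_to_posture(s.posture, tm) if s.posture is not None else None
    )
    return CorrectionResult(
        corrected_cycles=corrected,
        transfer=tm,
        eigen=corr.eigen_result_,
        corrected_posture=posture,
    )
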