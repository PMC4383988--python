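"""Rigid-body superposition and rotation analysis.

Least-squares (Kabsch) superposition of index-aligned Cα point sets,
sequence-based residue correspondence between homologous chains, and
axis/angle/fold decomposition of rotation matrices. These are the numeric
primitives behind symmetry-operation enumeration and point-group
classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

logger = logging.getLogger(__name__)

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x' = R @ x + t (column-vector convention, Å)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix has negative determinant (reflection)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class AxisAngle:
    """Rotation axis (unit vector, canonical sign), angle in [0, π], and fold.

    ``fold`` is the order of the rotation (smallest n ≥ 2 with angle close to
    a multiple of 2π/n), or ``None`` for the identity.
    """

    axis: np.ndarray
    angle: float
    fold: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "axis", np.asarray(self.axis, dtype=float).reshape(3))


def canonical_axis(axis: np.ndarray) -> np.ndarray:
    """Fix the sign of an axis direction: positive z, ties broken by y then x."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("zero axis")
    axis = axis / n
    for k in (2, 1, 0):
        if abs(axis[k]) > 1e-9:
            return axis if axis[k] > 0 else -axis
    return axis


def axis_angle_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation by ``angle`` about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(axis * angle).as_matrix()


def superpose_kabsch(
    moving: np.ndarray, fixed: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares optimal proper rigid transform mapping moving onto fixed.

    Parameters
    ----------
    moving, fixed
        Index-aligned (N, 3) coordinate arrays, N ≥ 3.

    Returns
    -------
    (RigidTransform, rmsd)
        rmsd = sqrt(mean ||R m_i + t − f_i||²) at the optimum. Reflections are
        disallowed: the determinant of the SVD solution is sign-corrected so
        the result is always a proper rotation.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape or moving.ndim != 2 or moving.shape[1] != 3:
        raise ValueError("point sets must be matching (N, 3) arrays")
    n = moving.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 points")

    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    m = moving - mc
    f = fixed - fc

    H = m.T @ f
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T

    # rank-deficient covariance: collinear/coplanar points leave a free axis
    if S[1] < 1e-9 * max(S[0], 1.0):
        logger.warning("degenerate (collinear) point set in superposition")

    t = fc - R @ mc
    diff = m @ R.T - f
    rmsd = float(np.sqrt((diff * diff).sum() / n))
    return RigidTransform(R, t), rmsd


def rotation_parameters(
    transform: RigidTransform | np.ndarray,
    angle_tol: float = 0.1,
    max_fold: int = 60,
) -> AxisAngle:
    """Decompose a rotation into canonical axis, angle in [0, π], and fold.

    The angle is arccos((trace(R) − 1) / 2); the axis is the +1 eigenvector of
    R with the sign convention of :func:`canonical_axis`. The fold is the
    smallest n in 2..max_fold whose grid 2πk/n contains the angle (i.e. the
    order of the rotation); identity → fold None. The per-fold tolerance is
    min(angle_tol, π/(n(n+1))) — capped at half the separation between the
    n- and (n+1)-fold grids, so neighboring folds never claim each other's
    angles no matter how loose ``angle_tol`` is.
    """
    R = transform.rotation if isinstance(transform, RigidTransform) else np.asarray(transform)
    angle = float(np.arccos(np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)))
    if angle <= angle_tol / 2:
        return AxisAngle(np.array([0.0, 0.0, 1.0]), 0.0, None)

    rotvec = Rotation.from_matrix(R).as_rotvec()
    axis = canonical_axis(rotvec)

    fold = None
    for n in range(2, max_fold + 1):
        k = round(angle * n / (2.0 * np.pi))
        tol_n = min(angle_tol, np.pi / (n * (n + 1)))
        if k >= 1 and abs(angle - 2.0 * np.pi * k / n) <= tol_n:
            fold = n
            break
    return AxisAngle(axis, angle, fold)


@dataclass
class Alignment:
    """Pairwise global alignment rendered as two gapped strings."""

    gapped_a: str
    gapped_b: str
    score: float

    def matched_columns(self) -> list[tuple[int, int]]:
        """(index_a, index_b) for columns where neither sequence is gapped."""
        pairs = []
        ia = ib = 0
        for ca, cb in zip(self.gapped_a, self.gapped_b):
            if ca != "-" and cb != "-":
                pairs.append((ia, ib))
            if ca != "-":
                ia += 1
            if cb != "-":
                ib += 1
        return pairs


def residue_correspondence(chain_a, chain_b) -> list[tuple[int, int]]:
    """Aligned residue index pairs between two chains' Cα traces.

    Sequences are globally aligned (affine gaps; the scoring scheme lives
    in :mod:`quatsym.seqcluster`); each returned pair indexes
    ``ca_coords`` of the respective chain at a matched (non-gap) column.
    Indices are strictly increasing in both chains. Identical sequences
    short-circuit to the trivial 1:1 correspondence.
    """
    if chain_a.sequence == chain_b.sequence:
        n = len(chain_a.sequence)
        return [(i, i) for i in range(n)]
    from .seqcluster import global_alignment

    aln = global_alignment(chain_a.sequence, chain_b.sequence)
    return aln.matched_columns()
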