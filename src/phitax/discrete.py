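"""Discrete two-time probability distributions and Markov-matrix machinery.

A system observed at two times t0 and t1 is described by the joint
distribution ``p(x0, x1)``.  Cutting the system into subsystems A and B
turns this into a rank-4 tensor ``p[i, i', j, j']`` = P(x0A=i, x0B=i',
x1A=j, x1B=j').  The dynamics is the column-stochastic Markov matrix
``M[j, j', i, i'] = p[i, i', j, j'] / p[i, i', :, :].sum()``, and the same
construction run backward in time gives the reverse Markov matrix.

Conventions
-----------
* Discrete entropies and mutual informations are in bits (log base 2).
* ``0 * log 0 = 0`` everywhere.
* Bit 0 is the most significant bit of a state index; a bipartition
  reorders bits as (sorted part_A, sorted part_B) before reshaping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TwoTimeDistribution",
    "JointDistribution",
    "MarkovModel",
    "Bipartition",
    "validate_joint",
    "apply_bipartition",
    "marginal",
    "entropy",
    "mutual_information",
    "markov_from_joint",
    "joint_from_markov",
    "reverse_markov",
    "stationary_distribution",
]

PROB_TOL = 1e-12
EIG_TOL = 1e-10


def _check_mass(p: np.ndarray, tol: float) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("distribution contains NaN or Inf")
    if p.min() < -tol:
        idx = np.unravel_index(int(p.argmin()), p.shape)
        raise ValueError(f"negative probability {p.min():g} at index {idx}")
    total = p.sum()
    if total <= 0:
        raise ValueError("zero total probability mass")
    if abs(total - 1.0) > max(tol, 1e-8):
        raise ValueError(f"total probability {total:g} differs from 1")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


@dataclass(frozen=True)
class TwoTimeDistribution:
    """Joint distribution p[i, j] of the system state at two times."""

    p: np.ndarray
    n_bits: int | None = None
    labels: Sequence[str] | None = None

    def __post_init__(self) -> None:
        p = _check_mass(self.p, PROB_TOL)
        if p.ndim != 2:
            raise ValueError("two-time distribution must be a 2-D array")
        if self.n_bits is not None and p.shape != (2**self.n_bits, 2**self.n_bits):
            raise ValueError(
                f"n_bits={self.n_bits} inconsistent with shape {p.shape}"
            )
        object.__setattr__(self, "p", p)

    @property
    def n0(self) -> int:
        return self.p.shape[0]

    @property
    def n1(self) -> int:
        return self.p.shape[1]


@dataclass(frozen=True)
class JointDistribution:
    """Rank-4 tensor p[i, i', j, j'] over a bipartitioned two-time system."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = _check_mass(self.p, PROB_TOL)
        if p.ndim != 4:
            raise ValueError("joint distribution must be a rank-4 array")
        object.__setattr__(self, "p", p)

    @property
    def nA(self) -> int:
        return self.p.shape[0]

    @property
    def nB(self) -> int:
        return self.p.shape[1]

    def as_two_time(self) -> np.ndarray:
        """Flatten to p[x0, x1] with x0 = (i, i') and x1 = (j, j')."""
        nA, nB = self.p.shape[0], self.p.shape[1]
        nA1, nB1 = self.p.shape[2], self.p.shape[3]
        return self.p.reshape(nA * nB, nA1 * nB1)


@dataclass(frozen=True)
class MarkovModel:
    """Column-stochastic transition tensor M[j, j', i, i'] plus p0[i, i'].

    ``degenerate_columns`` flags past states with zero probability whose
    columns were filled with the uniform distribution.
    """

    M: np.ndarray
    p0: np.ndarray
    degenerate_columns: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        M = np.asarray(self.M, dtype=float)
        p0 = _check_mass(self.p0, PROB_TOL)
        if M.ndim != 4:
            raise ValueError("Markov tensor must be rank 4")
        if M.min() < -PROB_TOL:
            raise ValueError("negative transition probability")
        cols = M.sum(axis=(0, 1))
        if not np.allclose(cols, 1.0, atol=1e-9):
            raise ValueError("Markov columns must sum to 1")
        deg = self.degenerate_columns
        if deg is None:
            deg = np.zeros(p0.shape, dtype=bool)
        object.__setattr__(self, "M", M)
        object.__setattr__(self, "p0", p0)
        object.__setattr__(self, "degenerate_columns", np.asarray(deg, dtype=bool))


@dataclass(frozen=True)
class Bipartition:
    """A cut of elements {0..n-1} into two nonempty ordered parts."""

    part_A: tuple[int, ...]
    part_B: tuple[int, ...]

    def __post_init__(self) -> None:
        a = tuple(sorted(self.part_A))
        b = tuple(sorted(self.part_B))
        if not a or not b:
            raise ValueError("both parts must be nonempty")
        n = len(a) + len(b)
        if set(a) | set(b) != set(range(n)) or set(a) & set(b):
            raise ValueError("parts must disjointly cover {0..n-1}")
        object.__setattr__(self, "part_A", a)
        object.__setattr__(self, "part_B", b)

    @property
    def n_elements(self) -> int:
        return len(self.part_A) + len(self.part_B)

    def complement(self) -> "Bipartition":
        return Bipartition(self.part_B, self.part_A)


def validate_joint(p, tol: float = PROB_TOL):
    """Validate a raw array as a distribution, renormalizing to exact sum 1.

    2-D input yields a :class:`TwoTimeDistribution`, 4-D a
    :class:`JointDistribution`.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim == 2:
        return TwoTimeDistribution(_check_mass(p, tol))
    if p.ndim == 4:
        return JointDistribution(_check_mass(p, tol))
    raise ValueError(f"expected rank 2 or 4, got rank {p.ndim}")


def apply_bipartition(p2t: TwoTimeDistribution, cut: Bipartition) -> JointDistribution:
    """Reshape a bit-string two-time distribution under a cut of its bits."""
    if p2t.n_bits is None:
        raise ValueError("apply_bipartition requires n_bits to be set")
    b = p2t.n_bits
    if cut.n_elements != b:
        raise ValueError(f"cut over {cut.n_elements} bits but system has {b}")
    bits_A, bits_B = cut.part_A, cut.part_B
    # axes: b past-bit axes then b future-bit axes; bit 0 is the MSB
    t = p2t.p.reshape((2,) * (2 * b))
    order = (
        [i for i in bits_A]
        + [i for i in bits_B]
        + [b + i for i in bits_A]
        + [b + i for i in bits_B]
    )
    t = np.transpose(t, order)
    nA, nB = 2 ** len(bits_A), 2 ** len(bits_B)
    return JointDistribution(t.reshape(nA, nB, nA, nB))


def marginal(p: JointDistribution | np.ndarray, keep_axes: Iterable[int]) -> np.ndarray:
    """Sum out all axes not in ``keep_axes`` (axis order preserved)."""
    arr = p.p if isinstance(p, JointDistribution) else np.asarray(p, dtype=float)
    keep = sorted(set(keep_axes))
    if not keep:
        raise ValueError("keep_axes must be nonempty")
    drop = tuple(ax for ax in range(arr.ndim) if ax not in keep)
    return arr.sum(axis=drop) if drop else arr


def entropy(p: np.ndarray, base: float = 2.0) -> float:
    """Shannon entropy -sum p log p, with 0 log 0 = 0."""
    p = np.asarray(p, dtype=float).ravel()
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(base))).sum())


def mutual_information(p: np.ndarray, base: float = 2.0) -> float:
    """I(A;B) = S(A) + S(B) - S(A,B) of a bivariate distribution."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 2:
        raise ValueError("mutual_information expects a 2-D bivariate array")
    sa = entropy(p.sum(axis=1), base)
    sb = entropy(p.sum(axis=0), base)
    return sa + sb - entropy(p, base)


def markov_from_joint(p: JointDistribution) -> MarkovModel:
    """Estimate M[j,j',i,i'] = p[i,i',j,j'] / p[i,i',.,.].

    Columns of unreachable past states (zero marginal probability) are
    filled with the uniform distribution and flagged; they carry no mass.
    """
    arr = p.p
    p0 = arr.sum(axis=(2, 3))
    deg = p0 <= 0
    safe = np.where(deg, 1.0, p0)
    M = np.transpose(arr, (2, 3, 0, 1)) / safe[None, None, :, :]
    if deg.any():
        nfut = arr.shape[2] * arr.shape[3]
        M = np.where(deg[None, None, :, :], 1.0 / nfut, M)
    return MarkovModel(M=M, p0=p0 / p0.sum(), degenerate_columns=deg)


def joint_from_markov(m: MarkovModel) -> JointDistribution:
    """Rebuild p[i,i',j,j'] = M[j,j',i,i'] * p0[i,i']."""
    arr = np.transpose(m.M * m.p0[None, None, :, :], (2, 3, 0, 1))
    return JointDistribution(arr / arr.sum())


def reverse_markov(p: JointDistribution) -> MarkovModel:
    """Backward conditional M~[i,i',j,j'] = p[i,i',j,j'] / p[.,.,j,j'].

    Returned as a MarkovModel whose tensor maps future states (columns)
    to past states, with ``p0`` holding the future marginal p^(1).
    """
    arr = p.p
    p1 = arr.sum(axis=(0, 1))
    deg = p1 <= 0
    safe = np.where(deg, 1.0, p1)
    Mrev = arr / safe[None, None, :, :]
    if deg.any():
        npast = arr.shape[0] * arr.shape[1]
        Mrev = np.where(deg[None, None, :, :], 1.0 / npast, Mrev)
    return MarkovModel(M=Mrev, p0=p1 / p1.sum(), degenerate_columns=deg)


def stationary_distribution(
    m: MarkovModel | np.ndarray, tol: float = EIG_TOL
) -> tuple[np.ndarray, bool]:
    """Stationary p with Mp = p via the unit-eigenvalue eigenvector.

    Returns ``(p, degenerate)``; ``degenerate`` is True when the unit
    eigenvalue is (numerically) repeated, in which case one eigenvector is
    returned (uniform for the exactly-degenerate identity-like case).
    """
    if isinstance(m, MarkovModel):
        shape = m.M.shape
        n = shape[0] * shape[1]
        M2 = m.M.reshape(n, n)
    else:
        M2 = np.asarray(m, dtype=float)
        n = M2.shape[0]
    vals, vecs = np.linalg.eig(M2)
    close = np.isclose(vals, 1.0, atol=1e-8)
    if not close.any():
        raise RuntimeError("no unit eigenvalue found for Markov matrix")
    degenerate = int(close.sum()) > 1
    idx = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, idx])
    if degenerate and np.allclose(M2, np.eye(n)):
        v = np.ones(n)
    v = np.abs(v)
    p = v / v.sum()
    if np.linalg.norm(M2 @ p - p) > max(tol, 1e-8) and not degenerate:
        raise RuntimeError("stationary eigenvector residual too large")
    return p, degenerate
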