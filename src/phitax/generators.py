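"""Synthetic systems: worked two-bit examples and random ensembles.

Every generator is a pure function of its parameters and seed.  The
ensembles mirror the numerical experiments the measures are usually
exercised on: iid-uniform random joints, subsystem-swap dynamics,
random-coding distributions, and the random autoregressive ensemble
A = eta*A0 + blockdiag(A1, A2) with Sigma = I used to stress the
graph-theory partition approximation.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .discrete import JointDistribution, validate_joint
from .gaussian import GaussianSystem, lyapunov_stationary

__all__ = [
    "random_joint",
    "swap_system",
    "random_coding",
    "two_bit_example",
    "ar_random",
    "boolean_coupling_matrix",
    "RANDOM_GATE",
    "ETA_PALETTE",
]

# coupling strengths the AR ensemble draws from, with equal probability
ETA_PALETTE = (0.1, 0.3, 0.5, 0.7, 1.0, 2.0, 10.0)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_joint(nA: int, nB: int, seed) -> JointDistribution:
    """Joint with (nA*nB)^2 iid U(0,1) entries normalized to sum 1."""
    if nA < 2 or nB < 2:
        raise ValueError("subsystem sizes must be >= 2")
    rng = _rng(seed)
    p = rng.uniform(size=(nA, nB, nA, nB))
    return validate_joint(p / p.sum())


def swap_system(n: int, seed) -> JointDistribution:
    """Random initial p0 evolved by the subsystem-swap Markov matrix
    M[j,j',i,i'] = delta_{i j'} delta_{i' j}."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = _rng(seed)
    p0 = rng.uniform(size=(n, n))
    p0 /= p0.sum()
    p = np.zeros((n, n, n, n))
    for i in range(n):
        for ip in range(n):
            p[i, ip, ip, i] = p0[i, ip]
    return validate_joint(p)


def random_coding(n: int, seed) -> JointDistribution:
    """Exactly n^2 of the n^4 entries set to 1/n^2, chosen uniformly;
    S(x) = 2 log2 n exactly."""
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = _rng(seed)
    flat = np.zeros(n**4)
    idx = rng.choice(n**4, size=n**2, replace=False)
    flat[idx] = 1.0 / n**2
    return validate_joint(flat.reshape(n, n, n, n))


TWO_BIT_EXAMPLES = ("frozen_correlated", "copy_or_flip", "correlated_noise")


def two_bit_example(name: str) -> JointDistribution:
    """The exact two-bit worked examples.

    frozen_correlated: two frozen bits, initially perfectly correlated
        (uniform over 00->00 and 11->11); phi^B = -1.
    copy_or_flip: known initial state 00 evolving to 00 or 11 with equal
        probability; phi^M = 1 bit even though I(x0, x1) = 0.
    correlated_noise: perfectly correlated bits independently randomized
        at both times (x0A=x0B, x1A=x1B, times independent); phi^M = 1,
        phi^MD = 0.
    """
    p = np.zeros((2, 2, 2, 2))
    if name == "frozen_correlated":
        p[0, 0, 0, 0] = 0.5
        p[1, 1, 1, 1] = 0.5
    elif name == "copy_or_flip":
        p[0, 0, 0, 0] = 0.5
        p[0, 0, 1, 1] = 0.5
    elif name == "correlated_noise":
        for i in range(2):
            for j in range(2):
                p[i, i, j, j] = 0.25
    else:
        raise ValueError(f"unknown two-bit example {name!r}")
    return validate_joint(p)


def ar_random(n: int, eta: float, seed) -> GaussianSystem:
    """The random AR ensemble A = eta*A0 + blockdiag(A1, A2), Sigma = I.

    A0 (n x n) and A1, A2 (n/2 x n/2) have iid standard-normal entries,
    each normalized to unit spectral radius; the summed A is renormalized
    to spectral radius 0.99 and C solves the Lyapunov equation.
    """
    if n % 2 != 0 or n < 2:
        raise ValueError("n must be even and >= 2")
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    rng = _rng(seed)
    h = n // 2

    def unit_radius(m: np.ndarray) -> np.ndarray:
        return m / np.abs(np.linalg.eigvals(m)).max()

    A0 = unit_radius(rng.standard_normal((n, n)))
    A1 = unit_radius(rng.standard_normal((h, h)))
    A2 = unit_radius(rng.standard_normal((h, h)))
    A = eta * A0
    A[:h, :h] += A1
    A[h:, h:] += A2
    A = 0.99 * unit_radius(A)
    C = lyapunov_stationary(A, np.eye(n))
    return GaussianSystem(C=C, B=C @ A.T)


RANDOM_GATE = "RANDOM"


def boolean_coupling_matrix(
    gates: Sequence[Callable[[Sequence[int]], int] | str],
    input_distribution: np.ndarray | None = None,
) -> np.ndarray:
    """Coupling matrix A_ij = P(flipping bit j flips bit i next step).

    ``gates[i]`` maps the current bit vector to the next value of bit i;
    the marker :data:`RANDOM_GATE` denotes an unbiased coin independent of
    all inputs (its row is zero: flips never propagate through it).
    ``input_distribution`` is over the 2^b current states (uniform when
    omitted).  Probabilities are averages over that distribution.
    """
    b = len(gates)
    n = 2**b
    if input_distribution is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(input_distribution, dtype=float).ravel()
        if w.size != n or w.min() < 0:
            raise ValueError(f"input distribution must be length {n}, nonnegative")
        w = w / w.sum()

    states = ((np.arange(n)[:, None] >> np.arange(b - 1, -1, -1)) & 1).astype(int)
    A = np.zeros((b, b))
    for i, gate in enumerate(gates):
        if isinstance(gate, str):
            if gate != RANDOM_GATE:
                raise ValueError(f"unknown gate marker {gate!r}")
            continue  # random output: no deterministic flip propagation
        outputs = np.array([int(gate(s)) for s in states])
        if not np.isin(outputs, (0, 1)).all():
            raise ValueError(f"gate {i} returned a non-bit value")
        for j in range(b):
            flipped_idx = np.arange(n) ^ (1 << (b - 1 - j))
            A[i, j] = float(((outputs != outputs[flipped_idx]) * w).sum())
    return A
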