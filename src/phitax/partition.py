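"""Capital-Phi: minimizing phi over bipartitions, exactly or approximately.

Exact mode enumerates all symmetric bipartitions (C(n, n/2)/2 unordered
cuts) and evaluates phi for each; for the Gaussian Markov measure phi^M
the per-cut log-determinants are evaluated in one batched pass.  The fast
approximation thresholds the coupling matrix |A_ij| (or |C_ij|) at the
level epsilon that makes the largest connected component of the resulting
directed graph as close as possible to half the system, and uses that
component as the candidate "cruelest cut".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Any, Iterator

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .discrete import Bipartition, TwoTimeDistribution, apply_bipartition
from .gaussian import GaussianSystem, PartitionedGaussian, _ld, phi_gaussian
from .measures import phi, phi_M

__all__ = [
    "CutSearchResult",
    "enumerate_symmetric_bipartitions",
    "phi_exact_min",
    "graph_bipartition",
    "phi_approx",
]

ENUMERATION_GUARD = 20


@dataclass
class CutSearchResult:
    phi_min: float
    phi_max: float
    argmin_cut: Bipartition
    argmax_cut: Bipartition
    n_cuts_evaluated: int
    method: str
    diagnostics: dict[str, Any] = field(default_factory=dict)


def enumerate_symmetric_bipartitions(n: int, guard: int = ENUMERATION_GUARD) -> Iterator[Bipartition]:
    """Yield all C(n, n/2)/2 unordered symmetric cuts of {0..n-1}.

    Complement pairs are deduplicated by pinning element 0 to part A;
    deterministic lexicographic order.
    """
    if n % 2 != 0:
        raise ValueError("symmetric bipartitions require even n")
    if n > guard:
        raise ValueError(f"n={n} exceeds enumeration guard {guard}")
    half = n // 2
    rest = range(1, n)
    for tail in combinations(rest, half - 1):
        a = (0,) + tail
        b = tuple(sorted(set(range(n)) - set(a)))
        yield Bipartition(a, b)


def n_symmetric_bipartitions(n: int, ordered: bool = False) -> int:
    count = comb(n, n // 2)
    return count if ordered else count // 2


def _batched_phi_M(system: GaussianSystem, cuts: list[Bipartition]) -> np.ndarray:
    """phi^M (nats) for all cuts at once via stacked Cholesky-free solves."""
    C, B = system.C, system.B
    ld_sigma = _ld(system.Sigma)

    def side_logdets(idx: np.ndarray) -> np.ndarray:
        # idx: (ncuts, h) index array; returns ln|Sigmahat| per cut
        Cs = C[idx[:, :, None], idx[:, None, :]]
        Bs = B[idx[:, :, None], idx[:, None, :]]
        X = np.linalg.solve(Cs, Bs)
        Sh = Cs - np.transpose(Bs, (0, 2, 1)) @ X
        sign, ld = np.linalg.slogdet(0.5 * (Sh + np.transpose(Sh, (0, 2, 1))))
        if np.any(sign <= 0):
            raise np.linalg.LinAlgError("non-PD factored covariance in batch")
        return ld

    idxA = np.array([c.part_A for c in cuts])
    idxB = np.array([c.part_B for c in cuts])
    return 0.5 * (side_logdets(idxA) + side_logdets(idxB) - ld_sigma)


def _phi_for_cut(system, cut: Bipartition, measure: str, state, units: str) -> float:
    if isinstance(system, GaussianSystem):
        return phi_gaussian(system, cut, measure, state=state, units=units).value
    joint = apply_bipartition(system, cut)
    if measure in ("M", "otu", "otuk"):
        return phi_M(joint).value
    return phi(joint, measure, state=state).value


def phi_exact_min(
    system: GaussianSystem | TwoTimeDistribution,
    measure: str = "M",
    state=None,
    units: str = "nats",
    keep_values: bool = False,
    guard: int = ENUMERATION_GUARD,
) -> CutSearchResult:
    """Minimum and maximum of phi over all symmetric bipartitions.

    Gaussian systems cut their n channels; discrete bit-string systems cut
    their bits.  The Gaussian phi^M path is batched.  Units apply to the
    Gaussian layer only (discrete values are bits).
    """
    if isinstance(system, GaussianSystem):
        n = system.n
    else:
        if system.n_bits is None:
            raise ValueError("discrete system needs n_bits for bipartitioning")
        n = system.n_bits
    cuts = list(enumerate_symmetric_bipartitions(n, guard))
    if isinstance(system, GaussianSystem) and measure in ("M", "otu", "otuk"):
        values = _batched_phi_M(system, cuts)
        if units == "bits":
            values = values / np.log(2)
    else:
        values = np.array(
            [_phi_for_cut(system, c, measure, state, units) for c in cuts]
        )
    imin, imax = int(values.argmin()), int(values.argmax())
    diag: dict[str, Any] = {"measure": measure, "units": units}
    if keep_values:
        diag["values"] = values
        diag["cuts"] = cuts
    return CutSearchResult(
        phi_min=float(values[imin]),
        phi_max=float(values[imax]),
        argmin_cut=cuts[imin],
        argmax_cut=cuts[imax],
        n_cuts_evaluated=len(cuts),
        method="exact",
        diagnostics=diag,
    )


def _largest_component(W: np.ndarray, eps: float, connection: str) -> np.ndarray:
    adj = (W >= eps).astype(np.int8)
    n_comp, labels = connected_components(
        csr_matrix(adj), directed=True, connection=connection
    )
    sizes = np.bincount(labels, minlength=n_comp)
    return np.flatnonzero(labels == int(sizes.argmax()))


def graph_bipartition(
    W: np.ndarray,
    connectivity: str = "weak",
    n_iter: int = 60,
) -> tuple[Bipartition, float, dict[str, Any]]:
    """Threshold W at the level making the largest connected component as
    close as possible to n/2, by interval halving on epsilon.

    The diagonal is ignored (self-loops carry no cross-partition
    information).  Among epsilon values tying on |size - n/2| the smallest
    wins.  Returns (cut, epsilon*, diagnostics); ``degenerate`` is set when
    no epsilon achieves an exactly balanced component.
    """
    W = np.abs(np.asarray(W, dtype=float)).copy()
    n = W.shape[0]
    if n < 2 or W.shape != (n, n):
        raise ValueError("W must be square with n >= 2")
    np.fill_diagonal(W, 0.0)
    target = n / 2

    best: tuple[float, float, np.ndarray] | None = None  # (|size-n/2|, eps, comp)

    def consider(eps: float) -> int:
        nonlocal best
        comp = _largest_component(W, eps, connectivity)
        size = comp.size
        if 1 <= size <= n - 1:
            key = (abs(size - target), eps)
            if best is None or key < (best[0], best[1]):
                best = (key[0], key[1], comp)
        return size

    lo, hi = 0.0, float(W.max()) + 1e-12
    consider(lo)
    consider(hi)
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        size = consider(mid)
        if size > target:
            lo = mid
        else:
            hi = mid

    if best is None:
        # fully connected at every epsilon below max, singletons above:
        # fall back to isolating the weakest-coupled single element
        comp = np.array([0])
        eps_star = float(W.max())
        degenerate = True
    else:
        comp = best[2]
        eps_star = best[1]
        degenerate = abs(comp.size - target) > 0
    part_a = tuple(int(i) for i in comp)
    part_b = tuple(i for i in range(n) if i not in set(part_a))
    cut = Bipartition(part_a, part_b)
    return cut, eps_star, {"degenerate": degenerate, "component_size": comp.size}


STRONG_CONNECTIVITY_CODES = frozenset({"2.5", "2.5'", "2.5''"})


def phi_approx(
    system: GaussianSystem,
    measure: str = "M",
    connectivity_policy: str = "auto",
    mode: str = "A",
    state=None,
    units: str = "nats",
) -> CutSearchResult:
    """Graph-approximate capital Phi for a Gaussian system.

    ``mode`` selects the thresholded matrix: "A" (evolution), "C"
    (covariance) or "best" (evaluate both candidate cuts and keep the
    smaller phi).  ``connectivity_policy`` "auto" uses strong connectivity
    for the 2.5-family and weak otherwise.
    """
    if connectivity_policy == "auto":
        connectivity = "strong" if measure in STRONG_CONNECTIVITY_CODES else "weak"
    else:
        connectivity = connectivity_policy

    candidates: dict[str, tuple[Bipartition, float, dict]] = {}
    if mode in ("A", "best"):
        candidates["A"] = graph_bipartition(system.A, connectivity)
    if mode in ("C", "best"):
        candidates["C"] = graph_bipartition(system.C, connectivity)
    if not candidates:
        raise ValueError(f"unknown approximation mode {mode!r}")

    evaluated: dict[str, float] = {}
    for key, (cut, _, _) in candidates.items():
        evaluated[key] = _phi_for_cut(system, cut, measure, state, units)
    best_key = min(evaluated, key=evaluated.get)
    cut, eps_star, info = candidates[best_key]
    return CutSearchResult(
        phi_min=evaluated[best_key],
        phi_max=evaluated[best_key],
        argmin_cut=cut,
        argmax_cut=cut,
        n_cuts_evaluated=len(evaluated),
        method=f"approx_{mode}",
        diagnostics={
            "epsilon": eps_star,
            "connectivity": connectivity,
            "candidates": evaluated,
            **info,
        },
    )
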