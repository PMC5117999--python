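"""Probability-distance options used as the final axis of the phi taxonomy.

Seven distances are available, selected by one-letter codes:

====  =========================================  ==========================
code  distance                                   range
====  =========================================  ==========================
k     Kullback-Leibler divergence (bits)         [0, inf]
1     L1 norm  sum |p - q|                       [0, 2]
2     L2 norm                                    [0, sqrt(2)]
h     Hilbert-space angle acos(sum sqrt(p q))    [0, pi/2]
s     Shannon-Jensen distance (base-2)           [0, 1]
e     earth-mover (optimal transport) distance   depends on ground metric
m     mismatched-decoding distance (bits)        [0, I(p)]
====  =========================================  ==========================

KL and MD are asymmetric; the rest are symmetric metrics.  KL returns
``inf`` (never raises) when q lacks support where p has mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.optimize import minimize_scalar

__all__ = [
    "DistanceCode",
    "distance",
    "kl_divergence",
    "earth_mover",
    "hamming_ground_metric",
    "mismatched_decoding",
    "mismatched_information",
]

DISTANCE_CODES = frozenset("k12hsem")
EMD_STATE_GUARD = 256


@dataclass(frozen=True)
class DistanceCode:
    """A Table-5 distance selector with an optional ground metric (code e)."""

    code: str
    ground_metric: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.code not in DISTANCE_CODES:
            raise ValueError(f"unknown distance code {self.code!r}")
        g = self.ground_metric
        if g is not None:
            g = np.asarray(g, dtype=float)
            if g.ndim != 2 or g.shape[0] != g.shape[1]:
                raise ValueError("ground metric must be square")
            if g.min() < 0 or np.abs(np.diag(g)).max() > 0:
                raise ValueError("ground metric must be nonnegative with zero diagonal")
            object.__setattr__(self, "ground_metric", g)


def _log2(x: np.ndarray) -> np.ndarray:
    return np.log2(x)


def kl_divergence(p: np.ndarray, q: np.ndarray, base: float = 2.0) -> float:
    """d_KL(p, q) = sum p log(p/q); +inf when q=0 where p>0 (flag, not error)."""
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    mask = p > 0
    if np.any(q[mask] <= 0):
        return float("inf")
    return float((p[mask] * (np.log(p[mask] / q[mask]) / np.log(base))).sum())


def _shannon_jensen(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)
    d2 = 0.5 * (kl_divergence(p, m) + kl_divergence(q, m))
    return float(np.sqrt(max(d2, 0.0)))


def hamming_ground_metric(n_bits: int) -> np.ndarray:
    """Pairwise bit-flip counts between all 2**n_bits bit-string states."""
    n = 2**n_bits
    idx = np.arange(n)
    xor = idx[:, None] ^ idx[None, :]
    return np.vectorize(lambda v: bin(v).count("1"))(xor).astype(float)


def earth_mover(p: np.ndarray, q: np.ndarray, ground_metric: np.ndarray) -> float:
    """Optimal-transport cost between p and q under a pairwise cost table.

    Solved as an exact linear program (no entropic regularization) so that
    values are reproducible.  Guarded to at most 256 states.
    """
    p = np.asarray(p, dtype=float).ravel()
    q = np.asarray(q, dtype=float).ravel()
    d = np.asarray(ground_metric, dtype=float)
    n = p.size
    if q.size != n or d.shape != (n, n):
        raise ValueError("shape mismatch between distributions and ground metric")
    if n > EMD_STATE_GUARD:
        raise ValueError(f"earth mover guarded to <= {EMD_STATE_GUARD} states")
    # variables f_ab >= 0; rows sum to p, columns sum to q
    A_eq = np.zeros((2 * n, n * n))
    for a in range(n):
        A_eq[a, a * n : (a + 1) * n] = 1.0
    for b in range(n):
        A_eq[n + b, b::n] = 1.0
    b_eq = np.concatenate([p, q])
    res = linprog(d.ravel(), A_eq=A_eq[:-1], b_eq=b_eq[:-1], method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def mismatched_information(p: np.ndarray, q: np.ndarray, beta: float) -> float:
    """I*(p, q, beta): information decoded with the model q^beta, in bits.

    ``p`` and ``q`` are bivariate over the same (row, column) index sets;
    the conditional q_{j|i} = q_ij / q_i. is raised to the power beta and
    renormalized (the normalization cancels between the two terms but is
    kept for numerical hygiene).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2:
        raise ValueError("p and q must be bivariate arrays of equal shape")
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    qi = q.sum(axis=1)
    if np.any((pi > 0) & (qi <= 0)):
        raise ValueError("q has no support on a row where p has mass")
    with np.errstate(divide="ignore", invalid="ignore"):
        qc = np.where(qi[:, None] > 0, q / np.where(qi[:, None] > 0, qi[:, None], 1), 0.0)
    qb = np.where(qc > 0, qc**beta, 0.0)
    norm = qb.sum(axis=1, keepdims=True)
    if np.any((pi > 0) & (norm.ravel() <= 0)):
        return float("-inf")
    qb = np.where(norm > 0, qb / np.where(norm > 0, norm, 1), 0.0)
    # first term: -sum_j p_.j log sum_i qb_{j|i} p_i.
    mix = (qb * pi[:, None]).sum(axis=0)
    mask_j = pj > 0
    if np.any(mix[mask_j] <= 0):
        return float("-inf")
    term1 = -(pj[mask_j] * _log2(mix[mask_j])).sum()
    mask = p > 0
    if np.any(qb[mask] <= 0):
        return float("-inf")
    term2 = (p[mask] * _log2(qb[mask])).sum()
    return float(term1 + term2)


def mismatched_decoding(
    p: np.ndarray,
    q: np.ndarray,
    beta_mode: str | float = 1.0,
) -> tuple[float, float]:
    """d_MD(p, q) = I(p) - max_beta I*(p, q, beta), with the maximizing beta.

    ``beta_mode`` is a fixed numeric beta (default 1, which in practice is
    near-optimal) or ``"optimize"`` for a coarse grid on log beta in
    [-6, 6] refined by bounded 1-D maximization.
    """
    from .discrete import mutual_information

    p = np.asarray(p, dtype=float)
    ip = mutual_information(p, base=2.0)
    if isinstance(beta_mode, str):
        if beta_mode != "optimize":
            raise ValueError(f"unknown beta_mode {beta_mode!r}")
        logb = np.linspace(-6.0, 6.0, 25)
        vals = np.array([mismatched_information(p, q, float(np.exp(l))) for l in logb])
        k = int(np.nanargmax(vals))
        lo = logb[max(k - 1, 0)]
        hi = logb[min(k + 1, len(logb) - 1)]
        res = minimize_scalar(
            lambda l: -mismatched_information(p, q, float(np.exp(l))),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        best = max(-res.fun, vals[k])
        beta_star = float(np.exp(res.x)) if -res.fun >= vals[k] else float(np.exp(logb[k]))
    else:
        beta_star = float(beta_mode)
        best = mismatched_information(p, q, beta_star)
    value = ip - best
    # the exact bounds 0 <= d_MD <= I(p) can be grazed by roundoff
    return float(min(max(value, 0.0), ip)), beta_star


def distance(p: np.ndarray, q: np.ndarray, code: str | DistanceCode) -> float:
    """Dispatch d(p, q) for a one-letter Table-5 code.

    For codes other than ``m`` the inputs are flattened; code ``m``
    requires bivariate (2-D) inputs, code ``e`` a ground metric.
    """
    dc = code if isinstance(code, DistanceCode) else DistanceCode(code)
    p_arr = np.asarray(p, dtype=float)
    q_arr = np.asarray(q, dtype=float)
    if p_arr.shape != q_arr.shape:
        raise ValueError(f"shape mismatch {p_arr.shape} vs {q_arr.shape}")
    if dc.code == "m":
        if p_arr.ndim != 2:
            raise ValueError("distance code m requires bivariate distributions")
        return mismatched_decoding(p_arr, q_arr, "optimize")[0]
    pf, qf = p_arr.ravel(), q_arr.ravel()
    if dc.code == "k":
        return kl_divergence(pf, qf)
    if dc.code == "1":
        return float(np.abs(pf - qf).sum())
    if dc.code == "2":
        return float(np.linalg.norm(pf - qf))
    if dc.code == "h":
        return float(np.arccos(np.clip(np.sqrt(pf * qf).sum(), -1.0, 1.0)))
    if dc.code == "s":
        return _shannon_jensen(pf, qf)
    if dc.code == "e":
        if dc.ground_metric is None:
            raise ValueError("distance code e requires a ground metric")
        return earth_mover(pf, qf, dc.ground_metric)
    raise AssertionError("unreachable")
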