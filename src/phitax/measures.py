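"""Named discrete integration measures and the generic taxonomy evaluator.

Every measure quantifies how badly the dynamics of a bipartitioned system
factorizes into independent A- and B-parts.  The generic path is

    factorize -> build_q -> distance,

and the named measures (phi^M, phi^B, phi^MD, the state-dependent family
and the 2.5-family minima) have closed forms that must agree with it.
Discrete values are reported in bits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .discrete import Bipartition, JointDistribution, marginal, mutual_information
from .distances import DistanceCode, distance, mismatched_decoding
from .factorizations import TaxonomyCode, build_q, classify, factorize

__all__ = [
    "PhiResult",
    "phi",
    "phi_M",
    "phi_M_reversed",
    "phi_B",
    "phi_MD",
    "phi_state_dependent",
    "phi_25_family",
    "NAMED_MEASURES",
]

# Table-2 roster: the distinct named measures surviving the taxonomy collapse.
NAMED_MEASURES = (
    "otu",  # phi^M
    "B",
    "otum",  # phi^MD
    "ots",
    "ofs",
    "ofu",
    "ofk",  # = otk, the state-dependent Markov measure
    "oak",
    "opk",
    "xfk",
    "nas",
    "nak",
    "nps",
    "npk",  # = phi^2.0
    "mas",
    "mak",
    "mps",
    "mpk",
    "2.5",
    "2.5'",
    "2.5''",
)


@dataclass
class PhiResult:
    """A measure value with its provenance and diagnostics."""

    value: float
    units: str
    code: str
    partition: Bipartition | None = None
    state: tuple | np.ndarray | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def infinite(self) -> bool:
        return bool(np.isinf(self.value))


def _pair_mi(p: JointDistribution) -> float:
    """I(x^A; x^B) where x^A = (x0A, x1A) and x^B = (x0B, x1B), in bits."""
    arr = np.transpose(p.p, (0, 2, 1, 3))
    nA = arr.shape[0] * arr.shape[1]
    return mutual_information(arr.reshape(nA, -1))


def phi(
    p: JointDistribution,
    code: str | TaxonomyCode,
    state: tuple[int, int] | None = None,
    *,
    beta_mode: str | float = "optimize",
    ground_metric: np.ndarray | None = None,
) -> PhiResult:
    """Evaluate any taxonomy cell via the generic factorize->q->distance path.

    Aliases resolve to their canonical cell; identically-zero cells are
    evaluated anyway (they come out ~0 up to roundoff); undefined cells
    raise.  ``state`` is required for k-conditioning.
    """
    c = TaxonomyCode.parse(code) if isinstance(code, str) else code
    cls = classify(c)
    resolved = c
    while cls.status == "alias":
        resolved = cls.canonical
        cls = classify(resolved)
    if cls.status == "undefined":
        raise ValueError(f"taxonomy cell {c} is undefined: {cls.rule}")
    if resolved.conditioning == "k" and state is None:
        raise ValueError(f"cell {c} requires a conditioning state")

    direction = "backward" if resolved.comparison == "p" else "forward"
    method = "o" if resolved.factorization == "a" else resolved.factorization
    factors = factorize(
        p, method, direction, state=state if method == "x" else None
    )
    p_cmp, q_cmp = build_q(p, factors, resolved.comparison, resolved.conditioning, state)

    diagnostics: dict[str, Any] = {"factor_method": method, "cell": str(resolved)}
    if resolved.distance == "m":
        if resolved.comparison == "t":
            n0 = p_cmp.shape[0] * p_cmp.shape[1]
            p2, q2 = p_cmp.reshape(n0, -1), q_cmp.reshape(n0, -1)
        else:
            p2, q2 = p_cmp, q_cmp
        value, beta_star = mismatched_decoding(p2, q2, beta_mode)
        diagnostics["beta_star"] = beta_star
    else:
        dc = DistanceCode(resolved.distance, ground_metric)
        value = distance(p_cmp, q_cmp, dc)
    if np.isinf(value):
        diagnostics["infinite"] = True
    return PhiResult(
        value=float(value), units="bits", code=str(c), state=state,
        diagnostics=diagnostics,
    )


def phi_M(p: JointDistribution) -> PhiResult:
    """phi^M = I(x^A, x^B) - I(x0A, x0B): the KL divergence between the
    two-time distribution and its best separable approximation."""
    i_pair = _pair_mi(p)
    i0 = mutual_information(marginal(p, (0, 1)))
    return PhiResult(
        value=i_pair - i0, units="bits", code="otuk",
        diagnostics={"I_pair": i_pair, "I_past": i0},
    )


def phi_M_reversed(p: JointDistribution) -> PhiResult:
    """Time-reversed Markov measure I(x^A, x^B) - I(x1A, x1B), identical to
    Ay's stochastic interaction S(x0A|x1A)+S(x0B|x1B)-S(x0|x1)."""
    i_pair = _pair_mi(p)
    i1 = mutual_information(marginal(p, (2, 3)))
    return PhiResult(
        value=i_pair - i1, units="bits", code="ot~uk",
        diagnostics={"I_pair": i_pair, "I_future": i1},
    )


def phi_B(p: JointDistribution) -> PhiResult:
    """Barrett-Seth measure I(x0,x1) - I(x0A,x1A) - I(x0B,x1B); the only
    named measure allowed to go negative."""
    i01 = mutual_information(p.as_two_time())
    iA = mutual_information(marginal(p, (0, 2)))
    iB = mutual_information(marginal(p, (1, 3)))
    value = i01 - iA - iB
    return PhiResult(
        value=value, units="bits", code="B",
        diagnostics={"I_01": i01, "I_A": iA, "I_B": iB, "negative": value < 0},
    )


def optimal_q(p: JointDistribution) -> np.ndarray:
    """The best separable two-time approximation
    q_{ii'jj'} = p_{ii'..} p_{i.j.} p_{.i'.j'} / (p_{i...} p_{.i'..})."""
    arr = p.p
    p0 = marginal(p, (0, 1))
    pairA = marginal(p, (0, 2))
    pairB = marginal(p, (1, 3))
    pA0 = np.where(pairA.sum(1) > 0, pairA.sum(1), 1.0)
    pB0 = np.where(pairB.sum(1) > 0, pairB.sum(1), 1.0)
    q = np.einsum("iI,ij,IJ->iIjJ", p0, pairA / pA0[:, None], pairB / pB0[:, None])
    return q


def phi_MD(
    p: JointDistribution, beta_mode: str | float = "optimize"
) -> PhiResult:
    """Mismatched-decoding measure phi^otum = d_MD(p, q) over the
    (past state, future state) bivariate structure, with q the optimal
    separable approximation."""
    q = optimal_q(p)
    n0 = p.p.shape[0] * p.p.shape[1]
    value, beta_star = mismatched_decoding(
        p.as_two_time(), q.reshape(n0, -1), beta_mode
    )
    return PhiResult(
        value=value, units="bits", code="otum",
        diagnostics={"beta_star": beta_star, "beta_mode": beta_mode},
    )


STATE_CODES = ("ofk", "oak", "opk", "nak", "npk", "mak", "mpk", "xfk")


def phi_state_dependent(
    p: JointDistribution, code: str, state: tuple[int, int]
) -> PhiResult:
    """State-conditioned measures (ofk/oak/opk/nak/npk/mak/mpk/xfk) at a
    known state.  xfk = I(x1A, x1B | x0), which vanishes for deterministic
    dynamics."""
    base = code[:3] if len(code) >= 3 else code
    if base not in STATE_CODES:
        raise ValueError(f"not a state-dependent measure code: {code!r}")
    if base == "xfk":
        k, kp = state
        col = p.p[k, kp]
        mass = col.sum()
        if mass <= 0:
            raise ValueError(f"state {state} has zero probability")
        value = mutual_information(col / mass)
        return PhiResult(value=value, units="bits", code="xfk", state=state)
    return phi(p, code, state=state)


def phi_25_family(
    p: JointDistribution, variant: str, state: tuple[int, int]
) -> PhiResult:
    """The 2.5-family minima over cause/effect integration:
    2.5 = min(nak, npk), 2.5' = min(mak, mpk), 2.5'' = min(oak, opk).
    All vanish for purely afferent and purely efferent couplings."""
    pairs = {"2.5": ("nak", "npk"), "2.5'": ("mak", "mpk"), "2.5''": ("oak", "opk")}
    if variant not in pairs:
        raise ValueError(f"unknown 2.5-family variant {variant!r}")
    ca, cp = pairs[variant]
    ra = phi(p, ca, state=state)
    rp = phi(p, cp, state=state)
    return PhiResult(
        value=min(ra.value, rp.value), units="bits", code=variant, state=state,
        diagnostics={ca: ra.value, cp: rp.value},
    )
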