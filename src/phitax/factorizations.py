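"""Separable approximations of a Markov process and taxonomy bookkeeping.

A phi-measure is specified by a 4-letter code choosing

* factorization  ``n/m/o/x/a`` — how M is approximated by M^A (x) M^B:
  uniform noising, mild (marginal) noising, optimal with state unknown,
  optimal at a known state, or optimal-on-average (provably identical to
  ``o`` and kept as an alias so 4-letter codes resolve);
* comparison     ``t/f/a/p`` — which distributions are compared: the full
  two-time joint, the future state, the future of subsystem A, or the
  past of subsystem A (via the time-reversed Markov matrix);
* conditioning   ``u/s/k`` — the present state is unknown, separably
  distributed, or known (k means the full state x0 for o-factorization
  and x0A for the noising factorizations; for backward comparisons the
  conditioning applies to the future state instead);
* distance       ``k/1/2/h/s/e/m`` — see :mod:`phitax.distances`.

The nominal 5*4*3*7 = 420 cells collapse: many are identically zero,
undefined, or aliases of one another.  :func:`classify` encodes the rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .discrete import JointDistribution, marginal, markov_from_joint, reverse_markov

__all__ = [
    "FactoredModel",
    "TaxonomyCode",
    "Classification",
    "classify",
    "all_cells",
    "factorize",
    "build_q",
]

FACTORIZATIONS = "nmoxa"
COMPARISONS = "tfap"
CONDITIONINGS = "usk"
DISTANCES = "k12hsem"


@dataclass(frozen=True)
class TaxonomyCode:
    factorization: str
    comparison: str
    conditioning: str
    distance: str

    def __post_init__(self) -> None:
        if (
            self.factorization not in FACTORIZATIONS
            or self.comparison not in COMPARISONS
            or self.conditioning not in CONDITIONINGS
            or self.distance not in DISTANCES
        ):
            raise ValueError(f"invalid taxonomy code {self}")

    @classmethod
    def parse(cls, code: str) -> "TaxonomyCode":
        """Parse a 3- or 4-letter code; 3-letter codes get the default
        trailing KL-distance letter ``k``."""
        code = code.strip()
        if len(code) == 3:
            code += "k"
        if len(code) != 4:
            raise ValueError(f"taxonomy code must have 3 or 4 letters: {code!r}")
        return cls(code[0], code[1], code[2], code[3])

    def __str__(self) -> str:
        return self.factorization + self.comparison + self.conditioning + self.distance

    def replace(self, **kw) -> "TaxonomyCode":
        d = dict(
            factorization=self.factorization,
            comparison=self.comparison,
            conditioning=self.conditioning,
            distance=self.distance,
        )
        d.update(kw)
        return TaxonomyCode(**d)


@dataclass(frozen=True)
class Classification:
    status: str  # well-defined | zero | undefined | alias
    canonical: "TaxonomyCode | None"
    rule: str


def classify(code: str | TaxonomyCode) -> Classification:
    """Classify a taxonomy cell per the collapse rules.

    ``alias`` cells point at the canonical cell computing the same value
    (a-factorization = o-factorization; phi^otk* = phi^ofk*; x-cells with
    u-conditioning equal their s-conditioned versions).
    """
    c = TaxonomyCode.parse(code) if isinstance(code, str) else code
    f, cmp_, cond, dist = c.factorization, c.comparison, c.conditioning, c.distance

    if dist == "m" and cmp_ in "ap":
        return Classification(
            "undefined", None, "mismatched decoding needs a bivariate comparison"
        )
    if f == "a":
        return Classification(
            "alias", c.replace(factorization="o"), "optimal-on-average equals optimal"
        )
    if f in "nm":
        if cmp_ in "tf" or cond == "u":
            return Classification(
                "undefined",
                None,
                "noising randomizes subsystem B: only a/p comparisons with s/k"
                " conditioning are defined",
            )
        return Classification("well-defined", c, "noising cell")
    if f == "o":
        if cmp_ in "ap" and cond in "us":
            return Classification(
                "zero", c, "optimal factors reproduce the subsystem marginals exactly"
            )
        if cmp_ == "t" and cond == "k":
            return Classification(
                "alias", c.replace(comparison="f"), "phi^otk* equals phi^ofk*"
            )
        return Classification("well-defined", c, "optimal-factorization cell")
    if f == "x":
        if cmp_ == "t":
            return Classification(
                "undefined", None, "two-time comparison undefined at a known state"
            )
        if cmp_ in "ap" and cond == "k":
            return Classification(
                "zero", c, "state-conditional factors equal the conditional marginals"
            )
        if cmp_ in "ap" and cond == "u":
            return Classification(
                "alias", c.replace(conditioning="s"), "x-cells with u equal s"
            )
        return Classification("well-defined", c, "state-optimal cell")
    raise AssertionError("unreachable")


def all_cells() -> list[tuple[TaxonomyCode, Classification]]:
    """Enumerate and classify all 420 taxonomy cells."""
    cells = []
    for f, cmp_, cond, dist in product(
        FACTORIZATIONS, COMPARISONS, CONDITIONINGS, DISTANCES
    ):
        code = TaxonomyCode(f, cmp_, cond, dist)
        cells.append((code, classify(code)))
    return cells


@dataclass(frozen=True)
class FactoredModel:
    """Separable factor pair (M^A, M^B) with its construction metadata.

    ``MA[out, in]`` and ``MB[out, in]`` are column-stochastic; for the
    forward direction *in* indexes past states and *out* future states,
    for the backward direction the reverse.
    """

    MA: np.ndarray
    MB: np.ndarray
    direction: str  # forward | backward
    method: str  # n m o x a
    state: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for name, m in (("MA", self.MA), ("MB", self.MB)):
            m = np.asarray(m, dtype=float)
            if m.min() < -1e-12 or not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
                raise ValueError(f"{name} is not column-stochastic")
        if self.method == "x" and self.state is None:
            raise ValueError("method x requires a state")
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"bad direction {self.direction!r}")


def _forward_factors(p: JointDistribution, method: str, state):
    arr = p.p
    nA0, nB0 = arr.shape[0], arr.shape[1]
    if method in "oa":
        pairA = marginal(p, (0, 2))  # p[i, j]
        pairB = marginal(p, (1, 3))
        MA = (pairA / np.where(pairA.sum(1) > 0, pairA.sum(1), 1.0)[:, None]).T
        MB = (pairB / np.where(pairB.sum(1) > 0, pairB.sum(1), 1.0)[:, None]).T
        MA = _fill_uniform(MA, pairA.sum(1) <= 0)
        MB = _fill_uniform(MB, pairB.sum(1) <= 0)
    elif method in "nm":
        M = markov_from_joint(p).M  # [j, j', i, i']
        if method == "n":
            wB = np.full(nB0, 1.0 / nB0)
            wA = np.full(nA0, 1.0 / nA0)
        else:
            wB = marginal(p, (1,))
            wA = marginal(p, (0,))
        MA = np.einsum("jJiI,I->ji", M, wB)
        MB = np.einsum("jJiI,i->JI", M, wA)
    elif method == "x":
        k, kp = state
        col = arr[k, kp]
        mass = col.sum()
        if mass <= 0:
            raise ValueError(f"state {state} has zero probability")
        a = col.sum(axis=1) / mass
        b = col.sum(axis=0) / mass
        MA = np.tile(a[:, None], (1, nA0))
        MB = np.tile(b[:, None], (1, nB0))
    else:
        raise ValueError(f"unknown factorization method {method!r}")
    return MA, MB


def _backward_factors(p: JointDistribution, method: str, state):
    arr = p.p
    nA1, nB1 = arr.shape[2], arr.shape[3]
    if method in "oa":
        pairA = marginal(p, (0, 2))  # p[i, j]
        pairB = marginal(p, (1, 3))
        MA = pairA / np.where(pairA.sum(0) > 0, pairA.sum(0), 1.0)[None, :]
        MB = pairB / np.where(pairB.sum(0) > 0, pairB.sum(0), 1.0)[None, :]
        MA = _fill_uniform(MA, pairA.sum(0) <= 0)
        MB = _fill_uniform(MB, pairB.sum(0) <= 0)
    elif method in "nm":
        Mrev = reverse_markov(p).M  # [i, i', j, j']
        if method == "n":
            wB = np.full(nB1, 1.0 / nB1)
            wA = np.full(nA1, 1.0 / nA1)
        else:
            wB = marginal(p, (3,))
            wA = marginal(p, (2,))
        MA = np.einsum("iIjJ,J->ij", Mrev, wB)
        MB = np.einsum("iIjJ,j->IJ", Mrev, wA)
    elif method == "x":
        k, kp = state
        col = arr[:, :, k, kp]
        mass = col.sum()
        if mass <= 0:
            raise ValueError(f"state {state} has zero probability")
        a = col.sum(axis=1) / mass
        b = col.sum(axis=0) / mass
        MA = np.tile(a[:, None], (1, nA1))
        MB = np.tile(b[:, None], (1, nB1))
    else:
        raise ValueError(f"unknown factorization method {method!r}")
    return MA, MB


def _fill_uniform(M: np.ndarray, dead_cols: np.ndarray) -> np.ndarray:
    if dead_cols.any():
        M = M.copy()
        M[:, dead_cols] = 1.0 / M.shape[0]
    return M


def factorize(
    p: JointDistribution,
    method: str,
    direction: str = "forward",
    state: tuple[int, int] | None = None,
) -> FactoredModel:
    """Build the Table-3 factor pair (M^A, M^B) for a factorization code.

    Method ``a`` is an alias of ``o`` (the minimization-on-average yields
    the identical factors); method ``x`` conditions on ``state`` = the
    known past state (forward) or future state (backward).
    """
    if direction == "forward":
        MA, MB = _forward_factors(p, method, state)
    else:
        MA, MB = _backward_factors(p, method, state)
    return FactoredModel(MA=MA, MB=MB, direction=direction, method=method, state=state)


def build_q(
    p: JointDistribution,
    f: FactoredModel,
    comparison: str,
    conditioning: str,
    state: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble the compared distributions (p_cmp, q_cmp) for a taxonomy cell.

    ``state`` is the conditioning state for k-conditioning: the full
    (k, k') for o/x factorization, of which only k is used when the
    factorization noises subsystem B.  For the backward comparison ``p``
    the state refers to the future; the factors must be backward.
    """
    arr = p.p
    if comparison in "tfa" and f.direction != "forward":
        raise ValueError("comparisons t/f/a require forward factors")
    if comparison == "p" and f.direction != "backward":
        raise ValueError("comparison p requires backward factors")
    if conditioning == "k" and state is None:
        raise ValueError("conditioning k requires a state")

    MA, MB = f.MA, f.MB
    p0 = marginal(p, (0, 1))
    pA0, pB0 = marginal(p, (0,)), marginal(p, (1,))
    p1 = marginal(p, (2, 3))
    pA1, pB1 = marginal(p, (2,)), marginal(p, (3,))

    if comparison == "t":
        if conditioning == "u":
            w0 = p0
            p_cmp = arr
        elif conditioning == "s":
            w0 = pA0[:, None] * pB0[None, :]
            p_cmp = arr
        else:  # k
            k, kp = state
            mass = arr[k, kp].sum()
            if mass <= 0:
                raise ValueError(f"state {state} has zero probability")
            w0 = np.zeros_like(p0)
            w0[k, kp] = 1.0
            p_cmp = np.zeros_like(arr)
            p_cmp[k, kp] = arr[k, kp] / mass
        q = np.einsum("ji,JI,iI->iIjJ", MA, MB, w0)
        return p_cmp, q

    if comparison == "f":
        if conditioning == "u":
            q = np.einsum("ji,JI,iI->jJ", MA, MB, p0)
            return p1, q
        if conditioning == "s":
            qa = MA @ pA0
            qb = MB @ pB0
            return p1, qa[:, None] * qb[None, :]
        k, kp = state
        mass = arr[k, kp].sum()
        if mass <= 0:
            raise ValueError(f"state {state} has zero probability")
        return arr[k, kp] / mass, MA[:, k][:, None] * MB[:, kp][None, :]

    # For k-conditioning below, the true distribution conditions on the
    # full known state (k, k') even for the noising factorizations, whose
    # q-column is indexed by the A-part alone (the B input is noised away):
    # this is what makes phi^npk the IIT-2.0 measure and gives
    # phi^2.5 = log2 n for swap dynamics.
    if comparison == "a":
        if conditioning in "us":
            return pA1, MA @ pA0
        k = state[0]
        slab = arr[k, state[1]]
        mass = slab.sum()
        if mass <= 0:
            raise ValueError(f"state {state} has zero probability")
        p_cmp = slab.sum(axis=1) / mass
        return p_cmp, MA[:, k]

    if comparison == "p":
        if conditioning in "us":
            return pA0, MA @ pA1
        k = state[0]
        slab = arr[:, :, k, state[1]]
        mass = slab.sum()
        if mass <= 0:
            raise ValueError(f"state {state} has zero probability")
        p_cmp = slab.sum(axis=1) / mass
        return p_cmp, MA[:, k]

    raise ValueError(f"unknown comparison {comparison!r}")
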