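"""Closed-form integration measures for stationary Gaussian (AR) systems.

A zero-mean stationary first-order autoregressive process

    x_{t+1} = A x_t + n_t,   <n n^t> = Sigma,

is fully described by the lag-0 covariance C = <x x^t> and the lag-1
cross-covariance B = <x_t x_{t+1}^t>, from which A = B^t C^{-1} and
Sigma = C - B^t C^{-1} B.  The same process read backward in time has
A~ = B C^{-1} and Sigma~ = C - B C^{-1} B^t; |Sigma| = |Sigma~| always.

All Gaussian measures are reported in nats (natural logs).  The codes
marked infinite for continuous systems (nas, nak, nps, npk, 2.5) are
rejected here; they remain computable in the discrete layer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.linalg import solve_discrete_lyapunov

from .discrete import Bipartition
from .measures import PhiResult

__all__ = [
    "GaussianSystem",
    "PartitionedGaussian",
    "fit_ar",
    "lyapunov_stationary",
    "gaussian_mi",
    "gaussian_kl",
    "phi_gaussian",
    "GAUSSIAN_CODES",
    "INFINITE_CODES",
]

INFINITE_CODES = frozenset({"nas", "nak", "nps", "npk", "2.5"})
GAUSSIAN_CODES = (
    "M", "B", "MD", "ots", "ofs", "ofu", "ofk",
    "oak", "opk", "xfk", "mas", "mak", "mps", "mpk", "2.5'", "2.5''",
)
_CODE_ALIASES = {"otu": "M", "otuk": "M", "otum": "MD", "ot~u": "ots"}


def _ensure_pd(C: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Symmetrize and floor eigenvalues at 1e-10 x the largest (warns)."""
    C = 0.5 * (C + C.T)
    w, V = np.linalg.eigh(C)
    floor = 1e-10 * max(w.max(), 1e-300)
    if w.min() < floor:
        warnings.warn(f"{name} floored to positive definiteness", stacklevel=2)
        w = np.clip(w, floor, None)
        C = (V * w) @ V.T
    return C


def _ld(M: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0:
        raise np.linalg.LinAlgError("non-positive determinant")
    return float(logdet)


@dataclass(frozen=True)
class GaussianSystem:
    """Stationary AR description (C, B) with derived forward/backward maps."""

    C: np.ndarray
    B: np.ndarray

    def __post_init__(self) -> None:
        C = np.asarray(self.C, dtype=float)
        B = np.asarray(self.B, dtype=float)
        if C.shape != B.shape or C.ndim != 2 or C.shape[0] != C.shape[1]:
            raise ValueError("C and B must be equal-shape square matrices")
        C = _ensure_pd(C, "C")
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "B", B)

    @property
    def n(self) -> int:
        return self.C.shape[0]

    @cached_property
    def A(self) -> np.ndarray:
        return np.linalg.solve(self.C, self.B).T  # B^t C^-1

    @cached_property
    def Sigma(self) -> np.ndarray:
        return 0.5 * ((self.C - self.B.T @ np.linalg.solve(self.C, self.B)) +
                      (self.C - self.B.T @ np.linalg.solve(self.C, self.B)).T)

    @cached_property
    def A_rev(self) -> np.ndarray:
        return np.linalg.solve(self.C, self.B.T).T  # B C^-1

    @cached_property
    def Sigma_rev(self) -> np.ndarray:
        S = self.C - self.B @ np.linalg.solve(self.C, self.B.T)
        return 0.5 * (S + S.T)

    @cached_property
    def T(self) -> np.ndarray:
        """Two-time covariance [[C, B], [B^t, C]] with x = (x0, x1)."""
        return np.block([[self.C, self.B], [self.B.T, self.C]])

    @classmethod
    def from_dynamics(cls, A: np.ndarray, Sigma: np.ndarray) -> "GaussianSystem":
        """Build the stationary system of x' = A x + n via the Lyapunov
        equation."""
        C = lyapunov_stationary(A, Sigma)
        return cls(C=C, B=C @ np.asarray(A, dtype=float).T)


def lyapunov_stationary(A: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """Solve C = A C A^t + Sigma for the stationary covariance.

    Direct (Kronecker) solve for n <= 200, fixed-point iteration above.
    Requires spectral radius of A below 1.
    """
    A = np.asarray(A, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    rho = np.abs(np.linalg.eigvals(A)).max()
    if rho >= 1.0:
        raise ValueError(f"spectral radius {rho:.6f} >= 1: no stationary state")
    if A.shape[0] <= 200:
        C = solve_discrete_lyapunov(A, Sigma, method="direct")
    else:
        C = Sigma.copy()
        for _ in range(100_000):
            Cn = A @ C @ A.T + Sigma
            if np.abs(Cn - C).max() < 1e-12:
                C = Cn
                break
            C = Cn
    return 0.5 * (C + C.T)


def fit_ar(series: np.ndarray) -> GaussianSystem:
    """Estimate (C, B) from a T x n time series by lag-0/lag-1 sample
    covariances (mean-subtracted, treated as stationary)."""
    X = np.asarray(series, dtype=float)
    if X.ndim != 2:
        raise ValueError("series must be a T x n matrix")
    T, n = X.shape
    if T <= n + 1:
        raise ValueError(f"series too short: T={T} for n={n} channels")
    if not np.all(np.isfinite(X)):
        raise ValueError("series contains non-finite values")
    X = X - X.mean(axis=0)
    C = X.T @ X / T
    B = X[:-1].T @ X[1:] / (T - 1)
    return GaussianSystem(C=C, B=B)


def gaussian_mi(T: np.ndarray, split: Bipartition | tuple) -> float:
    """I(x^A, x^B) = 0.5 ln(|T_A||T_B| / |T|) in nats for a joint covariance
    T partitioned by index sets."""
    T = np.asarray(T, dtype=float)
    if isinstance(split, Bipartition):
        ia, ib = list(split.part_A), list(split.part_B)
    else:
        ia, ib = list(split[0]), list(split[1])
    TA = T[np.ix_(ia, ia)]
    TB = T[np.ix_(ib, ib)]
    return 0.5 * (_ld(TA) + _ld(TB) - _ld(T))


def gaussian_kl(
    m_p: np.ndarray, C_p: np.ndarray, m_q: np.ndarray, C_q: np.ndarray
) -> float:
    """KL divergence between Gaussians, in nats:
    0.5 [dm^t Cq^-1 dm + tr(Cq^-1 Cp) + ln(|Cq|/|Cp|) - n]."""
    m_p = np.atleast_1d(np.asarray(m_p, dtype=float))
    m_q = np.atleast_1d(np.asarray(m_q, dtype=float))
    C_p = np.atleast_2d(np.asarray(C_p, dtype=float))
    C_q = np.atleast_2d(np.asarray(C_q, dtype=float))
    n = C_p.shape[0]
    dm = m_p - m_q
    Cq_inv_dm = np.linalg.solve(C_q, dm)
    return float(
        0.5
        * (
            dm @ Cq_inv_dm
            + np.trace(np.linalg.solve(C_q, C_p))
            + _ld(C_q)
            - _ld(C_p)
            - n
        )
    )


class PartitionedGaussian:
    """Block views of a GaussianSystem under a cut, with the o-factored
    (hatted) and mild-noised (barred) quantities."""

    def __init__(self, system: GaussianSystem, cut: Bipartition):
        if cut.n_elements != system.n:
            raise ValueError("cut size does not match system dimension")
        self.system = system
        self.cut = cut
        self.ia = list(cut.part_A)
        self.ib = list(cut.part_B)

    def _blk(self, M: np.ndarray, rows, cols) -> np.ndarray:
        return M[np.ix_(rows, cols)]

    @cached_property
    def C_A(self):
        return self._blk(self.system.C, self.ia, self.ia)

    @cached_property
    def C_B(self):
        return self._blk(self.system.C, self.ib, self.ib)

    @cached_property
    def B_A(self):
        return self._blk(self.system.B, self.ia, self.ia)

    @cached_property
    def B_B(self):
        return self._blk(self.system.B, self.ib, self.ib)

    @cached_property
    def A_A(self):
        return self._blk(self.system.A, self.ia, self.ia)

    @cached_property
    def A_B(self):
        return self._blk(self.system.A, self.ib, self.ib)

    @cached_property
    def A_AB(self):
        return self._blk(self.system.A, self.ia, self.ib)

    @cached_property
    def A_BA(self):
        return self._blk(self.system.A, self.ib, self.ia)

    @cached_property
    def Sigma_A(self):
        return self._blk(self.system.Sigma, self.ia, self.ia)

    @cached_property
    def Sigma_B(self):
        return self._blk(self.system.Sigma, self.ib, self.ib)

    # o-factorization (hat): each part fit from its own lag-0/lag-1 blocks
    @cached_property
    def Ahat_A(self):
        return np.linalg.solve(self.C_A, self.B_A).T

    @cached_property
    def Ahat_B(self):
        return np.linalg.solve(self.C_B, self.B_B).T

    @cached_property
    def Sigmahat_A(self):
        S = self.C_A - self.B_A.T @ np.linalg.solve(self.C_A, self.B_A)
        return 0.5 * (S + S.T)

    @cached_property
    def Sigmahat_B(self):
        S = self.C_B - self.B_B.T @ np.linalg.solve(self.C_B, self.B_B)
        return 0.5 * (S + S.T)

    # backward (tilde) blocks
    @cached_property
    def At_A(self):
        return self._blk(self.system.A_rev, self.ia, self.ia)

    @cached_property
    def At_AB(self):
        return self._blk(self.system.A_rev, self.ia, self.ib)

    @cached_property
    def Athat_A(self):
        return np.linalg.solve(self.C_A, self.B_A.T).T

    @cached_property
    def Sigmat_A(self):
        return self._blk(self.system.Sigma_rev, self.ia, self.ia)

    @cached_property
    def Sigmathat_A(self):
        S = self.C_A - self.B_A @ np.linalg.solve(self.C_A, self.B_A.T)
        return 0.5 * (S + S.T)

    # mild noising (bar): diagonal A-blocks kept, cross-talk becomes noise
    @cached_property
    def Sigmabar_A(self):
        return self.Sigma_A + self.A_AB @ self.C_B @ self.A_AB.T

    @cached_property
    def Sigmatbar_A(self):
        return self.Sigmat_A + self.At_AB @ self.C_B @ self.At_AB.T

    def block_hat(self) -> tuple[np.ndarray, np.ndarray]:
        """(Ahat, Sigmahat) assembled as block-diagonal in system order."""
        n = self.system.n
        Ah = np.zeros((n, n))
        Sh = np.zeros((n, n))
        Ah[np.ix_(self.ia, self.ia)] = self.Ahat_A
        Ah[np.ix_(self.ib, self.ib)] = self.Ahat_B
        Sh[np.ix_(self.ia, self.ia)] = self.Sigmahat_A
        Sh[np.ix_(self.ib, self.ib)] = self.Sigmahat_B
        return Ah, Sh

    def two_time_indices(self) -> tuple[list[int], list[int]]:
        """Index sets of x^A = (x0A, x1A) and x^B inside T's 2n ordering."""
        n = self.system.n
        return (
            self.ia + [n + i for i in self.ia],
            self.ib + [n + i for i in self.ib],
        )


def _state_vectors(pg: PartitionedGaussian, state) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = pg.system.n
    if state is None:
        warnings.warn(
            "no conditioning state supplied; defaulting to the mean (zero vector)",
            stacklevel=3,
        )
        state = np.zeros(n)
    x = np.asarray(state, dtype=float)
    if x.shape != (n,):
        raise ValueError(f"state must be a length-{n} vector")
    return x, x[pg.ia], x[pg.ib]


def phi_gaussian(
    system: GaussianSystem,
    cut: Bipartition,
    code: str,
    state: np.ndarray | None = None,
    units: str = "nats",
) -> PhiResult:
    """Evaluate a Gaussian integration measure for one bipartition.

    ``state`` is the conditioning vector for k-conditioned codes (x0 for
    forward codes, x1 for the backward codes opk/mpk); it defaults to the
    zero vector (the process mean) with a warning, which nulls the
    mean-mismatch terms.  ``units="bits"`` divides by ln 2.
    """
    code_in = code
    code = _CODE_ALIASES.get(code, code)
    if code in INFINITE_CODES:
        raise ValueError(
            f"measure {code_in!r} is infinite for continuous systems"
        )
    if code not in GAUSSIAN_CODES:
        raise ValueError(f"unknown Gaussian measure code {code_in!r}")
    pg = PartitionedGaussian(system, cut)
    diagnostics: dict = {}

    if code == "M":
        value = 0.5 * (
            _ld(pg.Sigmahat_A) + _ld(pg.Sigmahat_B) - _ld(system.Sigma)
        )
    elif code == "B":
        value = 0.5 * (
            _ld(system.C)
            + _ld(pg.Sigmahat_A)
            + _ld(pg.Sigmahat_B)
            - _ld(system.Sigma)
            - _ld(pg.C_A)
            - _ld(pg.C_B)
        )
    elif code == "MD":
        # I(x0;x1) - I*(p, q, beta=1) with the block o-factorization
        Ah, Sh = pg.block_hat()
        C = system.C
        Aacute = system.A - Ah
        Chat = Ah @ C @ Ah.T + Sh
        i_p = 0.5 * (_ld(C) - _ld(system.Sigma))
        i_star = 0.5 * (
            _ld(Chat)
            - _ld(Sh)
            + np.trace(np.linalg.solve(Chat, C))
            - np.trace(np.linalg.solve(Sh, system.Sigma))
            - np.trace(Aacute.T @ np.linalg.solve(Sh, Aacute) @ C)
        )
        value = i_p - i_star
        diagnostics.update({"I": i_p, "I_star_beta1": i_star, "beta": 1.0})
    elif code == "ots":
        value = gaussian_mi(system.T, pg.two_time_indices())
    elif code == "ofs":
        value = 0.5 * (_ld(pg.C_A) + _ld(pg.C_B) - _ld(system.C))
    elif code == "ofu":
        Ah, Sh = pg.block_hat()
        Cq = Ah @ system.C @ Ah.T + Sh
        value = gaussian_kl(np.zeros(system.n), system.C, np.zeros(system.n), Cq)
    elif code == "ofk":
        x0, _, _ = _state_vectors(pg, state)
        Ah, Sh = pg.block_hat()
        value = gaussian_kl(system.A @ x0, system.Sigma, Ah @ x0, Sh)
    elif code == "oak":
        _, xA, xB = _state_vectors(pg, state)
        m_p = pg.A_A @ xA + pg.A_AB @ xB
        value = gaussian_kl(m_p, pg.Sigma_A, pg.Ahat_A @ xA, pg.Sigmahat_A)
    elif code == "opk":
        _, xA, xB = _state_vectors(pg, state)  # state is x1 here
        m_p = pg.At_A @ xA + pg.At_AB @ xB
        value = gaussian_kl(m_p, pg.Sigmat_A, pg.Athat_A @ xA, pg.Sigmathat_A)
    elif code == "xfk":
        value = 0.5 * (_ld(pg.Sigma_A) + _ld(pg.Sigma_B) - _ld(system.Sigma))
    elif code == "mas":
        Cq = pg.Sigma_A + pg.A_A @ pg.C_A @ pg.A_A.T + pg.A_AB @ pg.C_B @ pg.A_AB.T
        value = gaussian_kl(
            np.zeros(len(pg.ia)), pg.C_A, np.zeros(len(pg.ia)), Cq
        )
    elif code == "mak":
        _, xA, _ = _state_vectors(pg, state)
        value = gaussian_kl(
            pg.Ahat_A @ xA, pg.Sigmahat_A, pg.A_A @ xA, pg.Sigmabar_A
        )
    elif code == "mps":
        Cq = (
            pg.Sigmat_A
            + pg.At_A @ pg.C_A @ pg.At_A.T
            + pg.At_AB @ pg.C_B @ pg.At_AB.T
        )
        value = gaussian_kl(
            np.zeros(len(pg.ia)), pg.C_A, np.zeros(len(pg.ia)), Cq
        )
    elif code == "mpk":
        _, xA, _ = _state_vectors(pg, state)  # state is x1
        value = gaussian_kl(
            pg.Athat_A @ xA, pg.Sigmathat_A, pg.At_A @ xA, pg.Sigmatbar_A
        )
    elif code in ("2.5'", "2.5''"):
        pair = ("mak", "mpk") if code == "2.5'" else ("oak", "opk")
        ra = phi_gaussian(system, cut, pair[0], state)
        rp = phi_gaussian(system, cut, pair[1], state)
        diagnostics.update({pair[0]: ra.value, pair[1]: rp.value})
        value = min(ra.value, rp.value)
    else:  # pragma: no cover
        raise AssertionError("unreachable")

    if units == "bits":
        value = value / np.log(2)
    elif units != "nats":
        raise ValueError(f"unknown units {units!r}")
    return PhiResult(
        value=float(value), units=units, code=code_in, partition=cut,
        state=None if state is None else np.asarray(state, dtype=float),
        diagnostics=diagnostics,
    )


def phi_M_tform(system: GaussianSystem, cut: Bipartition) -> float:
    """phi^M via the equivalent T-block form
    0.5 ln(|T_A||T_B||C| / (|T||C_A||C_B|)), in nats (cross-check path)."""
    pg = PartitionedGaussian(system, cut)
    ia2, ib2 = pg.two_time_indices()
    T = system.T
    return 0.5 * (
        _ld(T[np.ix_(ia2, ia2)])
        + _ld(T[np.ix_(ib2, ib2)])
        + _ld(system.C)
        - _ld(T)
        - _ld(pg.C_A)
        - _ld(pg.C_B)
    )
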