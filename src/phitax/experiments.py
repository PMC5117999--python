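"""Reproducible numerical studies built from the generators and searches."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discrete import mutual_information
from .generators import ETA_PALETTE, ar_random
from .partition import phi_approx, phi_exact_min

__all__ = ["ApproximationStudy", "approximation_study", "mean_random_mi"]


def mean_random_mi(n: int, n_draws: int, seed) -> float:
    """Mean mutual information (bits) of bivariate distributions with n x n
    iid U(0,1) entries normalized to sum 1."""
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(n_draws):
        p = rng.uniform(size=(n, n))
        total += mutual_information(p / p.sum())
    return total / n_draws


@dataclass
class ApproximationStudy:
    """Paired exact/approximate capital-Phi results on the random AR
    ensemble."""

    phi_min: np.ndarray
    phi_max: np.ndarray
    phi_approx: np.ndarray
    n: int

    @property
    def ratio(self) -> np.ndarray:
        return self.phi_max / self.phi_min

    def success_rate_pct(self, ratio_above: float = 2.0) -> float:
        """Percent of trials with a clear best cut (Phi_max/Phi_min above
        the threshold) where the approximate cut attains the exact
        minimum."""
        m = self.ratio > ratio_above
        hit = np.abs(self.phi_approx[m] - self.phi_min[m]) <= 1e-9 * np.maximum(
            1.0, np.abs(self.phi_min[m])
        )
        return 100.0 * float(hit.mean())

    def n_selected(self, ratio_above: float = 2.0) -> int:
        return int((self.ratio > ratio_above).sum())

    def median_overestimation_pct(self, ratio_at_most: float = 2.0) -> float:
        """Median of (Phi_approx/Phi_min - 1) in percent among trials with
        no clearly dominant cut."""
        m = self.ratio <= ratio_at_most
        return 100.0 * float(np.median(self.phi_approx[m] / self.phi_min[m] - 1.0))


def approximation_study(
    n_trials: int, n: int, seed, mode: str = "A"
) -> ApproximationStudy:
    """Run the random-AR ensemble (eta drawn from the standard palette,
    Sigma = I, spectral radius 0.99) with paired exact and graph-
    approximate Phi^M."""
    rng = np.random.default_rng(seed)
    mins = np.empty(n_trials)
    maxs = np.empty(n_trials)
    apxs = np.empty(n_trials)
    for t in range(n_trials):
        eta = float(rng.choice(ETA_PALETTE))
        g = ar_random(n, eta, rng)
        ex = phi_exact_min(g, "M")
        ap = phi_approx(g, "M", mode=mode)
        mins[t], maxs[t], apxs[t] = ex.phi_min, ex.phi_max, ap.phi_min
    return ApproximationStudy(phi_min=mins, phi_max=maxs, phi_approx=apxs, n=n)
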