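"""Uncertainty machinery: autocorrelation-aware bootstrap, ratio propagation,
and the membrane-partition arithmetic.

Trajectory observables are time series with substantial serial correlation, so
a naive bootstrap of per-frame values underestimates uncertainty.  The cure
used here: estimate the effective number of independent samples
``n_eff = n / (1 + 2·τ_int)`` from the integrated autocorrelation time
(summed until the autocorrelation first turns non-positive), then resample
only ``n_eff`` points per bootstrap replicate.  Confidence intervals are
percentile intervals over 1000 resamples by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import UndefinedRatioError

__all__ = [
    "BootstrapEstimate",
    "PartitionModel",
    "effective_sample_size",
    "bootstrap_ci",
    "propagate_ratio",
    "estimate_pl_ratio",
]


@dataclass(frozen=True)
class BootstrapEstimate:
    """Mean with a percentile bootstrap 95% CI and the effective sample count."""

    mean: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_eff: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean + 1e-12 and
                self.mean <= self.ci_high + 1e-12):
            raise ValueError("CI must bracket the mean")

    @property
    def se(self) -> float:
        """Normal-approximation standard error from the CI half-width."""
        return (self.ci_high - self.ci_low) / (2 * 1.959964)

    def contains(self, value: float) -> bool:
        return self.ci_low <= value <= self.ci_high


def effective_sample_size(series: np.ndarray) -> float:
    """Effective number of independent samples of an autocorrelated series.

    τ_int sums the normalized autocorrelation ρ_k from k=1 until ρ first turns
    non-positive (initial-positive-sequence truncation); then
    n_eff = n / (1 + 2 τ_int).  A constant series has zero correlation time,
    hence n_eff = n.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("series too short for autocorrelation estimation (n < 10)")
    if np.ptp(x) == 0:  # constant series: zero correlation time
        return float(n)
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return float(n)
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    tau = 0.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        tau += rho[k]
    return float(np.clip(n / (1.0 + 2.0 * tau), 1.0, n))


def bootstrap_ci(series: np.ndarray, n_boot: int = 1000, alpha: float = 0.05,
                 n_eff: float | None = None,
                 rng: np.random.Generator | int | None = 0) -> BootstrapEstimate:
    """Percentile bootstrap CI of the mean, resampling ``n_eff`` points.

    ``n_eff`` defaults to :func:`effective_sample_size` when the series is
    long enough, else to ``n``.  Deterministic for a fixed ``rng`` seed.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if n_eff is None:
        n_eff = effective_sample_size(x) if x.size >= 10 else float(x.size)
    if n_eff < 2:
        raise ValueError(f"n_eff={n_eff:.2f} < 2: too few independent samples")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    m = max(2, int(round(n_eff)))
    mean = float(x.mean())
    if np.ptp(x) == 0:
        return BootstrapEstimate(mean, mean, mean, n_boot, float(n_eff))
    idx = rng.integers(0, x.size, size=(n_boot, m))
    means = x[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    lo = min(lo, mean)
    hi = max(hi, mean)
    return BootstrapEstimate(mean, float(lo), float(hi), n_boot, float(n_eff))


def point_or_bootstrap(series: np.ndarray, n_boot: int = 1000,
                       rng: np.random.Generator | int | None = 0
                       ) -> BootstrapEstimate:
    """Bootstrap CI, degrading gracefully to a zero-width point estimate for
    single-sample series (e.g. single-frame analyses)."""
    x = np.asarray(series, dtype=float)
    if x.size == 1:
        v = float(x[0])
        return BootstrapEstimate(v, v, v, n_boot, 1.0)
    n_eff = effective_sample_size(x) if x.size >= 10 else float(x.size)
    return bootstrap_ci(x, n_boot=n_boot, n_eff=max(2.0, n_eff), rng=rng)


def propagate_ratio(a: float, sigma_a: float, b: float, sigma_b: float
                    ) -> tuple[float, float]:
    """First-order error propagation of the quotient a/b.

    σ_ratio = |a/b| · sqrt((σa/a)² + (σb/b)²).  Raises
    :class:`UndefinedRatioError` when the denominator's 95% interval spans 0.
    """
    if b == 0 or abs(b) <= 1.959964 * sigma_b:
        raise UndefinedRatioError(
            f"denominator {b} ± {sigma_b} indistinguishable from zero")
    ratio = a / b
    rel_a = (sigma_a / a) ** 2 if a != 0 else 0.0
    rel_b = (sigma_b / b) ** 2
    return ratio, abs(ratio) * float(np.sqrt(rel_a + rel_b))


@dataclass(frozen=True)
class PartitionModel:
    """Membrane partition inputs: Kp (dimensionless), MIC (mol/L),
    gamma_L (L/mol, lipid molar volume)."""

    Kp: float
    MIC: float
    gamma_L: float

    def __post_init__(self) -> None:
        if min(self.Kp, self.MIC, self.gamma_L) <= 0:
            raise ValueError("all partition inputs must be positive")


def estimate_pl_ratio(model: PartitionModel) -> float:
    """Peptide-to-lipid mole ratio implied by a partition equilibrium:
    P/L = MIC · Kp · γ_L (dimensionless)."""
    return model.MIC * model.Kp * model.gamma_L
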