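"""Dipole autocorrelation functions and exponential relaxation times.

The normalized ACF of a collective dipole series,
C(τ) = ⟨δM(t)·δM(t+τ)⟩/⟨δM²⟩, is averaged over all valid time origins.
Under a static field the mean dipole is nonzero, so the default removes the
series mean (δM = M − ⟨M⟩) and the ACF measures fluctuation relaxation;
``detrend="none"`` keeps the raw second moment for signals whose structure
is in the mean (e.g. a driven cosine). The long-time decay is summarized by
a single-exponential fit, C(τ) ≈ exp(−τ/τ_rel).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .dipoles import DipoleSeries

__all__ = ["ACFResult", "dipole_acf", "fit_relaxation_time", "average_acf"]


@dataclass
class ACFResult:
    """Normalized autocorrelation with (optionally) a fitted decay time."""

    lags: np.ndarray           # ps
    acf: np.ndarray
    tau: Optional[float] = None        # ps
    fit_window: Optional[Tuple[float, float]] = None
    fit_residual: Optional[float] = None

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])


def _autocovariance(x: np.ndarray, n_lags: int) -> np.ndarray:
    """⟨x(t)·x(t+k)⟩ averaged over all valid origins, lags 0..n_lags."""
    n = len(x)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    raw = np.fft.irfft(f * np.conj(f), nfft)[: n_lags + 1]
    return raw / (n - np.arange(n_lags + 1))


def dipole_acf(
    series: DipoleSeries, max_lag: float, detrend: str = "mean"
) -> ACFResult:
    """Normalized dipole ACF up to ``max_lag`` ps.

    ``detrend="mean"`` subtracts the series mean before correlating (the
    default; required for static-field series whose mean alignment is
    nonzero); ``"none"`` correlates the raw signal.
    """
    if detrend not in ("mean", "none"):
        raise ValueError("detrend must be 'mean' or 'none'")
    dt = series.dt
    n_lags = int(round(max_lag / dt))
    x = series.dipole_x.astype(float)
    if len(x) <= n_lags:
        raise ValueError("series shorter than requested max_lag")
    if detrend == "mean":
        x = x - x.mean()
    c = _autocovariance(x, n_lags)
    if c[0] <= 0 or not np.isfinite(c[0]):
        raise ValueError("zero variance: constant series with detrend='mean'")
    return ACFResult(lags=np.arange(n_lags + 1) * dt, acf=c / c[0])


def fit_relaxation_time(
    result: ACFResult, fit_range: Tuple[float, float]
) -> Tuple[float, float]:
    """Least-squares single-exponential fit C(τ) = exp(−τ/τ_rel).

    ``fit_range`` is (start, stop) in ps over the available lags. Returns
    (tau, rms residual) and records them on ``result``. Raises if the ACF
    is non-positive throughout the range (no exponential regime; try a
    shorter range).
    """
    t0, t1 = fit_range
    mask = (result.lags >= t0) & (result.lags <= t1)
    if mask.sum() < 2:
        raise ValueError("fit_range selects fewer than two lags")
    t = result.lags[mask]
    c = result.acf[mask]
    if np.all(c <= 0):
        raise ValueError(
            "ACF non-positive throughout fit range; choose a shorter range"
        )
    pos = c > 0
    slope, _ = np.polyfit(t[pos], np.log(c[pos]), 1)
    tau0 = -1.0 / slope if slope < 0 else (t1 - t0)
    tau0 = abs(tau0) if tau0 != 0 else (t1 - t0)
    popt, _ = curve_fit(
        lambda tt, tau: np.exp(-tt / tau), t, c, p0=[tau0], maxfev=10000
    )
    tau = float(popt[0])
    residual = float(np.sqrt(np.mean((np.exp(-t / tau) - c) ** 2)))
    result.tau = tau
    result.fit_window = (float(t0), float(t1))
    result.fit_residual = residual
    return tau, residual


def average_acf(results: Sequence[ACFResult]) -> ACFResult:
    """Average ACFs estimated on separate windows of equal lag grid."""
    if not results:
        raise ValueError("no ACFs to average")
    lags = results[0].lags
    for r in results[1:]:
        if len(r.lags) != len(lags) or not np.allclose(r.lags, lags):
            raise ValueError("ACFs have differing lag grids")
    acf = np.mean([r.acf for r in results], axis=0)
    return ACFResult(lags=lags.copy(), acf=acf)
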