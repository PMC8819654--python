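"""Field-phase lag of the dipolar response to an oscillating field.

Under E(t) = E_max cos(ω t), a group's collective dipole responds as
M(t) ≈ A·cos(ω·(t − t_lag)) + c: the response crest trails the field crest
by the lag time t_lag. For a Debye-type rotor with relaxation time τ the
closed form is t_lag = arctan(ωτ)/ω. The lag is estimated by linear
least-squares fit of the cosine model (robust to noise, unlike
peak-picking), reduced modulo the field period into [0, period).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dipoles import DipoleSeries
from .field import FieldSpec, period_of

__all__ = ["LagResult", "LagSummary", "estimate_lag_time", "lag_distribution",
           "lag_by_windows"]


@dataclass
class LagResult:
    """Fitted lag of one dipole series against the applied field."""

    group: str
    t_lag: float       # ps, in [0, period)
    amplitude: float   # D, >= 0
    offset: float      # D
    residual: float    # rms, D
    window_id: Optional[int] = None
    degenerate: bool = False  # amplitude indistinguishable from 0


@dataclass
class LagSummary:
    """Box-chart statistics of lag times across windows, per group."""

    stats: Dict[str, dict] = dc_field(default_factory=dict)


def estimate_lag_time(
    series: DipoleSeries, field: FieldSpec, window_id: Optional[int] = None
) -> LagResult:
    """Fit M(t) = A·cos(ω(t − t_lag)) + c and return the lag in [0, period).

    Requires a cosine field and a series spanning at least two periods.
    The fit is linear in (a, b, c) with M = a·cosωt' + b·sinωt' + c,
    t' = t − phase_origin; then A = √(a²+b²) and ω·t_lag = atan2(b, a).
    A fitted amplitude smaller than twice its standard error is flagged
    degenerate.
    """
    if field.waveform != "cosine":
        raise ValueError("lag undefined for a static field")
    period = period_of(field)
    span = series.times[-1] - series.times[0]
    # non-integer periods on a sampling grid can clip one sample at each end
    slack = 2.0 * series.dt if len(series.times) > 1 else 0.0
    if span < 2 * period - slack:
        raise ValueError(
            f"series spans {span:.1f} ps < two field periods ({2 * period:.1f} ps)"
        )
    omega = field.omega
    t = series.times - field.phase_origin
    design = np.column_stack([np.cos(omega * t), np.sin(omega * t), np.ones_like(t)])
    coef, *_ = np.linalg.lstsq(design, series.dipole_x, rcond=None)
    a, b, c = coef
    amplitude = float(np.hypot(a, b))
    resid = series.dipole_x - design @ coef
    residual = float(np.sqrt(np.mean(resid**2)))
    # standard error of the quadrature amplitudes for white residuals
    n = len(t)
    se_amp = residual * np.sqrt(2.0 / n)
    t_lag = (np.arctan2(b, a) / omega) % period
    if period - t_lag < 1e-9 * period:  # float wrap lands exactly on the period
        t_lag = 0.0
    return LagResult(
        group=series.group,
        t_lag=float(t_lag),
        amplitude=amplitude,
        offset=float(c),
        residual=residual,
        window_id=window_id,
        degenerate=amplitude < 2.0 * se_amp,
    )


def lag_by_windows(
    series: DipoleSeries, field: FieldSpec, windows: Sequence[Tuple[float, float]]
) -> List[LagResult]:
    """Fit the lag separately within each (start, end) window."""
    out = []
    for i, (start, end) in enumerate(windows):
        mask = (series.times >= start) & (series.times <= end)
        sub = DipoleSeries(
            group=series.group,
            times=series.times[mask],
            dipole_x=series.dipole_x[mask],
        )
        out.append(estimate_lag_time(sub, field, window_id=i))
    return out


def lag_distribution(results: Sequence[LagResult]) -> LagSummary:
    """Five-number summary of lag times per group (Tukey whiskers).

    Quartiles use linear interpolation; whiskers extend to the most extreme
    lags within 1.5·IQR of the quartiles, and lags beyond are listed as
    outliers. Requires at least 4 windows per group.
    """
    groups: Dict[str, List[float]] = {}
    for r in results:
        groups.setdefault(r.group, []).append(r.t_lag)
    summary = LagSummary()
    for g, lags in groups.items():
        if len(lags) < 4:
            raise ValueError(f"group {g!r} has {len(lags)} windows; need >= 4")
        arr = np.sort(np.asarray(lags))
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
        outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
        summary.stats[g] = {
            "median": float(med),
            "q1": float(q1),
            "q3": float(q3),
            "whisker_low": float(inside.min()),
            "whisker_high": float(inside.max()),
            "mean": float(arr.mean()),
            "outliers": [float(x) for x in outliers],
            "n": len(arr),
        }
    return summary
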