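"""Applied electric field: waveform conventions and unit conversions.

The applied field is uniform in space, E(t) = E_max cos(ω t) ê for the
oscillating case or E ê for static exposure. Intensities are specified as
root-mean-square values in V/Å; for a cosine waveform the peak amplitude is
E_max = √2·E_rms, while a static field uses the rms value directly as its
constant strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from ._units import PS_PER_GHZ_PERIOD

__all__ = ["FieldSpec", "period_of", "rms_to_max", "field_at"]

_UNIT_X = (1.0, 0.0, 0.0)


@dataclass(frozen=True)
class FieldSpec:
    """Specification of the applied electric field.

    Parameters
    ----------
    waveform:
        ``"static"`` or ``"cosine"``.
    e_rms:
        Root-mean-square intensity in V/Å (>= 0).
    frequency:
        Field frequency in GHz; required positive for ``cosine``, must be
        absent/zero for ``static``.
    direction:
        Unit 3-vector of the field axis; defaults to the laboratory x axis.
    phase_origin:
        Time (ps) at which the cosine argument is zero. Defaults to
        trajectory time zero; all lag times are reported relative to it.
    """

    waveform: str
    e_rms: float
    frequency: float = 0.0
    direction: tuple = dc_field(default=_UNIT_X)
    phase_origin: float = 0.0

    def __post_init__(self):
        if self.waveform not in ("static", "cosine"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.e_rms < 0:
            raise ValueError("e_rms must be non-negative")
        d = np.asarray(self.direction, dtype=float)
        if d.shape != (3,):
            raise ValueError("direction must be a 3-vector")
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("direction must have unit norm (within 1e-9)")
        object.__setattr__(self, "direction", tuple(d))
        if self.waveform == "cosine" and not self.frequency > 0:
            raise ValueError("cosine waveform requires frequency > 0 GHz")
        if self.waveform == "static" and self.frequency not in (0, 0.0, None):
            raise ValueError("static waveform must not carry a frequency")

    # -- derived quantities -------------------------------------------------

    @property
    def omega(self) -> float:
        """Angular frequency in rad/ps (cosine only; 0 for static)."""
        if self.waveform == "static":
            return 0.0
        return 2.0 * math.pi * self.frequency / PS_PER_GHZ_PERIOD


def period_of(spec: FieldSpec) -> float:
    """Field period in ps (1000 / frequency_GHz).

    2.45, 10 and 100 GHz give 408.16, 100 and 10 ps.
    """
    if spec.waveform != "cosine":
        raise ValueError("period undefined for static field")
    return PS_PER_GHZ_PERIOD / spec.frequency


def rms_to_max(spec: FieldSpec) -> float:
    """Peak amplitude E_max in V/Å.

    For a cosine field E_max = √2·E_rms; a static field's constant strength
    equals the quoted rms intensity.
    """
    if spec.waveform == "cosine":
        return math.sqrt(2.0) * spec.e_rms
    return spec.e_rms


def field_at(spec: FieldSpec, t) -> np.ndarray:
    """Field vector(s) in V/Å at time(s) ``t`` (ps).

    Scalar ``t`` gives shape (3,); an array of times gives (len(t), 3).
    """
    direction = np.asarray(spec.direction)
    e_max = rms_to_max(spec)
    t = np.asarray(t, dtype=float)
    if spec.waveform == "static":
        amp = np.full(t.shape, e_max)
    else:
        amp = e_max * np.cos(spec.omega * (t - spec.phase_origin))
    return np.multiply.outer(amp, direction)
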