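"""Field-period-aligned trajectory windows and the experiment condition matrix.

Long driven trajectories are analysed in overlapping fixed-length windows
whose start times are shifted by an integer multiple of the field period,
so the field phase is identical at every window start (e.g. a 100 ns run
in 10 ns windows shifted by five 2.45 GHz periods gives 45 windows). A
window is retained only if the tracked sub-shell's water composition is
stable for at least 90% of the segment. The condition matrix expands a
study design of zero field + static intensities + (frequency × intensity)
oscillating fields over box/salt setups; the reference design
(1 + 3 + 3×3) × 2 yields 26 conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .field import FieldSpec, period_of
from .shells import ShellAssignment

__all__ = [
    "WindowSpec",
    "Condition",
    "ConditionMatrix",
    "StabilityResult",
    "resolve_shift",
    "segment_windows",
    "occupancy_stability",
    "build_condition_matrix",
]

DEFAULT_MIN_SHIFT = 2000.0  # ps; smallest window shift, also the static default


@dataclass(frozen=True)
class WindowSpec:
    """Window length and shift policy.

    If ``period_multiple`` is given, the shift is that many field periods;
    if ``shift`` is given, it is snapped to the nearest integer multiple of
    the period; if neither, the shift defaults to the smallest integer
    multiple of the period that is at least 2000 ps (2000 ps flat for
    static/zero fields). The resolved shift is snapped down to the
    sampling grid.
    """

    window_length: float          # ps
    shift: Optional[float] = None  # ps
    period_multiple: Optional[int] = None

    def __post_init__(self):
        if self.window_length <= 0:
            raise ValueError("window_length must be positive")
        if self.shift is not None and self.shift <= 0:
            raise ValueError("shift must be positive")
        if self.period_multiple is not None and self.period_multiple < 1:
            raise ValueError("period_multiple must be a positive integer")


def resolve_shift(
    spec: WindowSpec, field: Optional[FieldSpec], sampling_dt: float = 1.0
) -> float:
    """Resolved window shift in ps, period-aligned and grid-snapped."""
    if field is not None and field.waveform == "cosine":
        period = period_of(field)
        if spec.period_multiple is not None:
            k = spec.period_multiple
        elif spec.shift is not None:
            k = max(1, round(spec.shift / period))
        else:
            k = max(1, math.ceil(DEFAULT_MIN_SHIFT / period))
        raw = k * period
    else:
        raw = spec.shift if spec.shift is not None else DEFAULT_MIN_SHIFT
    snapped = math.floor(raw / sampling_dt) * sampling_dt
    if snapped <= 0:
        raise ValueError("shift snapped to zero; sampling grid too coarse")
    return snapped


def segment_windows(
    total_length: float,
    spec: WindowSpec,
    field: Optional[FieldSpec] = None,
    sampling_dt: float = 1.0,
) -> List[Tuple[float, float]]:
    """Overlapping (start, end) windows fully inside [0, total_length].

    Starts at 0, shift, 2·shift, …; the count is
    floor((total − window)/shift) + 1.
    """
    if spec.window_length > total_length:
        raise ValueError("window longer than trajectory")
    shift = resolve_shift(spec, field, sampling_dt)
    n = int(math.floor((total_length - spec.window_length) / shift)) + 1
    return [(i * shift, i * shift + spec.window_length) for i in range(n)]


@dataclass
class StabilityResult:
    """Fraction of window frames matching the reference shell composition."""

    fraction: float
    retained: bool
    n_frames: int


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def occupancy_stability(
    assignments: Sequence[ShellAssignment],
    window: Tuple[float, float],
    shell: str = "shell1",
    jaccard_threshold: float = 1.0,
    min_fraction: float = 0.90,
) -> StabilityResult:
    """Shell-composition stability of one window.

    The reference composition is the tracked shell's molecule set at the
    window's first frame; a frame matches when its Jaccard similarity to
    the reference reaches ``jaccard_threshold`` (1.0 = exact membership).
    The window is retained when the matching fraction is at least
    ``min_fraction`` (inclusive ≥ 0.90 by default).
    """
    start, end = window
    in_win = [a for a in assignments if start <= a.frame_time <= end]
    if not in_win:
        raise ValueError("no shell assignments fall inside the window")
    reference = set(in_win[0].molecules_in(shell))
    matches = sum(
        1
        for a in in_win
        if _jaccard(set(a.molecules_in(shell)), reference) >= jaccard_threshold
    )
    fraction = matches / len(in_win)
    return StabilityResult(
        fraction=fraction, retained=fraction >= min_fraction, n_frames=len(in_win)
    )


@dataclass(frozen=True)
class Condition:
    """One cell of the study design: a setup label plus a field."""

    setup: str
    field: FieldSpec

    @property
    def key(self) -> tuple:
        return (
            self.setup,
            self.field.waveform,
            self.field.e_rms,
            self.field.frequency,
        )


@dataclass
class ConditionMatrix:
    """Expanded experiment design."""

    conditions: List[Condition]

    def __len__(self) -> int:
        return len(self.conditions)


def build_condition_matrix(
    static_intensities: Sequence[float],
    frequencies: Sequence[float],
    intensities: Sequence[float],
    setups: Sequence[str] = ("default",),
) -> ConditionMatrix:
    """Expand (zero ∪ static ∪ frequency×intensity) over setups.

    Count = (1 + n_static + n_freq·n_int) × n_setups; duplicates raise.
    """
    if len(setups) < 1:
        raise ValueError("need at least one setup")
    conditions: List[Condition] = []
    for setup in setups:
        conditions.append(Condition(setup, FieldSpec("static", 0.0)))
        for e in static_intensities:
            conditions.append(Condition(setup, FieldSpec("static", e)))
        for f in frequencies:
            for e in intensities:
                conditions.append(Condition(setup, FieldSpec("cosine", e, frequency=f)))
    keys = [c.key for c in conditions]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate conditions in design")
    return ConditionMatrix(conditions)
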