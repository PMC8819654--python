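"""Field conversions, the experiment design, and window planning.

Builds the applied-field specifications of a microwave-exposure study
(2.45/10/100 GHz at 0.005–0.02 V/Å rms), expands the full condition
matrix, and plans period-aligned overlapping analysis windows for a
100 ns production run.
"""

from hydrodipole import (
    FieldSpec,
    WindowSpec,
    build_condition_matrix,
    period_of,
    rms_to_max,
    segment_windows,
)

for freq in (2.45, 10.0, 100.0):
    spec = FieldSpec("cosine", 0.01, frequency=freq)
    print(
        f"{freq:6.2f} GHz: period {period_of(spec):7.2f} ps, "
        f"E_max {rms_to_max(spec):.4f} V/Å (rms {spec.e_rms} V/Å)"
    )

matrix = build_condition_matrix(
    static_intensities=[0.005, 0.01, 0.02],
    frequencies=[2.45, 10.0, 100.0],
    intensities=[0.005, 0.01, 0.02],
    setups=["rectangular", "cubic-150mM"],
)
print(f"\ncondition matrix: {len(matrix)} conditions "
      "(zero + 3 static + 3x3 oscillating, per box/salt setup)")

field = FieldSpec("cosine", 0.01, frequency=2.45)
windows = segment_windows(
    100_000.0, WindowSpec(window_length=10_000.0, period_multiple=5), field
)
print(
    f"100 ns run, 10 ns windows shifted by 5 field periods: "
    f"{len(windows)} overlapping windows, shift {windows[1][0] - windows[0][0]:.0f} ps"
)
# Every window starts at the same field phase (integer periods), so lag
# fits from different windows are directly comparable.
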