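"""Dipole relaxation time and field-phase lag of driven rotors.

Free rotors: the collective dipole ACF decays exponentially with
τ = 1/(2·D_r). Driven rotors: the collective dipole oscillates at the
field frequency, trailing it by the Debye lag arctan(ωτ)/ω. Both are
recovered by the analysis stages from raw simulated series.
"""

import numpy as np

from hydrodipole import (
    DipoleSeries,
    FieldSpec,
    RotorEnsembleConfig,
    debye_lag,
    dipole_acf,
    estimate_lag_time,
    fit_relaxation_time,
    simulate_ensemble,
)

MU = 2.3

# --- relaxation of free rotors ---------------------------------------------
d_rot = 0.1  # ps^-1  -> expected tau = 5 ps
cfg = RotorEnsembleConfig(
    n_rotors=800, mu=MU, d_rot=d_rot, dt=0.05, n_steps=60_000, seed=3,
    sample_every=20,
)
s = simulate_ensemble(cfg, FieldSpec("static", 0.0))
series = DipoleSeries("rotors", s.times, MU * s.unit_vectors[..., 0].sum(axis=1))
acf = dipole_acf(series, max_lag=25.0)
tau, residual = fit_relaxation_time(acf, (0.0, 15.0))
print(f"free rotors: fitted tau = {tau:.2f} ps (theory 1/(2 D_r) = {1/(2*d_rot):.2f} ps)")

# --- lag under an oscillating field ----------------------------------------
freq = 10.0  # GHz
omega = 2 * np.pi * freq / 1000.0
tau_rot = 1.0 / omega  # omega*tau = 1
field = FieldSpec("cosine", 0.02, frequency=freq)
cfg = RotorEnsembleConfig(
    n_rotors=3000, mu=MU, d_rot=1.0 / (2 * tau_rot), dt=0.25, n_steps=8000,
    seed=4, sample_every=4,
)
s = simulate_ensemble(cfg, field)
series = DipoleSeries("rotors", s.times, MU * s.unit_vectors[..., 0].sum(axis=1))
fit = estimate_lag_time(series, field)
print(
    f"driven rotors (omega*tau = 1): lag = {fit.t_lag:.2f} ps, "
    f"amplitude = {fit.amplitude:.1f} D "
    f"(Debye lag = {debye_lag(freq, tau_rot):.2f} ps = period/8)"
)
# The dipole crest trails the field crest by the fitted lag; at
# omega*tau = 1 Debye theory puts it exactly one-eighth period behind.
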