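"""Synthetic rotor ensembles: oracles, determinism and trajectory emission."""

import numpy as np
import pytest

from hydrodipole.dipoles import collective_dipole_component
from hydrodipole.field import FieldSpec
from hydrodipole.rotors import (
    OrientationSeries,
    RotorEnsembleConfig,
    debye_lag,
    emit_trajectory,
    langevin_alignment,
    simulate_ensemble,
    uniform_water_box,
)

ZERO_FIELD = FieldSpec("static", 0.0)


class TestLangevinFunction:
    def test_isotropic_limit(self):
        assert langevin_alignment(0.0) == 0.0

    def test_reference_value_at_one(self):
        # coth(1) - 1 by high-precision arithmetic
        assert langevin_alignment(1.0) == pytest.approx(0.3130352855, abs=1e-9)

    def test_saturation(self):
        assert langevin_alignment(100.0) == pytest.approx(1 - 1 / 100.0, abs=1e-6)

    def test_series_matches_exact_near_crossover(self):
        # the exact branch agrees with the Taylor series just above the switch
        x = 2e-4
        assert langevin_alignment(x) == pytest.approx(x / 3 - x**3 / 45, abs=1e-9)

    def test_vectorized(self):
        x = np.array([0.0, 0.5, 2.0])
        out = langevin_alignment(x)
        assert out.shape == (3,) and np.all(np.diff(out) > 0)


class TestDebyeLag:
    def test_unit_omega_tau_gives_eighth_period(self):
        f = 10.0  # GHz -> period 100 ps
        omega = 2 * np.pi * f / 1000.0
        assert debye_lag(f, 1.0 / omega) == pytest.approx(100.0 / 8)

    def test_low_frequency_limit_is_tau(self):
        assert debye_lag(1e-4, 5.0) == pytest.approx(5.0, rel=1e-6)

    def test_high_frequency_limit_is_quarter_period(self):
        assert debye_lag(100.0, 1e6) == pytest.approx(10.0 / 4, rel=1e-4)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            debye_lag(0.0, 5.0)
        with pytest.raises(ValueError):
            debye_lag(10.0, -1.0)


class TestSimulateEnsemble:
    def test_same_seed_bitwise_identical(self):
        cfg = RotorEnsembleConfig(n_rotors=50, n_steps=200, seed=9)
        a = simulate_ensemble(cfg, ZERO_FIELD)
        b = simulate_ensemble(cfg, ZERO_FIELD)
        assert np.array_equal(a.unit_vectors, b.unit_vectors)
        assert np.array_equal(a.times, b.times)

    def test_unit_norm_maintained(self):
        cfg = RotorEnsembleConfig(n_rotors=20, n_steps=500, seed=3, dt=0.1)
        s = simulate_ensemble(cfg, FieldSpec("static", 0.02))
        norms = np.linalg.norm(s.unit_vectors, axis=-1)
        assert np.allclose(norms, 1.0, atol=1e-8)

    def test_dt_guard_rejects_coarse_step(self):
        cfg = RotorEnsembleConfig(n_rotors=5, n_steps=10, dt=50.0, d_rot=0.5)
        with pytest.raises(ValueError, match="dt too large"):
            simulate_ensemble(cfg, FieldSpec("static", 0.05))

    def test_zero_field_isotropy(self):
        """Mean u_x over a long zero-field run vanishes within 3 SE."""
        cfg = RotorEnsembleConfig(
            n_rotors=2000, d_rot=0.2, dt=0.05, n_steps=2000, seed=11, sample_every=10
        )
        s = simulate_ensemble(cfg, ZERO_FIELD)
        per_rotor = s.unit_vectors[20:, :, 0].mean(axis=0)
        se = per_rotor.std(ddof=1) / np.sqrt(cfg.n_rotors)
        assert abs(per_rotor.mean()) < 3 * se

    def test_free_rotor_orientational_acf_decay(self):
        """⟨u(0)·u(t)⟩ of free rotors decays as exp(−2·D_r·t) within 10%."""
        d_rot = 0.2
        cfg = RotorEnsembleConfig(
            n_rotors=2000, d_rot=d_rot, dt=0.05, n_steps=1200, seed=21
        )
        s = simulate_ensemble(cfg, ZERO_FIELD)
        u = s.unit_vectors
        n_lag = 160
        acfs = [
            np.einsum("nij,ij->n", u[o:o + n_lag], u[o]) / cfg.n_rotors
            for o in range(0, len(u) - n_lag, 20)
        ]
        c = np.mean(acfs, axis=0)
        t = np.arange(n_lag) * cfg.dt
        mask = (t > 0) & (c > 0.05)
        slope = np.polyfit(t[mask], np.log(c[mask]), 1)[0]
        assert -1.0 / slope == pytest.approx(1.0 / (2 * d_rot), rel=0.10)


class TestEmitTrajectory:
    def _aligned_series(self, n, direction=(1.0, 0.0, 0.0)):
        u = np.tile(np.asarray(direction, float), (1, n, 1))
        return OrientationSeries(times=np.array([0.0]), unit_vectors=u)

    def test_single_rotor_recovers_mu(self):
        cfg = RotorEnsembleConfig(n_rotors=1, mu=2.3)
        traj, topo = emit_trajectory(self._aligned_series(1), cfg)
        mx = collective_dipole_component(traj.frame(0), topo, [0])
        assert mx == pytest.approx(2.3, rel=1e-6)

    def test_aligned_ensemble_is_additive(self):
        n = 12
        cfg = RotorEnsembleConfig(n_rotors=n, mu=2.3)
        traj, topo = emit_trajectory(self._aligned_series(n), cfg)
        mx = collective_dipole_component(traj.frame(0), topo, range(n))
        assert mx == pytest.approx(n * 2.3, rel=1e-6)

    def test_random_orientations_match_direct_sum(self):
        """Trajectory analysis recovers μ·Σu_x exactly; CLT bounds the total."""
        n = 500
        rng = np.random.default_rng(4)
        u = rng.standard_normal((1, n, 3))
        u /= np.linalg.norm(u, axis=-1, keepdims=True)
        series = OrientationSeries(times=np.array([0.0]), unit_vectors=u)
        cfg = RotorEnsembleConfig(n_rotors=n, mu=2.3)
        traj, topo = emit_trajectory(series, cfg)
        mx = collective_dipole_component(traj.frame(0), topo, range(n))
        direct = 2.3 * u[0, :, 0].sum()
        assert mx == pytest.approx(direct, rel=1e-6)
        assert abs(mx) <= 3 * 2.3 * np.sqrt(n / 3.0)

    def test_molecules_are_neutral_water_class(self):
        cfg = RotorEnsembleConfig(n_rotors=4, mu=1.85)
        _, topo = emit_trajectory(self._aligned_series(4), cfg)
        assert list(topo.mol_class) == ["water"] * 4
        for m in range(4):
            assert abs(topo.charges[topo.sites_of(m)].sum()) < 1e-12


class TestUniformWaterBox:
    def test_composition_and_neutrality(self):
        traj, topo = uniform_water_box(30, 25.0, seed=5)
        assert len(topo.molecules_of_class("water")) == 30
        assert len(topo.molecules_of_class("protein")) == 1
        assert traj.positions.shape == (1, 91, 3)

    def test_waters_fill_the_box(self):
        traj, topo = uniform_water_box(200, 30.0, seed=8)
        oxy = topo.water_oxygen_sites()
        pos = traj.positions[0, oxy]
        assert pos.min() >= 0 and pos.max() <= 30.0
        # occupancy spread over octants
        octant = (pos > 15.0).astype(int) @ np.array([1, 2, 4])
        assert len(np.unique(octant)) == 8
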