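import math

import numpy as np
import pytest

from electrosolv.bd import (SimulationConfig, Trajectory, UnstableTimestepError,
                            initialize_ensemble, run, stationarity_reached,
                            frame_potential_energy)
from electrosolv.constants import kBT
from electrosolv.potential import PairPotentialParams, params_from_minimum
from electrosolv.synth import SizeDistribution

KT = kBT()
K1 = 1e7
FREE = PairPotentialParams(A=0.0, B=0.0, kappa1=K1, kappa2=0.95 * K1)


def small_cfg(**kw):
    base = dict(box=(50e-6, 50e-6), n_particles=30, total_time=5.0,
                sample_interval=0.25, seed=3, placement_buffer=3.0 / K1)
    base.update(kw)
    return SimulationConfig(**base)


class TestInitialization:
    def test_particle_count_from_density(self):
        cfg = SimulationConfig(box=(200e-6, 200e-6), density=0.008e12)
        assert cfg.n == 320

    def test_zero_width_distribution_gives_equal_radii(self):
        cfg = small_cfg()
        ens = initialize_ensemble(cfg, SizeDistribution(2e-6, 0.0), seed=1)
        assert np.all(ens.radii == 1e-6)

    def test_no_overlaps(self):
        cfg = small_cfg(n_particles=60)
        ens = initialize_ensemble(cfg, SizeDistribution(3e-6, 0.03), seed=1)
        d = ens.positions[:, None, :] - ens.positions[None, :, :]
        for k, L in enumerate(cfg.box):
            d[..., k] -= L * np.rint(d[..., k] / L)
        r = np.hypot(d[..., 0], d[..., 1])
        contact = ens.radii[:, None] + ens.radii[None, :]
        iu = np.triu_indices(ens.n, 1)
        assert np.all(r[iu] >= contact[iu])

    def test_determinism(self):
        cfg = small_cfg()
        e1 = initialize_ensemble(cfg, SizeDistribution(2e-6, 0.05), seed=9)
        e2 = initialize_ensemble(cfg, SizeDistribution(2e-6, 0.05), seed=9)
        assert np.array_equal(e1.positions, e2.positions)
        assert np.array_equal(e1.radii, e2.radii)

    def test_overcrowded_box_raises(self):
        cfg = SimulationConfig(box=(10e-6, 10e-6), n_particles=40)
        with pytest.raises(RuntimeError, match="density too high"):
            initialize_ensemble(cfg, SizeDistribution(3e-6, 0.0), seed=0)


class TestIntegration:
    def test_seed_determinism_bit_identical(self):
        cfg = small_cfg()
        ens = initialize_ensemble(cfg, 1e-6, seed=3)
        t1 = run(ens, FREE, cfg)
        ens2 = initialize_ensemble(cfg, 1e-6, seed=3)
        t2 = run(ens2, FREE, cfg)
        assert np.array_equal(t1.frames, t2.frames)
        assert np.array_equal(t1.energy_per_particle, t2.energy_per_particle)

    def test_free_diffusion_displacement_variance(self):
        """Per-interval displacement variance equals 2 D dt per component."""
        cfg = small_cfg(box=(200e-6, 200e-6), n_particles=150, total_time=8.0,
                        sample_interval=0.5, dt=1e-3)
        ens = initialize_ensemble(cfg, 1e-6, seed=4)
        traj = run(ens, FREE, cfg)
        d = traj.frames[1:] - traj.frames[:-1]
        for k, L in enumerate(cfg.box):
            d[..., k] -= L * np.rint(d[..., k] / L)
        D = KT / (6 * math.pi * cfg.viscosity * 1e-6)
        expected = 2 * D * 0.5
        var = d.var()
        n = d.size
        sem = expected * math.sqrt(2.0 / n)
        assert abs(var - expected) < 3 * sem

    def test_com_has_no_systematic_drift(self):
        cfg = small_cfg(box=(200e-6, 200e-6), n_particles=100, total_time=10.0,
                        sample_interval=0.5, dt=1e-3)
        ens = initialize_ensemble(cfg, 1e-6, seed=5)
        traj = run(ens, FREE, cfg)
        d = traj.frames[1:] - traj.frames[:-1]
        for k, L in enumerate(cfg.box):
            d[..., k] -= L * np.rint(d[..., k] / L)
        com = d.mean(axis=1).sum(axis=0)       # net COM displacement
        D = KT / (6 * math.pi * cfg.viscosity * 1e-6)
        sd = math.sqrt(2 * D * 10.0 / 100)     # per component
        assert np.all(np.abs(com) < 4 * sd)

    def test_energy_trace_matches_from_scratch_recompute(self):
        p = params_from_minimum(-2 * KT, 300e-9, K1, 0.95 * K1)
        cfg = small_cfg(n_particles=40, total_time=3.0)
        ens = initialize_ensemble(cfg, 0.5e-6, seed=6)
        traj = run(ens, p, cfg)
        for i in (0, traj.n_frames // 2, traj.n_frames - 1):
            e = frame_potential_energy(traj.frames[i], traj.radii, traj.box,
                                       p, traj.cutoff)
            assert e == pytest.approx(traj.energy_per_particle[i],
                                      rel=1e-9, abs=1e-40)

    def test_unstable_timestep_raises(self):
        # a deep well with an absurdly large dt must be rejected
        p = params_from_minimum(-8 * KT, 300e-9, K1, 0.95 * K1)
        cfg = small_cfg(n_particles=30, dt=1.0, total_time=20.0,
                        sample_interval=5.0, placement_buffer=0.0)
        ens = initialize_ensemble(cfg, 0.5e-6, seed=7)
        with pytest.raises(UnstableTimestepError, match="reduce dt"):
            run(ens, p, cfg)

    def test_cutoff_must_fit_in_box(self):
        cfg = small_cfg(cutoff=30e-6)
        ens = initialize_ensemble(cfg, 1e-6, seed=3)
        with pytest.raises(ValueError, match="half the smallest box"):
            run(ens, FREE, cfg)


class TestStationarity:
    def make_traj(self, energies, dt=1.0):
        n = len(energies)
        frames = np.zeros((n, 2, 2))
        frames[:, 1, 0] = 10e-6
        return Trajectory(frames=frames, radii=np.array([1e-6, 1e-6]),
                          times=np.arange(n) * dt,
                          energy_per_particle=np.asarray(energies, float),
                          box=(50e-6, 50e-6), seed=0, dt=dt, cutoff=5e-6)

    def test_constant_trace_true_at_first_window(self):
        traj = self.make_traj(np.full(40, -1.5e-21))
        ok, onset = stationarity_reached(traj, window=5.0)
        assert ok and onset == 0.0

    def test_monotone_decreasing_trace_false(self):
        traj = self.make_traj(-1e-21 * np.arange(40.0))
        ok, onset = stationarity_reached(traj, window=5.0)
        assert not ok and onset is None

    def test_relaxation_then_plateau_finds_onset(self):
        rng = np.random.default_rng(0)
        e = np.concatenate([np.linspace(0, -3, 20),
                            -3 + 0.05 * rng.standard_normal(60)]) * 1e-21
        traj = self.make_traj(e)
        ok, onset = stationarity_reached(traj, window=10.0)
        assert ok
        assert 0 < onset <= 40.0
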