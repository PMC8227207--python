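import numpy as np
import pytest

from scmem import dynamics
from scmem.dynamics import (InstabilityError, SimulationConfig, langevin_run,
                            sample_bond_orientations, steered_pull)
from scmem.model import KB, PullProtocol
from scmem.potentials import GaussianZ, HarmonicZ, LinearZ, PotentialSpec
from conftest import make_trajectory

KBT = KB * 320.0


def free_start(n, rng, box=20.0):
    return make_trajectory(rng.uniform(-box / 2, box / 2, size=(1, n, 3)),
                           box=(box, box, box), species=["F"] * n)


class TestLangevin:
    def test_free_diffusion_obeys_einstein_relation(self, rng):
        # <|dr|^2> = 6 D tau for unconfined Brownian motion
        d_true, dt = 0.05, 0.1
        start = free_start(1000, rng)
        cfg = SimulationConfig(dt=dt, n_steps=200, seed=7,
                               diffusion={"F": d_true}, save_every=10,
                               periodic=False)
        traj = langevin_run(start, cfg)
        for lag in (5, 10, 20):
            dr = traj.coords[lag] - traj.coords[0]
            sq = (dr ** 2).sum(axis=1)
            tau = traj.times[lag] - traj.times[0]
            se = sq.std(ddof=1) / np.sqrt(len(sq))
            assert abs(sq.mean() - 6 * d_true * tau) < 3 * se

    def test_harmonic_tether_reaches_equipartition(self, rng):
        # stationary var(z) = kBT / k
        k = 10.0
        start = free_start(2000, rng, box=6.0)
        start.coords[..., 2] = 0.0
        cfg = SimulationConfig(dt=0.1, n_steps=3000, seed=3,
                               diffusion={"F": 0.05}, save_every=50,
                               periodic=False)
        pot = PotentialSpec([HarmonicZ(np.arange(2000), k, 0.0)])
        traj = langevin_run(start, cfg, pot)
        z = traj.coords[20:, :, 2]  # discard relaxation (tau = kBT/Dk ~ 5 ps)
        assert np.var(z) == pytest.approx(KBT / k, rel=0.05)

    def test_noiseless_relaxation_is_monotone(self):
        start = make_trajectory(np.array([[[0.0, 0.0, 1.0]]]),
                                species=["F"])
        cfg = SimulationConfig(dt=0.1, n_steps=700, seed=1,
                               diffusion={"F": 0.05}, save_every=1,
                               periodic=False, thermal_noise=False)
        pot = PotentialSpec([HarmonicZ([0], 5.0, 0.0)])
        traj = langevin_run(start, cfg, pot)
        z = traj.coords[:, 0, 2]
        assert np.all(np.diff(z) < 0) and z[-1] < 0.05

    def test_bitwise_determinism(self, rng):
        start = free_start(50, rng)
        cfg = SimulationConfig(dt=0.05, n_steps=100, seed=42,
                               diffusion={"F": 0.1})
        pot = PotentialSpec([HarmonicZ(np.arange(50), 2.0, 0.0)])
        a = langevin_run(start, cfg, pot)
        b = langevin_run(start, cfg, pot)
        assert np.array_equal(a.coords, b.coords)

    def test_frozen_species_do_not_move(self, rng):
        start = make_trajectory(rng.uniform(-1, 1, size=(1, 10, 3)),
                                species=["F"] * 5 + ["ROCK"] * 5)
        cfg = SimulationConfig(dt=0.05, n_steps=50, seed=2,
                               diffusion={"F": 0.1})
        traj = langevin_run(start, cfg)
        assert np.array_equal(traj.coords[-1, 5:], traj.coords[0, 5:])
        assert not np.array_equal(traj.coords[-1, :5], traj.coords[0, :5])

    def test_unstable_timestep_rejected(self, rng):
        start = free_start(5, rng)
        cfg = SimulationConfig(dt=1.0, n_steps=10, seed=1,
                               diffusion={"F": 0.1})
        pot = PotentialSpec([HarmonicZ(np.arange(5), 2000.0, 0.0)])
        with pytest.raises(ValueError, match="reduce dt"):
            langevin_run(start, cfg, pot)

    def test_per_axis_displacement_distribution(self, rng):
        # displacement over lag tau is Normal(0, 2 D tau) per axis
        d_true, lag_frames = 0.02, 10
        start = free_start(10000, rng, box=50.0)
        cfg = SimulationConfig(dt=0.1, n_steps=10 * lag_frames, seed=11,
                               diffusion={"F": d_true}, save_every=10,
                               periodic=False)
        traj = langevin_run(start, cfg)
        tau = traj.times[1] - traj.times[0]
        dx = np.diff(traj.coords[:, :, 0], axis=0).ravel()
        n = len(dx)
        var = 2 * d_true * tau
        assert abs(dx.mean()) < 3 * np.sqrt(var / n)
        assert np.var(dx) == pytest.approx(var, rel=3 * np.sqrt(2 / n) + 0.01)
        # excess kurtosis of a Gaussian is 0
        kurt = np.mean(dx ** 4) / np.var(dx) ** 2 - 3
        assert abs(kurt) < 0.1


class TestSteeredPull:
    def _tracer_start(self, n=1, z=0.0):
        coords = np.zeros((1, n, 3))
        coords[0, :, 2] = z
        return make_trajectory(coords, box=(10.0, 10.0, 10.0),
                               species=["LID"] * n)

    def test_flat_landscape_mean_force_vanishes(self):
        start = self._tracer_start(n=16, z=-2.0)
        cfg = SimulationConfig(dt=0.005, n_steps=40000, seed=5,
                               diffusion={"LID": 0.05}, save_every=10,
                               periodic=False)
        proto = PullProtocol(speed=1e-3, spring_k=2000.0, origin=-2.0,
                             direction=1)
        _, traces = steered_pull(start, cfg, None, proto,
                                 tracer_indices=np.arange(16))
        mean_f = np.mean([t.forces.mean() for t in traces])
        # residual drag is gamma*v = kBT/D * v ~ 0.05 kJ/mol/nm
        assert abs(mean_f) < 0.5

    def test_linear_ramp_mean_force_matches_slope(self):
        # quasi-static pull against U = s*z: <F> -> s (+ gamma*v drag)
        s = 5.0
        start = self._tracer_start(n=16, z=-2.0)
        cfg = SimulationConfig(dt=0.005, n_steps=40000, seed=6,
                               diffusion={"LID": 0.05}, save_every=10,
                               periodic=False)
        pot = PotentialSpec([LinearZ(np.arange(16), s)])
        proto = PullProtocol(speed=1e-3, spring_k=2000.0, origin=-2.0,
                             direction=1)
        traj, traces = steered_pull(start, cfg, pot, proto,
                                    tracer_indices=np.arange(16))
        mean_f = np.mean([t.forces.mean() for t in traces])
        assert mean_f == pytest.approx(s, abs=0.6)
        # stiff-spring mapping: the tracer tracks z_c with lag <F>/k
        zc = proto.center(traj.times)
        lag = (zc[:, None] - traj.coords[:, :16, 2]).mean()
        assert lag == pytest.approx(s / proto.spring_k, abs=0.6 / 2000)

    def test_trace_aligned_with_frames_and_deterministic(self):
        start = self._tracer_start()
        cfg = SimulationConfig(dt=0.01, n_steps=500, seed=9,
                               diffusion={"LID": 0.02}, save_every=5,
                               periodic=False)
        proto = PullProtocol(speed=1e-3, spring_k=500.0, origin=0.0,
                             direction=1, tracer=0)
        traj1, [tr1] = steered_pull(start, cfg, None, proto)
        traj2, [tr2] = steered_pull(start, cfg, None, proto)
        assert np.array_equal(tr1.forces, tr2.forces)
        assert np.array_equal(traj1.times, tr1.times)
        # recorded force equals k (z_c - z_tracer) at every saved frame
        zc = proto.center(tr1.times)
        expect = proto.spring_k * (zc - traj1.coords[:, 0, 2])
        assert np.allclose(tr1.forces, expect, atol=1e-10)

    def test_pull_exiting_nonperiodic_box_rejected(self):
        start = self._tracer_start()
        cfg = SimulationConfig(dt=0.01, n_steps=10 ** 6, seed=1,
                               diffusion={"LID": 0.02}, periodic=False)
        proto = PullProtocol(speed=1e-3, spring_k=500.0, origin=0.0,
                             direction=1, tracer=0)
        with pytest.raises(ValueError, match="exits"):
            steered_pull(start, cfg, None, proto)

    def test_missing_tracer_rejected(self):
        start = self._tracer_start()
        cfg = SimulationConfig(dt=0.01, n_steps=10, seed=1,
                               diffusion={"LID": 0.02})
        proto = PullProtocol(speed=1e-3, spring_k=500.0)
        with pytest.raises(ValueError, match="tracer"):
            steered_pull(start, cfg, None, proto)


class TestBondOrientations:
    def test_delta_parallel_bonds_have_no_lateral_component(self):
        traj = sample_bond_orientations("delta", 500, seed=1, theta=0.0)
        bonds = traj.coords[0, 1::2] - traj.coords[0, 0::2]
        assert np.abs(bonds[:, :2]).max() == 0.0
        assert np.allclose(bonds[:, 2], 0.47)

    def test_delta_in_plane_bonds_have_no_z_component(self):
        traj = sample_bond_orientations("delta", 500, seed=2,
                                        theta=np.pi / 2)
        bonds = traj.coords[0, 1::2] - traj.coords[0, 0::2]
        assert np.abs(bonds[:, 2]).max() < 1e-15

    def test_isotropic_cos2_moment(self):
        traj = sample_bond_orientations("isotropic", 10 ** 6, seed=3)
        bonds = traj.coords[0, 1::2] - traj.coords[0, 0::2]
        cos2 = bonds[:, 2] ** 2 / (bonds ** 2).sum(axis=1)
        assert cos2.mean() == pytest.approx(1 / 3, abs=0.002)

    def test_axial_concentration_increases_alignment(self):
        s = []
        for kappa in (1.0, 5.0, 50.0):
            traj = sample_bond_orientations("axial", 20000, seed=4,
                                            kappa=kappa)
            bonds = traj.coords[0, 1::2] - traj.coords[0, 0::2]
            cos2 = bonds[:, 2] ** 2 / (bonds ** 2).sum(axis=1)
            s.append(0.5 * (3 * cos2.mean() - 1))
        assert s[0] < s[1] < s[2] < 1.0

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ValueError, match="unknown distribution"):
            sample_bond_orientations("bogus", 10, seed=1)
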