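import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from scmem import pmf
from scmem.model import KCAL, ForceTrace, PullProtocol


def trace_from(forces, dt=1.0, speed=1e-3, origin=0.0, direction=1):
    forces = np.asarray(forces, dtype=float)
    times = np.arange(len(forces)) * dt
    proto = PullProtocol(speed=speed, spring_k=2000.0, origin=origin,
                         direction=direction)
    return ForceTrace(times, forces, proto)


class TestIntegrateWork:
    def test_constant_force_times_distance(self):
        # F = 10 kJ/mol/nm over 2 nm -> W = 20 kJ/mol
        n = 201
        trace = trace_from(np.full(n, 10.0), dt=10.0, speed=1e-3)
        z, w = pmf.integrate_work(trace)
        assert z[-1] == pytest.approx(2.0)
        assert w[-1] == pytest.approx(20.0, rel=1e-12)
        assert w[0] == 0.0

    def test_zero_force_zero_work(self):
        z, w = pmf.integrate_work(trace_from(np.zeros(10)))
        assert np.allclose(w, 0.0)

    def test_matches_independent_cumulative_trapezoid(self, rng):
        for _ in range(20):
            f = rng.normal(0, 5, size=10)
            direction = int(rng.choice([-1, 1]))
            trace = trace_from(f, dt=float(rng.uniform(0.5, 2.0)),
                               speed=2e-3, direction=direction)
            z, w = pmf.integrate_work(trace)
            oracle = cumulative_trapezoid(f, x=z, initial=0.0)
            assert np.allclose(w, oracle, atol=1e-13)

    def test_downward_pull_accumulates_positive_climb_work(self):
        # pulling toward -z with the tracer lagging above: F < 0, dz < 0
        trace = trace_from(np.full(11, -5.0), dt=10.0, speed=1e-3,
                           origin=2.0, direction=-1)
        z, w = pmf.integrate_work(trace)
        assert z[-1] < z[0]
        assert w[-1] == pytest.approx(0.5, rel=1e-12)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pmf.integrate_work(trace_from([1.0]))


class TestBinProfile:
    def test_samples_at_bin_centers_identity(self):
        z = np.array([0.025, 0.075, 0.125, 0.175])
        w = np.array([1.0, 2.0, 3.0, 4.0])
        prof = pmf.bin_profile(z, w, spacing=0.05)
        assert np.allclose(prof.w_kj, w)

    def test_bin_mean_of_two_samples(self):
        prof = pmf.bin_profile(np.array([0.01, 0.04]), np.array([1.0, 3.0]),
                               spacing=0.05)
        assert prof.w_kj[0] == pytest.approx(2.0)

    def test_dense_linear_samples_stay_linear(self):
        # symmetric samples per bin: bin means sit exactly on the line
        z = (np.arange(20000) + 0.5) * (2.0 / 20000)
        w = 3.0 * z + 1.0
        prof = pmf.bin_profile(z, w, spacing=0.05)
        assert np.allclose(prof.w_kj, 3.0 * prof.z + 1.0, atol=1e-9)

    def test_empty_interior_bin_interpolated_and_flagged(self):
        z = np.array([0.025, 0.075, 0.225])
        w = np.array([0.0, 1.0, 4.0])
        prof = pmf.bin_profile(z, w, spacing=0.05)
        assert prof.interpolated.sum() == 2
        # linear interpolation between 1.0 at z=0.075 and 4.0 at z=0.225
        assert prof.w_kj[2] == pytest.approx(2.0)
        assert prof.w_kj[3] == pytest.approx(3.0)

    def test_uniform_grid_enforced(self):
        with pytest.raises(ValueError, match="uniform"):
            pmf.PMFProfile(np.array([0.0, 0.1, 0.3]), np.zeros(3),
                           np.ones(3), np.zeros(3, dtype=bool))


class TestReferenceAndAverage:
    def _profile(self, values, z=None):
        values = np.asarray(values, dtype=float)
        if z is None:
            z = 0.05 * np.arange(len(values))
        return pmf.PMFProfile(z, values, np.ones(len(values)),
                              np.zeros(len(values), dtype=bool),
                              bulk_side="upper")

    def test_constant_offset_removed(self):
        p = self._profile(np.full(40, 5.0))
        out = pmf.reference_and_average([p])
        assert np.allclose(out.w_kj, 0.0, atol=1e-9)
        assert out.reference_region is not None

    def test_two_identical_profiles_average_to_either(self):
        p = self._profile(np.linspace(0, 3, 40))
        out = pmf.reference_and_average([p, p], reference_region=(1.9, 1.95))
        single = pmf.reference_and_average([p], reference_region=(1.9, 1.95))
        assert np.allclose(out.w_kj, single.w_kj)
        assert out.n_replicates == 2

    def test_kcal_conversion_constant(self):
        p = self._profile(np.full(10, 41.84))
        assert np.allclose(p.w_kcal, 10.0)

    def test_mismatched_grids_rejected(self):
        a = self._profile(np.zeros(10))
        b = self._profile(np.zeros(10), z=0.05 * np.arange(10) + 1.0)
        with pytest.raises(ValueError, match="grid"):
            pmf.reference_and_average([a, b])

    def test_unsampled_reference_region_rejected(self):
        p = self._profile(np.zeros(10))
        with pytest.raises(ValueError, match="reference region"):
            pmf.reference_and_average([p], reference_region=(5.0, 6.0))


class TestDescriptors:
    def _landscape_profile(self):
        z = np.arange(-0.5, 3.0, 0.05)
        barrier = 1.0 * np.exp(-((z - 1.0) ** 2) / (2 * 0.3 ** 2))
        well = -2.0 * np.exp(-(z ** 2) / (2 * 0.7 ** 2))
        w_kcal = barrier + well
        return pmf.PMFProfile(z, w_kcal * KCAL, np.ones_like(z),
                              np.zeros_like(z, dtype=bool),
                              bulk_side="upper"), w_kcal

    def test_constructed_barrier_and_well(self):
        prof, w_kcal = self._landscape_profile()
        desc = pmf.descriptors(prof, membrane_interior=(-0.5, 2.0))
        assert desc.global_min_depth == pytest.approx(w_kcal.min(), abs=1e-9)
        assert abs(desc.min_position) < 0.1
        # barrier: the local maximum between bulk and the minimum
        i_min = np.argmin(w_kcal)
        assert desc.entry_barrier == pytest.approx(w_kcal[i_min:].max(),
                                                   abs=1e-9)
        assert 0.9 < desc.barrier_position < 1.4

    def test_monotone_decreasing_profile_has_zero_barrier(self):
        z = np.arange(0.0, 2.0, 0.05)
        w = -z * KCAL  # decreasing toward... bulk at high z, falls inward
        prof = pmf.PMFProfile(z, w[::-1] - w[::-1][-1], np.ones_like(z),
                              np.zeros_like(z, dtype=bool), bulk_side="upper")
        desc = pmf.descriptors(prof, membrane_interior=(0.0, 1.0))
        assert desc.entry_barrier == pytest.approx(0.0, abs=1e-9)

    def test_interior_outside_grid_rejected(self):
        prof, _ = self._landscape_profile()
        with pytest.raises(ValueError, match="interior"):
            pmf.descriptors(prof, membrane_interior=(10.0, 12.0))

    def test_barrier_not_below_minimum(self):
        prof, _ = self._landscape_profile()
        desc = pmf.descriptors(prof, membrane_interior=(-0.5, 2.0))
        assert desc.global_min_depth <= desc.entry_barrier


class TestSymmetrize:
    def test_mirror_average_is_even(self):
        z = np.linspace(-2.0, 2.0, 81)
        w = z ** 3 + z ** 2  # odd + even parts
        prof = pmf.PMFProfile(z, w, np.ones_like(z),
                              np.zeros_like(z, dtype=bool))
        sym = pmf.symmetrize(prof)
        # the odd part cancels, leaving the even part
        assert np.allclose(sym.w_kj, z ** 2, atol=1e-9)


class TestFrictionBound:
    def test_linear_in_speed_and_range(self):
        assert pmf.friction_bias_bound(532.0, 1e-3, 3.0) == \
            pytest.approx(532.0 * 1e-3 * 3.0)

    def test_forward_backward_pulls_agree_within_dissipation(self):
        # symmetric barrier: opposite-direction pulls bracket the truth,
        # disagreeing by at most the dissipated work (plus noise)
        from scmem.model import KB, DEFAULT_TEMPERATURE
        from scmem.protocols import run_pull
        from scmem.potentials import GaussianZ

        d_tracer, v, reps = 0.005, 1e-3, 32
        landscape = GaussianZ(0, [2.0 * KCAL], [0.0], [0.5])
        gamma = KB * DEFAULT_TEMPERATURE / d_tracer
        profiles = {}
        for name, (z0, z1) in (("fwd", (-2.0, 2.0)), ("bwd", (2.0, -2.0))):
            traces = run_pull(seed=31, speed=v, n_replicates=reps,
                              d_tracer=d_tracer, dt=0.02, z_start=z0,
                              z_stop=z1, spring_k=2000.0,
                              landscape=landscape)
            parts = []
            for t in traces:
                z, w = pmf.integrate_work(t)
                parts.append(pmf.bin_profile(z, w, spacing=0.05))
            profiles[name] = pmf.reference_and_average(parts)
        f, b = profiles["fwd"], profiles["bwd"]
        assert np.allclose(f.z, b.z)
        bound = 2 * pmf.friction_bias_bound(gamma, v, 4.0)  # both biased
        noise = 4 * np.sqrt(2 * gamma * KB * DEFAULT_TEMPERATURE * v * 4.0
                            / reps)
        assert np.max(np.abs(f.w_kj - b.w_kj)) <= bound + noise
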