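import numpy as np
import pytest

from scmem import structure
from scmem.dynamics import PROBE_CHAINS, sample_bond_orientations
from conftest import make_trajectory


def leaflet_construction(rng, mean_z=1.2, sigma=0.15, n_per_leaflet=100,
                         n_frames=10, species="DPCE", bead="OH1",
                         box=(12.0, 12.0, 8.0)):
    n = 2 * n_per_leaflet
    signs = np.repeat([1.0, -1.0], n_per_leaflet)
    coords = np.empty((n_frames, n, 3))
    coords[:, :, :2] = rng.uniform(-5, 5, size=(n_frames, n, 2))
    coords[:, :, 2] = signs + 0.0
    coords[:, :, 2] = signs * mean_z + rng.normal(0, sigma, (n_frames, n))
    return make_trajectory(coords, box=box, species=[species] * n,
                           bead_names=[bead] * n)


class TestCentering:
    def test_shifted_slab_centered(self, rng):
        t = leaflet_construction(rng, n_frames=3)
        t.coords[..., 2] += 3.0
        c = structure.center_frames(t)
        assert np.allclose(c.coords[..., 2].mean(axis=1), 0.0, atol=1e-12)
        # xy untouched
        assert np.array_equal(c.coords[..., :2], t.coords[..., :2])

    def test_idempotent(self, rng):
        t = leaflet_construction(rng, n_frames=2)
        once = structure.center_frames(t)
        twice = structure.center_frames(once)
        assert np.allclose(once.coords, twice.coords, atol=1e-12)

    def test_centroid_matches_brute_force(self, rng):
        t = make_trajectory(rng.uniform(-4, 4, size=(5, 30, 3)))
        sel = np.zeros(30, dtype=bool)
        sel[:7] = True
        c = structure.center_frames(t, sel)
        for f in range(5):
            assert np.mean(c.coords[f, sel, 2]) == pytest.approx(0.0,
                                                                 abs=1e-12)

    def test_empty_selection_rejected(self, rng):
        t = make_trajectory(rng.uniform(-1, 1, size=(1, 4, 3)))
        with pytest.raises(ValueError, match="empty"):
            structure.center_frames(t, np.zeros(4, dtype=bool))


class TestLeaflets:
    def test_equal_split(self, rng):
        t = leaflet_construction(rng, sigma=0.0, n_frames=1)
        df = structure.assign_leaflets(t, {"DPCE": "OH1"})
        assert (df.leaflet == 1).sum() == 100
        assert (df.leaflet == -1).sum() == 100

    def test_all_upper(self, rng):
        t = leaflet_construction(rng, sigma=0.0, n_frames=1)
        t.coords[..., 2] = np.abs(t.coords[..., 2])
        df = structure.assign_leaflets(t, {"DPCE": "OH1"})
        assert (df.leaflet == 1).all()

    def test_z_flip_swaps_labels(self, rng):
        t = leaflet_construction(rng, n_frames=1)
        a = structure.assign_leaflets(t, {"DPCE": "OH1"})
        t.coords[..., 2] *= -1
        b = structure.assign_leaflets(t, {"DPCE": "OH1"})
        assert (a.leaflet == -b.leaflet).all()

    def test_missing_head_bead_rejected(self, rng):
        t = leaflet_construction(rng, n_frames=1)
        with pytest.raises(ValueError, match="head bead"):
            structure.assign_leaflets(t, {"DPCE": "NOPE"})


class TestDensityProfile:
    def test_uniform_gas_is_flat(self, rng):
        n = 10 ** 5
        box = (5.0, 5.0, 10.0)
        coords = rng.uniform(-0.5, 0.5, size=(1, n, 3)) * np.array(box)
        t = make_trajectory(coords, box=box, species=["W"] * n)
        prof = structure.density_profile(t, {"W": np.ones(n, dtype=bool)},
                                         bin_width=0.5)
        expected = n / (5.0 * 5.0 * 10.0)
        # Poisson noise per bin: sqrt(count)/V_bin
        per_bin = n / 20
        tol = 4 * np.sqrt(per_bin) / (0.5 * 25.0)
        assert np.all(np.abs(prof.values["W"] - expected) < tol)

    def test_conservation_exact_per_frame(self, rng):
        n = 777
        box = (4.0, 6.0, 9.0)
        coords = rng.uniform(-0.5, 0.5, size=(3, n, 3)) * np.array(box)
        t = make_trajectory(coords, box=box)
        prof = structure.density_profile(t, {"X": np.ones(n, dtype=bool)},
                                         bin_width=0.13)
        total = prof.values["X"].sum() * prof.bin_width * 4.0 * 6.0
        assert total == pytest.approx(n, rel=1e-12)

    def test_two_leaflet_modes_at_construction_means(self, rng):
        t = leaflet_construction(rng, mean_z=1.2, sigma=0.15,
                                 n_per_leaflet=500, n_frames=20)
        prof = structure.density_profile(
            t, {"DPCE": np.ones(t.n_beads, dtype=bool)}, bin_width=0.1)
        v = prof.values["DPCE"]
        upper = prof.z > 0
        z_up = prof.z[upper][np.argmax(v[upper])]
        z_lo = prof.z[~upper][np.argmax(v[~upper])]
        assert abs(z_up - 1.2) <= 0.1 + 1e-9
        assert abs(z_lo + 1.2) <= 0.1 + 1e-9

    def test_bin_width_larger_than_box_rejected(self, rng):
        t = make_trajectory(rng.uniform(-1, 1, (1, 5, 3)), box=(2, 2, 2))
        with pytest.raises(ValueError, match="exceeds box"):
            structure.density_profile(t, bin_width=5.0)


class TestInterleafletDistance:
    def test_point_mass_construction_exact(self, rng):
        t = leaflet_construction(rng, mean_z=1.239, sigma=0.0, n_frames=1)
        res = structure.interleaflet_distance(t, {"DPCE": "OH1"},
                                              tail_fraction=1.0)
        assert res.mean["DPCE"] == pytest.approx(24.78, abs=1e-12)

    def test_gaussian_construction_recovers_mean(self, rng):
        t = leaflet_construction(rng, mean_z=1.2, sigma=0.15,
                                 n_per_leaflet=100, n_frames=100)
        res = structure.interleaflet_distance(t, {"DPCE": "OH1"},
                                              tail_fraction=1.0)
        assert res.mean["DPCE"] == pytest.approx(24.0, abs=0.2)

    def test_z_inversion_invariance(self, rng):
        t = leaflet_construction(rng, n_frames=5)
        a = structure.interleaflet_distance(t, {"DPCE": "OH1"},
                                            tail_fraction=1.0)
        t.coords[..., 2] *= -1
        b = structure.interleaflet_distance(t, {"DPCE": "OH1"},
                                            tail_fraction=1.0)
        assert a.mean["DPCE"] == pytest.approx(b.mean["DPCE"], abs=1e-12)

    def test_empty_leaflet_names_component(self, rng):
        t = leaflet_construction(rng, sigma=0.0, n_frames=1)
        t.coords[..., 2] = np.abs(t.coords[..., 2])
        with pytest.raises(ValueError, match="DPCE"):
            structure.interleaflet_distance(t, {"DPCE": "OH1"},
                                            tail_fraction=1.0)

    def test_tail_fraction_selects_final_frames(self, rng):
        t = leaflet_construction(rng, sigma=0.0, n_frames=10)
        t.coords[:5, :, 2] *= 2.0  # early frames thicker
        res = structure.interleaflet_distance(t, {"DPCE": "OH1"},
                                              tail_fraction=0.5)
        assert res.mean["DPCE"] == pytest.approx(24.0, abs=1e-9)


class TestOrderParameters:
    def test_delta_grid_matches_closed_form(self):
        for deg in range(0, 181, 15):
            th = np.deg2rad(deg)
            traj = sample_bond_orientations("delta", 64, seed=deg, theta=th)
            s = structure.order_parameters(traj, PROBE_CHAINS).s(
                "PROBE", "tail", 0)
            assert s == pytest.approx(0.5 * (3 * np.cos(th) ** 2 - 1),
                                      abs=1e-12)

    def test_parallel_and_inplane_limits_exact(self):
        up = sample_bond_orientations("delta", 100, seed=1, theta=0.0)
        assert structure.order_parameters(up, PROBE_CHAINS).s(
            "PROBE", "tail", 0) == 1.0
        flat = sample_bond_orientations("delta", 100, seed=2,
                                        theta=np.pi / 2)
        assert structure.order_parameters(flat, PROBE_CHAINS).s(
            "PROBE", "tail", 0) == -0.5

    def test_xy_translation_invariance(self, rng):
        traj = sample_bond_orientations("axial", 200, seed=3, kappa=3.0)
        a = structure.order_parameters(traj, PROBE_CHAINS).s("PROBE", "tail", 0)
        traj.coords[..., :2] += rng.uniform(-3, 3, size=2)
        b = structure.order_parameters(traj, PROBE_CHAINS).s("PROBE", "tail", 0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_z_inversion_invariance(self):
        traj = sample_bond_orientations("axial", 200, seed=4, kappa=3.0)
        a = structure.order_parameters(traj, PROBE_CHAINS).s("PROBE", "tail", 0)
        traj.coords[..., 2] *= -1
        b = structure.order_parameters(traj, PROBE_CHAINS).s("PROBE", "tail", 0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_wrapped_bonds_use_minimum_image(self):
        # a bond crossing the boundary must not be measured across the box
        box = 4.0
        coords = np.array([[[0.0, 0.0, 1.9], [0.0, 0.0, -1.9]]])
        t = make_trajectory(coords, box=(box, box, box),
                            species=["PROBE"] * 2, bead_names=["B1", "B2"],
                            molecule_index=[1, 1])
        s = structure.order_parameters(t, PROBE_CHAINS).s("PROBE", "tail", 0)
        assert s == 1.0  # true bond is 0.2 nm along z through the boundary

    def test_zero_length_bonds_excluded_with_count(self):
        coords = np.zeros((1, 4, 3))
        coords[0, 1, 2] = 0.47  # one good bond, one degenerate
        t = make_trajectory(coords, species=["PROBE"] * 4,
                            bead_names=["B1", "B2", "B1", "B2"],
                            molecule_index=[1, 1, 2, 2])
        res = structure.order_parameters(t, PROBE_CHAINS)
        assert res.n_excluded == 1
        assert res.s("PROBE", "tail", 0) == 1.0

    def test_all_zero_length_raises(self):
        t = make_trajectory(np.zeros((1, 2, 3)), species=["PROBE"] * 2,
                            bead_names=["B1", "B2"], molecule_index=[1, 1])
        with pytest.raises(ValueError, match="zero length"):
            structure.order_parameters(t, PROBE_CHAINS)

    def test_isotropic_large_sample_near_zero(self):
        traj = sample_bond_orientations("isotropic", 10 ** 5, seed=5)
        s = structure.order_parameters(traj, PROBE_CHAINS).s("PROBE", "tail", 0)
        assert abs(s) < 0.01
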