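"""End-to-end validation experiments on synthetic ground truth.

The headline observables of microsecond coarse-grained SC simulations
(interleaflet distances, chain order, lateral diffusion, permeation PMFs)
cannot be recomputed at desk scale, so each analysis stage is validated
against Brownian-dynamics synthetic data whose ground truth is exact by
construction.  This module packages those experiments so the test suite,
the acceptance script and the examples all run the same protocols.

Problem sizes are scaled-down study conditions chosen once (see the
methods note): 500 molecules x 5000 frames for diffusion recovery, and a
2.5e-4 nm/ps base pull speed with 8 replicates for PMF recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import builder, diffusion, dynamics, pmf, structure
from .model import (KB, KCAL, BeadLabels, DEFAULT_TEMPERATURE, PullProtocol,
                    Trajectory)
from .potentials import GaussianZ, PotentialSpec

# ---------------------------------------------------------------------------
# Composition arithmetic of the four model systems
# ---------------------------------------------------------------------------

def table_compositions() -> dict[str, dict]:
    """Species count tables of the four SC model systems.

    625 lipids at 1:1:1 (CHOL/DPCE/BCN), the LA systems at 18:18:18:5, and
    solvent either pure polarizable water or the 50% molar ethanol mix.
    Ion counts are the explicit values of the model systems.
    """
    systems = {
        "SC": builder.CompositionSpec((1, 1, 1), 625, 21740, 0.0, (397, 81)),
        "SC+LA": builder.CompositionSpec((18, 18, 18, 5), 625, 21729, 0.0,
                                         (419, 59)),
        "SC+EtOH": builder.CompositionSpec((1, 1, 1), 625, 21740, 0.5,
                                           (397, 81)),
        "SC+LA+EtOH": builder.CompositionSpec((18, 18, 18, 5), 625, 21740,
                                              0.5, (419, 59)),
    }
    return {name: builder.compose_system(spec).summary()
            for name, spec in systems.items()}


# ---------------------------------------------------------------------------
# Order parameters
# ---------------------------------------------------------------------------

def order_parameter_checks(seed: int = 0, n_isotropic: int = 10 ** 6,
                           theta_grid: np.ndarray | None = None) -> dict:
    """P2 estimator vs closed form on delta and isotropic bond ensembles."""
    if theta_grid is None:
        theta_grid = np.deg2rad(np.arange(0.0, 181.0, 15.0))
    s_parallel = _delta_s(0.0, 1000, seed)
    s_inplane = _delta_s(np.pi / 2, 1000, seed + 1)
    iso = dynamics.sample_bond_orientations("isotropic", n_isotropic,
                                            seed=seed + 2)
    s_iso = structure.order_parameters(iso, dynamics.PROBE_CHAINS).s(
        "PROBE", "tail", 0)
    max_err = 0.0
    for i, th in enumerate(theta_grid):
        s_hat = _delta_s(float(th), 64, seed + 3 + i)
        s_true = 0.5 * (3.0 * np.cos(th) ** 2 - 1.0)
        max_err = max(max_err, abs(s_hat - s_true))
    return {"s_parallel": s_parallel, "s_inplane": s_inplane,
            "s_isotropic": s_iso, "delta_grid_max_error": max_err,
            "n_isotropic": n_isotropic}


def _delta_s(theta: float, n: int, seed: int) -> float:
    traj = dynamics.sample_bond_orientations("delta", n, seed=seed, theta=theta)
    return structure.order_parameters(traj, dynamics.PROBE_CHAINS).s(
        "PROBE", "tail", 0)


# ---------------------------------------------------------------------------
# Diffusion recovery
# ---------------------------------------------------------------------------

def free_diffusion_trajectory(d_true: float, n_molecules: int, n_frames: int,
                              seed: int, frame_interval: float = 1.0,
                              save_every: int = 10,
                              box_length: float = 10.0) -> Trajectory:
    """Brownian free diffusion of single-bead molecules in a periodic box."""
    labels = BeadLabels(
        np.repeat(np.array(["TRC"], dtype=object), n_molecules),
        np.arange(1, n_molecules + 1),
        np.repeat(np.array(["T"], dtype=object), n_molecules))
    rng = np.random.default_rng(seed)
    box = np.array([box_length, box_length, box_length])
    coords = rng.uniform(-box_length / 2, box_length / 2,
                         size=(1, n_molecules, 3))
    start = Trajectory(np.array([0.0]), box[None, :], coords, labels)
    cfg = dynamics.SimulationConfig(
        dt=frame_interval / save_every, n_steps=(n_frames - 1) * save_every,
        seed=seed, diffusion={"TRC": d_true}, save_every=save_every,
        periodic=True)
    return dynamics.langevin_run(start, cfg)


def diffusion_recovery(d_true: float, seed: int, n_molecules: int = 500,
                       n_frames: int = 5000,
                       max_lag_fraction: float = 0.1) -> dict:
    """Simulate free lateral diffusion at known D and re-estimate it.

    Runs the full pipeline: periodic Brownian trajectory -> lateral
    unwrapping -> drift-removed MSD -> windowed linear fit.  The recovery
    study restricts lags to 10% of the run: the variance of time-averaged
    MSD grows with lag/T, so short lags carry nearly all the information.
    """
    traj = free_diffusion_trajectory(d_true, n_molecules, n_frames, seed)
    unwrapped = diffusion.unwrap_lateral(traj)
    msd = diffusion.compute_msd(unwrapped, "TRC", max_lag_fraction=max_lag_fraction)
    est = diffusion.fit_diffusion(msd)
    return {"d_true": d_true, "d_fit": est.d_mean,
            "rel_error": abs(est.d_mean - d_true) / d_true,
            "d_sd": est.d_sd, "nonlinear": est.nonlinear,
            "n_molecules": n_molecules, "n_frames": n_frames}


# ---------------------------------------------------------------------------
# Thickness
# ---------------------------------------------------------------------------

def gaussian_leaflet_trajectory(mean_z: float = 1.2, sigma: float = 0.15,
                                n_per_leaflet: int = 100, n_frames: int = 100,
                                seed: int = 0) -> Trajectory:
    """Head beads scattered Gaussian about +/- mean_z, as a DPCE stand-in."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_leaflet
    labels = BeadLabels(
        np.repeat(np.array(["DPCE"], dtype=object), n),
        np.arange(1, n + 1),
        np.repeat(np.array(["OH1"], dtype=object), n))
    box = np.array([15.0, 15.0, 8.0])
    signs = np.repeat([1.0, -1.0], n_per_leaflet)
    coords = np.empty((n_frames, n, 3))
    coords[:, :, 0] = rng.uniform(-7.5, 7.5, size=(n_frames, n))
    coords[:, :, 1] = rng.uniform(-7.5, 7.5, size=(n_frames, n))
    coords[:, :, 2] = signs[None, :] * mean_z + rng.normal(
        0.0, sigma, size=(n_frames, n))
    times = np.arange(n_frames, dtype=float)
    return Trajectory(times, np.repeat(box[None, :], n_frames, axis=0),
                      coords, labels)


def thickness_checks(seed: int = 0) -> dict:
    """Interleaflet distance on constructions with known separation."""
    gauss = gaussian_leaflet_trajectory(seed=seed)
    res = structure.interleaflet_distance(gauss, tail_fraction=1.0)
    # point-mass construction at +/- 1.239 nm -> 24.78 angstrom exactly
    point = gaussian_leaflet_trajectory(mean_z=1.239, sigma=0.0,
                                        n_per_leaflet=10, n_frames=1,
                                        seed=seed)
    res_point = structure.interleaflet_distance(point, tail_fraction=1.0)
    return {"gaussian_A": res.mean["DPCE"], "gaussian_sd_A": res.sd["DPCE"],
            "point_A": res_point.mean["DPCE"]}


# ---------------------------------------------------------------------------
# PMF recovery
# ---------------------------------------------------------------------------

def lidocaine_test_potential(indices=0) -> GaussianZ:
    """Analytic permeation landscape used for PMF validation.

    A 1.0 kcal/mol Gaussian barrier at z = 1.0 nm (width 0.3 nm) over a
    -2.0 kcal/mol Gaussian well at the membrane center (width 0.7 nm) —
    the entry-barrier-plus-interior-minimum shape of a permeant PMF.
    """
    return GaussianZ(indices, heights=[1.0 * KCAL, -2.0 * KCAL],
                     centers=[1.0, 0.0], widths=[0.3, 0.7])


@dataclass
class PullStudy:
    """Result of one pull-speed condition of the PMF recovery study."""

    speed: float
    profile: pmf.PMFProfile
    rmsd_kcal: float
    descriptors: pmf.PMFDescriptors


def pmf_recovery(seed: int, speeds: tuple[float, ...] = (2e-3, 1e-3, 5e-4),
                 n_replicates: int = 64, d_tracer: float = 0.005,
                 dt: float = 0.02, z_start: float = 2.5,
                 z_stop: float = -0.5, spring_k: float = 2000.0,
                 grid_spacing: float = 0.05,
                 interior: tuple[float, float] = (-0.5, 2.0),
                 equal_compute: bool = True) -> dict:
    """Recover a known U(z) from steered pulls at a ladder of speeds.

    For each speed, independent Brownian tracers are pulled from bulk
    (z_start) through the landscape; their work profiles are binned,
    bulk-anchored and averaged, and compared with the true potential
    (RMSD in kcal/mol, plus barrier/minimum descriptors).

    ``n_replicates`` applies to the slowest speed; with ``equal_compute``
    faster rungs get proportionally more replicates (same number of
    integrator steps per rung).  This equalizes the stochastic work noise
    of the averaged profile across the ladder — the replicate-mean noise
    scales as sqrt(v / R) — so the speed dependence that remains is the
    friction bias, the quantity the ladder probes.
    """
    results: list[PullStudy] = []
    u_term = lidocaine_test_potential()
    v_min = min(speeds)
    for i, speed in enumerate(sorted(speeds, reverse=True)):
        reps = n_replicates * (int(round(speed / v_min)) if equal_compute else 1)
        profile = _pull_once(seed + 1000 * i, speed, reps, d_tracer,
                             dt, z_start, z_stop, spring_k, grid_spacing)
        u_true_kcal = np.asarray(u_term.potential(profile.z)) / KCAL
        lo, hi = profile.reference_region
        m = (profile.z >= lo - 1e-12) & (profile.z <= hi + 1e-12)
        u_true_kcal = u_true_kcal - u_true_kcal[m].mean()
        results.append(PullStudy(
            speed, profile, pmf.rmsd(profile, u_true_kcal),
            pmf.descriptors(profile, interior)))

    # ground-truth descriptors from the analytic landscape on a dense grid
    zg = np.arange(z_stop, z_start + 1e-9, grid_spacing / 10)
    ug = np.asarray(u_term.potential(zg)) / KCAL
    true_prof = pmf.PMFProfile(zg, ug * KCAL, np.ones_like(zg),
                               np.zeros_like(zg, dtype=bool),
                               bulk_side="upper")
    true_desc = pmf.descriptors(true_prof, interior)
    gamma = KB * DEFAULT_TEMPERATURE / d_tracer
    slowest = results[-1]
    return {
        "speeds": [r.speed for r in results],
        "rmsd_kcal": [r.rmsd_kcal for r in results],
        "profile": slowest.profile,
        "descriptors": slowest.descriptors,
        "true_descriptors": true_desc,
        "barrier_error_kcal": abs(slowest.descriptors.entry_barrier
                                  - true_desc.entry_barrier),
        "depth_error_kcal": abs(slowest.descriptors.global_min_depth
                                - true_desc.global_min_depth),
        "friction_bound_kJ": pmf.friction_bias_bound(
            gamma, slowest.speed, abs(z_start - z_stop)),
        "n_replicates": n_replicates,
    }


def run_pull(seed: int, speed: float, n_replicates: int, d_tracer: float,
             dt: float, z_start: float, z_stop: float, spring_k: float,
             landscape: GaussianZ | None = None,
             save_every: int = 10) -> list:
    """Steered pulls of independent Brownian tracers through a landscape.

    Returns one :class:`~scmem.model.ForceTrace` per replicate; replicates
    run as non-interacting tracers inside a single integration.
    """
    labels = BeadLabels(
        np.repeat(np.array(["LID"], dtype=object), n_replicates),
        np.arange(1, n_replicates + 1),
        np.repeat(np.array(["LID"], dtype=object), n_replicates))
    coords = np.zeros((1, n_replicates, 3))
    coords[0, :, 0] = np.arange(n_replicates) * 2.0 - n_replicates
    coords[0, :, 2] = z_start
    span = 2 * max(abs(z_start), abs(z_stop)) + 2.0
    box = np.array([max(4.0, 2.0 * n_replicates + 2), 4.0, span])
    start = Trajectory(np.array([0.0]), box[None, :], coords, labels)
    n_steps = int(round(abs(z_start - z_stop) / (speed * dt)))
    cfg = dynamics.SimulationConfig(dt=dt, n_steps=n_steps, seed=seed,
                                    diffusion={"LID": d_tracer},
                                    save_every=save_every, periodic=False)
    protocol = PullProtocol(speed=speed, spring_k=spring_k, origin=z_start,
                            direction=-1 if z_stop < z_start else 1)
    potential = PotentialSpec()
    if landscape is not None:
        potential.add(GaussianZ(np.arange(n_replicates), landscape.heights,
                                landscape.centers, landscape.widths))
    _, traces = dynamics.steered_pull(start, cfg, potential, protocol,
                                      tracer_indices=np.arange(n_replicates))
    return traces


def _pull_once(seed, speed, n_replicates, d_tracer, dt, z_start, z_stop,
               spring_k, grid_spacing) -> pmf.PMFProfile:
    traces = run_pull(seed, speed, n_replicates, d_tracer, dt, z_start,
                      z_stop, spring_k, landscape=lidocaine_test_potential())
    profiles = []
    for trace in traces:
        z, w = pmf.integrate_work(trace)
        profiles.append(pmf.bin_profile(z, w, spacing=grid_spacing))
    return pmf.reference_and_average(profiles)


# ---------------------------------------------------------------------------
# Density conservation
# ---------------------------------------------------------------------------

def density_conservation_check(seed: int = 0, n_beads: int = 2000,
                               n_frames: int = 5) -> dict:
    """Max relative error of sum(rho * V_bin) vs bead count per component."""
    rng = np.random.default_rng(seed)
    box = np.array([6.0, 6.0, 9.0])
    half = n_beads // 2
    labels = BeadLabels(
        np.array(["A"] * half + ["B"] * (n_beads - half), dtype=object),
        np.arange(1, n_beads + 1),
        np.array(["X"] * n_beads, dtype=object))
    coords = rng.uniform(-0.5, 0.5, size=(n_frames, n_beads, 3)) * box
    traj = Trajectory(np.arange(n_frames, dtype=float),
                      np.repeat(box[None, :], n_frames, axis=0), coords, labels)
    prof = structure.density_profile(
        traj, {"A": labels.mask(species="A"), "B": labels.mask(species="B")},
        bin_width=0.1)
    bin_volume = prof.bin_width * box[0] * box[1]
    errs = {}
    for name, count in (("A", half), ("B", n_beads - half)):
        total = prof.values[name].sum() * bin_volume
        errs[name] = abs(total - count) / count
    return {"max_rel_error": max(errs.values()), "per_component": errs}
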