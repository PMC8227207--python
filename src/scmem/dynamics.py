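"""Overdamped Langevin (Brownian dynamics) trajectory generator.

The integrator is Euler–Maruyama on the position Langevin equation

    x <- x + (D / kB T) F(x) dt + sqrt(2 D dt) xi,      xi ~ N(0, 1)

with a per-bead diffusion constant D (nm^2/ps).  Inertia, thermostats and
pairwise nonbonded forces are deliberately absent: the analyses under test
consume positions and pull forces only, and this way the ground truth
(diffusion constants, external free-energy profile, bond-orientation law)
is exact by construction.

Beads of species without a configured diffusion constant are frozen.  One
RNG stream drives the noise in bead-major order; a seed is mandatory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import (KB, BeadLabels, DEFAULT_TEMPERATURE, ForceTrace,
                    PullProtocol, Trajectory, wrap_coords)
from .potentials import GaussianZ, PotentialSpec


class InstabilityError(RuntimeError):
    """The integrator produced a non-physical step; reduce dt."""


@dataclass
class SimulationConfig:
    """Parameters of one Brownian-dynamics run.

    ``diffusion`` maps species name to D in nm^2/ps; species absent from the
    map are frozen in place (used for tether-free scaffold beads).
    """

    dt: float                       # ps
    n_steps: int
    seed: int                       # mandatory: no wall-clock default
    diffusion: Mapping[str, float] = field(default_factory=dict)
    temperature: float = DEFAULT_TEMPERATURE  # K
    save_every: int = 10
    box: Sequence[float] | None = None        # taken from the start frame if None
    periodic: bool = True
    thermal_noise: bool = True  # False: pure gradient descent (debug/oracle runs)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.save_every < 1:
            raise ValueError("save_every must be >= 1")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        for s, d in self.diffusion.items():
            if d <= 0:
                raise ValueError(f"diffusion constant for {s} must be > 0")

    @property
    def kbt(self) -> float:
        return KB * self.temperature


def bead_diffusion(labels: BeadLabels, diffusion: Mapping[str, float]) -> np.ndarray:
    """Per-bead diffusion constants; 0 marks a frozen bead."""
    d = np.zeros(len(labels))
    species = labels.species.astype(str)
    for name, value in diffusion.items():
        d[species == name] = value
    return d


def _validate_timestep(config: SimulationConfig, potential: PotentialSpec,
                       d_max: float, extra_stiffness: float = 0.0) -> None:
    """Reject timesteps that would make the stiffest mode unstable.

    For a harmonic mode of stiffness k the Euler–Maruyama damping factor is
    (1 - a) with a = D k dt / kBT; a > ~0.5 is strongly biased and a > 2
    diverges.  Gaussian profile terms additionally require the step length
    to resolve the smallest width w: D dt <= (0.1 w)^2.
    """
    if d_max == 0:
        return
    k_max = max(potential.max_stiffness(), extra_stiffness)
    if k_max > 0:
        a = d_max * k_max * config.dt / config.kbt
        if a > 0.5:
            raise ValueError(
                f"dt too large for stiffness {k_max:.3g} kJ/mol/nm^2: "
                f"D*k*dt/kBT = {a:.3f} > 0.5; reduce dt below "
                f"{0.5 * config.kbt / (d_max * k_max):.2e} ps")
    w = potential.min_length_scale()
    if w is not None and d_max * config.dt > (0.1 * w) ** 2:
        raise ValueError(
            f"dt too large to resolve profile width {w:.3g} nm: require "
            f"D*dt <= {(0.1 * w) ** 2:.3g} nm^2")


def langevin_run(start: Trajectory, config: SimulationConfig,
                 potential: PotentialSpec | None = None,
                 frame: int = 0) -> Trajectory:
    """Integrate a frame forward, saving every ``save_every`` steps.

    The returned trajectory begins with the starting frame and is
    bitwise-deterministic for a fixed (seed, config, potential).
    """
    traj, _ = _integrate(start, config, potential, frame=frame)
    return traj


def steered_pull(start: Trajectory, config: SimulationConfig,
                 potential: PotentialSpec | None,
                 protocol: PullProtocol,
                 tracer_indices: Sequence[int] | int | None = None,
                 frame: int = 0) -> tuple[Trajectory, list[ForceTrace]]:
    """Constant-velocity harmonic pull of tracer bead(s) along z.

    The spring center moves as z_c(t) = z0 + direction*v*t; each tracer
    feels F = k (z_c - z) along z and the instantaneous force is recorded
    at every saved frame, time-aligned with the trajectory.  Multiple
    tracer indices run as independent replicates in one integration (they
    do not interact).  Returns the trajectory and one trace per tracer.
    """
    if tracer_indices is None:
        if protocol.tracer is None:
            raise ValueError("no tracer: set protocol.tracer or tracer_indices")
        tracer_indices = [protocol.tracer]
    elif np.isscalar(tracer_indices):
        tracer_indices = [int(tracer_indices)]
    tracer_indices = list(tracer_indices)
    if not tracer_indices:
        raise ValueError("tracer_indices is empty")
    n = start.n_beads
    for t_i in tracer_indices:
        if not 0 <= t_i < n:
            raise ValueError(f"tracer index {t_i} outside 0..{n - 1}")
    box = np.asarray(config.box if config.box is not None
                     else start.boxes[frame], dtype=float)
    total_time = config.n_steps * config.dt
    z_end = protocol.center(total_time)
    if not config.periodic:
        half = box[2] / 2
        if not (-half <= protocol.origin <= half and -half <= z_end <= half):
            raise ValueError(
                f"pulled range [{protocol.origin:.2f}, {z_end:.2f}] nm exits "
                f"the non-periodic box (|z| <= {half:.2f} nm)")
    traj, forces = _integrate(start, config, potential, frame=frame,
                              protocol=protocol, tracers=tracer_indices)
    traces = [ForceTrace(traj.times.copy(), forces[:, k], protocol)
              for k in range(len(tracer_indices))]
    return traj, traces


def _integrate(start, config, potential, frame=0, protocol=None, tracers=None):
    labels = start.labels
    x = start.coords[frame].copy()
    t0 = float(start.times[frame])
    box = np.asarray(config.box if config.box is not None
                     else start.boxes[frame], dtype=float)
    potential = potential if potential is not None else PotentialSpec()
    d = bead_diffusion(labels, config.diffusion)
    if tracers is not None and np.any(d[np.asarray(tracers)] == 0):
        raise ValueError("pulled tracer bead has no diffusion constant")
    _validate_timestep(config, potential, float(d.max(initial=0.0)),
                       extra_stiffness=protocol.spring_k if protocol else 0.0)
    mobile = d > 0
    kbt = config.kbt
    drift_c = (d * config.dt / kbt)[:, None]
    noise_c = np.sqrt(2.0 * d * config.dt)[:, None]
    rng = np.random.default_rng(config.seed)
    half_min_box = float(box.min()) / 2

    n_saved = config.n_steps // config.save_every + 1
    times = np.empty(n_saved)
    frames = np.empty((n_saved, len(labels), 3))
    pull_f = np.empty((n_saved, len(tracers))) if tracers is not None else None
    tr = np.asarray(tracers, dtype=np.int64) if tracers is not None else None

    def record(slot, step):
        t = t0 + step * config.dt
        times[slot] = t
        frames[slot] = x
        if tr is not None:
            zc = protocol.center(step * config.dt)
            pull_f[slot] = protocol.spring_k * (zc - z_tr)

    # Track tracer z unwrapped so the spring force is well defined under PBC.
    if tr is not None:
        z_tr = x[tr, 2].copy()
    slot = 0
    record(slot, 0)
    slot += 1
    for step in range(1, config.n_steps + 1):
        f = potential.forces(x, box)
        if tr is not None:
            zc = protocol.center((step - 1) * config.dt)
            f[tr, 2] += protocol.spring_k * (zc - z_tr)
        if config.thermal_noise:
            disp = drift_c * f + noise_c * rng.standard_normal(x.shape)
        else:
            disp = drift_c * f
        disp[~mobile] = 0.0
        m = float(np.max(np.abs(disp)))
        if m > half_min_box:
            raise InstabilityError(
                f"step {step}: displacement {m:.3g} nm exceeds half the "
                f"smallest box length; reduce dt")
        if tr is not None:
            z_tr = z_tr + disp[tr, 2]
        x += disp
        if config.periodic:
            x = wrap_coords(x, box)
        if step % config.save_every == 0:
            record(slot, step)
            slot += 1
    traj = Trajectory(times[:slot], np.repeat(box[None, :], slot, axis=0),
                      frames[:slot], labels,
                      unwrapped=not config.periodic)
    return traj, (pull_f[:slot] if pull_f is not None else None)


# ---------------------------------------------------------------------------
# Synthetic chain-orientation sampler
# ---------------------------------------------------------------------------

def sample_bond_orientations(distribution: str, n: int, seed: int | None = None,
                             *, theta: float | None = None,
                             kappa: float | None = None,
                             bond_length: float = 0.47,
                             species: str = "PROBE") -> Trajectory:
    """Generate ``n`` two-bead probe molecules with prescribed bond vectors.

    ``distribution`` is one of:

    - ``"delta"``: every bond at polar angle ``theta`` (radians) from the
      z axis, azimuth uniform;
    - ``"isotropic"``: bond directions uniform on the sphere;
    - ``"axial"``: von Mises–Fisher about +z with concentration ``kappa``.

    Returns a single-frame trajectory whose species carries one chain
    ("tail", beads B1-B2) suitable for the order-parameter analysis.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if distribution == "delta":
        if theta is None:
            raise ValueError("delta distribution requires theta")
        cos_t = np.full(n, math.cos(theta))
    elif distribution == "isotropic":
        cos_t = rng.uniform(-1.0, 1.0, size=n)
    elif distribution == "axial":
        if kappa is None or kappa <= 0:
            raise ValueError("axial distribution requires kappa > 0")
        # Inverse-CDF sampling of the vMF polar angle about +z.
        u = rng.uniform(size=n)
        cos_t = 1.0 + np.log(u + (1 - u) * np.exp(-2 * kappa)) / kappa
    else:
        raise ValueError(f"unknown distribution {distribution!r}; expected "
                         "'delta', 'isotropic' or 'axial'")
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 0.0, None))
    bonds = bond_length * np.column_stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])

    # Base beads on a cubic grid in a box large enough to avoid wrap effects.
    per_side = int(np.ceil(n ** (1 / 3)))
    spacing = 2.0 * bond_length + 0.5
    g = np.arange(per_side) * spacing
    gx, gy, gz = np.meshgrid(g, g, g, indexing="ij")
    base = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])[:n]
    box_len = per_side * spacing + 2 * spacing
    base -= box_len / 2 - spacing  # keep everything inside the centered box

    coords = np.empty((2 * n, 3))
    coords[0::2] = base
    coords[1::2] = base + bonds
    labels = BeadLabels(
        np.repeat(np.array([species], dtype=object), 2 * n),
        np.repeat(np.arange(1, n + 1), 2),
        np.tile(np.array(["B1", "B2"], dtype=object), n))
    box = np.array([box_len, box_len, box_len])
    return Trajectory(np.array([0.0]), box[None, :], coords[None, :, :], labels)


#: Chain definition matching :func:`sample_bond_orientations` output.
PROBE_CHAINS = {"PROBE": {"tail": ("B1", "B2")}}
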