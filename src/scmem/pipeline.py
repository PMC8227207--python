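"""Configuration-driven pipeline tying the stages together.

A run configuration is a single YAML file with one block per stage
(``build``, ``simulate``, ``density``, ``thickness``, ``order``,
``diffusion``, ``pmf``) plus a global ``seed`` and ``output_dir``.  Every
present block is validated before any stage runs; stages then execute in
dependency order, each writing CSV/JSON artifacts plus a manifest
(inputs, parameters, package version, seed, wall time, row counts).

CSV outputs use a fixed float format, so a rerun with the same config and
seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__, builder, diffusion, dynamics, io, pmf, protocols, structure
from .model import KCAL, PullProtocol, Trajectory
from .potentials import Bonds, GaussianZ, HarmonicZ, PotentialSpec

logger = logging.getLogger("scmem.pipeline")

STAGE_ORDER = ("build", "simulate", "density", "thickness", "order",
               "diffusion", "pmf")
_FLOAT_FMT = "%.10g"


class ConfigError(ValueError):
    """Invalid run configuration; the message lists every violation."""


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _check(errors, cond, msg):
    if not cond:
        errors.append(msg)


def validate_config(cfg: Mapping[str, Any]) -> list[str]:
    """Validate a parsed run configuration; returns a list of problems."""
    errors: list[str] = []
    if not isinstance(cfg, Mapping):
        return ["configuration must be a mapping"]
    _check(errors, isinstance(cfg.get("seed"), int), "global integer 'seed' is required")
    _check(errors, isinstance(cfg.get("output_dir"), str),
           "'output_dir' (string) is required")
    known = set(STAGE_ORDER) | {"seed", "output_dir", "log_level",
                                "trajectory", "topology"}
    for key in cfg:
        _check(errors, key in known, f"unknown top-level key {key!r}")

    b = cfg.get("build")
    if b is not None:
        ratio = b.get("ratio", [1, 1, 1])
        _check(errors, isinstance(ratio, list) and len(ratio) in (3, 4)
               and all(isinstance(r, int) and r >= 0 for r in ratio),
               "build.ratio must be 3 or 4 non-negative integers")
        _check(errors, isinstance(b.get("n_lipids"), int) and b["n_lipids"] >= 3,
               "build.n_lipids must be an integer >= 3")
        _check(errors, b.get("solvent_beads", 0) >= 0,
               "build.solvent_beads must be >= 0")
        frac = b.get("ethanol_fraction", 0.0)
        _check(errors, 0.0 <= frac <= 1.0,
               "build.ethanol_fraction must lie in [0, 1]")
        box = b.get("box", [8.0, 8.0, 12.0])
        _check(errors, isinstance(box, list) and len(box) == 3
               and all(v > 0 for v in box), "build.box must be 3 positive lengths")
        _check(errors, b.get("z_leaflet", 1.2) > 0, "build.z_leaflet must be > 0")
    s = cfg.get("simulate")
    if s is not None:
        _check(errors, s.get("dt", 0) > 0, "simulate.dt must be > 0")
        _check(errors, isinstance(s.get("n_steps"), int) and s["n_steps"] >= 1,
               "simulate.n_steps must be an integer >= 1")
        _check(errors, s.get("save_every", 10) >= 1,
               "simulate.save_every must be >= 1")
        _check(errors, s.get("temperature", 320.0) > 0,
               "simulate.temperature must be > 0")
        diff = s.get("diffusion", {})
        _check(errors, isinstance(diff, Mapping)
               and all(v > 0 for v in diff.values()),
               "simulate.diffusion must map species to D > 0")
        _check(errors, s.get("k_tether", 150.0) >= 0,
               "simulate.k_tether must be >= 0")
    d = cfg.get("density")
    if d is not None:
        _check(errors, d.get("bin_width", 0.1) > 0,
               "density.bin_width must be > 0")
    t = cfg.get("thickness")
    if t is not None:
        _check(errors, 0 < t.get("tail_fraction", 0.5) <= 1,
               "thickness.tail_fraction must lie in (0, 1]")
    f = cfg.get("diffusion")
    if f is not None:
        win = f.get("fit_window", [0.1, 0.5])
        _check(errors, isinstance(win, list) and len(win) == 2
               and 0 <= win[0] < win[1] <= 1,
               "diffusion.fit_window must be [lo, hi] with 0 <= lo < hi <= 1")
        _check(errors, 0 < f.get("max_lag_fraction", 0.5) <= 1,
               "diffusion.max_lag_fraction must lie in (0, 1]")
    p = cfg.get("pmf")
    if p is not None:
        _check(errors, p.get("speed", 1e-5) > 0, "pmf.speed must be > 0")
        _check(errors, p.get("spring_k", 2000.0) > 0,
               "pmf.spring_k must be > 0")
        _check(errors, p.get("dt", 0.02) > 0, "pmf.dt must be > 0")
        _check(errors, isinstance(p.get("replicates", 3), int)
               and p.get("replicates", 3) >= 1,
               "pmf.replicates must be an integer >= 1")
        _check(errors, p.get("tracer_diffusion", 0.005) > 0,
               "pmf.tracer_diffusion must be > 0")
        _check(errors, p.get("grid_spacing", 0.05) > 0,
               "pmf.grid_spacing must be > 0")
        _check(errors, p.get("z_start", 3.0) != p.get("z_stop", -0.5),
               "pmf.z_start and pmf.z_stop must differ")
    return errors


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    errors = validate_config(cfg)
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return cfg


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _write_manifest(outdir: Path, stage: str, params: Mapping, inputs: list[str],
                    seed: int, wall: float, rows: int) -> None:
    manifest = {"stage": stage, "parameters": dict(params), "inputs": inputs,
                "seed": seed, "package_version": __version__,
                "wall_time_s": round(wall, 3), "rows": rows}
    (outdir / f"{stage}.manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def _write_csv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return len(df)


def stage_build(cfg: Mapping, outdir: Path, seed: int) -> Trajectory:
    spec = builder.CompositionSpec(
        tuple(cfg.get("ratio", [1, 1, 1])), cfg["n_lipids"],
        cfg.get("solvent_beads", 0), cfg.get("ethanol_fraction", 0.0),
        tuple(cfg.get("ions", [0, 0])),
        cfg.get("tracer"), cfg.get("tracer_count", 0))
    comp = builder.compose_system(spec)
    traj = builder.place_initial(comp, cfg.get("box", [8.0, 8.0, 12.0]),
                                 cfg.get("z_leaflet", 1.2), seed=seed)
    io.write_gro(outdir / "system.gro", traj)
    (outdir / "system.json").write_text(
        json.dumps(comp.summary(), indent=2, sort_keys=True) + "\n")
    return traj


def default_membrane_potential(start: Trajectory, k_tether: float = 150.0,
                               solvent_barrier_height: float = 12.0,
                               solvent_barrier_width: float = 1.2,
                               bond_k: float = 200.0,
                               angle_k: float = 10.0) -> PotentialSpec:
    """Scaffold potential for demo membrane runs.

    Membrane beads are z-tethered to their initial depths (preserving the
    leaflet architecture while leaving lateral motion free), chains carry
    harmonic bonds at their built rest lengths plus straightening angle
    springs, and solvent/ion beads feel a Gaussian midplane barrier that
    keeps them out of the hydrophobic core.
    """
    from .model import NON_MEMBRANE, REGISTRY
    from .potentials import Angles

    lab = start.labels
    species = lab.species.astype(str)
    membrane = ~np.isin(species, sorted(NON_MEMBRANE))
    pot = PotentialSpec()
    if membrane.any() and k_tether > 0:
        idx = np.nonzero(membrane)[0]
        pot.add(HarmonicZ(idx, k_tether, start.coords[0, idx, 2].copy()))
    if (~membrane).any() and solvent_barrier_height > 0:
        pot.add(GaussianZ(np.nonzero(~membrane)[0], [solvent_barrier_height],
                          [0.0], [solvent_barrier_width]))
    pairs, triples = [], []
    for sp_name in dict.fromkeys(species[membrane]):
        sp = REGISTRY.get(sp_name)
        if sp is None or not sp.chains:
            continue
        for chain in sp.chains.values():
            names = [sp.bead_names[i] for i in chain]
            cols = [np.nonzero((species == sp_name)
                               & (lab.bead_name.astype(str) == bn))[0]
                    for bn in names]
            order = [c[np.argsort(lab.molecule_index[c], kind="stable")]
                     for c in cols]
            for a, b in zip(order[:-1], order[1:]):
                pairs.append(np.column_stack([a, b]))
            for a, b, c in zip(order[:-2], order[1:-1], order[2:]):
                triples.append(np.column_stack([a, b, c]))
    if pairs and bond_k > 0:
        all_pairs = np.concatenate(pairs)
        d = start.coords[0, all_pairs[:, 1]] - start.coords[0, all_pairs[:, 0]]
        pot.add(Bonds(all_pairs, bond_k, np.linalg.norm(d, axis=1)))
    if triples and angle_k > 0:
        pot.add(Angles(np.concatenate(triples), angle_k, np.pi))
    return pot


def stage_simulate(cfg: Mapping, outdir: Path, seed: int,
                   start: Trajectory) -> Trajectory:
    potential = default_membrane_potential(
        start, cfg.get("k_tether", 150.0),
        cfg.get("solvent_barrier_height", 12.0),
        cfg.get("solvent_barrier_width", 1.2),
        cfg.get("bond_k", 200.0))
    sim = dynamics.SimulationConfig(
        dt=cfg["dt"], n_steps=cfg["n_steps"], seed=seed,
        diffusion=cfg.get("diffusion", {}),
        temperature=cfg.get("temperature", 320.0),
        save_every=cfg.get("save_every", 10))
    traj = dynamics.langevin_run(start, sim, potential)
    io.write_frames(outdir / "trajectory.frames", traj)
    return traj


def stage_density(cfg: Mapping, outdir: Path, traj: Trajectory) -> pd.DataFrame:
    centered = structure.center_frames(traj)
    prof = structure.density_profile(centered,
                                     bin_width=cfg.get("bin_width", 0.1),
                                     mass_weighted=cfg.get("mass_weighted",
                                                           False))
    df = prof.to_frame()
    _write_csv(df, outdir / "density.csv")
    return df


def stage_thickness(cfg: Mapping, outdir: Path, traj: Trajectory) -> pd.DataFrame:
    centered = structure.center_frames(traj)
    res = structure.interleaflet_distance(
        centered, tail_fraction=cfg.get("tail_fraction", 0.5))
    df = res.to_frame()
    _write_csv(df, outdir / "thickness.csv")
    return df


def stage_order(cfg: Mapping, outdir: Path, traj: Trajectory) -> pd.DataFrame:
    res = structure.order_parameters(traj)
    _write_csv(res.table, outdir / "order.csv")
    return res.table


def stage_diffusion(cfg: Mapping, outdir: Path, traj: Trajectory) -> pd.DataFrame:
    unwrapped = diffusion.unwrap_lateral(traj)
    components = cfg.get("components")
    if components is None:
        from .model import NON_MEMBRANE
        components = [s for s in dict.fromkeys(traj.labels.species.astype(str))
                      if s not in NON_MEMBRANE]
    rows = []
    msd_curves = {}
    for comp in components:
        msd = diffusion.compute_msd(
            unwrapped, comp,
            max_lag_fraction=cfg.get("max_lag_fraction", 0.5))
        est = diffusion.fit_diffusion(
            msd, fit_window=tuple(cfg.get("fit_window", [0.1, 0.5])))
        rows.append(est.to_frame())
        msd_curves[comp] = msd
    df = pd.concat(rows, ignore_index=True)
    _write_csv(df, outdir / "diffusion.csv")
    curves = pd.DataFrame({"lag_ps": next(iter(msd_curves.values())).lags})
    for comp, msd in msd_curves.items():
        curves[f"{comp}_msd_nm2"] = msd.msd
    _write_csv(curves, outdir / "msd.csv")
    return df


def stage_pmf(cfg: Mapping, outdir: Path, seed: int) -> pd.DataFrame:
    barrier = cfg.get("barrier", {"height_kcal": 1.0, "center": 1.0,
                                  "width": 0.3})
    well = cfg.get("well", {"height_kcal": -2.0, "center": 0.0, "width": 0.7})
    landscape = GaussianZ(
        0, [barrier["height_kcal"] * KCAL, well["height_kcal"] * KCAL],
        [barrier["center"], well["center"]],
        [barrier["width"], well["width"]])
    traces = protocols.run_pull(
        seed, cfg.get("speed", 1e-3), cfg.get("replicates", 3),
        cfg.get("tracer_diffusion", 0.005), cfg.get("dt", 0.02),
        cfg.get("z_start", 3.0), cfg.get("z_stop", -0.5),
        cfg.get("spring_k", 2000.0), landscape=landscape)
    profiles = []
    for i, trace in enumerate(traces):
        io.write_pull_xvg(outdir / f"pullf_{i:02d}.xvg", trace)
        z, w = pmf.integrate_work(trace)
        profiles.append(pmf.bin_profile(z, w,
                                        spacing=cfg.get("grid_spacing", 0.05)))
    profile = pmf.reference_and_average(profiles)
    df = profile.to_frame()
    _write_csv(df, outdir / "pmf.csv")
    desc = pmf.descriptors(profile, tuple(cfg.get("interior", [-0.5, 2.0])))
    (outdir / "pmf_descriptors.json").write_text(
        json.dumps(desc.to_dict(), indent=2, sort_keys=True) + "\n")
    return df


# ---------------------------------------------------------------------------
# Runner
# ---------------------------------------------------------------------------

def run(config_path: str | Path) -> Path:
    """Execute every configured stage in dependency order.

    Returns the output directory.  Invalid configurations raise
    :class:`ConfigError` (listing all problems) before anything runs.
    """
    cfg = load_config(config_path)
    logging.basicConfig(level=getattr(logging, str(cfg.get("log_level",
                                                           "INFO")).upper(), 20))
    outdir = Path(cfg["output_dir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]

    traj: Trajectory | None = None
    if "trajectory" in cfg:  # analyze an existing trajectory instead of simulating
        labels = io.read_gro(cfg["topology"]).labels
        traj = io.read_frames(cfg["trajectory"], labels)

    start: Trajectory | None = None
    for stage in STAGE_ORDER:
        if stage not in cfg or cfg[stage] is None:
            continue
        scfg = cfg[stage]
        t0 = time.perf_counter()
        if stage == "build":
            start = stage_build(scfg, outdir, seed)
            rows = start.n_beads
            inputs = []
        elif stage == "simulate":
            if start is None:
                raise ConfigError("simulate stage requires a build stage")
            traj = stage_simulate(scfg, outdir, seed + 1, start)
            rows = traj.n_frames
            inputs = ["system.gro"]
        elif stage == "pmf":
            df = stage_pmf(scfg, outdir, seed + 2)
            rows = len(df)
            inputs = []
        else:
            if traj is None:
                raise ConfigError(
                    f"{stage} stage requires a simulated or loaded trajectory")
            fn = {"density": stage_density, "thickness": stage_thickness,
                  "order": stage_order, "diffusion": stage_diffusion}[stage]
            df = fn(scfg, outdir, traj)
            rows = len(df)
            inputs = ["trajectory.frames"]
        wall = time.perf_counter() - t0
        logger.info("stage %-9s done in %.2f s (%d rows)", stage, wall, rows)
        _write_manifest(outdir, stage, scfg, inputs, seed, wall, rows)
    return outdir


DEMO_CONFIG = """\
# Small end-to-end demo: build a mixed SC bilayer patch, run Brownian
# dynamics on it, and run every analysis stage plus a steered-pull PMF.
seed: 7
output_dir: {outdir}
build:
  ratio: [1, 1, 1]
  n_lipids: 60
  solvent_beads: 300
  ethanol_fraction: 0.5
  box: [7.0, 7.0, 12.0]
simulate:
  dt: 0.02
  n_steps: 10000
  save_every: 50
  diffusion: {{DPCE: 0.03, BCN: 0.04, CHOL: 0.05, PW: 0.08, EtOH: 0.08}}
density: {{bin_width: 0.2}}
thickness: {{tail_fraction: 0.5}}
order: {{}}
diffusion:
  fit_window: [0.1, 0.5]
  components: [DPCE, BCN, CHOL]
pmf:
  speed: 2.0e-3
  replicates: 3
  z_start: 3.0
  z_stop: -0.5
"""


def write_demo_config(path: str | Path, outdir: str = "scmem_demo_out") -> Path:
    path = Path(path)
    path.write_text(DEMO_CONFIG.format(outdir=outdir))
    return path
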