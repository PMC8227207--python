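"""Deterministic composition and placement of model stratum-corneum systems.

The three-component SC bilayer mixes cholesterol (CHOL), the ceramide
N-stearoylsphingosine (DPCE) and behenic acid (BCN) in an integer ratio
(1:1:1 in the base system), optionally extended with linoleic acid (LA,
ratio 18:18:18:5) placed inside the bilayer, solvated by polarizable-water
beads optionally mixed with ethanol (50% molar in the enhancer systems),
plus explicit ion counts and an optional permeant tracer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model import BeadLabels, REGISTRY, Species, Trajectory

MAJOR_SPECIES = ("CHOL", "DPCE", "BCN")
#: Species receiving the integer remainder of a ratio split (the ceramide).
REMAINDER_SPECIES = "DPCE"


@dataclass(frozen=True)
class CompositionSpec:
    """Recipe for one model system.

    ``lipid_ratio`` is an integer ratio over (CHOL, DPCE, BCN); an optional
    fourth entry is the LA share relative to one major share.  Ion counts
    are explicit inputs, not derived from neutralization arithmetic.
    """

    lipid_ratio: tuple[int, ...] = (1, 1, 1)
    n_total_lipids: int = 625
    solvent_beads: int = 21740
    ethanol_molar_fraction: float = 0.0
    ion_counts: tuple[int, int] = (0, 0)    # (Na+, Cl-)
    tracer: str | None = None
    tracer_count: int = 0

    def __post_init__(self) -> None:
        if len(self.lipid_ratio) not in (3, 4):
            raise ValueError("lipid_ratio must have 3 (or 4, with LA) entries")
        if any(r < 0 for r in self.lipid_ratio) or not any(self.lipid_ratio[:3]):
            raise ValueError("ratio entries must be non-negative, majors not all 0")
        if not 0.0 <= self.ethanol_molar_fraction <= 1.0:
            raise ValueError("ethanol_molar_fraction must lie in [0, 1]")
        if self.solvent_beads < 0 or min(self.ion_counts) < 0 or self.tracer_count < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class SystemComposition:
    """Molecule counts per species, derived totals and net charge."""

    counts: dict[str, int]
    registry: Mapping[str, Species] = field(default_factory=lambda: REGISTRY)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("species counts must be non-negative")

    @property
    def n_molecules(self) -> int:
        return sum(self.counts.values())

    @property
    def n_beads(self) -> int:
        return sum(c * self.registry[s].n_beads for s, c in self.counts.items())

    @property
    def net_charge(self) -> int:
        return sum(c * self.registry[s].charge for s, c in self.counts.items())

    def summary(self) -> dict:
        return {"counts": dict(self.counts), "n_molecules": self.n_molecules,
                "n_beads": self.n_beads, "net_charge": self.net_charge}


# ---------------------------------------------------------------------------
# Composition arithmetic
# ---------------------------------------------------------------------------

def compose_lipids(ratio: Sequence[int], n_total_lipids: int,
                   species: Sequence[str] = MAJOR_SPECIES,
                   remainder_to: str = REMAINDER_SPECIES) -> dict[str, int]:
    """Split ``n_total_lipids`` over the major species by integer ratio.

    Counts are proportional with the integer remainder assigned to the
    ceramide, reproducing e.g. the 208/209/208 split of 625 lipids at 1:1:1.
    """
    if len(ratio) != len(species) or len(species) != 3:
        raise ValueError("ratio must cover exactly the three major species")
    if n_total_lipids < len(species):
        raise ValueError(
            f"need at least {len(species)} lipids, got {n_total_lipids}")
    total = sum(ratio)
    counts = {s: (n_total_lipids * r) // total for s, r in zip(species, ratio)}
    counts[remainder_to] += n_total_lipids - sum(counts.values())
    return counts


def add_enhancer_la(counts: Mapping[str, int],
                    ratio_extended: Sequence[int]) -> dict[str, int]:
    """Add linoleic acid per an extended ratio (e.g. 18:18:18:5).

    ``n_LA = floor(n_CHOL * r_LA / r_major)``: the only rounding consistent
    with 57 LA for 208 CHOL at 18:18:18:5.  LA is placed inside the bilayer.
    """
    if len(ratio_extended) != 4:
        raise ValueError("extended ratio must have 4 entries (majors + LA)")
    r_major, r_la = ratio_extended[0], ratio_extended[3]
    if r_major == 0:
        raise ValueError("major-species ratio share must be non-zero")
    out = dict(counts)
    out["LA"] = (out["CHOL"] * r_la) // r_major
    return out


def mix_solvent(solvent_beads: int, ethanol_molar_fraction: float) -> tuple[int, int]:
    """Split solvent beads into (polarizable water, ethanol).

    One PW bead counts as one solvent unit; the ethanol count is the molar
    fraction of the bead total, rounded half-to-even.
    """
    if solvent_beads < 0:
        raise ValueError("solvent bead count must be non-negative")
    if not 0.0 <= ethanol_molar_fraction <= 1.0:
        raise ValueError("ethanol fraction must lie in [0, 1]")
    n_etoh = round(ethanol_molar_fraction * solvent_beads)
    return solvent_beads - n_etoh, n_etoh


def compose_system(spec: CompositionSpec,
                   registry: Mapping[str, Species] = REGISTRY) -> SystemComposition:
    """Build the full per-species molecule count table from a recipe."""
    counts = compose_lipids(spec.lipid_ratio[:3], spec.n_total_lipids)
    if len(spec.lipid_ratio) == 4:
        counts = add_enhancer_la(counts, spec.lipid_ratio)
    n_pw, n_etoh = mix_solvent(spec.solvent_beads, spec.ethanol_molar_fraction)
    counts["PW"] = n_pw
    if n_etoh:
        counts["EtOH"] = n_etoh
    na, cl = spec.ion_counts
    if na:
        counts["NA"] = na
    if cl:
        counts["CL"] = cl
    if spec.tracer and spec.tracer_count:
        counts[spec.tracer] = counts.get(spec.tracer, 0) + spec.tracer_count
    return SystemComposition(counts, registry)


# ---------------------------------------------------------------------------
# Initial placement
# ---------------------------------------------------------------------------

def _lattice_2d(lx: float, ly: float, n_sites: int, min_spacing: float,
                kind: str) -> np.ndarray:
    nx = int(lx // min_spacing)
    ny = int(ly // min_spacing)
    if nx * ny < n_sites:
        need = n_sites * min_spacing ** 2
        raise ValueError(
            f"box too small for {n_sites} {kind} molecules at spacing "
            f"{min_spacing:.3f} nm: lateral area {lx * ly:.2f} nm^2, "
            f"required >= {need:.2f} nm^2")
    ax, ay = lx / nx, ly / ny
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    sites = np.column_stack([(gx.ravel() + 0.5) * ax - lx / 2,
                             (gy.ravel() + 0.5) * ay - ly / 2])
    return sites[:n_sites]


def place_initial(composition: SystemComposition, box: Sequence[float],
                  z_leaflet: float = 1.2, seed: int | None = None, *,
                  exclusion: float = 0.45, jitter: float = 0.08,
                  solvent_margin: float = 0.5) -> Trajectory:
    """Place a composed system into a box as a single starting frame.

    Lipid-category molecules (including LA) split between two leaflets
    (per-species difference <= 1) on jittered lattices, head beads at
    ``+/- z_leaflet`` pointing outward and chain beads stacked toward the
    midplane.  Solvent, ions and tracers go on a jittered 3-D lattice in
    the two slabs ``|z| > z_leaflet + solvent_margin``.  Coordinates use the
    centered box convention (bilayer midplane at z = 0).  Deterministic for
    a fixed seed.
    """
    if seed is None:
        raise ValueError("place_initial requires an explicit seed")
    box = np.asarray(box, dtype=float)
    if box.shape != (3,) or np.any(box <= 0):
        raise ValueError("box must be three positive lengths (nm)")
    rng = np.random.default_rng(seed)
    reg = composition.registry
    min_spacing = exclusion + 2 * jitter

    lipids = [s for s in composition.counts if reg[s].category == "lipid"]
    others = [s for s in composition.counts if reg[s].category != "lipid"]

    # Leaflet split: per-species difference <= 1, upper leaflet gets the odd one.
    per_leaflet: dict[int, list[str]] = {+1: [], -1: []}
    for s in lipids:
        n = composition.counts[s]
        per_leaflet[+1] += [s] * ((n + 1) // 2)
        per_leaflet[-1] += [s] * (n // 2)

    species_l, molidx_l, bead_l, coords_l = [], [], [], []
    mol_counter = 0
    for sign in (+1, -1):
        names = per_leaflet[sign]
        sites = _lattice_2d(box[0], box[1], len(names), min_spacing, "lipid")
        order = rng.permutation(len(names))
        for k, site in zip(order, sites):
            sp = reg[names[k]]
            mol_counter += 1
            xy = site + rng.uniform(-jitter, jitter, size=2)
            # head first, remaining beads stacked toward the midplane,
            # ending 0.25 nm short of it so leaflets do not interdigitate.
            n_rest = sp.n_beads - 1
            dz = (z_leaflet - 0.25) / max(n_rest, 1)
            head_i = sp.bead_names.index(sp.head_bead) if sp.head_bead else 0
            depth = 0
            for bi, bead in enumerate(sp.beads):
                d = 0 if bi == head_i else (depth := depth + 1)
                species_l.append(sp.name)
                molidx_l.append(mol_counter)
                bead_l.append(bead.name)
                coords_l.append([xy[0], xy[1], sign * (z_leaflet - d * dz)])

    # Solvent/ion/tracer beads on a 3-D lattice in the two solvent slabs.
    n_other = sum(composition.counts[s] * reg[s].n_beads for s in others)
    if n_other:
        z_lo = z_leaflet + solvent_margin
        slab_h = box[2] / 2 - z_lo
        if slab_h <= min_spacing:
            raise ValueError("box z too small for solvent slabs")
        nz = max(int(slab_h // min_spacing), 1)
        per_layer_needed = -(-n_other // (2 * nz))  # ceil
        sites_xy = _lattice_2d(box[0], box[1], min(per_layer_needed,
                               int(box[0] // min_spacing) * int(box[1] // min_spacing)),
                               min_spacing, "solvent")
        if len(sites_xy) * nz * 2 < n_other:
            raise ValueError(
                f"box too small for {n_other} solvent beads: capacity "
                f"{len(sites_xy) * nz * 2}")
        az = slab_h / nz
        sites = []
        for sign in (+1, -1):
            for iz in range(nz):
                z = sign * (z_lo + (iz + 0.5) * az)
                for xy in sites_xy:
                    sites.append([xy[0], xy[1], z])
        sites = np.array(sites)[:n_other]
        sites[:, :2] += rng.uniform(-jitter, jitter, size=(len(sites), 2))
        sites[:, 2] += rng.uniform(-min(jitter, az / 2 - exclusion / 2, 0.1),
                                   min(jitter, az / 2 - exclusion / 2, 0.1),
                                   size=len(sites)) if az > exclusion else 0.0
        # tracers first (deterministic placement at the start of the upper slab)
        ordered = sorted(others, key=lambda s: reg[s].category != "tracer")
        ptr = 0
        for s in ordered:
            sp = reg[s]
            for _ in range(composition.counts[s]):
                mol_counter += 1
                for bead in sp.beads:
                    species_l.append(sp.name)
                    molidx_l.append(mol_counter)
                    bead_l.append(bead.name)
                    coords_l.append(sites[ptr])
                    ptr += 1

    labels = BeadLabels(np.array(species_l, dtype=object), np.array(molidx_l),
                        np.array(bead_l, dtype=object))
    coords = np.asarray(coords_l, dtype=float)
    return Trajectory(np.array([0.0]), box[None, :], coords[None, :, :], labels)
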