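"""Structural bilayer analyses along the membrane normal.

Covers bilayer-centered per-component density profiles, leaflet
assignment, interleaflet distance between named headgroup beads (the
thickness metric of the SC model: P1 of the ceramide, Qa of behenic acid,
SP1 of cholesterol), and P2 chain-bond order parameters

    S = 1/2 < 3 cos^2(theta) - 1 >

with theta the angle between a chain bond vector and the fixed bilayer
normal (z).  The systems are planar bilayers, so no local-normal
estimation is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .model import (HEAD_BEADS, NON_MEMBRANE, REGISTRY, Species, Trajectory,
                    minimum_image)

logger = logging.getLogger(__name__)


def _membrane_mask(traj: Trajectory) -> np.ndarray:
    species = traj.labels.species.astype(str)
    return ~np.isin(species, sorted(NON_MEMBRANE))


# ---------------------------------------------------------------------------
# Centering and leaflets
# ---------------------------------------------------------------------------

def center_frames(traj: Trajectory, selection: np.ndarray | None = None) -> Trajectory:
    """Translate each frame so the reference centroid sits at z = 0.

    ``selection`` is a boolean bead mask; the default is all membrane
    (non-solvent, non-ion) beads.  x and y are untouched.  Re-centering is
    per frame, removing normal-axis drift of the membrane.
    """
    if selection is None:
        selection = _membrane_mask(traj)
    selection = np.asarray(selection, dtype=bool)
    if not selection.any():
        raise ValueError("centering selection is empty")
    out = traj.copy()
    zc = out.coords[:, selection, 2].mean(axis=1)
    out.coords[:, :, 2] -= zc[:, None]
    return out


def assign_leaflets(traj: Trajectory, head_beads: Mapping[str, str] = HEAD_BEADS,
                    frame: int = 0, eps: float = 1e-6,
                    registry: Mapping[str, Species] = REGISTRY) -> pd.DataFrame:
    """Label each membrane molecule upper (+1) or lower (-1) by head-bead z.

    Assumes a centered frame.  Molecules whose head sits within ``eps`` of
    the midplane are labeled by the sign of their last chain bead instead.
    Returns a DataFrame (species, molecule_index, leaflet).
    """
    lab = traj.labels
    species_arr = lab.species.astype(str)
    rows = []
    for sp_name in dict.fromkeys(species_arr[_membrane_mask(traj)]):
        if sp_name not in head_beads:
            raise ValueError(f"species {sp_name!r} has no head bead mapping")
        head = head_beads[sp_name]
        m = (species_arr == sp_name) & (lab.bead_name.astype(str) == head)
        if not m.any():
            raise ValueError(f"species {sp_name!r}: head bead {head!r} absent")
        mol = lab.molecule_index[m]
        z = traj.coords[frame, m, 2]
        side = np.sign(z)
        ties = np.abs(z) < eps
        if ties.any():
            side = side.copy()
            sp = registry.get(sp_name)
            end_bead = None
            if sp is not None and sp.chains:
                end_bead = sp.bead_names[list(sp.chains.values())[0][-1]]
            for k in np.nonzero(ties)[0]:
                if end_bead is not None:
                    me = (lab.molecule_index == mol[k]) & \
                         (lab.bead_name.astype(str) == end_bead)
                    zz = traj.coords[frame, me, 2]
                    side[k] = np.sign(zz[0]) if len(zz) else 1.0
                else:
                    side[k] = 1.0
        side[side == 0] = 1.0
        for mi, s in zip(mol.tolist(), side):
            rows.append((sp_name, mi, int(s)))
    return pd.DataFrame(rows, columns=["species", "molecule_index", "leaflet"])


# ---------------------------------------------------------------------------
# Density profiles
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Per-component number-density profile along the bilayer normal."""

    z: np.ndarray                    # bin centers, nm (bilayer-centered)
    values: dict[str, np.ndarray]    # beads nm^-3 (or amu nm^-3 if weighted)
    bin_width: float
    n_frames: int
    weighting: str = "number"

    def to_frame(self) -> pd.DataFrame:
        unit = "number_nm3" if self.weighting == "number" else "mass_amu_nm3"
        df = pd.DataFrame({"z_nm": self.z})
        for name, v in self.values.items():
            df[f"{name}_{unit}"] = v
        return df


def density_profile(traj: Trajectory,
                    selections: Mapping[str, np.ndarray] | None = None,
                    bin_width: float = 0.1,
                    mass_weighted: bool = False,
                    registry: Mapping[str, Species] = REGISTRY) -> DensityProfile:
    """Histogram selected bead z positions into a number-density profile.

    The trajectory must be centered.  Each frame's counts are divided by
    the bin volume ``bin_width * box_x * box_y`` of that frame and averaged
    over frames, so the profile integrates back to the mean selected bead
    count per frame exactly.  Default selections: one per species present.
    Beads are re-wrapped into ``[-Lz/2, Lz/2)`` about the midplane so every
    bead lands in a bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    lz = float(traj.boxes[:, 2].min())
    if bin_width > lz:
        raise ValueError(f"bin_width {bin_width} nm exceeds box z {lz} nm")
    if selections is None:
        selections = {str(s): traj.labels.mask(species=str(s))
                      for s in dict.fromkeys(traj.labels.species.astype(str))}
    n_bins = max(int(round(lz / bin_width)), 1)
    edges = np.linspace(-lz / 2, lz / 2, n_bins + 1)
    width = edges[1] - edges[0]
    centers = 0.5 * (edges[:-1] + edges[1:])

    masses = None
    if mass_weighted:
        by_bead = {(s.name, b.name): b.mass for s in registry.values()
                   for b in s.beads}
        masses = np.array([by_bead.get((sp, bn), 72.0) for sp, bn in
                           zip(traj.labels.species.astype(str),
                               traj.labels.bead_name.astype(str))])

    values: dict[str, np.ndarray] = {}
    for name, mask in selections.items():
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError(f"selection {name!r} is empty")
        acc = np.zeros(n_bins)
        for f in range(traj.n_frames):
            box = traj.boxes[f]
            z = traj.coords[f, mask, 2]
            z = z - lz * np.floor(z / lz + 0.5)  # wrap about the midplane
            w = masses[mask] if masses is not None else None
            hist, _ = np.histogram(z, bins=edges, weights=w)
            acc += hist / (width * box[0] * box[1])
        values[name] = acc / traj.n_frames
    return DensityProfile(centers, values, width, traj.n_frames,
                          "mass" if mass_weighted else "number")


# ---------------------------------------------------------------------------
# Interleaflet distance
# ---------------------------------------------------------------------------

@dataclass
class ThicknessResult:
    """Interleaflet distances (angstrom) per component."""

    per_frame: pd.DataFrame          # columns: time_ps, <component>_A ...
    mean: dict[str, float]           # angstrom
    sd: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"component": list(self.mean),
             "interleaflet_distance_A": [self.mean[c] for c in self.mean],
             "sd_A": [self.sd[c] for c in self.mean]})


def interleaflet_distance(traj: Trajectory,
                          head_beads: Mapping[str, str] = HEAD_BEADS,
                          tail_fraction: float = 0.5,
                          components: Sequence[str] | None = None) -> ThicknessResult:
    """Distance between mean head-bead z of the two leaflets, in angstrom.

    For each analyzed frame and component: |mean z of head beads in the
    upper leaflet - mean z in the lower leaflet| * 10.  By default only the
    final ``tail_fraction`` of frames enters the average (equilibration
    discard); pass 1.0 to use every frame.
    """
    if not 0 < tail_fraction <= 1:
        raise ValueError("tail_fraction must lie in (0, 1]")
    lab = traj.labels
    species_arr = lab.species.astype(str)
    if components is None:
        components = [s for s in dict.fromkeys(species_arr) if s in head_beads]
    if not components:
        raise ValueError("no components with a head-bead mapping")
    first = traj.n_frames - max(int(round(tail_fraction * traj.n_frames)), 1)
    masks = {}
    for comp in components:
        m = (species_arr == comp) & (lab.bead_name.astype(str) == head_beads[comp])
        if not m.any():
            raise ValueError(f"component {comp!r}: head bead "
                             f"{head_beads[comp]!r} not present")
        masks[comp] = m
    rows = []
    for f in range(first, traj.n_frames):
        row = {"time_ps": traj.times[f]}
        for comp, m in masks.items():
            z = traj.coords[f, m, 2]
            upper, lower = z[z >= 0], z[z < 0]
            if len(upper) == 0 or len(lower) == 0:
                raise ValueError(
                    f"component {comp!r} has an empty leaflet in frame {f}")
            row[comp] = abs(upper.mean() - lower.mean()) * 10.0
        rows.append(row)
    per_frame = pd.DataFrame(rows)
    mean = {c: float(per_frame[c].mean()) for c in components}
    sd = {c: float(per_frame[c].std(ddof=0)) for c in components}
    return ThicknessResult(per_frame, mean, sd)


# ---------------------------------------------------------------------------
# Order parameters
# ---------------------------------------------------------------------------

@dataclass
class OrderParameterResult:
    """P2 order parameter per chain bond, averaged over molecules and frames."""

    table: pd.DataFrame   # columns: species, chain, bond, S, n_samples
    n_excluded: int       # zero-length bond vectors dropped from the average

    def s(self, species: str, chain: str, bond: int) -> float:
        t = self.table
        row = t[(t.species == species) & (t.chain == chain) & (t.bond == bond)]
        return float(row.S.iloc[0])


def order_parameters(traj: Trajectory,
                     chains: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
                     registry: Mapping[str, Species] = REGISTRY) -> OrderParameterResult:
    """P2 order parameter of consecutive-bead chain bonds vs the z axis.

    ``chains`` maps species -> chain name -> ordered bead names; the default
    derives it from the species registry.  Bond *i* links chain beads *i*
    and *i+1*; bond vectors use minimum-image displacement, so wrapped
    coordinates are tolerated.  Zero-length bonds are excluded from the
    average (counted in ``n_excluded``); a bond with every sample excluded
    is an error.
    """
    lab = traj.labels
    species_arr = lab.species.astype(str)
    bead_arr = lab.bead_name.astype(str)
    if chains is None:
        chains = {}
        for sp_name in dict.fromkeys(species_arr):
            sp = registry.get(sp_name)
            if sp is not None and sp.chains:
                chains[sp_name] = {c: tuple(sp.bead_names[i] for i in idx)
                                   for c, idx in sp.chains.items()}
    rows = []
    n_excluded = 0
    for sp_name, sp_chains in chains.items():
        present = species_arr == sp_name
        if not present.any():
            continue
        for chain_name, bead_names in sp_chains.items():
            if len(bead_names) < 2:
                raise ValueError(
                    f"chain {chain_name!r} of {sp_name!r} needs >= 2 beads")
            # (n_molecules,) bead index per chain position, molecule-aligned
            idx_by_pos = []
            for bn in bead_names:
                sel = np.nonzero(present & (bead_arr == bn))[0]
                if len(sel) == 0:
                    raise ValueError(
                        f"bead {bn!r} of {sp_name!r} chain {chain_name!r} "
                        "not present")
                order = np.argsort(lab.molecule_index[sel], kind="stable")
                idx_by_pos.append(sel[order])
            for b in range(len(bead_names) - 1):
                i, j = idx_by_pos[b], idx_by_pos[b + 1]
                d = traj.coords[:, j, :] - traj.coords[:, i, :]
                d = minimum_image(d, traj.boxes[:, None, :])
                norm2 = np.einsum("fmd,fmd->fm", d, d)
                valid = norm2 > 0
                n_excluded += int((~valid).sum())
                if not valid.any():
                    raise ValueError(
                        f"bond {b} of {sp_name}/{chain_name}: all bond "
                        "vectors have zero length")
                cos2 = d[..., 2] ** 2 / np.where(valid, norm2, 1.0)
                s = 0.5 * (3.0 * cos2[valid].mean() - 1.0)
                rows.append((sp_name, chain_name, b, float(s), int(valid.sum())))
    if n_excluded:
        logger.warning("order_parameters: excluded %d zero-length bond vectors",
                       n_excluded)
    if not rows:
        raise ValueError("no chains found in trajectory")
    table = pd.DataFrame(rows, columns=["species", "chain", "bond", "S",
                                        "n_samples"])
    return OrderParameterResult(table, n_excluded)
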