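"""Domain types for coarse-grained membrane trajectories.

All quantities are carried in GROMACS-family internal units: lengths in
nm, times in ps, energies in kJ/mol, masses in amu.  Conversions (e.g. to
angstrom for thickness tables or kcal/mol for free energies) happen only at
output boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.0083145

#: Default thermostat temperature of the study conditions, K.
DEFAULT_TEMPERATURE = 320.0

#: kJ per kcal.
KCAL = 4.184


# ---------------------------------------------------------------------------
# Species / topology metadata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Bead:
    """A single coarse-grained interaction site."""

    name: str
    type: str
    mass: float = 72.0
    charge: float = 0.0


@dataclass(frozen=True)
class Species:
    """One molecular species: named beads, chain definitions, net charge.

    ``chains`` maps a chain name (e.g. ``"A"`` for the sphingosine tail of a
    ceramide) to an ordered tuple of bead indices; bond *i* of a chain links
    chain beads *i* and *i+1*.  ``head_bead`` names the hydrophilic bead used
    for leaflet assignment and interleaflet-distance measurements.
    """

    name: str
    beads: tuple[Bead, ...]
    chains: Mapping[str, tuple[int, ...]] = field(default_factory=dict)
    head_bead: str | None = None
    category: str = "lipid"  # lipid | solvent | ion | tracer

    def __post_init__(self) -> None:
        names = [b.name for b in self.beads]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate bead names in species {self.name!r}")
        for cname, idx in self.chains.items():
            if len(idx) < 2:
                raise ValueError(
                    f"chain {cname!r} of {self.name!r} needs >= 2 beads")
            for i in idx:
                if not 0 <= i < len(self.beads):
                    raise ValueError(
                        f"chain {cname!r} of {self.name!r} references bead "
                        f"index {i} outside 0..{len(self.beads) - 1}")
        if self.head_bead is not None and self.head_bead not in names:
            raise ValueError(
                f"head bead {self.head_bead!r} not a bead of {self.name!r}")

    @property
    def charge(self) -> int:
        """Net charge in e; by construction the sum of per-bead charges."""
        return int(round(sum(b.charge for b in self.beads)))

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def bead_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.beads)


def _c1(name: str) -> Bead:
    return Bead(name, "C1")


#: Built-in registry of the stratum-corneum model species.
#:
#: The bead layout is a schematic coarse-grained representation (one
#: hydrophilic head bead typed as in the MARTINI model -- P1 for the ceramide
#: hydroxyl/amide region, Qa for a deprotonated fatty-acid carboxylate, SP1
#: for the cholesterol hydroxyl -- plus apolar C1-type tail beads).  It
#: carries the labels and connectivity the analyses need; it is not a force
#: field.
REGISTRY: dict[str, Species] = {
    # N-stearoylsphingosine ceramide: sphingosine tail (chain A) and
    # stearoyl fatty-acid tail (chain B).
    "DPCE": Species(
        "DPCE",
        beads=(Bead("OH1", "P1"),
               _c1("A1"), _c1("A2"), _c1("A3"), _c1("A4"),
               _c1("B1"), _c1("B2"), _c1("B3"), _c1("B4")),
        chains={"A": (1, 2, 3, 4), "B": (5, 6, 7, 8)},
        head_bead="OH1",
    ),
    # Behenic acid (C22 saturated FFA), deprotonated carboxylate head.
    "BCN": Species(
        "BCN",
        beads=(Bead("COO", "Qa", charge=-1.0),
               _c1("T1"), _c1("T2"), _c1("T3"), _c1("T4"), _c1("T5")),
        chains={"tail": (1, 2, 3, 4, 5)},
        head_bead="COO",
    ),
    # Cholesterol: hydroxyl head plus a compact ring/tail stack.
    "CHOL": Species(
        "CHOL",
        beads=(Bead("ROH", "SP1"),
               Bead("R1", "SC1"), Bead("R2", "SC1"), Bead("R3", "SC1"),
               Bead("R4", "SC1"), _c1("C1")),
        chains={"tail": (1, 2, 3, 4, 5)},
        head_bead="ROH",
    ),
    # Linoleic acid (C18:2), deprotonated; one mid-chain unsaturated bead.
    "LA": Species(
        "LA",
        beads=(Bead("COO", "Qa", charge=-1.0),
               _c1("L1"), Bead("L2", "C3"), _c1("L3"), _c1("L4")),
        chains={"tail": (1, 2, 3, 4)},
        head_bead="COO",
    ),
    # One-bead ethanol.
    "EtOH": Species("EtOH", beads=(Bead("EOH", "P2", mass=46.0),),
                    category="solvent"),
    # Polarizable-water unit, treated as one solvent bead for bookkeeping.
    "PW": Species("PW", beads=(Bead("W", "POL"),), category="solvent"),
    # Point tracer standing in for the pulled permeant (lidocaine).
    "LID": Species("LID", beads=(Bead("LID", "SC3"),), category="tracer"),
    "NA": Species("NA", beads=(Bead("NA", "Qd", charge=1.0),),
                  category="ion"),
    "CL": Species("CL", beads=(Bead("CL", "Qa", charge=-1.0),),
                  category="ion"),
}

#: Default head-bead map for leaflet assignment / interleaflet distance.
HEAD_BEADS: dict[str, str] = {
    s.name: s.head_bead for s in REGISTRY.values() if s.head_bead is not None
}

#: Species excluded from the default "membrane" selection.
NON_MEMBRANE = {
    name for name, s in REGISTRY.items()
    if s.category in ("solvent", "ion", "tracer")
}


# ---------------------------------------------------------------------------
# Trajectory container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadLabels:
    """Per-bead labels shared by every frame of a trajectory."""

    species: np.ndarray          # (N,) str
    molecule_index: np.ndarray   # (N,) int, unique per molecule
    bead_name: np.ndarray        # (N,) str

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", np.asarray(self.species, dtype=object))
        object.__setattr__(self, "molecule_index",
                           np.asarray(self.molecule_index, dtype=np.int64))
        object.__setattr__(self, "bead_name",
                           np.asarray(self.bead_name, dtype=object))
        n = len(self.species)
        if len(self.molecule_index) != n or len(self.bead_name) != n:
            raise ValueError("label arrays must have equal length")

    def __len__(self) -> int:
        return len(self.species)

    def mask(self, species: str | Sequence[str] | None = None,
             bead_name: str | Sequence[str] | None = None) -> np.ndarray:
        """Boolean bead mask by species and/or bead name."""
        m = np.ones(len(self), dtype=bool)
        if species is not None:
            wanted = {species} if isinstance(species, str) else set(species)
            m &= np.isin(self.species.astype(str), sorted(wanted))
        if bead_name is not None:
            wanted = {bead_name} if isinstance(bead_name, str) else set(bead_name)
            m &= np.isin(self.bead_name.astype(str), sorted(wanted))
        return m

    def molecules(self, species: str | None = None) -> list[tuple[str, int]]:
        """Ordered unique (species, molecule_index) pairs."""
        sel = self.mask(species=species)
        pairs = list(zip(self.species[sel].astype(str),
                         self.molecule_index[sel].tolist()))
        seen: dict[tuple[str, int], None] = {}
        for p in pairs:
            seen.setdefault(p, None)
        return list(seen)


@dataclass
class Trajectory:
    """Ordered frames of bead coordinates with a periodic box.

    Coordinates are in nm and are treated as wrapped into the primary box
    unless ``unwrapped`` is set.  The wrapping convention is centered:
    each coordinate lies in ``[-L/2, L/2)`` for box length ``L`` (analyses
    use minimum-image arithmetic and are insensitive to the origin choice).
    """

    times: np.ndarray   # (n_frames,) ps, strictly increasing
    boxes: np.ndarray   # (n_frames, 3) nm
    coords: np.ndarray  # (n_frames, n_beads, 3) nm
    labels: BeadLabels
    unwrapped: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_beads, 3)")
        n = self.coords.shape[0]
        if self.times.shape != (n,) or self.boxes.shape != (n, 3):
            raise ValueError("times/boxes inconsistent with coords")
        if self.coords.shape[1] != len(self.labels):
            raise ValueError(
                f"{self.coords.shape[1]} beads per frame but "
                f"{len(self.labels)} labels")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if not np.all(self.boxes > 0):
            raise ValueError("box lengths must be strictly positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> "Trajectory":
        """Single-frame view (copying the slice) at frame index ``i``."""
        return Trajectory(self.times[i:i + 1].copy(), self.boxes[i:i + 1].copy(),
                          self.coords[i:i + 1].copy(), self.labels,
                          unwrapped=self.unwrapped)

    def copy(self) -> "Trajectory":
        return Trajectory(self.times.copy(), self.boxes.copy(),
                          self.coords.copy(), self.labels,
                          unwrapped=self.unwrapped)


def concatenate(first: Trajectory, second: Trajectory) -> Trajectory:
    """Concatenate two trajectories over the same beads in time order."""
    a, b = first.labels, second.labels
    if not (np.array_equal(a.species, b.species)
            and np.array_equal(a.molecule_index, b.molecule_index)
            and np.array_equal(a.bead_name, b.bead_name)):
        raise ValueError("cannot concatenate: bead labels differ")
    if first.unwrapped != second.unwrapped:
        raise ValueError("cannot concatenate wrapped with unwrapped trajectory")
    if second.times[0] <= first.times[-1]:
        raise ValueError("second trajectory must start after the first ends")
    return Trajectory(
        np.concatenate([first.times, second.times]),
        np.concatenate([first.boxes, second.boxes]),
        np.concatenate([first.coords, second.coords]),
        first.labels, unwrapped=first.unwrapped)


def wrap_coords(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap coordinates into the centered primary box [-L/2, L/2)."""
    box = np.asarray(box, dtype=float)
    return coords - box * np.floor(coords / box + 0.5)


def minimum_image(disp: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image convention applied to displacement vectors."""
    box = np.asarray(box, dtype=float)
    return disp - box * np.round(disp / box)


# ---------------------------------------------------------------------------
# Pull-force traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PullProtocol:
    """Constant-velocity harmonic pull along the membrane normal (z).

    Defaults echo the steered protocol of the study conditions: spring
    constant 2000 kJ mol^-1 nm^-2 and pull speed 1e-5 nm/ps.
    """

    speed: float = 1e-5          # nm / ps
    spring_k: float = 2000.0     # kJ mol^-1 nm^-2
    origin: float = 0.0          # nm, spring-center start
    direction: int = 1           # +1 pulls toward +z, -1 toward -z
    tracer: int | None = None    # bead index of the pulled tracer

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("pull speed must be > 0")
        if self.spring_k <= 0:
            raise ValueError("spring constant must be > 0")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    def center(self, t: np.ndarray | float) -> np.ndarray | float:
        """Spring-center position z_c(t) = origin + direction * speed * t."""
        return self.origin + self.direction * self.speed * np.asarray(t, dtype=float)


@dataclass
class ForceTrace:
    """Time series of the instantaneous pull-spring force."""

    times: np.ndarray    # (n,) ps, strictly increasing
    forces: np.ndarray   # (n,) kJ mol^-1 nm^-1, signed along +z
    protocol: PullProtocol

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.forces = np.asarray(self.forces, dtype=float)
        if self.times.shape != self.forces.shape or self.times.ndim != 1:
            raise ValueError("times and forces must be equal-length 1-D arrays")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("trace times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)
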