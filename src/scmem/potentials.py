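"""Test-harness potential terms for the Brownian-dynamics generator.

These are deliberately simple analytic terms — leaflet z-tethers, lateral
site tethers, a 1-D external profile U(z) built from Gaussians, linear
ramps, and intramolecular bond/angle springs.  They exist to give the
synthetic trajectories *known* ground truth (geometry, diffusion constants,
free-energy landscape); they are not a molecular force field.

Every term exposes ``add_forces(coords, box, out)`` accumulating forces in
kJ mol^-1 nm^-1 into ``out`` and, where meaningful, an ``energy`` helper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import minimum_image


def _idx(indices) -> np.ndarray:
    return np.atleast_1d(np.asarray(indices, dtype=np.int64))


@dataclass
class HarmonicZ:
    """Harmonic tether along z: U = k/2 (z - z0)^2 per selected bead."""

    indices: np.ndarray
    k: float
    z0: float | np.ndarray

    def __post_init__(self):
        self.indices = _idx(self.indices)
        if self.k < 0:
            raise ValueError("spring constant must be >= 0")

    def add_forces(self, coords, box, out):
        out[self.indices, 2] += -self.k * (coords[self.indices, 2] - self.z0)

    def max_stiffness(self) -> float:
        return self.k


@dataclass
class LateralTether:
    """Harmonic tether of selected beads to fixed lateral sites (x, y)."""

    indices: np.ndarray
    k: float
    sites: np.ndarray  # (n, 2)

    def __post_init__(self):
        self.indices = _idx(self.indices)
        self.sites = np.atleast_2d(np.asarray(self.sites, dtype=float))
        if self.k < 0:
            raise ValueError("spring constant must be >= 0")
        if self.sites.shape != (len(self.indices), 2):
            raise ValueError("need one (x, y) site per tethered bead")

    def add_forces(self, coords, box, out):
        out[self.indices, :2] += -self.k * (coords[self.indices, :2] - self.sites)

    def max_stiffness(self) -> float:
        return self.k


@dataclass
class GaussianZ:
    """External 1-D profile U(z) = sum_i h_i exp(-(z - c_i)^2 / (2 w_i^2)).

    Heights in kJ/mol (negative for wells), centers and widths in nm.
    """

    indices: np.ndarray
    heights: np.ndarray
    centers: np.ndarray
    widths: np.ndarray

    def __post_init__(self):
        self.indices = _idx(self.indices)
        self.heights = np.atleast_1d(np.asarray(self.heights, dtype=float))
        self.centers = np.atleast_1d(np.asarray(self.centers, dtype=float))
        self.widths = np.atleast_1d(np.asarray(self.widths, dtype=float))
        if not (len(self.heights) == len(self.centers) == len(self.widths)):
            raise ValueError("heights/centers/widths must align")
        if np.any(self.widths <= 0):
            raise ValueError("Gaussian widths must be > 0")

    def potential(self, z: np.ndarray | float) -> np.ndarray | float:
        z = np.asarray(z, dtype=float)
        u = np.zeros_like(z)
        for h, c, w in zip(self.heights, self.centers, self.widths):
            u = u + h * np.exp(-((z - c) ** 2) / (2 * w ** 2))
        return u

    def force(self, z):
        z = np.asarray(z, dtype=float)
        f = np.zeros_like(z)
        for h, c, w in zip(self.heights, self.centers, self.widths):
            f = f + h * (z - c) / w ** 2 * np.exp(-((z - c) ** 2) / (2 * w ** 2))
        return f

    def add_forces(self, coords, box, out):
        out[self.indices, 2] += self.force(coords[self.indices, 2])

    def min_width(self) -> float:
        return float(np.min(self.widths))

    def max_stiffness(self) -> float:
        # |U''| <= h (1 + ...) / w^2; h/w^2 is the right scale for stability.
        return float(np.max(np.abs(self.heights) / self.widths ** 2))


@dataclass
class LinearZ:
    """Linear ramp U = slope * z on selected beads (constant force -slope)."""

    indices: np.ndarray
    slope: float

    def __post_init__(self):
        self.indices = _idx(self.indices)

    def add_forces(self, coords, box, out):
        out[self.indices, 2] += -self.slope

    def max_stiffness(self) -> float:
        return 0.0


@dataclass
class Bonds:
    """Harmonic bonds U = k/2 (|r_ij| - r0)^2 with minimum-image vectors.

    ``r0`` may be a scalar or one rest length per bond.
    """

    pairs: np.ndarray  # (m, 2) bead indices
    k: float
    r0: float | np.ndarray

    def __post_init__(self):
        self.pairs = np.atleast_2d(np.asarray(self.pairs, dtype=np.int64))
        self.r0 = np.asarray(self.r0, dtype=float)
        if self.k < 0 or np.any(self.r0 < 0):
            raise ValueError("bond k and r0 must be >= 0")

    def add_forces(self, coords, box, out):
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        d = minimum_image(coords[j] - coords[i], box)
        r = np.linalg.norm(d, axis=1)
        r = np.where(r < 1e-12, 1e-12, r)
        f = (-self.k * (r - self.r0) / r)[:, None] * d  # force on j
        np.add.at(out, j, f)
        np.add.at(out, i, -f)

    def max_stiffness(self) -> float:
        return self.k


@dataclass
class Angles:
    """Harmonic angles U = k/2 (theta - theta0)^2 over bead triples (i, j, k)."""

    triples: np.ndarray  # (m, 3); j is the vertex
    k: float
    theta0: float  # radians

    def __post_init__(self):
        self.triples = np.atleast_2d(np.asarray(self.triples, dtype=np.int64))
        if self.k < 0:
            raise ValueError("angle k must be >= 0")

    def add_forces(self, coords, box, out):
        i, j, l = self.triples.T
        rij = minimum_image(coords[i] - coords[j], box)
        rlj = minimum_image(coords[l] - coords[j], box)
        nij = np.linalg.norm(rij, axis=1)
        nlj = np.linalg.norm(rlj, axis=1)
        nij = np.where(nij < 1e-12, 1e-12, nij)
        nlj = np.where(nlj < 1e-12, 1e-12, nlj)
        cos_t = np.clip(np.einsum("md,md->m", rij, rlj) / (nij * nlj), -1.0, 1.0)
        theta = np.arccos(cos_t)
        sin_t = np.sqrt(np.clip(1.0 - cos_t ** 2, 1e-12, None))
        coef = -self.k * (theta - self.theta0) / sin_t
        fi = (coef / nij)[:, None] * (rlj / nlj[:, None] - cos_t[:, None] * rij / nij[:, None])
        fl = (coef / nlj)[:, None] * (rij / nij[:, None] - cos_t[:, None] * rlj / nlj[:, None])
        np.add.at(out, i, fi)
        np.add.at(out, l, fl)
        np.add.at(out, j, -(fi + fl))

    def max_stiffness(self) -> float:
        return 0.0  # angle stiffness has units of energy, not energy/length^2


@dataclass
class PotentialSpec:
    """A sum of analytic potential terms acting on a frame of beads."""

    terms: list = field(default_factory=list)

    def add(self, term) -> "PotentialSpec":
        self.terms.append(term)
        return self

    def forces(self, coords: np.ndarray, box: np.ndarray) -> np.ndarray:
        out = np.zeros_like(coords)
        for term in self.terms:
            term.add_forces(coords, box, out)
        return out

    def max_stiffness(self) -> float:
        """Largest harmonic stiffness (kJ mol^-1 nm^-2) among the terms."""
        return max((t.max_stiffness() for t in self.terms), default=0.0)

    def min_length_scale(self) -> float | None:
        """Smallest Gaussian width among profile terms, if any."""
        widths = [t.min_width() for t in self.terms if isinstance(t, GaussianZ)]
        return min(widths) if widths else None
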