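"""Potential of mean force from constant-velocity pull force traces.

A tracer dragged through the membrane by a harmonic spring whose center
moves at constant speed does work W = int F dz on the system; in the
stiff-spring, slow-pull limit the accumulated work along the spring-center
schedule converges to the free-energy profile W(z).  The estimator here
integrates the instantaneous spring force over the schedule (trapezoid
rule), bins the work samples onto a uniform z grid, anchors the profile to
zero over a bulk-solvent reference region, and averages replicates
arithmetically.  No Jarzynski reweighting is applied; the friction bias of
a finite pull speed (~ gamma v per unit length) is reported as a
diagnostic, not corrected.

Energies are carried in kJ/mol with kcal/mol at the output boundary
(1 kcal = 4.184 kJ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import KCAL, ForceTrace


def integrate_work(trace: ForceTrace) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative pull work along the spring-center schedule.

    z(t) = z0 + direction * v * t; W(z(t_k)) is the cumulative trapezoid of
    F dz up to sample k, with W(z0) = 0.  Returns (z, W) in (nm, kJ/mol).
    """
    if len(trace) < 2:
        raise ValueError("need at least 2 force samples to integrate")
    t, f = trace.times, trace.forces
    if not np.all(np.diff(t) > 0):
        raise ValueError("trace times must be strictly increasing")
    p = trace.protocol
    z = p.origin + p.direction * p.speed * t
    dz = np.diff(z)
    w = np.concatenate([[0.0], np.cumsum(0.5 * (f[1:] + f[:-1]) * dz)])
    return z, w


@dataclass
class PMFProfile:
    """Free-energy profile on a uniform z grid (bilayer-centered nm)."""

    z: np.ndarray
    w_kj: np.ndarray
    counts: np.ndarray
    interpolated: np.ndarray          # bins filled by interpolation
    n_replicates: int = 1
    reference_region: tuple[float, float] | None = None
    bulk_side: str = "upper"          # side of the grid where the pull began

    def __post_init__(self) -> None:
        dz = np.diff(self.z)
        if len(dz) and not np.allclose(dz, dz[0], rtol=1e-6, atol=1e-12):
            raise ValueError("PMF grid must be uniform")

    @property
    def w_kcal(self) -> np.ndarray:
        return self.w_kj / KCAL

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_nm": self.z, "W_kJ_mol": self.w_kj,
                             "W_kcal_mol": self.w_kcal, "n": self.counts,
                             "interpolated": self.interpolated})


def bin_profile(z: np.ndarray, w: np.ndarray, spacing: float = 0.05,
                bulk_side: str | None = None) -> PMFProfile:
    """Average work samples onto a uniform z grid.

    Bin value = mean of the W samples falling in the bin.  Empty *interior*
    bins are filled by linear interpolation and flagged; empty bins at the
    grid edges are trimmed.
    """
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    if z.shape != w.shape or z.ndim != 1 or len(z) == 0:
        raise ValueError("z and w must be equal-length 1-D arrays")
    if spacing <= 0:
        raise ValueError("grid spacing must be > 0")
    lo = np.floor(z.min() / spacing) * spacing
    hi = np.ceil(z.max() / spacing) * spacing
    if hi <= lo:
        hi = lo + spacing
    n_bins = int(round((hi - lo) / spacing))
    edges = lo + spacing * np.arange(n_bins + 1)
    idx = np.clip(np.floor((z - lo) / spacing).astype(int), 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=w, minlength=n_bins)
    if not counts.any():
        raise ValueError("grid disjoint from samples")
    nz = np.nonzero(counts)[0]
    first, last = nz[0], nz[-1]          # trim empty edge bins
    counts = counts[first:last + 1]
    sums = sums[first:last + 1]
    centers = 0.5 * (edges[first:last + 1] + edges[first + 1:last + 2])
    filled = counts > 0
    values = np.where(filled, sums / np.where(filled, counts, 1.0), np.nan)
    interpolated = ~filled
    if interpolated.any():
        values[~filled] = np.interp(centers[~filled], centers[filled],
                                    values[filled])
    if bulk_side is None:
        bulk_side = "upper" if z[0] >= z[-1] else "lower"
    return PMFProfile(centers, values, counts, interpolated,
                      bulk_side=bulk_side)


def reference_and_average(profiles: list[PMFProfile],
                          reference_region: tuple[float, float] | None = None,
                          reference_width: float = 0.5) -> PMFProfile:
    """Anchor each profile to zero over a bulk region and average them.

    All profiles must share one grid.  The default reference region is the
    outermost ``reference_width`` nm of the grid on the bulk side (where
    the pull began).  Each profile is shifted so its mean over the region
    is zero, then averaged point-wise.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    ref = profiles[0]
    for p in profiles[1:]:
        if len(p.z) != len(ref.z) or not np.allclose(p.z, ref.z,
                                                     rtol=1e-9, atol=1e-9):
            raise ValueError("profiles do not share a grid")
    if reference_region is None:
        if ref.bulk_side == "upper":
            reference_region = (ref.z[-1] - reference_width, ref.z[-1])
        else:
            reference_region = (ref.z[0], ref.z[0] + reference_width)
    lo, hi = reference_region
    m = (ref.z >= lo - 1e-12) & (ref.z <= hi + 1e-12)
    if not m.any():
        raise ValueError(
            f"reference region [{lo}, {hi}] nm not sampled by the grid")
    shifted = np.stack([p.w_kj - p.w_kj[m].mean() for p in profiles])
    return PMFProfile(ref.z.copy(), shifted.mean(axis=0),
                      np.sum([p.counts for p in profiles], axis=0),
                      np.any([p.interpolated for p in profiles], axis=0),
                      n_replicates=len(profiles),
                      reference_region=(float(lo), float(hi)),
                      bulk_side=ref.bulk_side)


@dataclass
class PMFDescriptors:
    """Barrier/minimum descriptors of a permeation profile (kcal/mol)."""

    entry_barrier: float       # max W from bulk edge to the interior minimum
    barrier_position: float    # nm
    global_min_depth: float    # min W over the membrane interior
    min_position: float        # nm

    def to_dict(self) -> dict:
        return {"entry_barrier_kcal_mol": self.entry_barrier,
                "barrier_position_nm": self.barrier_position,
                "global_min_depth_kcal_mol": self.global_min_depth,
                "min_position_nm": self.min_position}


def descriptors(profile: PMFProfile,
                membrane_interior: tuple[float, float]) -> PMFDescriptors:
    """Entry barrier and global interior minimum of an anchored profile.

    The entry barrier is the maximum W (relative to the bulk anchor at 0)
    on the path from the bulk-side grid edge to the interior minimum; the
    global minimum depth is the lowest W inside ``membrane_interior``.
    """
    lo, hi = membrane_interior
    interior = (profile.z >= lo) & (profile.z <= hi)
    if not interior.any():
        raise ValueError(
            f"membrane interior [{lo}, {hi}] nm lies outside the grid")
    w_kcal = profile.w_kcal
    i_min = np.nonzero(interior)[0][np.argmin(w_kcal[interior])]
    if profile.bulk_side == "upper":
        path = slice(i_min, len(profile.z))
    else:
        path = slice(0, i_min + 1)
    i_bar = np.arange(len(profile.z))[path][np.argmax(w_kcal[path])]
    return PMFDescriptors(
        entry_barrier=max(float(w_kcal[i_bar]), 0.0),
        barrier_position=float(profile.z[i_bar]),
        global_min_depth=float(w_kcal[i_min]),
        min_position=float(profile.z[i_min]))


def symmetrize(profile: PMFProfile) -> PMFProfile:
    """Average a profile with its mirror image about the bilayer center.

    Off by default (a single-direction pull has no business being
    symmetric); useful when pulls in both directions across a symmetric
    bilayer are averaged.  Points whose mirror falls outside the grid keep
    their one-sided value.
    """
    z, w = profile.z, profile.w_kj
    mirrored = np.interp(-z, z, w, left=np.nan, right=np.nan)
    w_sym = np.where(np.isnan(mirrored), w, 0.5 * (w + mirrored))
    return PMFProfile(z.copy(), w_sym, profile.counts.copy(),
                      profile.interpolated.copy(),
                      n_replicates=profile.n_replicates,
                      reference_region=profile.reference_region,
                      bulk_side=profile.bulk_side)


def friction_bias_bound(gamma: float, speed: float, pulled_range: float) -> float:
    """Dissipation bound gamma * v * L (kJ/mol) for a pull diagnostic.

    ``gamma`` is the tracer friction kBT/D in kJ mol^-1 ps nm^-2.  Forward
    and backward pulls over a symmetric landscape should agree within this
    bound; it also bounds the work overestimate of a finite-speed pull.
    """
    return gamma * speed * pulled_range


def rmsd(profile: PMFProfile, reference: np.ndarray,
         region: tuple[float, float] | None = None) -> float:
    """RMSD (kcal/mol) between an anchored profile and reference values.

    ``reference`` gives the true free energy in kcal/mol on ``profile.z``.
    """
    w = profile.w_kcal
    if region is not None:
        m = (profile.z >= region[0]) & (profile.z <= region[1])
        w, reference = w[m], np.asarray(reference)[m]
    return float(np.sqrt(np.mean((w - np.asarray(reference)) ** 2)))
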