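"""Lateral diffusion coefficients from mean-squared displacement.

The estimator is the standard Einstein route: unwrap lateral coordinates
across the periodic boundary, remove the membrane's center-of-mass drift,
average MSD(tau) over molecules and all (overlapping) time origins, and
fit a line over an interior lag window; D = slope / (2 d) with d = 2 for
lateral motion.  Dispersion is reported across molecules, matching how
per-component error bars are usually drawn.

The per-molecule time-averaged MSD uses the FFT (Wiener–Khinchin)
algorithm, exact for all time origins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Trajectory, minimum_image

#: 1 nm^2/ps = 1e-14 cm^2 / 1e-12 s = 1e-2 cm^2/s.
NM2_PER_PS_TO_CM2_PER_S = 1e-2


def unwrap_lateral(traj: Trajectory) -> Trajectory:
    """Make x/y coordinates continuous across the periodic boundary.

    Accumulates minimum-image displacements between consecutive frames;
    z is untouched.  Requires adequate sampling: a per-bead minimum-image
    displacement reaching half the box between consecutive frames is
    ambiguous and raises, citing frame and bead.  Already-unwrapped input
    is returned unchanged (copy).
    """
    out = traj.copy()
    if traj.unwrapped or traj.n_frames < 2:
        out.unwrapped = True
        return out
    xy = out.coords[:, :, :2]
    raw = np.diff(xy, axis=0)
    disp = minimum_image(raw, traj.boxes[:-1, None, :2])
    bad = np.abs(disp) >= traj.boxes[:-1, None, :2] / 2
    if bad.any():
        f, b, _ = np.argwhere(bad)[0]
        raise ValueError(
            f"frame {f + 1}, bead {b}: displacement reaches half the box; "
            "sampling too sparse to unwrap")
    out.coords[1:, :, :2] = xy[0] + np.cumsum(disp, axis=0)
    out.unwrapped = True
    return out


def wrap_lateral(traj: Trajectory) -> Trajectory:
    """Inverse of :func:`unwrap_lateral`: wrap x/y back into the primary box."""
    out = traj.copy()
    lxy = out.boxes[:, None, :2]
    xy = out.coords[:, :, :2]
    out.coords[:, :, :2] = xy - lxy * np.floor(xy / lxy + 0.5)
    out.unwrapped = False
    return out


@dataclass
class MSDResult:
    """Lateral MSD per molecule and ensemble mean."""

    lags: np.ndarray           # ps
    msd: np.ndarray            # (n_lags,) nm^2, ensemble mean
    per_molecule: np.ndarray   # (n_molecules, n_lags) nm^2
    component: str
    molecules: list[tuple[str, int]]


def _msd_fft(x: np.ndarray) -> np.ndarray:
    """Time-averaged 1-D MSD over all origins for each row of x (m, T)."""
    m, T = x.shape
    nfft = 1 << (2 * T - 1).bit_length()
    f = np.fft.rfft(x, n=nfft, axis=1)
    s2 = np.fft.irfft(f * np.conj(f), n=nfft, axis=1)[:, :T].real
    counts = T - np.arange(T)
    s2 /= counts
    d = x ** 2
    q = 2.0 * d.sum(axis=1)
    s1 = np.empty_like(s2)
    s1[:, 0] = q / T
    for tau in range(1, T):
        q -= d[:, tau - 1] + d[:, T - tau]
        s1[:, tau] = q / (T - tau)
    return s1 - 2.0 * s2


def compute_msd(traj: Trajectory, component: str | np.ndarray,
                max_lag_fraction: float = 0.5,
                remove_drift: bool = True,
                drift_selection: np.ndarray | None = None) -> MSDResult:
    """Lateral MSD(tau), molecule- and time-origin-averaged.

    ``component`` is a species name or a boolean bead mask; each molecule
    contributes the centroid of its selected beads.  Membrane
    center-of-mass drift is removed by subtracting the per-frame mean
    lateral displacement of the drift reference (default: every selected
    bead's molecule set, i.e. all analyzed beads).  The trajectory must be
    unwrapped and uniformly sampled in time.
    """
    if not traj.unwrapped:
        raise ValueError("compute_msd needs an unwrapped trajectory; "
                         "run unwrap_lateral first")
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    dts = np.diff(traj.times)
    if not np.allclose(dts, dts[0], rtol=1e-8, atol=1e-12):
        raise ValueError("frames must be uniformly spaced in time")
    if isinstance(component, str):
        mask = traj.labels.mask(species=component)
        name = component
    else:
        mask = np.asarray(component, dtype=bool)
        name = "selection"
    if not mask.any():
        raise ValueError(f"empty selection for component {name!r}")

    xy = traj.coords[:, :, :2]
    if remove_drift:
        ref = mask if drift_selection is None else np.asarray(drift_selection,
                                                              dtype=bool)
        drift = xy[:, ref, :].mean(axis=1)
        xy = xy - (drift - drift[0])[:, None, :]

    mols = traj.labels.molecules()
    mols = [(s, m) for s, m in mols
            if mask[(traj.labels.molecule_index == m)
                    & (traj.labels.species.astype(str) == s)].any()]
    centroids = np.empty((len(mols), traj.n_frames, 2))
    mol_idx = traj.labels.molecule_index
    species_arr = traj.labels.species.astype(str)
    for k, (s, m) in enumerate(mols):
        bm = mask & (mol_idx == m) & (species_arr == s)
        centroids[k] = xy[:, bm, :].mean(axis=1)

    n_lags = max(int(round(max_lag_fraction * (traj.n_frames - 1))), 1) + 1
    per_mol = (_msd_fft(centroids[:, :, 0]) +
               _msd_fft(centroids[:, :, 1]))[:, :n_lags]
    per_mol[:, 0] = 0.0  # exact by definition; clears FFT round-off
    lags = (traj.times - traj.times[0])[:n_lags]
    return MSDResult(lags, per_mol.mean(axis=0), per_mol, name, mols)


@dataclass
class DiffusionEstimate:
    """Fitted lateral diffusion coefficient with cross-molecule dispersion."""

    d_mean: float              # nm^2 / ps
    d_sd: float                # nm^2 / ps, std across molecules
    per_molecule: np.ndarray   # (n_molecules,) nm^2 / ps
    fit_window: tuple[float, float]   # ps
    dimensionality: int
    component: str
    nonlinear: bool            # curvature diagnostic: MSD/tau not constant

    @property
    def d_mean_cm2_s(self) -> float:
        return self.d_mean * NM2_PER_PS_TO_CM2_PER_S

    @property
    def d_sd_cm2_s(self) -> float:
        return self.d_sd * NM2_PER_PS_TO_CM2_PER_S

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "component": self.component,
            "D_nm2_ps": self.d_mean, "D_sd_nm2_ps": self.d_sd,
            "D_cm2_s": self.d_mean_cm2_s, "D_sd_cm2_s": self.d_sd_cm2_s,
            "n_molecules": len(self.per_molecule),
            "fit_lag_min_ps": self.fit_window[0],
            "fit_lag_max_ps": self.fit_window[1],
            "nonlinear_flag": self.nonlinear}])


def fit_diffusion(msd: MSDResult, fit_window: tuple[float, float] = (0.1, 0.5),
                  dimensionality: int = 2,
                  curvature_tol: float = 0.25) -> DiffusionEstimate:
    """Least-squares line through MSD vs lag; D = slope / (2 d).

    ``fit_window`` is a (lo, hi) pair of fractions of the maximum lag;
    the default [10%, 50%] skips short-lag correlation and long-lag noise.
    Per-molecule slopes give the dispersion.  A curvature diagnostic
    compares the slope over the two halves of the window and flags the fit
    when they differ by more than ``curvature_tol`` relative (e.g. pure
    drift, confinement).
    """
    lo, hi = fit_window
    if not 0 <= lo < hi <= 1:
        raise ValueError("fit_window fractions must satisfy 0 <= lo < hi <= 1")
    n = len(msd.lags)
    i0, i1 = int(np.floor(lo * (n - 1))), int(np.ceil(hi * (n - 1)))
    if i1 - i0 + 1 < 2:
        raise ValueError("fewer than 2 lags in the fit window")
    sl = slice(i0, i1 + 1)
    tau = msd.lags[sl]

    def slope(y: np.ndarray, t: np.ndarray) -> np.ndarray:
        t0 = t - t.mean()
        return (y - y.mean(axis=-1, keepdims=True)) @ t0 / (t0 @ t0)

    s_all = float(slope(msd.msd[sl], tau))
    s_mol = slope(msd.per_molecule[:, sl], tau)
    mid = (i0 + i1) // 2
    nonlinear = False
    if mid - i0 >= 1 and i1 - mid >= 1:
        s1 = float(slope(msd.msd[i0:mid + 1], msd.lags[i0:mid + 1]))
        s2 = float(slope(msd.msd[mid:i1 + 1], msd.lags[mid:i1 + 1]))
        scale = max(abs(s1), abs(s2), 1e-300)
        nonlinear = abs(s2 - s1) / scale > curvature_tol and scale > 1e-15
    denom = 2.0 * dimensionality
    return DiffusionEstimate(
        d_mean=s_all / denom, d_sd=float(np.std(s_mol / denom, ddof=0)),
        per_molecule=s_mol / denom,
        fit_window=(float(tau[0]), float(tau[-1])),
        dimensionality=dimensionality, component=msd.component,
        nonlinear=nonlinear)
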