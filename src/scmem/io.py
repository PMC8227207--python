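"""Readers and writers for the file formats the pipeline touches.

GRO coordinate files (fixed-column dialect), a documented plain-text frame
format for multi-frame trajectories, XTC via an MDAnalysis adapter, and
two-column XVG force traces with ``#``/``@`` comment headers.

Plain-text frame format (``.frames``), one block per frame::

    # scmem frames 1
    frame <time_ps> <n_beads>
    box <bx> <by> <bz>
    <x> <y> <z>        (n_beads rows, nm)

Bead labels are not stored in the frame file; they are supplied by the
caller (typically from the GRO file of the initial configuration).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .model import BeadLabels, ForceTrace, PullProtocol, Trajectory


class ParseError(ValueError):
    """A file violated its format contract; the message names the line."""


# ---------------------------------------------------------------------------
# GRO
# ---------------------------------------------------------------------------

def read_gro(path: str | os.PathLike) -> Trajectory:
    """Read a GRO coordinate file into a single-frame :class:`Trajectory`.

    Columns follow the fixed GRO layout (resid 0:5, resname 5:10, atom name
    10:15, atom number 15:20, x/y/z in 8.3f fields).  Velocities, if
    present, are ignored.  Coordinates are nm.
    """
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: fewer than 3 lines, not a GRO file")
    title = lines[0]
    try:
        n_atoms = int(lines[1].strip())
    except ValueError:
        raise ParseError(f"{path}: line 2: malformed atom count "
                         f"{lines[1].strip()!r}") from None
    if len(lines) < 2 + n_atoms + 1:
        raise ParseError(
            f"{path}: declares {n_atoms} atoms but holds only "
            f"{max(len(lines) - 3, 0)} coordinate records")
    species, molidx, bead = [], [], []
    coords = np.empty((n_atoms, 3))
    for i in range(n_atoms):
        ln = lines[2 + i]
        try:
            molidx.append(int(ln[0:5]))
            species.append(ln[5:10].strip())
            bead.append(ln[10:15].strip())
            coords[i] = [float(ln[20:28]), float(ln[28:36]), float(ln[36:44])]
        except (ValueError, IndexError):
            raise ParseError(f"{path}: line {3 + i}: malformed atom record "
                             f"{ln!r}") from None
    box_line = lines[2 + n_atoms].split()
    if len(box_line) < 3:
        raise ParseError(f"{path}: line {3 + n_atoms}: missing or short box line")
    try:
        box = np.array([float(v) for v in box_line[:3]])
    except ValueError:
        raise ParseError(f"{path}: line {3 + n_atoms}: malformed box line") from None
    time = 0.0
    if "t=" in title:
        try:
            time = float(title.rsplit("t=", 1)[1].split()[0])
        except (ValueError, IndexError):
            time = 0.0
    labels = BeadLabels(np.array(species, dtype=object),
                        np.array(molidx), np.array(bead, dtype=object))
    return Trajectory(np.array([time]), box[None, :], coords[None, :, :], labels)


def write_gro(path: str | os.PathLike, traj: Trajectory, frame: int = 0,
              title: str = "scmem configuration") -> None:
    """Write one frame of a trajectory as a GRO file (3-decimal nm)."""
    lab = traj.labels
    xyz = traj.coords[frame]
    with open(path, "w") as fh:
        fh.write(f"{title}, t= {traj.times[frame]:.3f}\n")
        fh.write(f"{traj.n_beads:5d}\n")
        for i in range(traj.n_beads):
            fh.write("%5d%-5s%5s%5d%8.3f%8.3f%8.3f\n" % (
                int(lab.molecule_index[i]) % 100000, str(lab.species[i])[:5],
                str(lab.bead_name[i])[:5], (i + 1) % 100000,
                xyz[i, 0], xyz[i, 1], xyz[i, 2]))
        fh.write("%10.5f%10.5f%10.5f\n" % tuple(traj.boxes[frame]))


# ---------------------------------------------------------------------------
# Multi-frame trajectories
# ---------------------------------------------------------------------------

def write_frames(path: str | os.PathLike, traj: Trajectory) -> None:
    """Write a trajectory in the plain-text frame format."""
    with open(path, "w") as fh:
        fh.write("# scmem frames 1\n")
        for f in range(traj.n_frames):
            fh.write(f"frame {traj.times[f]:.6f} {traj.n_beads}\n")
            fh.write("box %.6f %.6f %.6f\n" % tuple(traj.boxes[f]))
            np.savetxt(fh, traj.coords[f], fmt="%.6f")


def _read_text_frames(path: str | os.PathLike, labels: BeadLabels) -> Trajectory:
    times, boxes, frames = [], [], []
    with open(path) as fh:
        lineno = 0
        line = None

        def nextline():
            nonlocal lineno
            while True:
                ln = fh.readline()
                lineno += 1
                if not ln:
                    return None
                ln = ln.strip()
                if ln and not ln.startswith("#"):
                    return ln

        while True:
            line = nextline()
            if line is None:
                break
            parts = line.split()
            if parts[0] != "frame" or len(parts) != 3:
                raise ParseError(f"{path}: line {lineno}: expected "
                                 f"'frame <time> <n>', got {line!r}")
            t, n = float(parts[1]), int(parts[2])
            if n != len(labels):
                raise ParseError(
                    f"{path}: line {lineno}: frame holds {n} beads but "
                    f"labels describe {len(labels)}")
            box_ln = nextline()
            if box_ln is None or not box_ln.startswith("box"):
                raise ParseError(f"{path}: line {lineno}: missing box line "
                                 f"for frame at t={t}")
            box = [float(v) for v in box_ln.split()[1:4]]
            xyz = np.empty((n, 3))
            for i in range(n):
                row = nextline()
                if row is None:
                    raise ParseError(
                        f"{path}: unreadable frame {len(frames)}: ended after "
                        f"{i} of {n} coordinate rows")
                try:
                    xyz[i] = [float(v) for v in row.split()[:3]]
                except (ValueError, IndexError):
                    raise ParseError(f"{path}: line {lineno}: malformed "
                                     f"coordinate row {row!r}") from None
            times.append(t)
            boxes.append(box)
            frames.append(xyz)
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return Trajectory(np.array(times), np.array(boxes), np.array(frames), labels)


def _read_xtc(path: str | os.PathLike, labels: BeadLabels) -> Trajectory:
    # MDAnalysis works in angstrom; the adapter converts to nm on the way in.
    from MDAnalysis.coordinates.XTC import XTCReader

    times, boxes, frames = [], [], []
    with XTCReader(str(path)) as reader:
        if reader.n_atoms != len(labels):
            raise ParseError(
                f"{path}: XTC holds {reader.n_atoms} beads but labels "
                f"describe {len(labels)}")
        for ts in reader:
            times.append(float(ts.time))
            boxes.append(np.asarray(ts.dimensions[:3], dtype=float) / 10.0)
            frames.append(np.asarray(ts.positions, dtype=float) / 10.0)
    return Trajectory(np.array(times), np.array(boxes), np.array(frames), labels)


def read_frames(path: str | os.PathLike, labels: BeadLabels | Trajectory) -> Trajectory:
    """Read a multi-frame trajectory, dispatching on the file suffix.

    ``.xtc`` goes through the MDAnalysis adapter; anything else is parsed as
    the plain-text frame format.  ``labels`` supplies per-bead identities and
    may be a :class:`BeadLabels` or any trajectory carrying them.
    """
    if isinstance(labels, Trajectory):
        labels = labels.labels
    if str(path).endswith(".xtc"):
        return _read_xtc(path, labels)
    return _read_text_frames(path, labels)


# ---------------------------------------------------------------------------
# XVG force traces
# ---------------------------------------------------------------------------

_PROTO_KEYS = ("speed", "spring_k", "origin", "direction")


def read_xvg(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column XVG file; ``#``/``@`` lines are comments.

    Returns ``(times, values)`` in file order.
    """
    times, values = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            ln = raw.strip()
            if not ln or ln.startswith("#") or ln.startswith("@"):
                continue
            parts = ln.split()
            try:
                t, v = float(parts[0]), float(parts[1])
            except (ValueError, IndexError):
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric data row {ln!r}") from None
            times.append(t)
            values.append(v)
    if len(times) < 2:
        raise ParseError(f"{path}: fewer than 2 data rows")
    return np.array(times), np.array(values)


def write_pull_xvg(path: str | os.PathLike, trace: ForceTrace) -> None:
    """Write a force trace as two-column XVG with protocol metadata headers."""
    p = trace.protocol
    with open(path, "w") as fh:
        fh.write("@ title \"scmem pull force\"\n")
        fh.write("@ xaxis label \"time (ps)\"\n")
        fh.write("@ yaxis label \"force (kJ/mol/nm)\"\n")
        fh.write(f"@ scmem speed {p.speed:.10g}\n")
        fh.write(f"@ scmem spring_k {p.spring_k:.10g}\n")
        fh.write(f"@ scmem origin {p.origin:.10g}\n")
        fh.write(f"@ scmem direction {p.direction:d}\n")
        for t, f in zip(trace.times, trace.forces):
            fh.write(f"{t:.6f} {f:.8f}\n")


def read_pull_xvg(path: str | os.PathLike,
                  protocol: PullProtocol | None = None) -> ForceTrace:
    """Read a pull-force XVG into a :class:`ForceTrace`.

    Protocol parameters are taken from ``@ scmem <key> <value>`` headers if
    present; an explicit ``protocol`` argument overrides the headers.
    """
    meta: dict[str, float] = {}
    with open(path) as fh:
        for raw in fh:
            ln = raw.strip()
            if ln.startswith("@ scmem "):
                parts = ln.split()
                if len(parts) == 4 and parts[2] in _PROTO_KEYS:
                    meta[parts[2]] = float(parts[3])
    times, forces = read_xvg(path)
    if protocol is None:
        missing = [k for k in _PROTO_KEYS if k not in meta]
        if missing:
            raise ParseError(
                f"{path}: no protocol given and headers missing {missing}")
        protocol = PullProtocol(speed=meta["speed"], spring_k=meta["spring_k"],
                                origin=meta["origin"],
                                direction=int(meta["direction"]))
    return ForceTrace(times, forces, protocol)
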