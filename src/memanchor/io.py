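"""Readers and writers for the package's on-disk formats.

Three text formats are used:

* GRO structure files (fixed-column dialect) carrying atom names,
  residues and one set of coordinates;
* a topology sidecar CSV with the per-atom annotations a GRO file cannot
  hold (element, mass, charge, leaflet, hydrogen-bond role);
* multi-frame extended-XYZ trajectories whose comment line carries the
  frame time (ps) and the orthorhombic box lengths (nm), e.g.
  ``time=200.0 box=6.4,6.4,10.0``.

Only orthorhombic boxes are supported; a GRO box line with non-zero
off-diagonal components raises :class:`UnsupportedFormatError`.
Truncated files always raise rather than returning partial data.
"""

from __future__ import annotations

import re
from pathlib import Path
import numpy as np
import pandas as pd

from .core import SIDECAR_COLUMNS, Frame, Topology, Trajectory


class GroParseError(ValueError):
    """Malformed GRO input; the message names the offending line."""


class XYZParseError(ValueError):
    """Malformed extended-XYZ trajectory input."""


class UnsupportedFormatError(ValueError):
    """Input uses a feature outside the supported dialect (e.g. triclinic box)."""


# ---------------------------------------------------------------------------
# GRO structure files
# ---------------------------------------------------------------------------

def read_gro(path: str | Path) -> tuple[pd.DataFrame, Frame]:
    """Read a GRO structure file.

    Returns a topology *skeleton* (DataFrame with ``atom_id``, ``name``,
    ``residue_name``, ``residue_id``) and one :class:`Frame`.  Positions
    are in nm; velocity columns, if present, are ignored.  Use
    :func:`load_system` to combine with a sidecar CSV into a full
    :class:`Topology`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GroParseError(f"{path}: file too short to be a GRO file")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise GroParseError(f"{path}, line 2: malformed atom count "
                            f"{lines[1]!r}") from exc
    if len(lines) < 2 + n_atoms + 1:
        raise GroParseError(
            f"{path}: declared {n_atoms} atoms but file ends at line {len(lines)}"
        )

    rec = {"atom_id": [], "name": [], "residue_name": [], "residue_id": []}
    positions = np.empty((n_atoms, 3))
    for i in range(n_atoms):
        ln = 3 + i  # 1-based line number
        line = lines[2 + i]
        if len(line) < 44:
            raise GroParseError(f"{path}, line {ln}: atom record too short")
        try:
            rec["residue_id"].append(int(line[0:5]))
            rec["residue_name"].append(line[5:10].strip())
            rec["name"].append(line[10:15].strip())
            rec["atom_id"].append(i + 1)  # GRO atom numbers wrap at 99999
            positions[i, 0] = float(line[20:28])
            positions[i, 1] = float(line[28:36])
            positions[i, 2] = float(line[36:44])
        except ValueError as exc:
            raise GroParseError(f"{path}, line {ln}: malformed atom record "
                                f"{line!r}") from exc

    box_ln = 2 + n_atoms + 1
    try:
        box_vals = [float(tok) for tok in lines[2 + n_atoms].split()]
    except ValueError as exc:
        raise GroParseError(f"{path}, line {box_ln}: malformed box line "
                            f"{lines[2 + n_atoms]!r}") from exc
    if len(box_vals) == 9:
        if any(abs(v) > 0 for v in box_vals[3:]):
            raise UnsupportedFormatError(
                f"{path}, line {box_ln}: triclinic boxes are not supported"
            )
        box_vals = box_vals[:3]
    if len(box_vals) != 3:
        raise GroParseError(
            f"{path}, line {box_ln}: expected 3 (or 9) box components, "
            f"got {len(box_vals)}"
        )
    if any(v <= 0 for v in box_vals):
        raise GroParseError(f"{path}, line {box_ln}: non-positive box length")

    skeleton = pd.DataFrame(rec)[["atom_id", "name", "residue_name", "residue_id"]]
    frame = Frame(time=0.0, box=np.array(box_vals), positions=positions)
    return skeleton, frame


def write_gro(path: str | Path, topology: Topology, frame: Frame,
              title: str = "memanchor system") -> None:
    """Write a GRO structure file (positions only, %8.3f precision)."""
    if frame.n_atoms != topology.n_atoms:
        raise ValueError("frame and topology atom counts differ")
    with open(path, "w") as fh:
        fh.write(f"{title}\n{topology.n_atoms}\n")
        for i in range(topology.n_atoms):
            resid = int(topology.residue_ids[i]) % 100000
            atomid = (i + 1) % 100000
            x, y, z = frame.positions[i]
            fh.write(
                f"{resid:5d}{topology.residue_names[i]:<5.5s}"
                f"{topology.names[i]:>5.5s}{atomid:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        fh.write(f"{frame.box[0]:10.5f}{frame.box[1]:10.5f}{frame.box[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# Topology sidecar CSV
# ---------------------------------------------------------------------------

def read_sidecar(path: str | Path) -> Topology:
    """Read the topology annotation sidecar CSV into a :class:`Topology`."""
    df = pd.read_csv(path, dtype={"bonded_donor_id": "Int64"})
    missing = [c for c in SIDECAR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: sidecar is missing columns {missing}")
    return Topology(df)


def write_sidecar(path: str | Path, topology: Topology) -> None:
    topology.to_dataframe().to_csv(path, index=False)


def load_system(gro_path: str | Path, sidecar_path: str | Path
                ) -> tuple[Topology, Frame]:
    """Combine a GRO structure and its sidecar into (Topology, Frame).

    The two files must agree on atom count, atom names and residue
    names; a mismatch raises ``ValueError`` naming the first offending
    atom.
    """
    skeleton, frame = read_gro(gro_path)
    topology = read_sidecar(sidecar_path)
    if len(skeleton) != topology.n_atoms:
        raise ValueError(
            f"atom count mismatch: {gro_path} has {len(skeleton)}, "
            f"{sidecar_path} has {topology.n_atoms}"
        )
    for col in ("name", "residue_name"):
        a = skeleton[col].to_numpy()
        b = topology.to_dataframe()[col].to_numpy()
        bad = np.flatnonzero(a != b)
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"{col} mismatch at atom {i + 1}: GRO has {a[i]!r}, "
                f"sidecar has {b[i]!r}"
            )
    return topology, frame


# ---------------------------------------------------------------------------
# Extended-XYZ trajectories
# ---------------------------------------------------------------------------

_COMMENT_RE = re.compile(
    r"time=(?P<time>[-+0-9.eE]+)\s+"
    r"box=(?P<bx>[-+0-9.eE]+),(?P<by>[-+0-9.eE]+),(?P<bz>[-+0-9.eE]+)"
)


def write_xyz_trajectory(path: str | Path, traj: Trajectory,
                         decimals: int = 6) -> None:
    """Write a trajectory as multi-frame extended XYZ (nm / ps)."""
    elements = traj.topology.elements
    fmt = f"%.{decimals}f"
    with open(path, "w") as fh:
        for frame in traj.frames:
            fh.write(f"{frame.n_atoms}\n")
            fh.write(
                f"time={frame.time:.{decimals}f} "
                f"box={frame.box[0]:.{decimals}f},{frame.box[1]:.{decimals}f},"
                f"{frame.box[2]:.{decimals}f}\n"
            )
            for el, pos in zip(elements, frame.positions):
                fh.write(f"{el} {fmt % pos[0]} {fmt % pos[1]} {fmt % pos[2]}\n")


def read_xyz_trajectory(path: str | Path, topology: Topology) -> Trajectory:
    """Read a multi-frame extended-XYZ trajectory.

    Every frame must carry ``time=<ps> box=<Lx>,<Ly>,<Lz>`` on its
    comment line and match the topology's atom count.  Non-increasing
    frame times or a truncated final frame raise :class:`XYZParseError`.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    n_lines = len(lines)
    while i < n_lines:
        if lines[i].strip() == "" and i == n_lines - 1:
            break  # trailing blank line
        ln = i + 1
        try:
            n_atoms = int(lines[i].strip())
        except ValueError as exc:
            raise XYZParseError(
                f"{path}, line {ln}: expected atom count, got {lines[i]!r}"
            ) from exc
        if n_atoms != topology.n_atoms:
            raise XYZParseError(
                f"{path}, line {ln}: frame has {n_atoms} atoms, "
                f"topology has {topology.n_atoms}"
            )
        if i + 1 >= n_lines:
            raise XYZParseError(f"{path}: truncated file (missing comment line)")
        m = _COMMENT_RE.search(lines[i + 1])
        if m is None:
            raise XYZParseError(
                f"{path}, line {ln + 1}: comment line lacks "
                f"'time=<ps> box=<Lx>,<Ly>,<Lz>': {lines[i + 1]!r}"
            )
        time = float(m.group("time"))
        box = np.array([float(m.group(k)) for k in ("bx", "by", "bz")])
        if i + 2 + n_atoms > n_lines:
            raise XYZParseError(
                f"{path}: truncated frame starting at line {ln}"
            )
        positions = np.empty((n_atoms, 3))
        for j in range(n_atoms):
            toks = lines[i + 2 + j].split()
            if len(toks) < 4:
                raise XYZParseError(
                    f"{path}, line {ln + 2 + j}: malformed atom record"
                )
            positions[j] = [float(toks[1]), float(toks[2]), float(toks[3])]
        if frames and time <= frames[-1].time:
            raise XYZParseError(
                f"{path}, line {ln + 1}: frame time {time} not greater than "
                f"previous frame time {frames[-1].time}"
            )
        frames.append(Frame(time=time, box=box, positions=positions))
        i += 2 + n_atoms
    if not frames:
        raise XYZParseError(f"{path}: no frames found")
    return Trajectory(topology, frames)
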