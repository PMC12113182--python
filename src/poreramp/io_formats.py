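"""Readers and writers for the plain-text formats the pipeline touches.

* GRO — fixed-column GROMACS coordinate files, single- or multi-frame
  (frames concatenated, each with a ``t=`` title, atom count, records and a
  box line).  Positions are nm at three decimals; residue and atom serials
  are 1-based and wrap at 100000.  Velocities are ignored on read and
  omitted on write.
* XVG-dialect series — whitespace-separated numeric columns with ``#`` and
  ``@`` comment lines preserved as provenance.

Readers and writers are inverse pairs on their own output.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TextIO

import numpy as np

from .system_model import (
    BEAD_CHARGES,
    CAT_ANION,
    CAT_CATION,
    CAT_LIPID,
    CAT_WATER,
    LIPID_BEAD_NAMES,
    Box,
    Frame,
    MembraneError,
    MembraneSystem,
    Trajectory,
    assign_leaflets,
)


class ParseError(ValueError):
    """Malformed input; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None) -> None:
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def _open(stream, mode: str):
    if isinstance(stream, (str, Path)):
        return open(stream, mode), True
    return stream, False


# ---------------------------------------------------------------------------
# GRO


def format_gro_atom_line(
    resid: int, resname: str, name: str, serial: int, x: float, y: float, z: float
) -> str:
    """One fixed-column GRO atom record (serials wrap at 100000)."""
    for v, lbl in ((x, "x"), (y, "y"), (z, "z")):
        if not -999.0 < v < 9999.0:
            raise ValueError(f"coordinate {lbl}={v} overflows the 8.3f GRO field")
    return (
        f"{resid % 100000:>5d}{resname:<5.5s}{name:>5.5s}{serial % 100000:>5d}"
        f"{x:8.3f}{y:8.3f}{z:8.3f}"
    )


def write_gro(obj, stream) -> None:
    """Write a :class:`MembraneSystem`, :class:`Frame` or :class:`Trajectory`
    as (multi-frame) GRO.  Byte-deterministic for a fixed input."""
    fh, owned = _open(stream, "w")
    try:
        if isinstance(obj, Trajectory):
            for frame in obj.frames:
                _write_gro_frame(frame.topology, frame.positions, frame.time, fh)
        elif isinstance(obj, Frame):
            _write_gro_frame(obj.topology, obj.positions, obj.time, fh)
        elif isinstance(obj, MembraneSystem):
            _write_gro_frame(obj, obj.positions, obj.time, fh)
        else:
            raise TypeError(f"cannot write {type(obj).__name__} as GRO")
    finally:
        if owned:
            fh.close()


def _write_gro_frame(
    system: MembraneSystem, positions: np.ndarray, time: float, fh: TextIO
) -> None:
    fh.write(f"poreramp CG membrane t= {time:.5f} ns\n")
    fh.write(f"{system.n_beads:>5d}\n")
    lines = [
        format_gro_atom_line(
            int(system.resids[i]), str(system.resnames[i]), str(system.names[i]),
            i + 1, positions[i, 0], positions[i, 1], positions[i, 2],
        )
        for i in range(system.n_beads)
    ]
    fh.write("\n".join(lines))
    fh.write("\n")
    b = system.box
    fh.write(f"{b.Lx:10.5f}{b.Ly:10.5f}{b.Lz:10.5f}\n")


_TIME_RE = re.compile(r"t=\s*(-?[0-9.eE+-]+)")


def read_gro(stream):
    """Read GRO content: one frame gives a :class:`MembraneSystem`, several
    give a :class:`Trajectory`.

    Residues named DPPC become lipids (12 beads each, canonical order), W
    water beads, and ION (or NA/CL) residues ions.  Raises
    :class:`ParseError` with a line number on malformed content.
    """
    fh, owned = _open(stream, "r")
    try:
        lines = fh.read().splitlines()
    finally:
        if owned:
            fh.close()

    frames: list[tuple[float, list[tuple[str, str, str]], np.ndarray, Box]] = []
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        title = lines[ln]
        m = _TIME_RE.search(title)
        time = float(m.group(1)) if m else 0.0
        try:
            natoms = int(lines[ln + 1].strip())
        except (IndexError, ValueError):
            raise ParseError("expected atom count after title", ln + 2)
        first_atom = ln + 2
        box_line_no = first_atom + natoms
        if box_line_no >= len(lines):
            raise ParseError(
                f"atom count {natoms} exceeds remaining records", ln + 2
            )
        records: list[tuple[str, str, str]] = []
        coords = np.empty((natoms, 3))
        for k in range(natoms):
            line = lines[first_atom + k]
            if len(line) < 44:
                raise ParseError(
                    f"atom record shorter than 44 fixed columns ({len(line)})",
                    first_atom + k + 1,
                )
            resid_s = line[0:5]
            resname = line[5:10].strip()
            name = line[10:15].strip()
            try:
                int(resid_s)
                coords[k] = (float(line[20:28]), float(line[28:36]), float(line[36:44]))
            except ValueError:
                raise ParseError("malformed fixed-column numeric field", first_atom + k + 1)
            records.append((resid_s, resname, name))
        box_fields = lines[box_line_no].split()
        if len(box_fields) < 3:
            raise ParseError("box line must hold at least three lengths", box_line_no + 1)
        try:
            box = Box(*[float(v) for v in box_fields[:3]])
        except ValueError as exc:
            raise ParseError(f"bad box line: {exc}", box_line_no + 1)
        frames.append((time, records, coords, box))
        ln = box_line_no + 1

    if not frames:
        raise ParseError("no frames found", 1)

    system = _system_from_records(frames[0][1], frames[0][2], frames[0][3],
                                  frames[0][0], base_line=2)
    if len(frames) == 1:
        return system

    traj_frames = [Frame(system, frames[0][2], frames[0][0])]
    for time, records, coords, _ in frames[1:]:
        if len(records) != system.n_beads:
            raise ParseError(
                f"frame at t={time} has {len(records)} beads, expected {system.n_beads}"
            )
        traj_frames.append(Frame(system, coords, time))
    return Trajectory(topology=system, frames=traj_frames)


def _system_from_records(records, coords, box, time, base_line=2) -> MembraneSystem:
    names, resids, resnames, charges, cats = [], [], [], [], []
    lipid_rows: list[list[int]] = []
    current_lipid: list[int] = []
    current_lipid_names: list[str] = []
    resid_counter = 0
    prev_raw: str | None = None

    for i, (resid_s, resname, name) in enumerate(records):
        line_no = base_line + i + 1
        if resid_s != prev_raw:
            resid_counter += 1
            prev_raw = resid_s
            if current_lipid:
                _close_lipid(current_lipid, current_lipid_names, lipid_rows, line_no)
                current_lipid, current_lipid_names = [], []
        if resname == "DPPC":
            if name not in LIPID_BEAD_NAMES:
                raise ParseError(f"unknown DPPC bead name {name!r}", line_no)
            cats.append(CAT_LIPID)
            charges.append(BEAD_CHARGES[name])
            current_lipid.append(i)
            current_lipid_names.append(name)
        elif resname == "W":
            cats.append(CAT_WATER)
            charges.append(0.0)
        elif resname in ("ION", "NA", "CL"):
            key = name.strip("+-")
            if key not in ("NA", "CL"):
                raise ParseError(f"unknown ion bead name {name!r}", line_no)
            cats.append(CAT_CATION if key == "NA" else CAT_ANION)
            charges.append(BEAD_CHARGES[key])
            name = key
        else:
            raise ParseError(f"unknown residue name {resname!r}", line_no)
        names.append(name)
        resids.append(resid_counter)
        resnames.append("ION" if resname in ("NA", "CL") else resname)
    if current_lipid:
        _close_lipid(current_lipid, current_lipid_names, lipid_rows,
                     base_line + len(records))

    system = MembraneSystem(
        box=box,
        names=np.array(names),
        resids=np.array(resids),
        resnames=np.array(resnames),
        charges=np.array(charges),
        categories=np.array(cats),
        positions=np.asarray(coords, dtype=float),
        lipid_bead_indices=(np.array(lipid_rows).reshape(-1, 12)
                            if lipid_rows else np.empty((0, 12), dtype=int)),
        time=time,
    )
    if system.n_lipids >= 2:
        try:
            assign_leaflets(system)
        except MembraneError:
            pass  # leave unassigned; analyses will re-raise with context
    return system


def _close_lipid(indices, bead_names, lipid_rows, line_no) -> None:
    if sorted(bead_names) != sorted(LIPID_BEAD_NAMES):
        raise ParseError(
            f"DPPC residue does not contain the 12 canonical beads: {bead_names}",
            line_no,
        )
    order = {n: k for k, n in enumerate(LIPID_BEAD_NAMES)}
    lipid_rows.append([i for _, i in sorted(zip(bead_names, indices),
                                            key=lambda p: order[p[0]])])


# ---------------------------------------------------------------------------
# XVG-dialect series


@dataclass
class SeriesTable:
    """Named numeric columns of equal length plus provenance comment lines."""

    columns: dict[str, np.ndarray]
    comments: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.columns.values()}
        if len(lengths) > 1:
            raise ValueError(f"column lengths differ: {lengths}")
        self.columns = {k: np.asarray(v, dtype=float) for k, v in self.columns.items()}
        for key in ("time", "t"):
            if key in self.columns:
                t = self.columns[key]
                if len(t) > 1 and not np.all(np.diff(t) > 0):
                    raise ValueError("time column must be strictly increasing")
                break

    def __getitem__(self, key: str) -> np.ndarray:
        return self.columns[key]

    @property
    def names(self) -> list[str]:
        return list(self.columns)


def write_series(table: SeriesTable, stream) -> None:
    """Write an XVG-dialect table; comment lines are emitted verbatim."""
    fh, owned = _open(stream, "w")
    try:
        for c in table.comments:
            if not c.startswith(("#", "@")):
                c = "# " + c
            fh.write(c.rstrip("\n") + "\n")
        fh.write("# columns: " + " ".join(table.names) + "\n")
        cols = list(table.columns.values())
        if cols:
            data = np.column_stack(cols)
            for row in data:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    finally:
        if owned:
            fh.close()


def read_series(stream) -> SeriesTable:
    """Read an XVG-dialect table; ``#``/``@`` lines are kept as comments.

    Column names come from a ``# columns:`` header when present, else
    ``c0..cN``.  Ragged rows raise :class:`ParseError`.
    """
    fh, owned = _open(stream, "r")
    try:
        lines = fh.read().splitlines()
    finally:
        if owned:
            fh.close()
    comments: list[str] = []
    names: list[str] | None = None
    rows: list[list[float]] = []
    width: int | None = None
    for ln, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(("#", "@")):
            if stripped.startswith("# columns:"):
                names = stripped[len("# columns:"):].split()
            else:
                comments.append(line)
            continue
        try:
            row = [float(v) for v in stripped.split()]
        except ValueError:
            raise ParseError(f"non-numeric data row: {stripped!r}", ln)
        if width is None:
            width = len(row)
        elif len(row) != width:
            raise ParseError(
                f"ragged row: {len(row)} fields, expected {width}", ln
            )
        rows.append(row)
    if width is None:
        raise ParseError("no data rows", len(lines) or 1)
    data = np.array(rows)
    if names is None or len(names) != width:
        names = [f"c{i}" for i in range(width)]
    return SeriesTable(
        columns={n: data[:, i] for i, n in enumerate(names)}, comments=comments
    )
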