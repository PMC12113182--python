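"""Grid-based membrane-orientation statistics.

The membrane plane is divided into ~1 nm x 1 nm subregions along X and Y.
In each subregion the local membrane normal is the total-least-squares plane
normal of that leaflet's phosphate (PO4) beads, its tilt is the angle to the
Z axis (the field direction), and the summary statistic is the fraction of
subregions with tilt strictly below 45 degrees.

Cells with fewer than three usable beads are first augmented with neighbours
within a halo around the cell; cells that still cannot support a plane fit
are marked MISSING (NaN) and excluded from the fraction's numerator and
denominator.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .field_protocol import FieldProtocol
from .system_model import Frame, Trajectory, assign_leaflets

#: Sentinel for subregions without a fittable normal.
MISSING = np.nan


@dataclass
class GridAngleMap:
    """Per-subregion tilt angles (degrees) on a periodic 2-D grid.

    ``angles[i, j]`` is the tilt of cell (i, j) in [0, 90] or NaN (MISSING).
    ``n_x = floor(Lx / cell_size)`` and the cells tile the box exactly, so
    the effective cell width is ``Lx / n_x`` (~= cell_size).
    """

    cell_size: float
    n_x: int
    n_y: int
    angles: np.ndarray
    leaflet: str
    frame_time: float

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.shape != (self.n_x, self.n_y):
            raise ValueError(f"angles shape {self.angles.shape} != ({self.n_x}, {self.n_y})")
        finite = self.angles[np.isfinite(self.angles)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 90 + 1e-9):
            raise ValueError("angles must lie in [0, 90] degrees or be MISSING")

    def to_text(self) -> str:
        """Plain-text matrix export with a provenance header."""
        buf = io.StringIO()
        buf.write(f"# cell_size_nm {self.cell_size}\n")
        buf.write(f"# leaflet {self.leaflet}\n")
        buf.write(f"# time_ns {self.frame_time}\n")
        np.savetxt(buf, self.angles, fmt="%.3f")
        return buf.getvalue()


def local_normal(points: np.ndarray) -> np.ndarray | None:
    """Unit normal of the total-least-squares plane through >= 3 points.

    Points must already be unwrapped (no periodic jumps).  The normal is
    oriented with a nonnegative Z component.  Returns ``None`` (MISSING) for
    fewer than three points or a collinear/degenerate configuration.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        return None
    centred = pts - pts.mean(axis=0)
    # TLS plane: normal = singular vector of the smallest singular value
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] <= max(s[0] * 1e-8, 1e-12):  # collinear points: no unique plane
        return None
    n = vt[2]
    if n[2] < 0:
        n = -n
    return n / np.linalg.norm(n)


def angle_to_z(normal: np.ndarray) -> float:
    """Angle (degrees, in [0, 90]) between a unit normal and the Z axis."""
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"normal must be a unit vector, |n| = {norm}")
    return float(np.degrees(np.arccos(np.clip(n[2] / norm, -1.0, 1.0))))


def compute_angle_map(
    frame: Frame,
    leaflet: str = "upper",
    cell_size: float = 1.0,
    halo: float = 0.5,
) -> GridAngleMap:
    """Tilt-angle map of one leaflet's phosphate surface.

    For each cell, the leaflet's PO4 beads whose periodic-wrapped XY falls in
    the cell are gathered; cells with fewer than three gain neighbours within
    ``halo`` nm of the cell edge.  Coordinates are unwrapped about the cell
    centre (minimum image in XY, and in Z about the cell's first member)
    before the plane fit.
    """
    topo = frame.topology
    if np.all(topo.leaflets == "unassigned"):
        assign_leaflets(topo)
    box = topo.box
    po4 = topo.po4_indices(leaflet)
    pts = frame.positions[po4]
    if len(pts) == 0:
        raise ValueError(f"empty leaflet {leaflet!r}")

    n_x = max(1, int(box.Lx // cell_size))
    n_y = max(1, int(box.Ly // cell_size))
    wx, wy = box.Lx / n_x, box.Ly / n_y
    angles = np.full((n_x, n_y), MISSING)

    x = pts[:, 0] % box.Lx
    y = pts[:, 1] % box.Ly
    z = pts[:, 2]

    for i in range(n_x):
        cxi = (i + 0.5) * wx
        dx = x - cxi
        dx -= box.Lx * np.round(dx / box.Lx)
        for j in range(n_y):
            cyj = (j + 0.5) * wy
            dy = y - cyj
            dy -= box.Ly * np.round(dy / box.Ly)
            in_cell = (np.abs(dx) <= wx / 2) & (np.abs(dy) <= wy / 2)
            members = in_cell
            if int(in_cell.sum()) < 3 and halo > 0:
                members = (np.abs(dx) <= wx / 2 + halo) & (np.abs(dy) <= wy / 2 + halo)
            if int(members.sum()) < 3:
                continue
            zm = z[members]
            dz = zm - zm[0]
            dz -= box.Lz * np.round(dz / box.Lz)
            local = np.column_stack([dx[members], dy[members], dz])
            n = local_normal(local)
            if n is not None:
                angles[i, j] = angle_to_z(n)

    return GridAngleMap(
        cell_size=cell_size, n_x=n_x, n_y=n_y, angles=angles,
        leaflet=leaflet, frame_time=frame.time,
    )


def fraction_below(angle_map: GridAngleMap, threshold: float = 45.0) -> float:
    """Fraction of non-MISSING subregions with tilt strictly below threshold.

    A cell at exactly the threshold counts as not-below.  Raises if every
    cell is MISSING.
    """
    a = angle_map.angles
    valid = np.isfinite(a)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("all subregions MISSING: nothing to analyse")
    return float(np.sum(a[valid] < threshold) / n_valid)


def endpoint_orientation(
    traj: Trajectory,
    protocol: FieldProtocol,
    cell_size: float = 1.0,
    threshold: float = 45.0,
    halo: float = 0.5,
    leaflet: str | None = None,
) -> float:
    """Below-threshold fraction at the end of the field's rise phase.

    Uses the frame nearest ``t = rise_time`` (ties toward the earlier frame)
    and averages the fraction over both leaflets unless a single ``leaflet``
    is requested.  Raises if the trajectory does not reach the rise phase end.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    times = traj.times
    if times[-1] < protocol.rise_time - 1e-9:
        raise ValueError(
            f"trajectory ends at {times[-1]} ns, before the {protocol.rise_time} ns "
            "rise phase completes"
        )
    frame = traj.frame_nearest(protocol.rise_time)
    leaflets = (leaflet,) if leaflet is not None else ("upper", "lower")
    fracs = [
        fraction_below(
            compute_angle_map(frame, lf, cell_size=cell_size, halo=halo), threshold
        )
        for lf in leaflets
    ]
    return float(np.mean(fracs))
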