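"""Transmembrane water-chain pore detection, timing, size and recovery.

A pore is called when a continuous chain of CG water beads spans the
hydrophobic core of the bilayer — the slab between the two phosphate planes,
shrunk by a margin so headgroup-bound waters do not short-circuit it.  Chain
connectivity uses a distance cutoff just above the CG water contact distance
(~0.47 nm) with the minimum image applied in XY only: a path through the
periodic solvent reservoir in Z must not count as transmembrane.

Pore formation time is reported under both accounting conventions of the
source experiments: total time from the start of the run (ramp included) and
time measured from the field peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import label as ndi_label
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .field_protocol import FieldProtocol
from .system_model import (
    Frame,
    MembraneError,
    TAIL_BEAD_NAMES,
    Trajectory,
    assign_leaflets,
)


@dataclass
class PoreEvent:
    """A persistent transmembrane water chain.

    ``formation_time_total`` counts from t = 0 (ramp included);
    ``formation_time_post_peak`` counts from the end of the rise phase and is
    negative when the pore forms during the ramp.
    """

    formation_time_total: float
    formation_time_post_peak: float
    persisted: bool
    radius_series: list[tuple[float, float]] = field(default_factory=list)

    @property
    def max_radius(self) -> float:
        if not self.radius_series:
            return 0.0
        return max(r for _, r in self.radius_series)


def _ensure_leaflets(frame: Frame) -> None:
    if np.all(frame.topology.leaflets == "unassigned"):
        assign_leaflets(frame.topology)


def hydrophobic_slab(frame: Frame, margin: float = 0.3) -> tuple[float, float]:
    """Z bounds of the hydrophobic core: mean leaflet PO4 planes +/- margin."""
    _ensure_leaflets(frame)
    topo = frame.topology
    z_up = float(np.mean(frame.positions[topo.po4_indices("upper"), 2]))
    z_lo = float(np.mean(frame.positions[topo.po4_indices("lower"), 2]))
    low, high = z_lo + margin, z_up - margin
    if low >= high:
        raise MembraneError(
            f"degenerate membrane: hydrophobic slab inverted ({low:.3f} >= {high:.3f})"
        )
    return low, high


def detect_spanning_chain(
    frame: Frame,
    cutoff: float = 0.6,
    margin: float = 0.3,
    slab: tuple[float, float] | None = None,
) -> bool:
    """True iff a connected water chain spans the hydrophobic slab.

    Water beads inside the slab, plus those within ``cutoff`` of either slab
    face, form a graph whose edges join pairs closer than ``cutoff`` (minimum
    image in XY, plain distance in Z).  The chain spans when one connected
    component touches both z < z_low and z > z_high.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if slab is None:
        slab = hydrophobic_slab(frame, margin=margin)
    z_low, z_high = slab
    topo = frame.topology
    widx = topo.water_indices
    if len(widx) == 0:
        raise ValueError("frame has no water beads")
    w = frame.positions[widx]
    near = (w[:, 2] >= z_low - cutoff) & (w[:, 2] <= z_high + cutoff)
    pts = w[near]
    if len(pts) == 0:
        return False
    below = pts[:, 2] < z_low
    above = pts[:, 2] > z_high
    if not (np.any(below) and np.any(above)):
        return False

    box = topo.box
    shifted = pts.copy()
    shifted[:, 0] %= box.Lx
    shifted[:, 1] %= box.Ly
    z0 = shifted[:, 2].min()
    shifted[:, 2] -= z0
    # periodic in XY only: give Z a box far larger than the data extent
    z_span = float(shifted[:, 2].max()) + 10.0 * cutoff + 1.0
    tree = cKDTree(shifted, boxsize=(box.Lx, box.Ly, z_span))
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    n = len(pts)
    if len(pairs):
        data = np.ones(len(pairs))
        adj = coo_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(n)
    return bool(np.intersect1d(labels[below], labels[above]).size > 0)


def pore_radius(
    frame: Frame,
    grid_resolution: float = 0.5,
    margin: float = 0.3,
    cutoff: float = 0.6,
) -> float:
    """Equivalent pore radius sqrt(A / pi) in nm.

    A is the area of the largest XY-connected patch of ``grid_resolution``
    cells that contain water but no lipid tail beads inside the hydrophobic
    slab (periodic connectivity).  Raises when no spanning chain is present.
    """
    if not detect_spanning_chain(frame, cutoff=cutoff, margin=margin):
        raise ValueError("no transmembrane pore in this frame")
    z_low, z_high = hydrophobic_slab(frame, margin=margin)
    topo = frame.topology
    box = topo.box
    n_x = max(1, int(round(box.Lx / grid_resolution)))
    n_y = max(1, int(round(box.Ly / grid_resolution)))

    def occupancy(idx: np.ndarray) -> np.ndarray:
        p = frame.positions[idx]
        in_slab = (p[:, 2] > z_low) & (p[:, 2] < z_high)
        p = p[in_slab]
        ix = np.floor(p[:, 0] % box.Lx / box.Lx * n_x).astype(int) % n_x
        iy = np.floor(p[:, 1] % box.Ly / box.Ly * n_y).astype(int) % n_y
        occ = np.zeros((n_x, n_y), dtype=bool)
        occ[ix, iy] = True
        return occ

    water_occ = occupancy(topo.water_indices)
    tail_occ = occupancy(topo.bead_indices_by_name(*TAIL_BEAD_NAMES))
    pore_cells = water_occ & ~tail_occ
    if not pore_cells.any():
        return 0.0

    labels, n_lab = ndi_label(pore_cells)
    if n_lab == 0:
        return 0.0
    # merge labels across the periodic seams
    parent = list(range(n_lab + 1))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    for j in range(n_y):
        a, b = labels[0, j], labels[-1, j]
        if a and b:
            union(a, b)
    for i in range(n_x):
        a, b = labels[i, 0], labels[i, -1]
        if a and b:
            union(a, b)
    roots = np.array([find(l) if l else 0 for l in range(n_lab + 1)])
    merged = roots[labels]
    sizes = np.bincount(merged.ravel(), minlength=1)
    sizes[0] = 0
    area = sizes.max() * (box.Lx / n_x) * (box.Ly / n_y)
    return float(np.sqrt(area / np.pi))


def _chain_flags(
    traj: Trajectory, cutoff: float, margin: float
) -> np.ndarray:
    return np.array(
        [detect_spanning_chain(f, cutoff=cutoff, margin=margin) for f in traj.frames]
    )


def _first_persistent_run(flags: np.ndarray, k: int) -> int | None:
    run = 0
    for i, f in enumerate(flags):
        run = run + 1 if f else 0
        if run >= k:
            return i - k + 1
    return None


def pore_formation_time(
    traj: Trajectory,
    protocol: FieldProtocol,
    persistence_frames: int = 3,
    cutoff: float = 0.6,
    margin: float = 0.3,
    grid_resolution: float = 0.5,
    with_radius: bool = True,
) -> PoreEvent | None:
    """First frame at which the spanning chain appears and persists.

    The chain must remain detected for ``persistence_frames`` consecutive
    frames (a flicker filter); ``None`` means no persistent pore — a valid
    outcome.  Both timing conventions are reported.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if persistence_frames < 1:
        raise ValueError("persistence_frames must be >= 1")
    flags = _chain_flags(traj, cutoff, margin)
    start = _first_persistent_run(flags, persistence_frames)
    if start is None:
        return None
    t_total = float(traj.frames[start].time)
    radius_series: list[tuple[float, float]] = []
    if with_radius:
        for f, flag in zip(traj.frames[start:], flags[start:]):
            if not flag:
                continue
            try:
                radius_series.append(
                    (float(f.time), pore_radius(f, grid_resolution, margin, cutoff))
                )
            except ValueError:  # pragma: no cover - flag and radius disagree
                continue
    return PoreEvent(
        formation_time_total=t_total,
        formation_time_post_peak=t_total - protocol.rise_time,
        persisted=True,
        radius_series=radius_series,
    )


def detect_recovery(
    traj: Trajectory,
    protocol: FieldProtocol,
    persistence_frames: int = 3,
    cutoff: float = 0.6,
    margin: float = 0.3,
) -> bool:
    """True iff a pore present at falling-edge onset reseals before the end.

    Requires a protocol with a concrete falling edge and a spanning chain at
    fall onset; resealing means the chain is absent for
    ``persistence_frames`` consecutive frames afterwards.
    """
    if protocol.fall_time <= 0 or protocol.fall_onset is None:
        raise ValueError("recovery analysis needs a protocol with a falling edge")
    onset = protocol.fall_onset
    times = traj.times
    if len(times) == 0 or times[-1] < onset:
        raise ValueError("trajectory does not reach the falling edge")
    at_onset = traj.frame_nearest(onset)
    if not detect_spanning_chain(at_onset, cutoff=cutoff, margin=margin):
        raise ValueError("no pore present at fall onset: recovery is not applicable")
    after = [f for f in traj.frames if f.time >= at_onset.time]
    flags = np.array(
        [detect_spanning_chain(f, cutoff=cutoff, margin=margin) for f in after]
    )
    return _first_persistent_run(~flags, persistence_frames) is not None
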