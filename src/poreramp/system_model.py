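"""Domain types for coarse-grained membrane systems.

The model follows the Martini mapping of DPPC: 12 beads per lipid — a
positively charged choline bead (NC3), a negatively charged phosphate bead
(PO4), two neutral glycerol beads (GL1, GL2) and two four-bead hydrophobic
tails (C1A–C4A for sn-2, C1B–C4B for sn-1).  Ions are single NA/CL beads and
water is the four-to-one CG water bead W.

Units throughout the package: coordinates in nm, times in ns, charges in
elementary charges, forces in kJ/mol/nm, fields in V/nm, pressures in bar.
Unit conversions happen only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Canonical bead order of one DPPC lipid (headgroup outward-in, then tails).
LIPID_BEAD_NAMES: tuple[str, ...] = (
    "NC3", "PO4", "GL1", "GL2",
    "C1A", "C2A", "C3A", "C4A",
    "C1B", "C2B", "C3B", "C4B",
)

#: Hydrophobic tail bead names (used for the pore-size lipid-exclusion test).
TAIL_BEAD_NAMES: frozenset[str] = frozenset(
    {"C1A", "C2A", "C3A", "C4A", "C1B", "C2B", "C3B", "C4B"}
)

#: Partial charges in elementary-charge units.  The zwitterionic headgroup
#: carries +1 on the choline bead and -1 on the phosphate bead; glycerol and
#: tail beads are neutral.
BEAD_CHARGES: dict[str, float] = {
    "NC3": +1.0,
    "PO4": -1.0,
    "NA": +1.0,
    "CL": -1.0,
    "W": 0.0,
}
BEAD_CHARGES.update({name: 0.0 for name in LIPID_BEAD_NAMES[2:]})

#: Bead category codes stored per bead.
CAT_LIPID, CAT_WATER, CAT_CATION, CAT_ANION = 0, 1, 2, 3

LEAFLET_UPPER = "upper"
LEAFLET_LOWER = "lower"
LEAFLET_UNASSIGNED = "unassigned"


class MembraneError(ValueError):
    """Raised for degenerate or inconsistent membrane systems."""


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic simulation box (nm), periodic in x, y and z."""

    Lx: float
    Ly: float
    Lz: float

    def __post_init__(self) -> None:
        if not (self.Lx > 0 and self.Ly > 0 and self.Lz > 0):
            raise ValueError(f"box lengths must be positive, got {self}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.Lx, self.Ly, self.Lz], dtype=float)

    def wrap_xy(self, xy: np.ndarray) -> np.ndarray:
        """Wrap x/y coordinates into [0, L)."""
        out = np.asarray(xy, dtype=float).copy()
        out[..., 0] %= self.Lx
        out[..., 1] %= self.Ly
        return out

    def min_image(self, delta: np.ndarray, axes: Sequence[int] = (0, 1, 2)) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        out = np.asarray(delta, dtype=float).copy()
        L = self.lengths
        for ax in axes:
            out[..., ax] -= L[ax] * np.round(out[..., ax] / L[ax])
        return out


@dataclass(frozen=True)
class Bead:
    """A single coarse-grained particle (view onto the system arrays)."""

    index: int
    name: str
    residue_id: int
    residue_name: str
    charge: float
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("bead index must be >= 0")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"bead {self.index} has non-finite position")


@dataclass
class LipidMolecule:
    """One DPPC molecule: exactly 12 beads in the canonical order."""

    residue_id: int
    beads: list[Bead]
    leaflet: str = LEAFLET_UNASSIGNED

    def __post_init__(self) -> None:
        names = sorted(b.name for b in self.beads)
        if names != sorted(LIPID_BEAD_NAMES):
            raise MembraneError(
                f"lipid {self.residue_id}: bead names {names} do not form one "
                f"DPPC molecule {sorted(LIPID_BEAD_NAMES)}"
            )


class MembraneSystem:
    """One frame of the world: a solvated CG bilayer with ions.

    Internally array-of-structs for speed; :class:`Bead` / :class:`LipidMolecule`
    views are materialised on demand.  Every bead belongs to exactly one
    category (lipid / water / cation / anion).

    Parameters
    ----------
    box:
        Periodic box.
    names, resids, resnames, charges, categories:
        Per-bead metadata arrays, all of length ``n_beads``.
    positions:
        ``(n_beads, 3)`` coordinates in nm.
    lipid_bead_indices:
        ``(n_lipids, 12)`` integer matrix; row *i* holds the bead indices of
        lipid *i* in :data:`LIPID_BEAD_NAMES` order.
    time:
        Frame time in ns.
    """

    def __init__(
        self,
        box: Box,
        names: np.ndarray,
        resids: np.ndarray,
        resnames: np.ndarray,
        charges: np.ndarray,
        categories: np.ndarray,
        positions: np.ndarray,
        lipid_bead_indices: np.ndarray,
        time: float = 0.0,
    ) -> None:
        self.box = box
        self.names = np.asarray(names)
        self.resids = np.asarray(resids, dtype=int)
        self.resnames = np.asarray(resnames)
        self.charges = np.asarray(charges, dtype=float)
        self.categories = np.asarray(categories, dtype=int)
        self.positions = np.asarray(positions, dtype=float)
        self.lipid_bead_indices = np.asarray(lipid_bead_indices, dtype=int).reshape(-1, 12)
        self.time = float(time)
        self.leaflets = np.full(self.n_lipids, LEAFLET_UNASSIGNED, dtype=object)
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        n = len(self.names)
        for arr, label in (
            (self.resids, "resids"),
            (self.resnames, "resnames"),
            (self.charges, "charges"),
            (self.categories, "categories"),
        ):
            if len(arr) != n:
                raise MembraneError(f"{label} length {len(arr)} != n_beads {n}")
        if self.positions.shape != (n, 3):
            raise MembraneError(f"positions shape {self.positions.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.positions)):
            raise MembraneError("non-finite coordinates")
        # every lipid row must reference lipid-category beads with the right names
        if self.n_lipids:
            ref = self.lipid_bead_indices.ravel()
            if not np.all(self.categories[ref] == CAT_LIPID):
                raise MembraneError("lipid bead index references a non-lipid bead")
            got = self.names[self.lipid_bead_indices[0]]
            if tuple(got) != LIPID_BEAD_NAMES:
                raise MembraneError(f"lipid bead order {tuple(got)} != {LIPID_BEAD_NAMES}")
        # categories partition the beads
        n_lipid_beads = int(np.sum(self.categories == CAT_LIPID))
        if n_lipid_beads != 12 * self.n_lipids:
            raise MembraneError(
                f"{n_lipid_beads} lipid-category beads but {self.n_lipids} lipids"
            )

    @property
    def n_beads(self) -> int:
        return len(self.names)

    @property
    def n_lipids(self) -> int:
        return len(self.lipid_bead_indices)

    def category_indices(self, cat: int) -> np.ndarray:
        return np.flatnonzero(self.categories == cat)

    @property
    def water_indices(self) -> np.ndarray:
        return self.category_indices(CAT_WATER)

    @property
    def cation_indices(self) -> np.ndarray:
        return self.category_indices(CAT_CATION)

    @property
    def anion_indices(self) -> np.ndarray:
        return self.category_indices(CAT_ANION)

    def bead_indices_by_name(self, *bead_names: str) -> np.ndarray:
        mask = np.isin(self.names, list(bead_names))
        return np.flatnonzero(mask)

    def po4_indices(self, leaflet: str | None = None) -> np.ndarray:
        """Bead indices of PO4 beads, optionally restricted to one leaflet."""
        po4_col = LIPID_BEAD_NAMES.index("PO4")
        rows = np.arange(self.n_lipids)
        if leaflet is not None:
            rows = rows[self.leaflets == leaflet]
            if len(rows) == 0:
                raise MembraneError(f"no lipids in leaflet {leaflet!r}")
        return self.lipid_bead_indices[rows, po4_col]

    # -- object views ------------------------------------------------------

    def bead(self, i: int) -> Bead:
        return Bead(
            index=int(i),
            name=str(self.names[i]),
            residue_id=int(self.resids[i]),
            residue_name=str(self.resnames[i]),
            charge=float(self.charges[i]),
            position=self.positions[i].copy(),
        )

    @property
    def lipids(self) -> list[LipidMolecule]:
        return [
            LipidMolecule(
                residue_id=int(self.resids[row[0]]),
                beads=[self.bead(i) for i in row],
                leaflet=str(self.leaflets[k]),
            )
            for k, row in enumerate(self.lipid_bead_indices)
        ]

    @property
    def waters(self) -> list[Bead]:
        return [self.bead(i) for i in self.water_indices]

    @property
    def cations(self) -> list[Bead]:
        return [self.bead(i) for i in self.cation_indices]

    @property
    def anions(self) -> list[Bead]:
        return [self.bead(i) for i in self.anion_indices]

    def copy(self) -> "MembraneSystem":
        out = MembraneSystem(
            box=self.box,
            names=self.names.copy(),
            resids=self.resids.copy(),
            resnames=self.resnames.copy(),
            charges=self.charges.copy(),
            categories=self.categories.copy(),
            positions=self.positions.copy(),
            lipid_bead_indices=self.lipid_bead_indices.copy(),
            time=self.time,
        )
        out.leaflets = self.leaflets.copy()
        return out


@dataclass
class Frame:
    """Positions (and optionally per-bead forces) for all beads at one time.

    ``topology`` carries the immutable identity of every bead; frames share it.
    """

    topology: MembraneSystem
    positions: np.ndarray
    time: float
    field_strength: float = 0.0
    forces: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.time < 0:
            raise ValueError(f"frame time must be nonnegative, got {self.time}")
        n = self.topology.n_beads
        if self.positions.shape != (n, 3):
            raise ValueError(f"positions shape {self.positions.shape} != ({n}, 3)")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != (n, 3):
                raise ValueError(f"forces shape {self.forces.shape} != ({n}, 3)")

    def as_system(self) -> MembraneSystem:
        """Materialise a standalone :class:`MembraneSystem` at this frame."""
        sys = self.topology.copy()
        sys.positions = self.positions.copy()
        sys.time = self.time
        return sys


@dataclass
class Trajectory:
    """Time-ordered frames over a shared topology, plus provenance metadata."""

    topology: MembraneSystem
    frames: list[Frame] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")
        for f in self.frames:
            if f.topology.n_beads != self.topology.n_beads:
                raise ValueError("bead count changes across frames")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=float)

    def __len__(self) -> int:
        return len(self.frames)

    def frame_nearest(self, t: float) -> Frame:
        """Frame whose time is nearest to ``t`` (ties broken toward earlier)."""
        if not self.frames:
            raise ValueError("empty trajectory")
        times = self.times
        return self.frames[int(np.argmin(np.abs(times - t)))]


def assign_leaflets(system: MembraneSystem) -> MembraneSystem:
    """Label each lipid upper/lower by its PO4 height relative to the median.

    The offset from the per-frame median PO4 z is taken with the minimum-image
    convention in z, so a membrane drifting through the periodic boundary is
    still split correctly.  Raises :class:`MembraneError` if all lipids end up
    on one side (monolayer or collapsed membrane).
    """
    if system.n_lipids < 2:
        raise MembraneError("need at least 2 lipids to assign leaflets")
    po4_z = system.positions[system.po4_indices(), 2]
    Lz = system.box.Lz
    # wrap-aware membrane centre (circular mean), then median-of-offsets:
    # a membrane drifting through the periodic boundary stays correctly split
    ang = 2.0 * np.pi * po4_z / Lz
    center = Lz * np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang))) / (2 * np.pi)
    dz = po4_z - center
    dz -= Lz * np.round(dz / Lz)
    dz -= np.median(dz)
    upper = dz > 0
    lower = dz < 0
    # beads exactly at the median join the smaller side to keep both nonempty
    ties = ~upper & ~lower
    if np.any(ties):
        n_up, n_lo = int(upper.sum()), int(lower.sum())
        for i in np.flatnonzero(ties):
            if n_up <= n_lo:
                upper[i] = True
                n_up += 1
            else:
                lower[i] = True
                n_lo += 1
    if not (np.any(upper) and np.any(lower)) or np.ptp(dz) == 0:
        raise MembraneError("monolayer or collapsed membrane")
    system.leaflets[upper] = LEAFLET_UPPER
    system.leaflets[lower] = LEAFLET_LOWER
    return system


def net_charge(system: MembraneSystem) -> float:
    """Total charge of the system in elementary charges."""
    return float(np.sum(system.charges))
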