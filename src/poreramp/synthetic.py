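"""Surrogate coarse-grained bilayer trajectories for ramped-field experiments.

This module builds the solvated DPPC system (default: 1024 lipids of 12 beads,
244 Na+, 244 Cl-, ~21,000 CG waters in a 17.3 x 17.3 x 12.5 nm box) and
generates surrogate trajectories whose statistical structure follows the
causal chain the analysis stages probe:

    field ramp -> membrane deformation (tilt field) -> surface tension
               -> pore-nucleation hazard -> transmembrane water column

It is an emulator, not an MD engine: per output step the per-cell tilt field
relaxes toward an equilibrium set by the instantaneous field and a slowly
accumulating deformation mode, lipid beads are re-posed on the corresponding
periodic height map, the emitted pressure tensor encodes the instantaneous
tension exactly, per-bead Coulomb forces follow the local surface slope, and
pore nucleation is a Bernoulli event with hazard
``rate0 * exp(a * E^2 - b * gamma)``.  At most one pore forms per trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .field_protocol import FieldProtocol
from .mechanics import (
    COULOMB_KJ_PER_MOL_NM,
    MN_PER_M_PER_BAR_NM,
    PressureTensorSeries,
)
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

#: Z offsets (nm) of each lipid bead relative to its PO4 bead, for an upper
#: leaflet lipid (positive = toward the water phase).  The tail reaches the
#: bilayer midplane ~2 nm below the phosphate plane.
_BEAD_Z_OFFSETS: dict[str, float] = {
    "NC3": +0.30, "PO4": 0.00, "GL1": -0.35, "GL2": -0.55,
    "C1A": -0.95, "C2A": -1.30, "C3A": -1.65, "C4A": -2.00,
    "C1B": -0.95, "C2B": -1.30, "C3B": -1.65, "C4B": -2.00,
}
#: XY offset (nm) separating the sn-1 tail stack from the sn-2 stack.
_TAIL_XY_OFFSET = 0.25
#: Distance (nm) of the phosphate plane from the bilayer midplane.
_PO4_HALF_HEIGHT = 2.0


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the surrogate dynamics.

    Attributes
    ----------
    undulation_modes:
        Number of Fourier modes of the membrane height field.
    undulation_amp0:
        Field-free undulation amplitude, nm (sets the thermal tilt scale).
    tilt_relax_tau:
        Headgroup reorientation timescale, ns.  Phospholipid headgroups
        reorient with a rotational time constant of 0.1-0.5 ns, so the
        default sits in the middle of that range.
    thermal_noise_sigma:
        Stationary standard deviation of per-cell tilt noise, degrees.
    deformation_tension_coupling:
        Tension gained per unit mean-squared tilt, mN/m per deg^2.
    baseline_tension:
        Field-free membrane tension, mN/m.
    nucleation_rate0:
        Base pore-nucleation hazard, 1/ns.
    field_susceptibility:
        Hazard exponent coefficient on E^2, (V/nm)^-2 (electroporation
        energetics scale with the square of the transmembrane voltage).
    tension_penalty:
        Hazard exponent coefficient on tension, (mN/m)^-1; higher tension
        suppresses nucleation.
    seed:
        RNG seed; generation is bit-reproducible for fixed (params, protocol,
        seed).
    align_coupling:
        Shrinkage of thermal undulations with field, (V/nm)^-2 — a stronger
        instantaneous field pulls the local normals toward Z.
    deformation_tau:
        Timescale (ns) of the slow deformation mode that accumulates while
        the membrane is under field; long ramps accumulate more deformation
        before the plateau than short ones.
    deformation_amp:
        Undulation amplitude (nm) added at full deformation.
    pore_growth_rate:
        Pore radius growth after nucleation, nm/ns.
    pore_radius_cap:
        Maximum pore radius, nm (box-scale pores stop growing here).
    recovery_radius_threshold:
        Pores smaller than this (nm) at falling-edge onset reseal; larger
        ones persist.
    water_spacing:
        Bead spacing (nm) inside the transmembrane water column.
    force_noise_sigma:
        Per-bead force noise, kJ/mol/nm.
    """

    undulation_modes: int = 4
    undulation_amp0: float = 0.5
    tilt_relax_tau: float = 0.3
    thermal_noise_sigma: float = 2.0
    deformation_tension_coupling: float = 0.012
    baseline_tension: float = 1.0
    nucleation_rate0: float = 2e-4
    field_susceptibility: float = 360.0
    tension_penalty: float = 0.1
    seed: int = 0
    align_coupling: float = 20.0
    deformation_tau: float = 15.0
    deformation_amp: float = 0.8
    pore_growth_rate: float = 1.0
    pore_radius_cap: float = 3.0
    recovery_radius_threshold: float = 1.5
    water_spacing: float = 0.4
    force_noise_sigma: float = 5.0

    def __post_init__(self) -> None:
        positive = (
            "undulation_modes", "undulation_amp0", "tilt_relax_tau",
            "deformation_tension_coupling", "nucleation_rate0",
            "field_susceptibility", "tension_penalty", "deformation_tau",
            "pore_growth_rate", "pore_radius_cap",
            "recovery_radius_threshold", "water_spacing",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"SurrogateParams.{name} must be positive")
        for name in ("thermal_noise_sigma", "deformation_amp", "align_coupling",
                     "force_noise_sigma", "baseline_tension"):
            if getattr(self, name) < 0:
                raise ValueError(f"SurrogateParams.{name} must be >= 0")


@dataclass
class SurrogateState:
    """Instantaneous generator state on the analysis grid."""

    tilt_deg: np.ndarray          # (n_x, n_y), degrees in [0, 90]
    tension: float                # mN/m
    deformation: float            # slow mode, dimensionless in [0, 1]
    pore_formed: bool = False
    pore_time: float | None = None
    pore_center: np.ndarray | None = None
    pore_radius: float = 0.0


class Undulation:
    """Periodic random height field ``h(x, y) = A * u(x, y)``.

    The unit shape ``u`` is a fixed sum of low-wavevector Fourier modes,
    normalised so its RMS slope is 1 per nm of amplitude; the per-cell slope
    of the posed membrane is then simply ``A * |grad u|``.
    """

    #: candidate integer wavevectors (long wavelengths first)
    _WAVEVECTORS = ((1, 0), (0, 1), (1, 1), (1, -1), (2, 0), (0, 2), (2, 1), (1, 2))

    def __init__(self, box: Box, n_modes: int, rng: np.random.Generator) -> None:
        self.box = box
        n_modes = min(n_modes, len(self._WAVEVECTORS))
        self.kvecs = np.array(self._WAVEVECTORS[:n_modes], dtype=float)
        self.phases = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
        # mild decay with mode index so long wavelengths dominate
        self.weights = 1.0 / (1.0 + 0.5 * np.arange(n_modes))
        self._scale = 1.0
        self._scale = 1.0 / self._rms_slope()

    def _angular(self, xy: np.ndarray) -> np.ndarray:
        kx = 2.0 * np.pi * self.kvecs[:, 0] / self.box.Lx
        ky = 2.0 * np.pi * self.kvecs[:, 1] / self.box.Ly
        return np.outer(xy[:, 0], kx) + np.outer(xy[:, 1], ky) + self.phases

    def height(self, xy: np.ndarray) -> np.ndarray:
        """Unit-amplitude height at (n, 2) positions."""
        return self._scale * np.sin(self._angular(xy)) @ self.weights

    def gradient(self, xy: np.ndarray) -> np.ndarray:
        """Unit-amplitude height gradient, shape (n, 2)."""
        ang = self._angular(xy)
        kx = 2.0 * np.pi * self.kvecs[:, 0] / self.box.Lx
        ky = 2.0 * np.pi * self.kvecs[:, 1] / self.box.Ly
        c = np.cos(ang)
        gx = c @ (self.weights * kx)
        gy = c @ (self.weights * ky)
        return self._scale * np.stack([gx, gy], axis=1)

    def _rms_slope(self, n: int = 48) -> float:
        xs = np.linspace(0, self.box.Lx, n, endpoint=False)
        ys = np.linspace(0, self.box.Ly, n, endpoint=False)
        xy = np.stack(np.meshgrid(xs, ys), axis=-1).reshape(-1, 2)
        g = self.gradient(xy)
        return float(np.sqrt(np.mean(np.sum(g * g, axis=1))))


def build_system(
    n_lipids: int = 1024,
    n_cations: int = 244,
    n_anions: int = 244,
    n_waters: int = 21000,
    box: tuple[float, float, float] = (17.3, 17.3, 12.5),
    area_per_lipid: float | None = None,
    hydrophobic_half_thickness: float = 2.3,
    seed: int = 0,
    jitter: float = 0.08,
) -> MembraneSystem:
    """Build a flat solvated bilayer with the default composition of the
    source experiments (1024 DPPC, 244 Na+, 244 Cl-, ~21,000 CG waters).

    Each leaflet is a jittered square lattice of ``n_lipids / 2`` lipids; the
    12 beads of each lipid are stacked along Z in the canonical bonding order.
    Waters and ions fill the box uniformly outside a hydrophobic slab of
    half-thickness ``hydrophobic_half_thickness`` around the midplane.
    Deterministic for a fixed seed.
    """
    if n_lipids % 2 or n_lipids < 2:
        raise ValueError("n_lipids must be even and >= 2")
    bx = Box(*box)
    per_leaflet = n_lipids // 2
    if area_per_lipid is None:
        area_per_lipid = bx.Lx * bx.Ly / per_leaflet
    if area_per_lipid * per_leaflet > bx.Lx * bx.Ly * (1 + 1e-9):
        raise ValueError(
            f"lattice overflow: {per_leaflet} lipids x {area_per_lipid:.3f} nm^2 "
            f"exceed the {bx.Lx:.2f} x {bx.Ly:.2f} nm box area"
        )
    rng = np.random.default_rng(seed)
    n_side = math.isqrt(per_leaflet)
    if n_side * n_side < per_leaflet:
        n_side += 1
    sx, sy = bx.Lx / n_side, bx.Ly / n_side
    sites = np.array([(i * sx + sx / 2, j * sy + sy / 2)
                      for i in range(n_side) for j in range(n_side)])
    mid = bx.Lz / 2.0

    names, resids, resnames, charges, cats = [], [], [], [], []
    pos_list = []
    lipid_rows = []
    resid = 0
    bead_i = 0
    for leaflet_sign in (+1, -1):  # upper first
        anchors = sites[:per_leaflet] + rng.uniform(-jitter, jitter, size=(per_leaflet, 2))
        for ax, ay in anchors:
            resid += 1
            row = []
            for name in LIPID_BEAD_NAMES:
                dz = _BEAD_Z_OFFSETS[name]
                x, y = ax, ay
                if name.endswith("B"):
                    x += _TAIL_XY_OFFSET
                z = mid + leaflet_sign * (_PO4_HALF_HEIGHT + dz)
                names.append(name)
                resids.append(resid)
                resnames.append("DPPC")
                charges.append(BEAD_CHARGES[name])
                cats.append(CAT_LIPID)
                pos_list.append((x % bx.Lx, y % bx.Ly, z))
                row.append(bead_i)
                bead_i += 1
            lipid_rows.append(row)

    def solvent_positions(n: int) -> np.ndarray:
        xy = rng.uniform(0.0, [bx.Lx, bx.Ly], size=(n, 2))
        free = bx.Lz - 2.0 * hydrophobic_half_thickness
        if free <= 0:
            raise ValueError("hydrophobic slab thicker than the box")
        z = rng.uniform(0.0, free, size=n)
        z = np.where(z >= mid - hydrophobic_half_thickness,
                     z + 2.0 * hydrophobic_half_thickness, z)
        return np.column_stack([xy, z])

    for count, name, resname, cat in (
        (n_waters, "W", "W", CAT_WATER),
        (n_cations, "NA", "ION", CAT_CATION),
        (n_anions, "CL", "ION", CAT_ANION),
    ):
        if count == 0:
            continue
        p = solvent_positions(count)
        for k in range(count):
            resid += 1
            names.append(name)
            resids.append(resid)
            resnames.append(resname)
            charges.append(BEAD_CHARGES[name])
            cats.append(cat)
            pos_list.append(tuple(p[k]))
            bead_i += 1

    system = MembraneSystem(
        box=bx,
        names=np.array(names),
        resids=np.array(resids),
        resnames=np.array(resnames),
        charges=np.array(charges),
        categories=np.array(cats),
        positions=np.array(pos_list),
        lipid_bead_indices=np.array(lipid_rows),
        time=0.0,
    )
    return assign_leaflets(system)


# ---------------------------------------------------------------------------
# posing helpers


def _lipid_anchor_xy(system: MembraneSystem) -> np.ndarray:
    """(n_lipids, 2) anchor = PO4 xy of each lipid in the reference system."""
    return system.positions[system.po4_indices(), :2].copy()


def pose_on_surface(
    system: MembraneSystem,
    undulation: Undulation,
    amplitude: float,
) -> np.ndarray:
    """Return positions with lipid beads re-posed on ``h = amplitude * u``.

    The height map displaces each whole lipid vertically by the height at its
    anchor; solvent beads keep their reference positions.
    """
    pos = system.positions.copy()
    anchors = _lipid_anchor_xy(system)
    h = amplitude * undulation.height(anchors)
    lip = system.lipid_bead_indices
    pos[lip, 2] += h[:, None]
    return pos


def _column_points(
    center: np.ndarray,
    radius: float,
    z_lo: float,
    z_hi: float,
    spacing: float,
) -> np.ndarray:
    """Bead positions filling a vertical cylinder spanning [z_lo, z_hi]."""
    zs = np.arange(z_lo, z_hi + spacing / 2, spacing)
    lateral = [(0.0, 0.0)]
    if radius > 0:
        g = np.arange(-radius, radius + 1e-9, max(spacing * 0.875, 1e-3))
        for dx in g:
            for dy in g:
                if 0 < dx * dx + dy * dy <= radius * radius:
                    lateral.append((dx, dy))
    pts = [(center[0] + dx, center[1] + dy, z) for dx, dy in lateral for z in zs]
    return np.array(pts)


def _apply_pore(
    system: MembraneSystem,
    positions: np.ndarray,
    center: np.ndarray,
    radius: float,
    spacing: float,
    margin: float = 0.3,
) -> np.ndarray:
    """Carve a pore: displace lipids radially out of the cylinder and recruit
    the nearest waters into a transmembrane column.  Bead count is conserved.
    """
    box = system.box
    pos = positions.copy()
    # slab between the leaflet phosphate planes
    po4_u = system.po4_indices("upper")
    po4_l = system.po4_indices("lower")
    z_hi = float(np.mean(pos[po4_u, 2]))
    z_lo = float(np.mean(pos[po4_l, 2]))

    # displace lipids whose anchor lies inside the pore radius
    anchors = system.positions[system.po4_indices(), :2]
    d = anchors - center
    d[:, 0] -= box.Lx * np.round(d[:, 0] / box.Lx)
    d[:, 1] -= box.Ly * np.round(d[:, 1] / box.Ly)
    r = np.hypot(d[:, 0], d[:, 1])
    clear = radius + margin
    inside = r < clear
    if np.any(inside):
        rr = np.maximum(r[inside], 1e-6)
        push = (clear - rr) / rr
        shift = d[inside] * push[:, None]
        rows = system.lipid_bead_indices[inside]
        pos[rows, 0] += shift[:, 0][:, None]
        pos[rows, 1] += shift[:, 1][:, None]
        pos[rows, 0] %= box.Lx
        pos[rows, 1] %= box.Ly

    # recruit the waters nearest the pore mouth into the column
    col = _column_points(center, radius, z_lo - 0.2, z_hi + 0.2, spacing)
    widx = system.water_indices
    if len(col) > len(widx):
        col = col[: len(widx)]
    wd = system.positions[widx, :2] - center
    wd[:, 0] -= box.Lx * np.round(wd[:, 0] / box.Lx)
    wd[:, 1] -= box.Ly * np.round(wd[:, 1] / box.Ly)
    order = np.argsort(np.hypot(wd[:, 0], wd[:, 1]), kind="stable")
    chosen = widx[order[: len(col)]]
    col[:, 0] %= box.Lx
    col[:, 1] %= box.Ly
    pos[chosen] = col
    return pos


def inject_pore(frame: Frame, center_xy, radius: float, spacing: float = 0.4) -> Frame:
    """Return a copy of ``frame`` with a cylindrical transmembrane water pore.

    A positive control for spanning-chain detection: lipids within ``radius``
    of the centre are displaced outward and the nearest water beads are
    re-posed into a column (bead spacing <= 0.45 nm) spanning the hydrophobic
    slab.  ``radius`` 0 returns the frame unchanged.
    """
    box = frame.topology.box
    if radius >= min(box.Lx, box.Ly) / 2:
        raise ValueError(f"pore radius {radius} nm too large for the box")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return Frame(frame.topology, frame.positions.copy(), frame.time,
                     frame.field_strength, None if frame.forces is None
                     else frame.forces.copy())
    center = np.asarray(center_xy, dtype=float)
    pos = _apply_pore(frame.topology, frame.positions, center, radius, spacing)
    return Frame(frame.topology, pos, frame.time, frame.field_strength)


# ---------------------------------------------------------------------------
# trajectory generation


def _equilibrium_amplitude(params: SurrogateParams, E: float, deformation: float) -> float:
    """Target undulation amplitude: thermal part shrunk by field alignment,
    plus the slow accumulated deformation."""
    thermal = params.undulation_amp0 * math.exp(-params.align_coupling * E * E)
    return thermal + params.deformation_amp * deformation


def _tension(params: SurrogateParams, tilt_deg: np.ndarray) -> float:
    """gamma(t) = baseline + coupling * <tilt^2> (mN/m, tilt in degrees)."""
    return params.baseline_tension + (
        params.deformation_tension_coupling * float(np.mean(tilt_deg**2))
    )


def _hazard(params: SurrogateParams, E: float, gamma: float) -> float:
    """Pore-nucleation hazard, 1/ns."""
    return params.nucleation_rate0 * math.exp(
        params.field_susceptibility * E * E - params.tension_penalty * gamma
    )


def generate_trajectory(
    system: MembraneSystem,
    protocol: FieldProtocol,
    params: SurrogateParams,
    dt_out: float = 0.1,
    max_plateau: float = 50.0,
    fall_delay: float = 4.0,
    post_pore: float = 3.0,
    record_forces: bool = True,
    cell_size: float = 1.0,
    force_selector: str = "choline",
):
    """Generate a surrogate trajectory under a ramped-field protocol.

    Returns ``(trajectory, pressure_series, force_series)`` where the
    pressure series is an exact inversion of the mechanical surface-tension
    formula for the instantaneous tension (Pzz held at 1 bar, Pxx = Pyy), and
    the force series holds the per-frame component sums of the per-bead
    Coulomb forces over the choline (NC3) beads as
    ``(times, Fx, Fy, Fz)`` arrays.

    The run ends at ``rise + max_plateau`` if no pore forms, ``post_pore`` ns
    after nucleation otherwise; with a falling edge the plateau is held until
    ``fall_delay`` ns after nucleation, then the edge is applied and the run
    continues one extra ns past the end of the fall.  Pores smaller than
    ``recovery_radius_threshold`` at fall onset reseal; larger pores persist.

    Deterministic (bit-reproducible) for fixed (system, protocol, params).
    """
    if np.all(system.leaflets == "unassigned"):
        assign_leaflets(system)
    rng = np.random.default_rng(params.seed)
    box = system.box
    und = Undulation(box, params.undulation_modes, rng)
    # symmetry-breaking in-plane direction of the lateral Coulomb component
    phi = rng.uniform(0.0, 2.0 * np.pi)
    u_lat = np.array([math.cos(phi), math.sin(phi)])

    n_x = max(1, int(box.Lx // cell_size))
    n_y = max(1, int(box.Ly // cell_size))
    cx = (np.arange(n_x) + 0.5) * (box.Lx / n_x)
    cy = (np.arange(n_y) + 0.5) * (box.Ly / n_y)
    cell_xy = np.stack(np.meshgrid(cx, cy, indexing="ij"), axis=-1).reshape(-1, 2)
    g_cell = np.linalg.norm(und.gradient(cell_xy), axis=1)  # unit-shape slope
    mean_g = max(float(np.mean(g_cell)), 1e-9)

    # initial tilt field: equilibrium at zero field
    amp = _equilibrium_amplitude(params, 0.0, 0.0)
    tilt = np.degrees(np.arctan(amp * g_cell))
    state = SurrogateState(tilt_deg=tilt, tension=_tension(params, tilt), deformation=0.0)

    from .mechanics import bead_selector

    sel_idx = bead_selector(force_selector)(system)
    charges = system.charges

    decay = math.exp(-dt_out / params.tilt_relax_tau)
    noise_scale = params.thermal_noise_sigma * math.sqrt(max(0.0, 1.0 - decay * decay))
    d_decay = math.exp(-dt_out / params.deformation_tau)

    proto_eff = protocol
    frames: list[Frame] = []
    times, pxx_l, pzz_l, gam_l = [], [], [], []
    f_sums: list[tuple[float, float, float]] = []
    recovering = False
    radius_at_onset = 0.0
    t = 0.0
    step = 0
    end_time: float | None = None

    while True:
        E = proto_eff.field_at(t)

        # (i) slow deformation mode and per-cell tilt relaxation
        target = 1.0 if E > 1e-12 else 0.0
        state.deformation = target + (state.deformation - target) * d_decay
        amp_eq = _equilibrium_amplitude(params, E, state.deformation)
        tilt_eq = np.degrees(np.arctan(amp_eq * g_cell))
        tilt = tilt_eq + (state.tilt_deg - tilt_eq) * decay
        if noise_scale > 0:
            tilt = tilt + noise_scale * rng.standard_normal(tilt.shape)
        state.tilt_deg = np.clip(tilt, 0.0, 90.0)

        # (ii) reconstruct the surface and re-pose the lipid beads
        safe = np.clip(state.tilt_deg, 0.0, 80.0)
        amp_inst = float(np.mean(np.tan(np.radians(safe)))) / mean_g
        pos = pose_on_surface(system, und, amp_inst)

        # (iii) tension and the pressure triple that encodes it exactly
        gamma = _tension(params, state.tilt_deg)
        state.tension = gamma
        gamma_bar_nm = gamma / MN_PER_M_PER_BAR_NM
        pzz = 1.0
        pxx = pzz - 2.0 * gamma_bar_nm / box.Lz
        times.append(t)
        pxx_l.append(pxx)
        pzz_l.append(pzz)
        gam_l.append(gamma)

        # (v) pore nucleation / growth / recovery
        if state.pore_formed and state.pore_time is not None:
            onset = proto_eff.fall_onset
            if recovering and onset is not None and t >= onset:
                shrink = radius_at_onset * (t - onset) / max(proto_eff.fall_time, dt_out)
                state.pore_radius = max(0.0, radius_at_onset - shrink)
            else:
                state.pore_radius = min(
                    params.pore_radius_cap,
                    params.pore_growth_rate * (t - state.pore_time),
                )
        if state.pore_formed and state.pore_center is not None and not (
            recovering and state.pore_radius <= 0.0
        ):
            pos = _apply_pore(system, pos, state.pore_center, state.pore_radius,
                              params.water_spacing)

        # (iv) per-bead Coulomb forces: field projected on the local normal
        forces = None
        if record_forces:
            grad = und.gradient(pos[:, :2]) * amp_inst
            slope = np.hypot(grad[:, 0], grad[:, 1])
            cos_t = 1.0 / np.sqrt(1.0 + slope**2)
            sin_t = slope * cos_t
            fmag = charges * E * COULOMB_KJ_PER_MOL_NM
            forces = np.zeros_like(pos)
            forces[:, 2] = fmag * cos_t
            forces[:, 0] = np.abs(fmag) * sin_t * u_lat[0]
            forces[:, 1] = np.abs(fmag) * sin_t * u_lat[1]
            if params.force_noise_sigma > 0:
                forces = forces + params.force_noise_sigma * rng.standard_normal(
                    forces.shape
                )
            fs = forces[sel_idx].sum(axis=0)
            f_sums.append((fs[0], fs[1], fs[2]))

        if not np.all(np.isfinite(pos)):
            raise RuntimeError(f"surrogate generator produced non-finite state at step {step}")
        frames.append(Frame(system, pos, t, float(E), forces))

        # nucleation draw (after emitting the frame: pores appear next step)
        if not state.pore_formed:
            lam = _hazard(params, E, gamma)
            if rng.random() < -math.expm1(-lam * dt_out):
                state.pore_formed = True
                state.pore_time = t + dt_out
                state.pore_center = np.array([
                    rng.uniform(0.0, box.Lx), rng.uniform(0.0, box.Ly)
                ])
                if protocol.fall_time > 0 and protocol.constant_duration is None:
                    onset = max(protocol.rise_time, state.pore_time + fall_delay)
                    proto_eff = protocol.with_constant_duration(
                        onset - protocol.rise_time
                    )
                    r_onset = min(params.pore_radius_cap,
                                  params.pore_growth_rate * (onset - state.pore_time))
                    radius_at_onset = r_onset
                    recovering = r_onset < params.recovery_radius_threshold
                    end_time = onset + protocol.fall_time + 1.0
                else:
                    # always cover the full ramp so end-of-rise analyses work
                    end_time = max(state.pore_time + post_pore, protocol.rise_time)

        # termination
        hard_stop = protocol.rise_time + max_plateau
        if end_time is None and t >= hard_stop - 1e-9:
            if protocol.fall_time > 0 and protocol.constant_duration is None:
                proto_eff = protocol.with_constant_duration(max_plateau)
                end_time = hard_stop + protocol.fall_time + 1.0
            else:
                break
        if end_time is not None and t >= end_time - 1e-9:
            break
        t = round((step + 1) * dt_out, 9)
        step += 1

    metadata = {
        "generator": "poreramp-surrogate",
        "seed": params.seed,
        "protocol": proto_eff,
        "requested_protocol": protocol,
        "pore_time": state.pore_time,
        "pore_center": None if state.pore_center is None else state.pore_center.tolist(),
        "recovered": bool(recovering and state.pore_formed),
        "dt_out": dt_out,
    }
    traj = Trajectory(topology=system, frames=frames, metadata=metadata)
    pressure = PressureTensorSeries(
        times=np.array(times),
        Pxx=np.array(pxx_l),
        Pyy=np.array(pxx_l),
        Pzz=np.array(pzz_l),
        Lz=box.Lz,
    )
    force_series = {
        "times": np.array(times),
        "Fx": np.array([f[0] for f in f_sums]),
        "Fy": np.array([f[1] for f in f_sums]),
        "Fz": np.array([f[2] for f in f_sums]),
    } if record_forces else None
    traj.metadata["gamma_true"] = np.array(gam_l)
    return traj, pressure, force_series
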