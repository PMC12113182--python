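"""Pressure-tensor surface tension and Coulomb-force anisotropy.

The membrane surface tension is computed from the diagonal pressure
components with the standard mechanical-equilibrium expression

    gamma = (Lz / 2) * [Pzz - (Pxx + Pyy) / 2]

with pressures in bar, Lz in nm, and the result converted from bar nm to
mN/m (1 bar nm = 0.1 mN/m).  A variant replacing the lateral mean by the
lateral difference, gamma = (Lz/2) Pzz - (Pxx - Pyy)/2, appears in parts of
the electroporation literature; it is available behind ``literal_form=True``
for fidelity experiments but yields nonzero tension for an isotropic fluid
and is not the default.

The Coulomb-force anisotropy splits the summed per-bead electrostatic force
on a membrane bead selection into the magnitude of the in-plane (XY) vector
sum and the normal (Z) component sum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .system_model import Frame, MembraneSystem

#: 1 bar nm in mN/m.
MN_PER_M_PER_BAR_NM = 0.1
#: Force on one elementary charge in a 1 V/nm field, in kJ/mol/nm.
COULOMB_KJ_PER_MOL_NM = 96.4853


@dataclass(frozen=True)
class PressureTensorSample:
    """Diagonal pressure components (bar) at one time (ns)."""

    time: float
    Pxx: float
    Pyy: float
    Pzz: float

    def __post_init__(self) -> None:
        if not all(np.isfinite(v) for v in (self.time, self.Pxx, self.Pyy, self.Pzz)):
            raise ValueError("non-finite pressure sample")


@dataclass
class PressureTensorSeries:
    """Time series of diagonal pressure components with the box height Lz."""

    times: np.ndarray
    Pxx: np.ndarray
    Pyy: np.ndarray
    Pzz: np.ndarray
    Lz: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.Pxx = np.asarray(self.Pxx, dtype=float)
        self.Pyy = np.asarray(self.Pyy, dtype=float)
        self.Pzz = np.asarray(self.Pzz, dtype=float)
        n = len(self.times)
        if not (len(self.Pxx) == len(self.Pyy) == len(self.Pzz) == n):
            raise ValueError("pressure component lengths differ")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not self.Lz > 0:
            raise ValueError("Lz must be > 0")

    @property
    def samples(self) -> list[PressureTensorSample]:
        return [
            PressureTensorSample(t, x, y, z)
            for t, x, y, z in zip(self.times, self.Pxx, self.Pyy, self.Pzz)
        ]


@dataclass(frozen=True)
class ForceDecomposition:
    """Anisotropy split of the summed Coulomb force on a bead selection."""

    time: float
    F_xy: float  # magnitude of the XY vector sum, kJ/mol/nm (>= 0)
    F_z: float   # sum of Z components, kJ/mol/nm

    def __post_init__(self) -> None:
        if self.F_xy < 0:
            raise ValueError("F_xy is a magnitude and must be >= 0")


def surface_tension(sample, Lz: float = 12.5, literal_form: bool = False) -> float:
    """Surface tension (mN/m) from one pressure-tensor sample.

    ``sample`` may be a :class:`PressureTensorSample` or an
    ``(Pxx, Pyy, Pzz)`` triple in bar.  ``Lz`` is the box height in nm
    (default 12.5 nm, the production box of the source experiments).
    """
    if not Lz > 0:
        raise ValueError("Lz must be > 0")
    if isinstance(sample, PressureTensorSample):
        pxx, pyy, pzz = sample.Pxx, sample.Pyy, sample.Pzz
    else:
        pxx, pyy, pzz = sample
    if literal_form:
        gamma_bar_nm = 0.5 * Lz * pzz - 0.5 * (pxx - pyy)
    else:
        gamma_bar_nm = 0.5 * Lz * (pzz - 0.5 * (pxx + pyy))
    return gamma_bar_nm * MN_PER_M_PER_BAR_NM


def tension_series(
    series: PressureTensorSeries,
    smoothing_window: float = 1.0,
    literal_form: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample surface tension with a centred running mean.

    Returns ``(times, gamma)`` in ns and mN/m.  The running mean covers
    samples within ``smoothing_window / 2`` of each time; end points use
    truncated windows.  A window smaller than the sampling interval leaves
    the series unsmoothed.
    """
    if len(series.times) == 0:
        raise ValueError("empty pressure series")
    if literal_form:
        gamma = (0.5 * series.Lz * series.Pzz - 0.5 * (series.Pxx - series.Pyy))
    else:
        gamma = 0.5 * series.Lz * (series.Pzz - 0.5 * (series.Pxx + series.Pyy))
    gamma = gamma * MN_PER_M_PER_BAR_NM
    t = series.times
    half = smoothing_window / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(gamma)])
    smoothed = (csum[hi] - csum[lo]) / np.maximum(hi - lo, 1)
    return t.copy(), smoothed


def bead_selector(name: str) -> Callable[[MembraneSystem], np.ndarray]:
    """Named bead selections for the force decomposition.

    ``"choline"`` — NC3 beads (the default Z-force proxy: the signed Z sum
    over the full zwitterionic headgroup cancels by charge symmetry);
    ``"headgroups"`` — NC3 + PO4; ``"lipids"`` — all lipid beads;
    ``"charged"`` — every bead with nonzero charge.
    """
    def choline(s: MembraneSystem) -> np.ndarray:
        return s.bead_indices_by_name("NC3")

    def headgroups(s: MembraneSystem) -> np.ndarray:
        return s.bead_indices_by_name("NC3", "PO4")

    def lipids(s: MembraneSystem) -> np.ndarray:
        return s.lipid_bead_indices.ravel()

    def charged(s: MembraneSystem) -> np.ndarray:
        return np.flatnonzero(s.charges != 0)

    table = {"choline": choline, "headgroups": headgroups,
             "lipids": lipids, "charged": charged}
    try:
        return table[name]
    except KeyError:
        raise ValueError(f"unknown bead selector {name!r}; options: {sorted(table)}")


def coulomb_decompose(frame: Frame, membrane_bead_selector="choline") -> ForceDecomposition:
    """Split the summed Coulomb force on the selected beads into XY and Z.

    ``membrane_bead_selector`` is a named selection (see :func:`bead_selector`),
    an index array, or a callable mapping the topology to indices.  Requires
    per-bead forces on the frame.
    """
    if frame.forces is None:
        raise ValueError(
            "frame carries no per-bead forces; regenerate the trajectory with "
            "force output enabled (record_forces=True)"
        )
    sel = membrane_bead_selector
    if isinstance(sel, str):
        sel = bead_selector(sel)
    idx = sel(frame.topology) if callable(sel) else np.asarray(sel, dtype=int)
    if len(idx) == 0:
        raise ValueError("bead selector yielded no beads")
    f = frame.forces[idx]
    fx, fy, fz = f[:, 0].sum(), f[:, 1].sum(), f[:, 2].sum()
    return ForceDecomposition(time=frame.time, F_xy=float(np.hypot(fx, fy)),
                              F_z=float(fz))


def window_stats(
    times: Sequence[float],
    values: Sequence[float],
    center: float,
    width: float = 1.0,
    exclude_before: float = 0.0,
) -> tuple[float, float]:
    """Mean and population SD of samples in a time window.

    Uses samples with ``|t - center| <= width / 2`` and ``t >= exclude_before``
    (the latter excludes the field's rise phase).  Raises if the admissible
    window is empty.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    mask = (np.abs(t - center) <= width / 2.0 + 1e-12) & (t >= exclude_before - 1e-12)
    if not np.any(mask):
        raise ValueError(
            f"no samples in window |t - {center}| <= {width / 2} with t >= {exclude_before}"
        )
    sel = v[mask]
    return float(np.mean(sel)), float(np.std(sel))
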