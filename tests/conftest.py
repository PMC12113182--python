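"""Shared fixtures: small bilayers, water-only boxes, and surrogate runs.

All fixtures are generated programmatically; the "small" membrane (128
lipids in a 6.2 x 6.2 x 12.5 nm box) keeps end-to-end tests fast while the
session-scoped default system checks the full production composition.
"""

from __future__ import annotations

import numpy as np
import pytest

import poreramp as pr
from poreramp.system_model import (
    BEAD_CHARGES,
    CAT_WATER,
    Box,
    MembraneSystem,
)

SMALL_KW = dict(
    n_lipids=128, n_cations=30, n_anions=30, n_waters=2600,
    box=(6.2, 6.2, 12.5),
)


@pytest.fixture(scope="session")
def default_system() -> MembraneSystem:
    """The full production composition (1024 lipids, 244+244 ions)."""
    return pr.build_system(seed=0)


@pytest.fixture()
def small_system() -> MembraneSystem:
    return pr.build_system(seed=1, **SMALL_KW)


@pytest.fixture()
def small_frame(small_system) -> pr.Frame:
    return pr.Frame(small_system, small_system.positions.copy(), 0.0)


def water_only_system(positions: np.ndarray, box: Box) -> MembraneSystem:
    """A box containing only water beads at the given positions."""
    n = len(positions)
    return MembraneSystem(
        box=box,
        names=np.array(["W"] * n),
        resids=np.arange(1, n + 1),
        resnames=np.array(["W"] * n),
        charges=np.zeros(n),
        categories=np.full(n, CAT_WATER),
        positions=np.asarray(positions, dtype=float),
        lipid_bead_indices=np.empty((0, 12), dtype=int),
    )


def surface_frame(system: MembraneSystem, amplitude: float,
                  wavelength_x: float | None = None) -> pr.Frame:
    """Frame with every lipid displaced onto z += A sin(2 pi x / Lx)."""
    Lx = system.box.Lx if wavelength_x is None else wavelength_x
    pos = system.positions.copy()
    anchors = pos[system.po4_indices(), :2]
    h = amplitude * np.sin(2 * np.pi * anchors[:, 0] / Lx)
    pos[system.lipid_bead_indices, 2] += h[:, None]
    return pr.Frame(system, pos, 0.0)


def brute_force_spanning(points: np.ndarray, box: Box, z_low: float,
                         z_high: float, cutoff: float) -> bool:
    """Exhaustive all-pairs + BFS oracle for transmembrane connectivity."""
    pts = np.asarray(points, dtype=float)
    near = (pts[:, 2] >= z_low - cutoff) & (pts[:, 2] <= z_high + cutoff)
    pts = pts[near]
    n = len(pts)
    if n == 0:
        return False
    d = pts[:, None, :] - pts[None, :, :]
    d[..., 0] -= box.Lx * np.round(d[..., 0] / box.Lx)
    d[..., 1] -= box.Ly * np.round(d[..., 1] / box.Ly)
    adj = (d ** 2).sum(axis=-1) <= cutoff ** 2
    below = np.flatnonzero(pts[:, 2] < z_low)
    above = set(np.flatnonzero(pts[:, 2] > z_high))
    if len(below) == 0 or not above:
        return False
    seen = set()
    stack = list(below)
    while stack:
        i = stack.pop()
        if i in seen:
            continue
        seen.add(i)
        if i in above:
            return True
        stack.extend(int(j) for j in np.flatnonzero(adj[i]) if j not in seen)
    return False
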