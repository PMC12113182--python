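"""Applied electric-field waveforms: linear rise, plateau, optional linear fall.

The field is applied along +Z.  A protocol is E(t) with a linear ramp from
zero to the peak over ``rise_time``, a constant plateau at the peak (open
ended by default — in the source experiments the field was held until pore
formation), and an optional linear falling edge back to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

#: Peak field strengths of the default experiment grid, V/nm.
DEFAULT_PEAKS: tuple[float, ...] = (0.16, 0.18, 0.20)
#: Rise times of the default experiment grid, ns.
DEFAULT_RISE_TIMES: tuple[float, ...] = (1.0, 5.0, 10.0, 15.0, 20.0, 30.0)
#: Replicates per grid condition.
DEFAULT_REPLICATES: int = 5


@dataclass(frozen=True)
class FieldProtocol:
    """Piecewise-linear Z-axis field protocol.

    Parameters
    ----------
    peak:
        Peak field strength, V/nm (> 0).
    rise_time:
        Ramp duration, ns (>= 0; 0 means a step to the peak at t = 0).
    constant_duration:
        Plateau duration, ns, or ``None`` for an open-ended plateau.
    fall_time:
        Falling-edge duration, ns (0 = no falling edge).  A falling edge is
        only evaluable once ``constant_duration`` is concrete.
    """

    peak: float
    rise_time: float
    constant_duration: float | None = None
    fall_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.peak > 0:
            raise ValueError(f"peak must be > 0 V/nm, got {self.peak}")
        if self.rise_time < 0:
            raise ValueError(f"rise_time must be >= 0 ns, got {self.rise_time}")
        if self.constant_duration is not None and self.constant_duration < 0:
            raise ValueError("constant_duration must be >= 0 ns or None")
        if self.fall_time < 0:
            raise ValueError(f"fall_time must be >= 0 ns, got {self.fall_time}")

    @property
    def fall_onset(self) -> float | None:
        """Time at which the falling edge starts, if determined."""
        if self.fall_time > 0 and self.constant_duration is not None:
            return self.rise_time + self.constant_duration
        return None

    def with_constant_duration(self, duration: float) -> "FieldProtocol":
        """Concretise an open-ended plateau (e.g. once a pore has formed)."""
        return replace(self, constant_duration=float(duration))

    def field_at(self, t):
        """Field strength E(t) in V/nm; accepts scalars or arrays, t >= 0."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < 0):
            raise ValueError("field_at is undefined for negative times")
        out = np.full_like(t_arr, self.peak, dtype=float)
        if self.rise_time > 0:
            rising = t_arr < self.rise_time
            out[rising] = self.peak * t_arr[rising] / self.rise_time
        onset = self.fall_onset
        if onset is not None:
            falling = t_arr >= onset
            frac = 1.0 - (t_arr[falling] - onset) / self.fall_time
            out[falling] = self.peak * np.clip(frac, 0.0, 1.0)
        elif self.fall_time == 0 and self.constant_duration is not None:
            out[t_arr > self.rise_time + self.constant_duration] = 0.0
        if np.ndim(t) == 0:
            return float(out)
        return out

    def rise_integral(self) -> float:
        """Closed-form integral of E over the rise phase (triangle area)."""
        return 0.5 * self.peak * self.rise_time


def field_at(protocol: FieldProtocol, t):
    """Module-level convenience wrapper for :meth:`FieldProtocol.field_at`."""
    return protocol.field_at(t)


def condition_seed(base_seed: int, peak: float, rise_time: float, replicate: int) -> int:
    """Deterministic per-condition seed, counter-based.

    The seed is derived from the tuple (base_seed, peak, rise, replicate)
    through :class:`numpy.random.SeedSequence`, so adding or removing grid
    conditions never perturbs the random streams of the others.  Values stay
    below 2**31.
    """
    key = (
        int(base_seed),
        int(round(peak * 1_000_000)),
        int(round(rise_time * 1_000_000)),
        int(replicate),
    )
    ss = np.random.SeedSequence(key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def protocol_grid(
    peaks: Sequence[float] = DEFAULT_PEAKS,
    rise_times: Sequence[float] = DEFAULT_RISE_TIMES,
    replicates: int = DEFAULT_REPLICATES,
    base_seed: int = 0,
    fall_time: float = 0.0,
) -> list[tuple[FieldProtocol, int]]:
    """Cartesian product of peaks x rise times, each with replicate seeds.

    Returns a list of ``(FieldProtocol, seed)`` pairs (len(peaks) *
    len(rise_times) * replicates entries).  Raises on duplicate
    (peak, rise, seed) triples.
    """
    if not peaks or not rise_times:
        raise ValueError("peaks and rise_times must be nonempty")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    runs: list[tuple[FieldProtocol, int]] = []
    seen: set[tuple[float, float, int]] = set()
    for peak in peaks:
        for rise in rise_times:
            for rep in range(replicates):
                seed = condition_seed(base_seed, peak, rise, rep)
                triple = (float(peak), float(rise), seed)
                if triple in seen:
                    raise ValueError(f"duplicate grid condition {triple}")
                seen.add(triple)
                runs.append(
                    (FieldProtocol(peak=float(peak), rise_time=float(rise),
                                   fall_time=float(fall_time)), seed)
                )
    return runs
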