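"""Run configuration: a versioned, structured description of a full study.

A :class:`RunConfig` fully determines every output of the pipeline given the
code version: the system builder parameters, the surrogate dynamics, the
field-protocol grid, and every analysis constant (no hidden constants — the
pipeline consumes the analysis section verbatim, which a test enforces).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .field_protocol import DEFAULT_PEAKS, DEFAULT_REPLICATES, DEFAULT_RISE_TIMES
from .synthetic import SurrogateParams

SCHEMA_VERSION = 1


@dataclass
class SystemConfig:
    """System-builder parameters (defaults: the full production system)."""

    n_lipids: int = 1024
    n_cations: int = 244
    n_anions: int = 244
    n_waters: int = 21000
    box: tuple[float, float, float] = (17.3, 17.3, 12.5)
    area_per_lipid: float | None = None
    hydrophobic_half_thickness: float = 2.3


@dataclass
class ProtocolConfig:
    """Field-protocol experiment grid."""

    peaks: tuple[float, ...] = DEFAULT_PEAKS
    rise_times: tuple[float, ...] = DEFAULT_RISE_TIMES
    fall_time: float = 0.0
    replicates: int = DEFAULT_REPLICATES
    base_seed: int = 2025
    max_plateau: float = 50.0
    dt_out: float = 0.1
    fall_delay: float = 4.0
    post_pore: float = 3.0


@dataclass
class AnalysisConfig:
    """Analysis constants (defaults follow the source experiments)."""

    cell_size: float = 1.0           # nm, orientation subregion edge
    angle_threshold: float = 45.0    # degrees, strict "below" threshold
    halo: float = 0.5                # nm, sparse-cell neighbour halo
    chain_cutoff: float = 0.6        # nm, water-chain connectivity cutoff
    slab_margin: float = 0.3         # nm, inside the PO4 planes
    persistence_frames: int = 3      # flicker filter for the pore call
    radius_grid: float = 0.5         # nm, pore-size grid resolution
    window_width: float = 1.0        # ns, stats window around the pore moment
    smoothing_window: float = 1.0    # ns, tension running mean
    force_selector: str = "choline"  # bead selection for the force split


@dataclass
class RunConfig:
    schema_version: int = SCHEMA_VERSION
    system: SystemConfig = field(default_factory=SystemConfig)
    surrogate: SurrogateParams = field(default_factory=SurrogateParams)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "poreramp_runs"
    log_level: str = "INFO"

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        version = data.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(
                f"config schema version {version} unsupported (expected {SCHEMA_VERSION})"
            )
        sys_d = dict(data.pop("system", {}))
        if "box" in sys_d and sys_d["box"] is not None:
            sys_d["box"] = tuple(sys_d["box"])
        proto_d = dict(data.pop("protocol", {}))
        for key in ("peaks", "rise_times"):
            if key in proto_d:
                proto_d[key] = tuple(proto_d[key])
        return cls(
            schema_version=SCHEMA_VERSION,
            system=SystemConfig(**sys_d),
            surrogate=SurrogateParams(**data.pop("surrogate", {})),
            protocol=ProtocolConfig(**proto_d),
            analysis=AnalysisConfig(**data.pop("analysis", {})),
            output_dir=data.pop("output_dir", "poreramp_runs"),
            log_level=data.pop("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    # -- presets -----------------------------------------------------------

    @classmethod
    def default(cls) -> "RunConfig":
        """The full study grid: 3 peaks x 6 rise times x 5 replicates."""
        return cls()

    @classmethod
    def smoke(cls, base_seed: int = 2025) -> "RunConfig":
        """Reduced grid and system for fast end-to-end runs.

        One peak, two rise times (1 and 30 ns), three replicates on a
        128-lipid membrane — small enough to run end to end in minutes while
        keeping the rise-time contrast that drives every trend.
        """
        return cls(
            system=SystemConfig(
                n_lipids=128, n_cations=30, n_anions=30, n_waters=2600,
                box=(6.2, 6.2, 12.5),
            ),
            protocol=ProtocolConfig(
                peaks=(0.16,), rise_times=(1.0, 30.0), replicates=3,
                base_seed=base_seed, dt_out=0.25,
            ),
            output_dir="poreramp_smoke",
        )
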