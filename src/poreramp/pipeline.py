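"""End-to-end orchestration: generate the experiment grid, analyse every
run, and summarise the trends.

``generate`` writes one multi-frame GRO trajectory plus pressure and force
XVG series per grid condition and seed, with a manifest listing all
artifacts.  ``analyze`` re-reads those artifacts and applies the analysis
stages — pore timing under both conventions, the end-of-ramp orientation
fraction, window tension, and the Coulomb-force anisotropy — producing one
row per run and a per-condition summary.  ``report`` renders the summary as
a plain-text account of the rise-time trends.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats, mechanics, orientation, pores
from .config import RunConfig
from .field_protocol import FieldProtocol, protocol_grid
from .synthetic import SurrogateParams, build_system, generate_trajectory

log = logging.getLogger("poreramp")

MANIFEST_NAME = "manifest.tsv"
RUNS_NAME = "runs.tsv"
SUMMARY_NAME = "summary.tsv"
REPORT_NAME = "report.txt"

#: How the pipeline maps AnalysisConfig fields onto analysis-stage keyword
#: arguments.  Every config field must appear here (config-coverage test).
ANALYSIS_KWARG_MAP: dict[str, str] = {
    "cell_size": "orientation.compute_angle_map(cell_size=...)",
    "angle_threshold": "orientation.fraction_below(threshold=...)",
    "halo": "orientation.compute_angle_map(halo=...)",
    "chain_cutoff": "pores.*(cutoff=...)",
    "slab_margin": "pores.*(margin=...)",
    "persistence_frames": "pores.pore_formation_time(persistence_frames=...)",
    "radius_grid": "pores.pore_radius(grid_resolution=...)",
    "window_width": "mechanics.window_stats(width=...)",
    "smoothing_window": "mechanics.tension_series(smoothing_window=...)",
    "force_selector": "mechanics.coulomb_decompose(membrane_bead_selector=...)",
}


def _run_id(peak: float, rise: float, seed: int) -> str:
    return f"peak{peak:.2f}_rise{rise:g}_seed{seed}"


def generate(config: RunConfig, out_dir: str | Path | None = None,
             force: bool = False) -> Path:
    """Generate every run of the grid; returns the manifest path."""
    out = Path(out_dir if out_dir is not None else config.output_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(
            f"output directory {out} is not empty; pass force=True / --force"
        )
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())

    p = config.protocol
    grid = protocol_grid(p.peaks, p.rise_times, p.replicates, p.base_seed,
                         fall_time=p.fall_time)
    rows = []
    for protocol, seed in grid:
        t0 = _time.perf_counter()
        run_id = _run_id(protocol.peak, protocol.rise_time, seed)
        run_dir = out / run_id
        run_dir.mkdir(exist_ok=True)
        s = config.system
        system = build_system(
            n_lipids=s.n_lipids, n_cations=s.n_cations, n_anions=s.n_anions,
            n_waters=s.n_waters, box=s.box, area_per_lipid=s.area_per_lipid,
            hydrophobic_half_thickness=s.hydrophobic_half_thickness, seed=seed,
        )
        params = dataclasses.replace(config.surrogate, seed=seed)
        traj, pressure, force_series = generate_trajectory(
            system, protocol, params, dt_out=p.dt_out, max_plateau=p.max_plateau,
            fall_delay=p.fall_delay, post_pore=p.post_pore,
            cell_size=config.analysis.cell_size,
            force_selector=config.analysis.force_selector,
        )
        io_formats.write_gro(traj, run_dir / "traj.gro")
        io_formats.write_series(
            io_formats.SeriesTable(
                columns={"time": pressure.times, "Pxx": pressure.Pxx,
                         "Pyy": pressure.Pyy, "Pzz": pressure.Pzz},
                comments=[f"# pressure tensor diagonal, bar; Lz {pressure.Lz} nm"],
            ),
            run_dir / "pressure.xvg",
        )
        io_formats.write_series(
            io_formats.SeriesTable(
                columns={"time": force_series["times"], "Fx": force_series["Fx"],
                         "Fy": force_series["Fy"], "Fz": force_series["Fz"]},
                comments=[
                    "# Coulomb force component sums over the "
                    f"{config.analysis.force_selector} bead selection, kJ/mol/nm"
                ],
            ),
            run_dir / "forces.xvg",
        )
        proto_eff: FieldProtocol = traj.metadata["protocol"]
        (run_dir / "protocol.json").write_text(json.dumps({
            "peak": proto_eff.peak,
            "rise_time": proto_eff.rise_time,
            "constant_duration": proto_eff.constant_duration,
            "fall_time": proto_eff.fall_time,
            "seed": seed,
        }, sort_keys=True))
        rows.append({
            "run_id": run_id, "peak": protocol.peak, "rise_ns": protocol.rise_time,
            "fall_ns": protocol.fall_time, "seed": seed,
            "n_frames": len(traj), "path": run_id,
        })
        log.info("generated %s (%d frames) in %.1f s", run_id, len(traj),
                 _time.perf_counter() - t0)
    manifest = pd.DataFrame(rows)
    manifest_path = out / MANIFEST_NAME
    manifest.to_csv(manifest_path, sep="\t", index=False, float_format="%.6g")
    return manifest_path


def _analyze_run(config: RunConfig, run_dir: Path) -> dict:
    a = config.analysis
    proto_d = json.loads((run_dir / "protocol.json").read_text())
    seed = proto_d.pop("seed")
    protocol = FieldProtocol(**proto_d)
    traj = io_formats.read_gro(run_dir / "traj.gro")
    if not hasattr(traj, "frames"):  # single-frame file
        raise ValueError(f"{run_dir}: trajectory has a single frame")

    row: dict = {"peak": protocol.peak, "rise_ns": protocol.rise_time,
                 "seed": seed, "error": ""}

    event = pores.pore_formation_time(
        traj, protocol, persistence_frames=a.persistence_frames,
        cutoff=a.chain_cutoff, margin=a.slab_margin,
        grid_resolution=a.radius_grid,
    )
    row["t_total_ns"] = np.nan if event is None else event.formation_time_total
    row["t_post_peak_ns"] = np.nan if event is None else event.formation_time_post_peak
    row["max_radius_nm"] = np.nan if event is None else event.max_radius

    row["frac_below_45"] = orientation.endpoint_orientation(
        traj, protocol, cell_size=a.cell_size, threshold=a.angle_threshold,
        halo=a.halo,
    )

    ptab = io_formats.read_series(run_dir / "pressure.xvg")
    pseries = mechanics.PressureTensorSeries(
        times=ptab["time"], Pxx=ptab["Pxx"], Pyy=ptab["Pyy"], Pzz=ptab["Pzz"],
        Lz=traj.topology.box.Lz,
    )
    t_g, gamma = mechanics.tension_series(pseries, smoothing_window=a.smoothing_window)
    ftab = io_formats.read_series(run_dir / "forces.xvg")
    f_xy = np.hypot(ftab["Fx"], ftab["Fy"])
    if event is not None:
        center = event.formation_time_total
        exclude = protocol.rise_time
        try:
            row["tension_mN_m"], row["tension_sd"] = mechanics.window_stats(
                t_g, gamma, center, width=a.window_width, exclude_before=exclude)
            row["F_xy"], row["F_xy_sd"] = mechanics.window_stats(
                ftab["time"], f_xy, center, width=a.window_width,
                exclude_before=exclude)
            row["F_z"], row["F_z_sd"] = mechanics.window_stats(
                ftab["time"], ftab["Fz"], center, width=a.window_width,
                exclude_before=exclude)
        except ValueError:
            # pore formed during the ramp: no admissible post-peak window
            for k in ("tension_mN_m", "tension_sd", "F_xy", "F_xy_sd",
                      "F_z", "F_z_sd"):
                row[k] = np.nan
    else:
        for k in ("tension_mN_m", "tension_sd", "F_xy", "F_xy_sd", "F_z", "F_z_sd"):
            row[k] = np.nan

    if protocol.fall_time > 0 and event is not None:
        try:
            row["recovered"] = bool(pores.detect_recovery(
                traj, protocol, persistence_frames=a.persistence_frames,
                cutoff=a.chain_cutoff, margin=a.slab_margin))
        except ValueError:
            row["recovered"] = np.nan
    else:
        row["recovered"] = np.nan
    return row


RESULT_COLUMNS = [
    "run_id", "peak", "rise_ns", "seed", "t_total_ns", "t_post_peak_ns",
    "max_radius_nm", "frac_below_45", "tension_mN_m", "tension_sd",
    "F_xy", "F_xy_sd", "F_z", "F_z_sd", "recovered", "error",
]


def analyze(config: RunConfig, manifest_path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyse every run in the manifest.

    Returns ``(runs, summary)`` data frames and writes them as TSV beside
    the manifest.  Missing or broken artifacts produce per-run error rows.
    """
    manifest_path = Path(manifest_path)
    out = manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t")
    rows = []
    for rec in manifest.itertuples(index=False):
        run_dir = out / rec.path
        t0 = _time.perf_counter()
        try:
            row = _analyze_run(config, run_dir)
            row["run_id"] = rec.run_id
        except (OSError, ValueError) as exc:
            log.error("run %s failed: %s", rec.run_id, exc)
            row = {"run_id": rec.run_id, "peak": rec.peak, "rise_ns": rec.rise_ns,
                   "seed": rec.seed, "error": str(exc)}
        rows.append(row)
        log.info("analysed %s in %.1f s", rec.run_id, _time.perf_counter() - t0)
    runs = pd.DataFrame(rows).reindex(columns=RESULT_COLUMNS)

    ok = runs[runs["error"].fillna("") == ""]
    summary = (
        ok.groupby(["peak", "rise_ns"], as_index=False)
        .agg(
            n=("seed", "size"),
            t_total_mean=("t_total_ns", "mean"),
            t_total_sd=("t_total_ns", lambda v: float(np.std(v.dropna()))),
            t_post_peak_mean=("t_post_peak_ns", "mean"),
            frac_below_45_mean=("frac_below_45", "mean"),
            tension_mean=("tension_mN_m", "mean"),
            F_xy_mean=("F_xy", "mean"),
            F_z_mean=("F_z", "mean"),
        )
        .sort_values(["peak", "rise_ns"])
    )
    runs.to_csv(out / RUNS_NAME, sep="\t", index=False, float_format="%.6g")
    summary.to_csv(out / SUMMARY_NAME, sep="\t", index=False, float_format="%.6g")
    return runs, summary


def report(results_dir: str | Path) -> str:
    """Render a plain-text summary of the rise-time trends; idempotent."""
    out = Path(results_dir)
    summary_path = out / SUMMARY_NAME
    if not summary_path.exists():
        text = "poreramp report\n\nno runs\n"
        (out / REPORT_NAME).write_text(text)
        return text
    summary = pd.read_csv(summary_path, sep="\t")
    if summary.empty:
        text = "poreramp report\n\nno runs\n"
        (out / REPORT_NAME).write_text(text)
        return text

    lines = ["poreramp report", ""]
    for peak, grp in summary.groupby("peak"):
        grp = grp.sort_values("rise_ns")
        fast, slow = grp.iloc[0], grp.iloc[-1]
        lines.append(f"peak field {peak:g} V/nm "
                     f"(rise {fast.rise_ns:g} ns vs {slow.rise_ns:g} ns):")
        lines.append(
            f"  pore formation time: {fast.t_total_mean:.2f} ns vs "
            f"{slow.t_total_mean:.2f} ns — shorter rise, shorter pore time"
        )
        lines.append(
            f"  fraction of subregions with tilt < 45 deg at ramp end: "
            f"{fast.frac_below_45_mean:.3f} vs {slow.frac_below_45_mean:.3f} — "
            f"shorter rise, larger below-45 fraction"
        )
        lines.append(
            f"  window tension around the pore moment: "
            f"{fast.tension_mean:.2f} vs {slow.tension_mean:.2f} mN/m — "
            f"shorter rise, lower tension"
        )
        lines.append(
            f"  Coulomb force split: F_z {fast.F_z_mean:.3g} vs {slow.F_z_mean:.3g}, "
            f"F_xy {fast.F_xy_mean:.3g} vs {slow.F_xy_mean:.3g} kJ/mol/nm — "
            f"shorter rise, larger F_z and smaller F_xy"
        )
        lines.append("")
    text = "\n".join(lines)
    (out / REPORT_NAME).write_text(text)
    return text
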