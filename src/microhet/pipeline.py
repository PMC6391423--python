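"""Reproducible end-to-end runs: config in, tables/plots/manifest out.

A run executes simulate → render → segment → quantify → heterogeneity on one
promoter preset (or user-supplied image stacks), writes per-cell and
per-frame CSVs, a JSON summary, figure files, and a manifest recording the
full configuration, software version, per-file SHA-256 checksums and every
warning raised along the way.  Fixed seed + fixed config gives byte-identical
outputs (the timestamped run.log is the one file excluded from checksums).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .config import ConfigurationError, ImagingParams, config_to_dict
from .heterogeneity import (GrowthPhaseMarks, fit_calibration)
from .presets import PRESET_NAMES, default_imaging
from .render import render_frames, write_stacks
from .segment import segment_frame
from .simulate import simulate_colony
from .study import (MovieAnalysis, StudyResult, analyze_stacks,
                    imaged_calibration, run_preset_study)

__all__ = ["RunConfig", "RunManifest", "run_pipeline", "load_run_config"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML/JSON loadable)."""

    out_dir: str
    seed: int = 0
    preset: Optional[str] = None          # sunA | sunI
    phase_stack: Optional[str] = None     # TIFF path (real data path)
    fluor_stack: Optional[str] = None
    frame_interval: Optional[float] = None  # min, for real stacks
    pixel_size: Optional[float] = None      # µm/px, for real stacks
    calibration: str = "imaged"           # 'imaged' or CSV path of mean,sd
    reference_profile: Optional[str] = None  # summary.json of reference strain
    user_marks: Optional[List[float]] = None
    write_tiffs: bool = False
    overrides: Dict = field(default_factory=dict)     # ColonyConfig fields
    imaging_overrides: Dict = field(default_factory=dict)

    def validate(self) -> None:
        has_preset = self.preset is not None
        has_stacks = self.phase_stack is not None or self.fluor_stack is not None
        if has_preset == has_stacks:
            raise ConfigurationError(
                "exactly one input source required: a simulation preset "
                "xor real phase/fluorescence stacks")
        if has_preset and self.preset not in ("sunA", "sunI"):
            raise ConfigurationError(f"unknown preset {self.preset!r}")
        if has_stacks and (self.phase_stack is None or self.fluor_stack is None):
            raise ConfigurationError("real input needs both phase and fluor stacks")
        if has_stacks and (self.frame_interval is None or self.pixel_size is None):
            raise ConfigurationError("real stacks need frame_interval and pixel_size")


@dataclass
class RunManifest:
    config: Dict
    version: str
    seed: int
    checksums: Dict[str, str]
    warnings: List[str]
    summary: Dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def load_run_config(path) -> RunConfig:
    """Load a run config from YAML (JSON is a YAML subset)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(out: Path) -> logging.Logger:
    logger = logging.getLogger(f"microhet.run.{out}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (logging.StreamHandler(sys.stderr),
              logging.FileHandler(out / "run.log", mode="w")):
        h.setFormatter(fmt)
        logger.addHandler(h)
    logger.propagate = False
    return logger


def _plot_growth(profile, analysis: MovieAnalysis, out: Path) -> None:
    """Growth curve + mean fluorescence with heterogeneity error bars."""
    fig, ax1 = plt.subplots(figsize=(7, 4))
    t = analysis.times
    ax1.plot(t, analysis.feret_um, "k-", label="cumulative Feret (µm)")
    ax1.set_xlabel("time (min)")
    ax1.set_ylabel("cumulative Feret diameter (µm)")
    ax2 = ax1.twinx()
    st = [s.time for s in profile.snapshots]
    mean = [s.mean_fluor for s in profile.snapshots]
    err = [s.sd_corrected or 0.0 for s in profile.snapshots]
    ax2.errorbar(st, mean, yerr=err, color="grey", lw=1, elinewidth=0.5,
                 label="mean fluorescence ± corrected SD")
    ax2.set_ylabel("fluorescence (AU)")
    if profile.grey_zone:
        ax2.axvspan(*profile.grey_zone, color="0.85", zorder=0)
    for m in profile.marks.as_tuple():
        ax1.axvline(m, color="tab:blue", ls=":", lw=0.8)
    fig.tight_layout()
    fig.savefig(out / "growth_fluorescence.png", dpi=120)
    plt.close(fig)


def _plot_heterogeneity_bars(profile, out: Path) -> None:
    snaps = profile.at_marks()
    labels = ["exponential", "transition", "early stationary", "late stationary"]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(labels, [s.sd_corrected or 0.0 for s in snaps],
           color=["0.8", "0.6", "0.4", "0.2"])
    ax.set_ylabel("corrected SD (AU)")
    ax.tick_params(axis="x", rotation=20)
    fig.tight_layout()
    fig.savefig(out / "heterogeneity_marks.png", dpi=120)
    plt.close(fig)


def _plot_histogram3d(hist, out: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    extent = [hist.intensity_bin_edges[0], hist.intensity_bin_edges[-1],
              hist.time_bin_edges[0], hist.time_bin_edges[-1]]
    ax.imshow(hist.counts, aspect="auto", origin="lower", extent=extent,
              cmap="viridis")
    ax.set_xlabel("corrected fluorescence (AU)")
    ax.set_ylabel("time (min)")
    fig.tight_layout()
    fig.savefig(out / "expression_histogram3d.png", dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute a full run; any stage failure aborts with the stage name."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger = _setup_logging(out)
    warnings: List[str] = []
    written: List[Path] = []
    stage = "init"
    try:
        stage = "simulate/load"
        logger.info("stage %s", stage)
        imaging = default_imaging(**config.imaging_overrides)
        if config.preset is not None:
            from .presets import get_preset
            cfg, expr = get_preset(config.preset, config.seed, **config.overrides)
            gt = simulate_colony(cfg, expr)
            stacks = render_frames(gt, imaging)
            cell_width = cfg.cell_width
            gt_df = gt.to_dataframe()
            gt_path = out / "ground_truth.csv"
            gt_df.to_csv(gt_path, index=False)
            written.append(gt_path)
            if config.write_tiffs:
                written += write_stacks(stacks, out / "stacks")
        else:
            import tifffile
            from .render import RenderedStacks
            phase = tifffile.imread(config.phase_stack)
            fluor = tifffile.imread(config.fluor_stack)
            times = [i * config.frame_interval for i in range(phase.shape[0])]
            stacks = RenderedStacks(times, phase, fluor,
                                    np.zeros_like(phase, dtype=np.int32),
                                    config.pixel_size)
            cell_width = 1.0
            gt = None

        stage = "segment/quantify"
        logger.info("stage %s", stage)
        analysis = analyze_stacks(stacks, cell_width_um=cell_width)
        warnings += analysis.warnings
        cells_path = out / "cells.csv"
        analysis.cells_dataframe().to_csv(cells_path, index=False)
        written.append(cells_path)

        stage = "calibration"
        logger.info("stage %s", stage)
        if config.calibration == "imaged":
            model, points = imaged_calibration(config.seed + 10_000)
        else:
            points = pd.read_csv(config.calibration)
            if not {"mean_fluor", "sd_raw"} <= set(points.columns):
                raise ConfigurationError(
                    "calibration CSV needs mean_fluor and sd_raw columns")
            model = fit_calibration(list(zip(points["mean_fluor"], points["sd_raw"])))
        cal_path = out / "calibration_points.csv"
        points.to_csv(cal_path, index=False)
        written.append(cal_path)

        stage = "heterogeneity"
        logger.info("stage %s", stage)
        from .heterogeneity import (build_profile, expression_histogram3d,
                                    is_homogeneous)
        user_marks = (GrowthPhaseMarks(*config.user_marks)
                      if config.user_marks else None)
        ref_activity = None
        if config.reference_profile:
            with open(config.reference_profile) as fh:
                ref_activity = json.load(fh)["max_activity"]
        profile = build_profile(analysis.snapshots, model,
                                analysis.feret_curve(), user_marks=user_marks,
                                reference_activity=ref_activity)
        prof_path = out / "profile.csv"
        analysis.snapshots_dataframe().to_csv(prof_path, index=False)
        written.append(prof_path)

        cells_df = analysis.cells_dataframe()
        t_edges = np.linspace(cells_df["time_min"].min(),
                              cells_df["time_min"].max() + 1e-9, 9)
        vmax = max(float(cells_df["mean_fluor_corrected"].max()), 1.0)
        i_edges = np.linspace(min(0.0, float(cells_df["mean_fluor_corrected"].min())),
                              vmax, 33)
        hist = expression_histogram3d(cells_df["time_min"],
                                      cells_df["mean_fluor_corrected"],
                                      t_edges, i_edges)
        hist_path = out / "histogram3d.csv"
        pd.DataFrame(hist.counts,
                     index=hist.time_bin_edges[:-1],
                     columns=np.round(hist.intensity_bin_edges[:-1], 3),
                     ).to_csv(hist_path)
        written.append(hist_path)

        homogeneous = is_homogeneous(profile, model)
        summary = {
            "marks": dict(zip(
                ["t_exponential", "t_transition", "t_early_stationary",
                 "t_late_stationary"], profile.marks.as_tuple())),
            "max_activity": profile.max_activity,
            "max_activity_normalized": profile.max_activity_normalized,
            "grey_zone": list(profile.grey_zone) if profile.grey_zone else None,
            "homogeneous": homogeneous,
            "expression_call": "homogeneous" if homogeneous else "heterogeneous",
            "calibration": {"slope": model.slope, "intercept": model.intercept,
                            "r_squared": model.r_squared,
                            "residual_sd": model.residual_sd,
                            "n_points": model.n_points},
            "modes_per_time_bin": hist.modes_per_time_bin(),
            "cv_at_marks": [s.cv for s in profile.at_marks()],
            "sd_corrected_at_marks": [s.sd_corrected for s in profile.at_marks()],
        }
        sum_path = out / "summary.json"
        sum_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
        written.append(sum_path)

        stage = "figures"
        logger.info("stage %s", stage)
        _plot_growth(profile, analysis, out)
        _plot_heterogeneity_bars(profile, out)
        _plot_histogram3d(hist, out)
        written += [out / "growth_fluorescence.png",
                    out / "heterogeneity_marks.png",
                    out / "expression_histogram3d.png"]
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "manifest"
    checksums = {p.name if p.parent == out else str(p.relative_to(out)): _sha256(p)
                 for p in written}
    manifest = RunManifest(
        config={"run": dataclasses.asdict(config)},
        version=__version__, seed=config.seed,
        checksums=checksums, warnings=warnings, summary=summary)
    (out / "manifest.json").write_text(manifest.to_json())
    logger.info("run complete: %d files", len(checksums))
    return manifest
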