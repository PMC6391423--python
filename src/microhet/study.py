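"""End-to-end orchestration: simulate → render → segment → quantify → correct.

These functions tie the modules together in memory; the file-writing pipeline
(:mod:`microhet.pipeline`) and the CLI are thin layers over them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .benchmark import MatchResult, match_labels
from .config import ColonyConfig, ExpressionParams, ImagingParams
from .heterogeneity import (CalibrationModel, GrowthPhaseMarks,
                            HeterogeneityProfile, build_profile,
                            fit_calibration, is_homogeneous)
from .presets import (calibration_imaging, calibration_presets,
                      default_imaging, get_preset)
from .quantify import (CellObservation, PopulationSnapshot,
                       estimate_background, measure_cells,
                       observations_to_frame, population_stats)
from .render import RenderedStacks, render_frames
from .segment import LabelMask, cumulative_feret, region_geometry, segment_frame
from .simulate import GroundTruthSeries, simulate_colony

__all__ = ["MovieAnalysis", "StudyResult", "analyze_stacks",
           "imaged_calibration", "run_preset_study"]

MIN_CELLS_PER_CALIBRATION_POINT = 10


@dataclass
class MovieAnalysis:
    """Per-frame masks, observations and population statistics of one movie."""

    times: List[float]
    masks: List[LabelMask]
    observations: List[List[CellObservation]]
    snapshots: List[PopulationSnapshot]
    feret_um: List[float]
    backgrounds: List[float]
    warnings: List[str] = field(default_factory=list)

    def cells_dataframe(self) -> pd.DataFrame:
        flat = [o for obs in self.observations for o in obs]
        return observations_to_frame(flat)

    def snapshots_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.time, s.n_cells, s.mean_fluor, s.sd_raw, s.sd_corrected,
              s.cv, ";".join(s.flags)) for s in self.snapshots],
            columns=["time_min", "n_cells", "mean_fluor", "sd_raw",
                     "sd_corrected", "cv", "flags"],
        )

    def feret_curve(self) -> Tuple[List[float], List[float]]:
        return self.times, self.feret_um


def analyze_stacks(stacks: RenderedStacks, cell_width_um: float = 1.0,
                   min_area_px: Optional[int] = None) -> MovieAnalysis:
    """Segment and quantify every frame of a rendered movie."""
    masks: List[LabelMask] = []
    observations: List[List[CellObservation]] = []
    snapshots: List[PopulationSnapshot] = []
    ferets: List[float] = []
    backgrounds: List[float] = []
    warnings: List[str] = list(stacks.warnings)
    for i, t in enumerate(stacks.times):
        mask = segment_frame(stacks.phase[i], frame_index=i,
                             pixel_size=stacks.pixel_size,
                             cell_width_um=cell_width_um,
                             min_area_px=min_area_px)
        geo = region_geometry(mask)
        bg = estimate_background(stacks.fluor[i], mask)
        if bg.fallback_used:
            warnings.append(f"frame {i}: confluent, background from 1st percentile")
        obs = measure_cells(stacks.fluor[i], mask, bg.value, t, geometry=geo)
        masks.append(mask)
        observations.append(obs)
        ferets.append(sum(g.feret_diameter for g in geo) * stacks.pixel_size)
        backgrounds.append(bg.value)
        if obs:
            snapshots.append(population_stats(obs))
    return MovieAnalysis(list(stacks.times), masks, observations, snapshots,
                         ferets, backgrounds, warnings)


def imaged_calibration(
    seed: int,
    imaging: Optional[ImagingParams] = None,
    min_cells: int = MIN_CELLS_PER_CALIBRATION_POINT,
    **colony_overrides,
) -> Tuple[CalibrationModel, pd.DataFrame]:
    """Calibrate the setup-noise trend from imaged homogeneous colonies.

    Four constitutive colonies at four synthesis levels are simulated,
    rendered and measured with the same pipeline as the samples; every frame
    with at least ``min_cells`` cells contributes one (mean, SD) point, and
    an OLS line through the pooled points is the calibration model —
    mirroring an inducer-titrated homogeneous control imaged on the same
    setup across the whole movie.
    """
    imaging = imaging or calibration_imaging()
    rows = []
    for level, (cfg, expr) in enumerate(calibration_presets(seed, **colony_overrides)):
        gt = simulate_colony(cfg, expr)
        stacks = render_frames(gt, imaging)
        analysis = analyze_stacks(stacks, cell_width_um=cfg.cell_width)
        for s in analysis.snapshots:
            if s.n_cells >= min_cells:
                rows.append((level, expr.synthesis_rate_on, s.time,
                             s.n_cells, s.mean_fluor, s.sd_raw))
    points = pd.DataFrame(rows, columns=["level", "synthesis_rate", "time_min",
                                         "n_cells", "mean_fluor", "sd_raw"])
    model = fit_calibration(list(zip(points["mean_fluor"], points["sd_raw"])))
    return model, points


@dataclass
class StudyResult:
    """Everything one preset run produces, in memory."""

    gt: GroundTruthSeries
    stacks: RenderedStacks
    analysis: MovieAnalysis
    calibration: CalibrationModel
    calibration_points: pd.DataFrame
    profile: HeterogeneityProfile
    homogeneous: bool

    def ground_truth_cv(self, t: float) -> float:
        return self.gt.concentration_cv(self.gt.frame_index_at(t))

    def segmentation_match(self, t: float, iou_threshold: float = 0.5) -> MatchResult:
        i = self.gt.frame_index_at(t)
        return match_labels(self.stacks.gt_labels[i], self.analysis.masks[i].labels,
                            iou_threshold)


def run_preset_study(
    preset: str,
    seed: int,
    imaging: Optional[ImagingParams] = None,
    calibration: Optional[Tuple[CalibrationModel, pd.DataFrame]] = None,
    user_marks: Optional[GrowthPhaseMarks] = None,
    reference_activity: Optional[float] = None,
    **colony_overrides,
) -> StudyResult:
    """Run one promoter regime end to end with an imaged calibration."""
    cfg, expr = get_preset(preset, seed, **colony_overrides)
    imaging = imaging or default_imaging()
    gt = simulate_colony(cfg, expr)
    stacks = render_frames(gt, imaging)
    analysis = analyze_stacks(stacks, cell_width_um=cfg.cell_width)
    if calibration is None:
        calibration = imaged_calibration(seed + 10_000)
    model, points = calibration
    profile = build_profile(analysis.snapshots, model, analysis.feret_curve(),
                            user_marks=user_marks,
                            reference_activity=reference_activity)
    return StudyResult(gt, stacks, analysis, model, points, profile,
                       is_homogeneous(profile, model))
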