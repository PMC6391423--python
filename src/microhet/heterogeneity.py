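"""Calibration-corrected expression heterogeneity statistics.

The central idea: the standard deviation of per-cell fluorescence in an
isogenic population mixes true cell-to-cell expression variability with
setup-inherent noise (detection noise, size-dependent measurement bias).
A homogeneous control promoter titrated to several mean levels shows that
the setup-inherent SD is linear in mean fluorescence, so an ordinary
least-squares trend SD = slope·mean + intercept fitted on the control is
subtracted from every sample SD.  What remains — the corrected SD, clamped
at zero — is the biological heterogeneity; divided by the mean it gives the
coefficient of variation (CV).

Heterogeneity is reported at four growth-phase marks (mid-exponential,
transition, early and late stationary) located automatically on the
cumulative-Feret growth curve, and the maximum promoter activity is the
highest population mean inside the stationary "grey zone", optionally
normalized to a reference strain.  A time × intensity histogram with a
local-maxima count per time bin supports bistability (bimodality) calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.stats import linregress

from .quantify import PopulationSnapshot

__all__ = [
    "CalibrationError",
    "CalibrationModel",
    "GrowthPhaseMarks",
    "HeterogeneityProfile",
    "ExpressionHistogram3D",
    "CorrectedSD",
    "fit_calibration",
    "correct_sd",
    "coefficient_of_variation",
    "mark_growth_phases",
    "max_promoter_activity",
    "normalize_activity",
    "expression_histogram3d",
    "build_profile",
    "is_homogeneous",
]


class CalibrationError(ValueError):
    pass


@dataclass
class CalibrationModel:
    """Linear setup-noise trend SD = slope·mean + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    residual_sd: float  # sqrt(SSR/(n−2)); 0 for an exact 2-point fit

    def predict(self, mean):
        return self.slope * np.asarray(mean, dtype=float) + self.intercept


@dataclass
class GrowthPhaseMarks:
    """The four heterogeneity sampling times along the growth curve."""

    t_exponential: float
    t_transition: float
    t_early_stationary: float
    t_late_stationary: float

    def as_tuple(self) -> Tuple[float, float, float, float]:
        return (self.t_exponential, self.t_transition,
                self.t_early_stationary, self.t_late_stationary)

    def validate(self, t_min: float, t_max: float) -> None:
        ts = self.as_tuple()
        if not all(a < b for a, b in zip(ts, ts[1:])):
            raise ValueError("growth-phase marks must be strictly increasing")
        if ts[0] < t_min or ts[-1] > t_max:
            raise ValueError("growth-phase marks outside recorded time range")


class CorrectedSD(NamedTuple):
    value: float
    clamped: bool  # True when sd_raw fell below the trend line


@dataclass
class HeterogeneityProfile:
    """Time-ordered snapshots with corrected SD and CV filled."""

    snapshots: List[PopulationSnapshot]
    marks: GrowthPhaseMarks
    max_activity: float
    max_activity_normalized: Optional[float] = None
    grey_zone: Optional[Tuple[float, float]] = None

    def snapshot_at(self, t: float) -> PopulationSnapshot:
        times = np.array([s.time for s in self.snapshots])
        return self.snapshots[int(np.argmin(np.abs(times - t)))]

    def at_marks(self) -> List[PopulationSnapshot]:
        return [self.snapshot_at(t) for t in self.marks.as_tuple()]


def fit_calibration(control_points: Sequence[Tuple[float, float]]) -> CalibrationModel:
    """OLS line through (mean, SD) points of the homogeneous control."""
    pts = np.asarray(control_points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise CalibrationError("need at least 2 (mean, sd) control points")
    means, sds = pts[:, 0], pts[:, 1]
    if np.ptp(means) == 0:
        raise CalibrationError("control means are all equal; cannot fit a trend")
    if pts.shape[0] == 2:
        slope = (sds[1] - sds[0]) / (means[1] - means[0])
        intercept = sds[0] - slope * means[0]
        return CalibrationModel(float(slope), float(intercept), 1.0, 2, 0.0)
    res = linregress(means, sds)
    pred = res.slope * means + res.intercept
    ssr = float(((sds - pred) ** 2).sum())
    resid_sd = float(np.sqrt(ssr / (pts.shape[0] - 2)))
    return CalibrationModel(float(res.slope), float(res.intercept),
                            float(res.rvalue ** 2), int(pts.shape[0]), resid_sd)


def correct_sd(sd_raw: float, mean: float, model: CalibrationModel) -> CorrectedSD:
    """Subtract the setup-noise trend; clamp negative results to 0 (flagged)."""
    raw = sd_raw - float(model.predict(mean))
    if raw < 0:
        return CorrectedSD(0.0, True)
    return CorrectedSD(float(raw), False)


def coefficient_of_variation(sd_corrected: float, mean: float) -> float:
    """CV = corrected SD / mean; defined only for positive means."""
    if mean <= 0:
        raise ValueError("CV undefined for non-positive mean fluorescence")
    return float(sd_corrected) / float(mean)


def mark_growth_phases(
    times: Sequence[float],
    cumulative_feret: Sequence[float],
    user_marks: Optional[GrowthPhaseMarks] = None,
    rate_drop: float = 0.5,
    early_frac: float = 0.25,
    late_frac: float = 0.9,
    smooth_frames: int = 3,
) -> GrowthPhaseMarks:
    """Locate the four sampling marks on a cumulative-Feret growth curve.

    Mid-exponential is the median time of the near-maximal specific growth
    rate plateau; transition is the first later time at which the rate falls
    below ``rate_drop`` × maximum; the stationary marks sit ``early_frac``
    and ``late_frac`` of the way through the post-transition interval.
    Explicit ``user_marks`` are validated and returned verbatim.
    """
    t = np.asarray(times, dtype=float)
    f = np.asarray(cumulative_feret, dtype=float)
    if t.size != f.size or t.size < 10:
        raise ValueError("need >= 10 (time, feret) samples spanning the growth curve")
    if user_marks is not None:
        user_marks.validate(float(t[0]), float(t[-1]))
        return user_marks
    # drop any leading frames where nothing was detected yet
    pos = np.flatnonzero(f > 0)
    if pos.size < 10:
        raise ValueError("need >= 10 frames with detectable colony")
    t = t[pos[0]:]
    f = f[pos[0]:]
    f = np.maximum(f, np.max(f) * 1e-6)  # guard isolated dropouts
    logf = np.log(f)
    if smooth_frames > 1:
        kernel = np.ones(smooth_frames) / smooth_frames
        pad = smooth_frames // 2
        logf = np.convolve(np.pad(logf, pad, mode="edge"), kernel, mode="valid")
        logf = logf[: t.size]
    rate = np.gradient(logf, t)
    max_rate = float(rate.max())
    total_fold = f[-1] / max(f[0], 1e-12)
    if max_rate <= 1e-6 or total_fold < 1.1:
        raise ValueError("no detectable growth; cannot place growth-phase marks")
    plateau = np.flatnonzero(rate >= 0.95 * max_rate)
    t_exp = float(np.median(t[plateau]))
    after = np.flatnonzero((t > t_exp) & (rate < rate_drop * max_rate))
    if after.size == 0:
        raise ValueError("growth never slowed; no transition found")
    t_trans = float(t[after[0]])
    span = float(t[-1]) - t_trans
    if span <= 0:
        raise ValueError("no post-transition interval recorded")
    marks = GrowthPhaseMarks(t_exp, t_trans,
                             t_trans + early_frac * span,
                             t_trans + late_frac * span)
    marks.validate(float(t[0]), float(t[-1]))
    return marks


def max_promoter_activity(snapshots: Sequence[PopulationSnapshot],
                          window: Tuple[float, float]) -> float:
    """Maximum population mean fluorescence within a time window."""
    t0, t1 = window
    vals = [s.mean_fluor for s in snapshots if t0 <= s.time <= t1]
    if not vals:
        raise ValueError(f"no snapshots in window [{t0}, {t1}]")
    return float(max(vals))


def normalize_activity(value: float, reference_value: float) -> float:
    """Promoter activity relative to a reference (e.g. parental) strain."""
    if reference_value <= 0:
        raise ValueError("reference activity must be positive")
    return float(value) / float(reference_value)


@dataclass
class ExpressionHistogram3D:
    """Cell counts binned by time and corrected intensity."""

    time_bin_edges: np.ndarray
    intensity_bin_edges: np.ndarray
    counts: np.ndarray  # (n_time_bins, n_intensity_bins)

    def modes_per_time_bin(self, smooth_sigma: float = 1.0,
                           min_prominence_frac: float = 0.05) -> List[int]:
        """Local-maxima count of each smoothed intensity histogram row."""
        out = []
        for row in self.counts:
            if row.sum() == 0:
                out.append(0)
                continue
            sm = gaussian_filter1d(row.astype(float), smooth_sigma)
            prom = max(min_prominence_frac * sm.max(), 1e-9)
            peaks, _ = find_peaks(sm, prominence=prom)
            # a mode at either edge of the range still counts
            interior_max = sm[peaks].max() if peaks.size else -np.inf
            for edge in (0, sm.size - 1):
                neighbor = sm[1] if edge == 0 else sm[-2]
                if sm[edge] > neighbor and sm[edge] >= prom:
                    peaks = np.append(peaks, edge)
            out.append(int(np.unique(peaks).size))
        return out

    def bimodal_time_bins(self, **kw) -> List[bool]:
        return [m >= 2 for m in self.modes_per_time_bin(**kw)]


def expression_histogram3d(times: Sequence[float], intensities: Sequence[float],
                           time_bins, intensity_bins) -> ExpressionHistogram3D:
    """Histogram cells over (time, corrected intensity) bins."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(intensities, dtype=float)
    if t.size == 0 or t.size != v.size:
        raise ValueError("need matching, non-empty time and intensity vectors")
    t_edges = np.asarray(time_bins, dtype=float)
    i_edges = np.asarray(intensity_bins, dtype=float)
    if t_edges.size < 2 or i_edges.size < 2:
        raise ValueError("bin specifications need at least 2 edges")
    if np.any(np.diff(t_edges) <= 0) or np.any(np.diff(i_edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    counts, _, _ = np.histogram2d(t, v, bins=[t_edges, i_edges])
    return ExpressionHistogram3D(t_edges, i_edges, counts)


def build_profile(
    snapshots: Sequence[PopulationSnapshot],
    model: CalibrationModel,
    feret_curve: Tuple[Sequence[float], Sequence[float]],
    user_marks: Optional[GrowthPhaseMarks] = None,
    grey_zone: Optional[Tuple[float, float]] = None,
    reference_activity: Optional[float] = None,
    exclude_single_cell: bool = True,
) -> HeterogeneityProfile:
    """Fill corrected SD / CV on snapshots and assemble the full profile.

    The grey zone defaults to [t_early_stationary, end of recording]; the
    maximum promoter activity is taken inside it.
    """
    snaps = sorted(snapshots, key=lambda s: s.time)
    if exclude_single_cell:
        snaps = [s for s in snaps if "single_cell" not in s.flags] or list(snaps)
    for s in snaps:
        corr = correct_sd(s.sd_raw, s.mean_fluor, model)
        s.sd_corrected = corr.value
        if corr.clamped and "sd_clamped" not in s.flags:
            s.flags.append("sd_clamped")
        s.cv = (coefficient_of_variation(corr.value, s.mean_fluor)
                if s.mean_fluor > 0 else None)
    marks = mark_growth_phases(*feret_curve, user_marks=user_marks)
    t_end = float(max(s.time for s in snaps))
    zone = grey_zone if grey_zone is not None else (marks.t_early_stationary, t_end)
    max_act = max_promoter_activity(snaps, zone)
    norm = (normalize_activity(max_act, reference_activity)
            if reference_activity is not None else None)
    return HeterogeneityProfile(snaps, marks, max_act, norm, zone)


def is_homogeneous(profile: HeterogeneityProfile, model: CalibrationModel,
                   n_residual_sds: float = 2.0) -> bool:
    """Homogeneous call: corrected SD below ``n``·(calibration residual SD)
    at all four growth-phase marks."""
    thr = n_residual_sds * model.residual_sd
    return all((s.sd_corrected or 0.0) < thr for s in profile.at_marks())
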