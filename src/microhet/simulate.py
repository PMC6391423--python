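"""Agent-based simulator of rod-shaped microcolonies with stochastic expression.

Cells are 2D spherocylinders growing on a virtual agarose pad.  The simulator
produces a :class:`GroundTruthSeries` — per-frame lists of cells with exact
geometry and expression state — which serves as the oracle for everything
downstream (segmentation fidelity, fluorescence measurement, heterogeneity
statistics).

Mechanics
---------
Elongation is exponential in length at rate ln(2)/doubling_time.  A cell
divides when it reaches ``division_length``, splitting into two daughters
along its axis with a small (±5% by default) length asymmetry.  Overlaps are
resolved by iterative pairwise repulsion: for every pair of spherocylinders
whose centerline segments come closer than the cell width, both cells are
displaced apart along the line of closest approach, and the sweep is repeated
to a fixed point (capped per substep).

Expression
----------
The telegraph promoter switches ON/OFF with exact exponential waiting times
within each time step; GFP concentration integrates
d(conc)/dt = synthesis(state, phase) − dilution · conc analytically over each
constant-state segment.  Dilution equals the elongation rate and stops when
the colony enters stationary phase, so concentrations accumulate linearly in
non-growing cells — the behaviour that makes a stationary-phase-active
promoter light up late in the movie.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import ColonyConfig, ConfigurationError, ExpressionParams

__all__ = [
    "SimCell",
    "GroundTruthSeries",
    "CalibrationLevel",
    "simulate_colony",
    "generate_calibration_series",
    "calibration_points",
]


@dataclass
class SimCell:
    """One simulated cell at one frame (ground truth)."""

    cell_id: int
    parent_id: int
    x: float                  # µm, colony-centred coordinates
    y: float                  # µm
    orientation: float        # rad
    length: float             # µm, total spherocylinder length
    width: float              # µm
    promoter_state: bool      # True = ON
    gfp_concentration: float  # AU/fl
    extrinsic_factor: float = 1.0


@dataclass
class GroundTruthSeries:
    """Ordered frames of simulated cells plus run metadata."""

    times: List[float]
    frames: List[List[SimCell]]
    config: ColonyConfig
    expression: ExpressionParams
    warnings: List[str] = field(default_factory=list)
    stationary_time: Optional[float] = None

    def __len__(self) -> int:
        return len(self.frames)

    def cell_counts(self) -> np.ndarray:
        return np.array([len(f) for f in self.frames])

    def total_length(self, i: int) -> float:
        return float(sum(c.length for c in self.frames[i]))

    def concentrations(self, i: int) -> np.ndarray:
        return np.array([c.gfp_concentration for c in self.frames[i]])

    def concentration_cv(self, i: int) -> float:
        """Between-cell CV of true GFP concentration at frame ``i``."""
        conc = self.concentrations(i)
        m = conc.mean()
        if m <= 0:
            return float("nan")
        return float(conc.std(ddof=1) / m) if conc.size > 1 else 0.0

    def frame_index_at(self, t: float) -> int:
        return int(np.argmin(np.abs(np.asarray(self.times) - t)))

    def to_dataframe(self) -> pd.DataFrame:
        px = self.config.pixel_size
        rows = []
        for i, (t, cells) in enumerate(zip(self.times, self.frames)):
            for c in cells:
                rows.append(
                    (i, t, c.cell_id, c.parent_id, c.x / px, c.y / px,
                     c.orientation, c.length / px,
                     "ON" if c.promoter_state else "OFF", c.gfp_concentration)
                )
        return pd.DataFrame(
            rows,
            columns=["frame", "time_min", "cell_id", "parent_id", "x_px",
                     "y_px", "orientation_rad", "length_px", "state",
                     "concentration"],
        )


# ---------------------------------------------------------------------------
# mechanics helpers


def _segment_endpoints(x, y, theta, length, width):
    """Centerline segment endpoints of spherocylinders (shaft only)."""
    half = np.maximum(length - width, 0.0) / 2.0
    ux, uy = np.cos(theta), np.sin(theta)
    return (x - half * ux, y - half * uy, x + half * ux, y + half * uy)


def _pair_segment_distance(p1, q1, p2, q2):
    """Vectorized closest-approach between segment pairs.

    Arguments are (N,2) arrays of endpoints.  Returns (dist, c1, c2) where
    c1/c2 are the closest points on each segment.  Classic clamped
    quadratic-minimisation formulation.
    """
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    f = np.einsum("ij,ij->i", d2, r)
    c = np.einsum("ij,ij->i", d1, r)
    b = np.einsum("ij,ij->i", d1, d2)
    denom = a * e - b * b
    s = np.where(denom > 1e-12, (b * f - c * e) / np.where(denom > 1e-12, denom, 1.0), 0.0)
    s = np.clip(s, 0.0, 1.0)
    # degenerate segments (points) fall out naturally via the clamps
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(e > 1e-12, (b * s + f) / np.where(e > 1e-12, e, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    s = np.where(a > 1e-12, np.clip((b * t - c) / np.where(a > 1e-12, a, 1.0), 0.0, 1.0), 0.0)
    c1 = p1 + s[:, None] * d1
    c2 = p2 + t[:, None] * d2
    diff = c1 - c2
    dist = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    return dist, c1, c2


class _Colony:
    """Mutable array-of-structs colony state."""

    def __init__(self):
        self.x = np.empty(0)
        self.y = np.empty(0)
        self.theta = np.empty(0)
        self.length = np.empty(0)
        self.cell_id = np.empty(0, dtype=np.int64)
        self.parent_id = np.empty(0, dtype=np.int64)
        self.state = np.empty(0, dtype=bool)
        self.conc = np.empty(0)
        self.extrinsic = np.empty(0)

    @property
    def n(self) -> int:
        return self.x.size

    def snapshot(self, width: float) -> List[SimCell]:
        return [
            SimCell(int(self.cell_id[i]), int(self.parent_id[i]),
                    float(self.x[i]), float(self.y[i]), float(self.theta[i]),
                    float(self.length[i]), width, bool(self.state[i]),
                    float(self.conc[i]), float(self.extrinsic[i]))
            for i in range(self.n)
        ]


def _relax(col: _Colony, width: float, max_iter: int, rng: np.random.Generator) -> None:
    """Fixed-point pairwise repulsion until residual overlap is small."""
    tol = 0.03 * width
    for _ in range(max_iter):
        if col.n < 2:
            return
        pts = np.column_stack([col.x, col.y])
        reach = float(col.length.max())  # contact impossible beyond this
        pairs = cKDTree(pts).query_pairs(r=reach + width, output_type="ndarray")
        if pairs.size == 0:
            return
        i, j = pairs[:, 0], pairs[:, 1]
        ax, ay, bx, by = _segment_endpoints(col.x, col.y, col.theta, col.length, width)
        p = np.column_stack([ax, ay])
        q = np.column_stack([bx, by])
        dist, c1, c2 = _pair_segment_distance(p[i], q[i], p[j], q[j])
        overlap = width - dist
        active = overlap > tol
        if not np.any(active):
            return
        i, j = i[active], j[active]
        ov = overlap[active]
        delta = c1[active] - c2[active]
        d = dist[active]
        zero = d < 1e-9
        if np.any(zero):  # coincident centerlines: push in a random direction
            ang = rng.uniform(0, 2 * np.pi, int(zero.sum()))
            delta[zero] = np.column_stack([np.cos(ang), np.sin(ang)])
            d = np.where(zero, 1.0, d)
        n_hat = delta / d[:, None]
        push = 0.55 * ov[:, None] * n_hat  # slight over-relaxation
        dx = np.zeros(col.n)
        dy = np.zeros(col.n)
        np.add.at(dx, i, push[:, 0])
        np.add.at(dy, i, push[:, 1])
        np.add.at(dx, j, -push[:, 0])
        np.add.at(dy, j, -push[:, 1])
        col.x += dx
        col.y += dy


def _divide(col: _Colony, cfg: ColonyConfig, expr: ExpressionParams,
            rng: np.random.Generator, next_id: int) -> int:
    """Split every cell at/above division length; returns next free id."""
    due = np.flatnonzero(col.length >= cfg.division_length * (1 - 1e-9))
    if due.size == 0:
        return next_id
    keep = np.setdiff1d(np.arange(col.n), due)
    new = {k: [] for k in ("x", "y", "theta", "length", "cell_id",
                           "parent_id", "state", "conc", "extrinsic")}
    for idx in due:
        L = col.length[idx]
        if cfg.deterministic_growth or cfg.division_asymmetry == 0:
            asym = 0.0
        else:
            asym = rng.uniform(-cfg.division_asymmetry, cfg.division_asymmetry)
        ux, uy = math.cos(col.theta[idx]), math.sin(col.theta[idx])
        for sign, frac in ((-1, 0.5 * (1 + asym)), (+1, 0.5 * (1 - asym))):
            jitter = 0.0 if cfg.deterministic_growth else rng.normal(0.0, cfg.orientation_jitter)
            new["x"].append(col.x[idx] + sign * L / 4 * ux)
            new["y"].append(col.y[idx] + sign * L / 4 * uy)
            new["theta"].append(col.theta[idx] + jitter)
            new["length"].append(L * frac)
            new["cell_id"].append(next_id)
            new["parent_id"].append(col.cell_id[idx])
            new["state"].append(col.state[idx])
            new["conc"].append(col.conc[idx])  # concentration is intensive
            new["extrinsic"].append(_draw_extrinsic(expr, rng))
            next_id += 1
    col.x = np.concatenate([col.x[keep], new["x"]])
    col.y = np.concatenate([col.y[keep], new["y"]])
    col.theta = np.concatenate([col.theta[keep], new["theta"]])
    col.length = np.concatenate([col.length[keep], new["length"]])
    col.cell_id = np.concatenate([col.cell_id[keep], np.array(new["cell_id"], dtype=np.int64)])
    col.parent_id = np.concatenate([col.parent_id[keep], np.array(new["parent_id"], dtype=np.int64)])
    col.state = np.concatenate([col.state[keep], np.array(new["state"], dtype=bool)])
    col.conc = np.concatenate([col.conc[keep], new["conc"]])
    col.extrinsic = np.concatenate([col.extrinsic[keep], new["extrinsic"]])
    return next_id


def _draw_extrinsic(expr: ExpressionParams, rng: np.random.Generator) -> float:
    cv = expr.extrinsic_noise_cv
    if cv <= 0:
        return 1.0
    sigma2 = math.log(1.0 + cv * cv)
    return float(rng.lognormal(-sigma2 / 2.0, math.sqrt(sigma2)))


# ---------------------------------------------------------------------------
# expression integration


def _integrate_conc(conc: float, rate: float, lam: float, dt: float) -> float:
    """Advance d(conc)/dt = rate − lam·conc over dt (analytic)."""
    if lam > 0:
        decay = math.exp(-lam * dt)
        return conc * decay + rate / lam * (1.0 - decay)
    return conc + rate * dt


def _update_expression(col: _Colony, expr: ExpressionParams, dt: float,
                       lam: float, phase_mult: float,
                       rng: np.random.Generator) -> None:
    s_on = expr.synthesis_rate_on * phase_mult
    if expr.model == "constitutive":
        rates = expr.basal_rate + s_on * col.extrinsic
        if lam > 0:
            decay = math.exp(-lam * dt)
            col.conc = col.conc * decay + rates / lam * (1.0 - decay)
        else:
            col.conc = col.conc + rates * dt
        col.state[:] = True
        return
    # telegraph: exact exponential waiting times per cell within dt
    for idx in range(col.n):
        t_rem = dt
        state = bool(col.state[idx])
        conc = float(col.conc[idx])
        m = float(col.extrinsic[idx])
        while True:
            rate_sw = expr.k_off if state else expr.k_on
            tau = rng.exponential(1.0 / rate_sw) if rate_sw > 0 else math.inf
            synth = expr.basal_rate + (s_on * m if state else 0.0)
            if tau >= t_rem:
                conc = _integrate_conc(conc, synth, lam, t_rem)
                break
            conc = _integrate_conc(conc, synth, lam, tau)
            t_rem -= tau
            state = not state
        col.state[idx] = state
        col.conc[idx] = conc


# ---------------------------------------------------------------------------
# main entry points


def simulate_colony(config: ColonyConfig, expr: ExpressionParams) -> GroundTruthSeries:
    """Simulate a growing microcolony and return its ground-truth series.

    Frames are recorded every ``config.frame_interval`` minutes from t = 0 to
    ``config.total_duration``.  If ``config.arena_size`` is set and the colony
    outgrows it, the simulation stops early with a warning flag on the series.
    """
    config.validate()
    expr.validate()
    rng = np.random.default_rng(config.rng_seed)
    lam_growth = math.log(2.0) / config.doubling_time

    col = _Colony()
    n0 = config.n_initial_cells
    if n0 == 1:
        col.x = np.zeros(1)
        col.y = np.zeros(1)
    else:
        radius = math.sqrt(n0) * config.division_length / 2.0
        ang = rng.uniform(0, 2 * np.pi, n0)
        rad = radius * np.sqrt(rng.uniform(0, 1, n0))
        col.x = rad * np.cos(ang)
        col.y = rad * np.sin(ang)
    if config.deterministic_growth:
        col.theta = np.zeros(n0)
        col.length = np.full(n0, config.birth_length)
    else:
        col.theta = rng.uniform(0, np.pi, n0)
        # balanced age distribution: length = birth · 2^U, capped below division
        col.length = np.minimum(
            config.birth_length * 2.0 ** rng.uniform(0, 1, n0),
            config.division_length * 0.999,
        )
    col.cell_id = np.arange(n0, dtype=np.int64)
    col.parent_id = np.full(n0, -1, dtype=np.int64)
    if expr.model == "telegraph":
        ksum = expr.k_on + expr.k_off
        p_on = expr.k_on / ksum if ksum > 0 else 0.0
        col.state = rng.uniform(0, 1, n0) < p_on
    else:
        col.state = np.ones(n0, dtype=bool)
    col.extrinsic = np.array([_draw_extrinsic(expr, rng) for _ in range(n0)])
    # start near the exponential-phase quasi-steady state to limit transients
    mult0 = expr.synthesis_rate_exponential_factor
    base0 = expr.basal_rate + expr.synthesis_rate_on * mult0 * col.extrinsic * col.state
    col.conc = base0 / lam_growth
    next_id = n0
    _relax(col, config.cell_width, config.relax_iterations, rng)

    times: List[float] = []
    frames: List[List[SimCell]] = []
    warnings: List[str] = []
    stationary_time: Optional[float] = None

    n_frames = int(math.floor(config.total_duration / config.frame_interval + 1e-9)) + 1
    t = 0.0
    stopped = False
    for fi in range(n_frames):
        if fi > 0:
            n_sub = max(1, int(math.ceil(config.frame_interval / config.mechanics_substep)))
            dt_sub = config.frame_interval / n_sub
            for k in range(n_sub):
                t_sub = (fi - 1) * config.frame_interval + k * dt_sub
                if stationary_time is None and config.stationary_onset is not None \
                        and t_sub >= config.stationary_onset:
                    stationary_time = config.stationary_onset
                in_stationary = stationary_time is not None
                lam = 0.0 if in_stationary else lam_growth
                if not in_stationary:
                    col.length = col.length * math.exp(lam_growth * dt_sub)
                    next_id = _divide(col, config, expr, rng, next_id)
                _relax(col, config.cell_width, config.relax_iterations, rng)
                phase_mult = 1.0 if in_stationary else expr.synthesis_rate_exponential_factor
                _update_expression(col, expr, dt_sub, lam, phase_mult, rng)
                if stationary_time is None and config.stationary_cell_cap is not None \
                        and col.n >= config.stationary_cell_cap:
                    stationary_time = t_sub + dt_sub
            t = fi * config.frame_interval
        # recenter so the colony stays in frame
        if col.n:
            col.x -= col.x.mean()
            col.y -= col.y.mean()
        if config.arena_size is not None and col.n:
            extent = 2 * (np.hypot(col.x, col.y).max() + col.length.max() / 2)
            if extent > config.arena_size:
                warnings.append(
                    f"colony exceeded arena ({extent:.1f} µm > "
                    f"{config.arena_size:.1f} µm) at t={t:.0f} min; stopping"
                )
                stopped = True
        times.append(t)
        frames.append(col.snapshot(config.cell_width))
        if stopped:
            break

    return GroundTruthSeries(times, frames, config, expr,
                             warnings=warnings, stationary_time=stationary_time)


@dataclass
class CalibrationLevel:
    """Per-cell fluorescence values at one induction level."""

    target_mean: float
    values: np.ndarray

    def sample_mean(self) -> float:
        return float(np.mean(self.values))

    def sample_sd(self) -> float:
        return float(np.std(self.values, ddof=1))


def generate_calibration_series(
    mean_levels: Sequence[float],
    setup_slope: float,
    setup_intercept: float,
    n_cells_per_level: int,
    rng_seed: int = 0,
) -> List[CalibrationLevel]:
    """Homogeneous control series: four inducer levels with linear setup noise.

    Emulates an IPTG-titrated homogeneous promoter imaged on the same setup:
    per-cell values at each level are normal with SD = slope·mean + intercept,
    the setup-inherent noise the trend-line correction is meant to capture.
    Output is ordered by ascending mean.
    """
    means = [float(m) for m in mean_levels]
    if len(means) != 4 or len(set(means)) != 4 or any(m <= 0 for m in means):
        raise ConfigurationError("need 4 distinct positive mean levels")
    if n_cells_per_level < 30:
        raise ConfigurationError("need at least 30 cells per level")
    rng = np.random.default_rng(rng_seed)
    out = []
    for m in sorted(means):
        sd = setup_slope * m + setup_intercept
        if sd < 0:
            raise ConfigurationError(f"implied SD negative at mean {m}")
        out.append(CalibrationLevel(m, rng.normal(m, sd, n_cells_per_level)))
    return out


def calibration_points(levels: Sequence[CalibrationLevel]) -> List[Tuple[float, float]]:
    """(sample mean, sample SD) pairs for calibration fitting."""
    return [(lv.sample_mean(), lv.sample_sd()) for lv in levels]
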