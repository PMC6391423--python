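"""Configuration types for the synthetic microcolony generator.

Three parameter groups drive a simulated time-lapse experiment:

* :class:`ColonyConfig` — geometry and growth of a rod-shaped microcolony on a
  2D agarose surface (lengths in µm, times in minutes).
* :class:`ExpressionParams` — the promoter model producing per-cell GFP
  concentration (arbitrary units per femtolitre, "AU" throughout).
* :class:`ImagingParams` — the virtual microscope used to render paired
  phase-contrast / fluorescence frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class ColonyConfig:
    """Growth and geometry parameters of a simulated microcolony.

    Cells are spherocylinders (total length ``length`` including the two
    hemispherical caps of diameter ``cell_width``) that elongate exponentially
    at rate ln(2)/``doubling_time`` and divide symmetrically when they reach
    ``division_length``.  Growth stops globally at ``stationary_onset``
    minutes, or when the colony reaches ``stationary_cell_cap`` cells
    (nutrient capacity), whichever is configured and occurs first.
    """

    n_initial_cells: int = 1
    doubling_time: float = 30.0        # min
    division_length: float = 5.0       # µm
    birth_length: float = 2.5          # µm
    cell_width: float = 1.0            # µm
    frame_interval: float = 6.0        # min; recordings every 5–7 min
    total_duration: float = 1020.0     # min (~17 h experiment)
    stationary_onset: Optional[float] = None    # min, or None
    stationary_cell_cap: Optional[int] = None   # cells, or None
    pixel_size: float = 0.1            # µm / px
    arena_size: Optional[float] = None  # µm; simulation stops if exceeded
    division_asymmetry: float = 0.05   # ±fractional daughter-length noise
    orientation_jitter: float = 0.05   # rad, at division
    mechanics_substep: float = 2.0     # min, growth/relaxation substep
    relax_iterations: int = 200        # cap on repulsion sweeps per substep
    deterministic_growth: bool = False  # disable all geometric noise
    rng_seed: int = 0

    def validate(self) -> None:
        if self.doubling_time <= 0:
            raise ConfigurationError("doubling_time must be > 0")
        if not (0 < self.birth_length < self.division_length):
            raise ConfigurationError("need 0 < birth_length < division_length")
        if self.frame_interval <= 0:
            raise ConfigurationError("frame_interval must be > 0")
        if self.total_duration < self.frame_interval:
            raise ConfigurationError("total_duration must be >= frame_interval")
        if self.cell_width <= 0 or self.pixel_size <= 0:
            raise ConfigurationError("cell_width and pixel_size must be > 0")
        if self.n_initial_cells < 1:
            raise ConfigurationError("need at least one initial cell")


@dataclass
class ExpressionParams:
    """Promoter model parameters.

    ``model='constitutive'`` keeps every cell's promoter permanently ON;
    ``model='telegraph'`` switches each cell between ON and OFF as a
    continuous-time two-state process with rates ``k_on`` (OFF→ON) and
    ``k_off`` (ON→OFF), using exact exponential waiting times.

    GFP concentration follows d(conc)/dt = synthesis − dilution, where
    synthesis = ``basal_rate`` + state × ``synthesis_rate_on`` × m × phase
    multiplier, dilution is the elongation rate (zero once growth stops), the
    phase multiplier is ``synthesis_rate_exponential_factor`` before
    stationary onset and 1 afterwards, and m is a per-cell lognormal extrinsic
    factor with unit mean and coefficient of variation ``extrinsic_noise_cv``
    drawn at birth.
    """

    model: str = "constitutive"        # 'constitutive' | 'telegraph'
    k_on: float = 0.0                  # 1/min
    k_off: float = 0.0                 # 1/min
    synthesis_rate_on: float = 1.0     # AU/fl/min
    synthesis_rate_exponential_factor: float = 1.0
    basal_rate: float = 0.0            # AU/fl/min
    extrinsic_noise_cv: float = 0.0

    def validate(self) -> None:
        if self.model not in ("constitutive", "telegraph"):
            raise ConfigurationError(f"unknown expression model {self.model!r}")
        for name in ("k_on", "k_off", "synthesis_rate_on", "basal_rate",
                     "synthesis_rate_exponential_factor", "extrinsic_noise_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class ImagingParams:
    """Virtual microscope: rendering of phase and fluorescence frames."""

    background_level: float = 200.0    # AU, camera offset + medium
    read_noise_sd: float = 5.0         # AU, Gaussian per pixel
    psf_sigma: float = 1.0             # px, Gaussian point-spread function
    bit_depth: int = 16                # 8 or 16
    phase_contrast_cell_intensity: float = 120.0  # AU, darker than background
    phase_width_fraction: float = 0.75  # dark footprint width / true width
    image_shape: Tuple[int, int] = (512, 512)     # (rows, cols) px

    def validate(self) -> None:
        if self.background_level < 0:
            raise ConfigurationError("background_level must be >= 0")
        if self.psf_sigma < 0:
            raise ConfigurationError("psf_sigma must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ConfigurationError("bit_depth must be 8 or 16")
        if self.phase_contrast_cell_intensity >= self.background_level:
            raise ConfigurationError("cells must render darker than background")
        if not (0 < self.phase_width_fraction <= 1):
            raise ConfigurationError("phase_width_fraction must be in (0, 1]")

    @property
    def max_dn(self) -> int:
        return (1 << self.bit_depth) - 1


def config_to_dict(*configs) -> dict:
    """Merge dataclass configs into one plain dict (for manifests/YAML)."""
    out: dict = {}
    for c in configs:
        out[type(c).__name__] = asdict(c)
    return out
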