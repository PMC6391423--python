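"""Plate-reader optical path-length correction and OD normalization.

Microtiter wells have a fill-dependent optical path, so raw OD600 readings
are not comparable to cuvette measurements.  The near-infrared water
absorbance difference OD977 − OD900 is proportional to the light path, so

    d = (OD977 − OD900)_sample / (OD977 − OD900)_reference × 1 cm

with the reference measured in a 1 cm cuvette, and OD600 is divided by d to
give an absorbance per cm.  Reference values are caller-supplied; nothing is
hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["PathLengthResult", "path_length", "normalize_od", "normalize_od_table"]


@dataclass
class PathLengthResult:
    d: float                  # cm
    od600_raw: float
    od600_normalized: float   # absorbance / cm
    flagged: bool = False     # non-positive path length (evaporation/artifact)


def path_length(od977_sample: float, od900_sample: float,
                od977_ref: float, od900_ref: float) -> float:
    """Optical path in cm from water absorbance differences."""
    ref_diff = od977_ref - od900_ref
    if ref_diff == 0:
        raise ValueError("reference OD977 - OD900 difference is zero")
    return (od977_sample - od900_sample) / ref_diff * 1.0


def normalize_od(od600: float, d: float) -> float:
    """OD600 divided by the optical path length (cm)."""
    if d <= 0:
        raise ValueError("path length must be positive to normalize OD")
    return od600 / d


def normalize_od_table(table: pd.DataFrame, od977_ref: float,
                       od900_ref: float) -> pd.DataFrame:
    """Apply the path-length correction to a plate table.

    Expects columns well, od600, od900, od977; adds path_cm,
    od600_per_cm and a flag column for non-positive path lengths.
    """
    req = {"well", "od600", "od900", "od977"}
    missing = req - set(table.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    out = table.copy()
    d = [path_length(o977, o900, od977_ref, od900_ref)
         for o977, o900 in zip(out["od977"], out["od900"])]
    out["path_cm"] = d
    out["path_flagged"] = [x <= 0 for x in d]
    out["od600_per_cm"] = [
        normalize_od(od, x) if x > 0 else float("nan")
        for od, x in zip(out["od600"], d)
    ]
    return out
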