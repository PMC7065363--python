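"""Buoyant-density handling for CsCl gradient fractions.

After isopycnic centrifugation a gradient is dripped into ~12 fractions; the
CsCl density of each is estimated from a refractometer reading via a linear
calibration, and fractions are pooled into "heavy" (13C-shifted DNA) and
"light" (unlabelled DNA) classes by density windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "DensityCalibration",
    "FractionThresholds",
    "GradientFraction",
    "ri_to_density",
    "designate_fractions",
    "DEFAULT_CALIBRATION",
    "DEFAULT_THRESHOLDS",
]


class CalibrationError(ValueError):
    """Raised for an unusable refractive-index/density calibration."""


@dataclass(frozen=True)
class DensityCalibration:
    """Linear map from refractive index (nD) to CsCl density (g/ml).

    density = slope * nD + intercept.  The default constants are the standard
    linearization of the CsCl density/refractive-index relation used by SIP
    protocols; they are configuration, not physics baked into the code.
    """

    slope: float = 10.9276
    intercept: float = -13.593

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise CalibrationError("calibration slope must be non-zero")


@dataclass(frozen=True)
class FractionThresholds:
    """Density windows (g/ml, inclusive at both ends) for heavy/light pooling."""

    heavy_min: float = 1.725
    heavy_max: float = 1.735
    light_min: float = 1.705
    light_max: float = 1.720

    def __post_init__(self) -> None:
        if self.heavy_min > self.heavy_max or self.light_min > self.light_max:
            raise ValueError("each density window must be non-empty")
        if self.light_max > self.heavy_min:
            raise ValueError(
                "light window must lie entirely below the heavy window "
                f"(light_max={self.light_max} > heavy_min={self.heavy_min})"
            )


DEFAULT_CALIBRATION = DensityCalibration()
DEFAULT_THRESHOLDS = FractionThresholds()


@dataclass
class GradientFraction:
    """One collected fraction of a CsCl gradient."""

    fraction_index: int
    refractive_index: float | None = None
    density: float | None = None
    dna_recovered: float | None = None


def ri_to_density(
    refractive_index: float,
    calibration: DensityCalibration = DEFAULT_CALIBRATION,
    *,
    sanity_window: tuple[float, float] = (1.3, 1.5),
) -> float:
    """Convert a refractometer reading to CsCl buoyant density (g/ml).

    Readings outside `sanity_window` are almost certainly instrument or
    transcription errors; they trigger a warning but are still converted.
    """
    lo, hi = sanity_window
    if not (lo <= refractive_index <= hi):
        warnings.warn(
            f"refractive index {refractive_index} outside sanity window "
            f"[{lo}, {hi}]",
            stacklevel=2,
        )
    return calibration.slope * refractive_index + calibration.intercept


def designate_fractions(
    fractions: Iterable[GradientFraction],
    thresholds: FractionThresholds = DEFAULT_THRESHOLDS,
) -> Mapping[int, str]:
    """Assign each fraction to exactly one of {'heavy', 'light', 'discard'}.

    Windows are inclusive at both ends; anything between or outside the two
    windows is discarded.  Densities must already be computed.
    """
    out: dict[int, str] = {}
    for frac in fractions:
        if frac.density is None:
            raise ValueError(
                f"fraction {frac.fraction_index} has no density; run "
                "ri_to_density first"
            )
        if frac.fraction_index in out:
            raise ValueError(f"duplicate fraction_index {frac.fraction_index}")
        d = frac.density
        if thresholds.heavy_min <= d <= thresholds.heavy_max:
            out[frac.fraction_index] = "heavy"
        elif thresholds.light_min <= d <= thresholds.light_max:
            out[frac.fraction_index] = "light"
        else:
            out[frac.fraction_index] = "discard"
    return out
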