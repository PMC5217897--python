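"""Total cyanide from picrate-paper readings.

The picrate kit quantifies cyanogens two ways: photometrically, where
total cyanide in ppm equals the 510 nm absorbance of the eluate times
396 under the kit's nominal geometry (100 mg sample, 5.0 mL elution),
and semi-quantitatively by matching the strip to a 10-shade colour
chart spanning 0-800 ppm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

#: ppm of total cyanide per unit absorbance at 510 nm (kit geometry).
PICRATE_FACTOR_PPM = 396.0
NOMINAL_SAMPLE_MASS_MG = 100.0
NOMINAL_ELUTION_VOLUME_ML = 5.0

#: Relative deviation from the nominal geometry tolerated silently.
_GEOMETRY_RTOL = 1e-6


@dataclass(frozen=True)
class AbsorbanceReading:
    """One 510 nm eluate absorbance with its assay geometry."""

    absorbance_510nm: float
    sample_mass_mg: float = NOMINAL_SAMPLE_MASS_MG
    elution_volume_ml: float = NOMINAL_ELUTION_VOLUME_ML

    def __post_init__(self) -> None:
        if self.absorbance_510nm < 0:
            raise ValueError("negative absorbance: instrument error")
        if self.sample_mass_mg <= 0 or self.elution_volume_ml <= 0:
            raise ValueError("sample mass and elution volume must be > 0")


@dataclass(frozen=True)
class ColorChart:
    """The kit's shade-to-ppm anchor values, ascending from 0 to 800."""

    shade_levels_ppm: tuple[float, ...]

    def __post_init__(self) -> None:
        levels = tuple(float(v) for v in self.shade_levels_ppm)
        object.__setattr__(self, "shade_levels_ppm", levels)
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise ValueError("shade levels must be strictly increasing")
        if levels[0] != 0.0 or levels[-1] != 800.0:
            raise ValueError("shade levels must span 0 to 800 ppm")


#: The kit does not publish per-shade ppm values; by default the ten
#: shades are taken as evenly spaced anchors over 0-800 ppm.
DEFAULT_CHART = ColorChart(tuple(np.linspace(0.0, 800.0, 10)))


def cyanide_ppm(r: AbsorbanceReading, *,
                rescale_off_nominal: bool = False) -> float:
    """Total cyanide in ppm from a 510 nm absorbance reading.

    The 396 factor presumes the kit's 100 mg / 5.0 mL geometry.
    Off-nominal geometry triggers a warning; with
    ``rescale_off_nominal=True`` the factor is rescaled proportionally
    (x 100/mass_mg x volume_ml/5.0), the only dimensionally consistent
    extension.
    """
    factor = PICRATE_FACTOR_PPM
    mass_off = abs(r.sample_mass_mg - NOMINAL_SAMPLE_MASS_MG) \
        > _GEOMETRY_RTOL * NOMINAL_SAMPLE_MASS_MG
    vol_off = abs(r.elution_volume_ml - NOMINAL_ELUTION_VOLUME_ML) \
        > _GEOMETRY_RTOL * NOMINAL_ELUTION_VOLUME_ML
    if mass_off or vol_off:
        warnings.warn(
            f"off-nominal picrate geometry ({r.sample_mass_mg} mg, "
            f"{r.elution_volume_ml} mL); factor "
            f"{'rescaled' if rescale_off_nominal else 'NOT rescaled'}",
            stacklevel=2,
        )
        if rescale_off_nominal:
            factor *= (NOMINAL_SAMPLE_MASS_MG / r.sample_mass_mg) \
                * (r.elution_volume_ml / NOMINAL_ELUTION_VOLUME_ML)
    return r.absorbance_510nm * factor


def chart_class(ppm: float, chart: ColorChart = DEFAULT_CHART) -> float:
    """Nearest colour-chart shade level (ppm); ties break downward."""
    if ppm < 0:
        raise ValueError("cyanide concentration cannot be negative")
    levels = np.asarray(chart.shade_levels_ppm)
    # argmin returns the first minimiser; levels ascend, so exact
    # midpoints resolve to the lower shade.
    return float(levels[int(np.argmin(np.abs(levels - ppm)))])
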