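"""Bulk density, swelling index and thermogravimetric moisture content.

All three are simple ratios of two raw readings:

* bulk density  BD = m / V          (tapped-cylinder volume, g/cm3)
* swelling index SI = V_swollen / V_initial   (after a 4 h soak)
* moisture content h = (fwt - dwt) / fwt      (drying loss, 105 C oven)

The moisture formula is the drying loss.  The literal dry/fresh ratio
``dwt/fwt`` is available behind ``as_printed=True`` for traceability
only: for oven-dried gari it returns ~0.91-0.96 rather than the
expected few-percent moisture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .errors import DegenerateInputError, InconsistentReadingError

#: Relative 24 h vs 48 h mass change above which a moisture reading is
#: flagged as not dried to constant weight.
DRYING_STABILITY_TOL = 0.001


@dataclass(frozen=True)
class BulkDensityReading:
    """Sample mass (g) and tapped volume (cm3) from one cylinder run."""

    sample_mass_g: float
    tapped_volume_cm3: float

    def __post_init__(self) -> None:
        if self.sample_mass_g <= 0:
            raise ValueError("sample mass must be > 0")
        if self.tapped_volume_cm3 <= 0:
            raise DegenerateInputError("tapped volume must be > 0")


@dataclass(frozen=True)
class SwellingReading:
    """Initial and swollen volumes (mL) from one soak."""

    initial_volume_ml: float
    swollen_volume_ml: float

    def __post_init__(self) -> None:
        if self.initial_volume_ml <= 0:
            raise DegenerateInputError("initial volume must be > 0")
        if self.swollen_volume_ml <= 0:
            raise ValueError("swollen volume must be > 0")


@dataclass(frozen=True)
class MoistureReading:
    """Fresh and oven-dry weights (g); optional 24 h check weight."""

    fresh_weight_g: float
    dry_weight_g: float
    mass_24h_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.dry_weight_g <= 0:
            raise ValueError("dry weight must be > 0")
        if self.dry_weight_g > self.fresh_weight_g:
            raise InconsistentReadingError(
                "dry weight exceeds fresh weight (sample gained mass)"
            )


def bulk_density(r: BulkDensityReading) -> float:
    """Bulk density in g/cm3: mass over tapped volume."""
    return r.sample_mass_g / r.tapped_volume_cm3


def swelling_index(r: SwellingReading) -> float:
    """Dimensionless swelling index: swollen over initial volume.

    Values below 1 (shrinkage) are physically unexpected for gari and
    trigger a warning but are accepted.
    """
    si = r.swollen_volume_ml / r.initial_volume_ml
    if si < 1.0:
        warnings.warn(
            f"swelling index {si:.3f} < 1: sample shrank on soaking",
            stacklevel=2,
        )
    return si


def moisture_content(r: MoistureReading, *, as_printed: bool = False) -> float:
    """Moisture content as a fraction in [0, 1).

    Returns the drying loss ``(fwt - dwt) / fwt``.  With
    ``as_printed=True`` returns the literal dry/fresh ratio instead.
    """
    if as_printed:
        return r.dry_weight_g / r.fresh_weight_g
    return (r.fresh_weight_g - r.dry_weight_g) / r.fresh_weight_g


def drying_converged(r: MoistureReading,
                     tol: float = DRYING_STABILITY_TOL) -> bool:
    """Whether the 24 h and final weights agree within ``tol`` (relative).

    Readings without a 24 h check weight are treated as converged.
    """
    if r.mass_24h_g is None:
        return True
    return abs(r.mass_24h_g - r.dry_weight_g) / r.dry_weight_g <= tol
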