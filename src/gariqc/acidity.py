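"""Total titratable acidity (TTA) as percent lactic acid.

A 20.0 mL aliquot of a 5.00 g / 100.0 mL aqueous gari extract is
titrated with 0.05 M NaOH to a phenolphthalein endpoint.  The
dry-matter-corrected acidity is

    TTA% = 0.450 * V_NaOH[mL] / (1 - h)

with h the sample's moisture fraction.  The 0.450 coefficient is the
published constant for this protocol (it folds in the NaOH molarity,
aliquot/extract ratio, sample mass and the 90.08 g/mol molar mass of
lactic acid) and is kept literally; only lactic-acid equivalents are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass

#: % lactic acid per mL of 0.05 M NaOH at zero moisture.
TTA_COEFFICIENT = 0.450


@dataclass(frozen=True)
class TitrationReading:
    """NaOH volume to endpoint plus the sample's moisture fraction."""

    titration_volume_ml: float
    moisture_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.titration_volume_ml < 0:
            raise ValueError("titration volume must be >= 0")
        if not 0.0 <= self.moisture_fraction < 1.0:
            raise ValueError("moisture fraction must lie in [0, 1)")


def corrected_tta(r: TitrationReading) -> float:
    """Moisture-corrected TTA in % lactic acid (g / 100 g dry-corrected)."""
    return TTA_COEFFICIENT * r.titration_volume_ml / (1.0 - r.moisture_fraction)


def uncorrected_tta(r: TitrationReading) -> float:
    """TTA in % lactic acid without the moisture correction."""
    return TTA_COEFFICIENT * r.titration_volume_ml
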