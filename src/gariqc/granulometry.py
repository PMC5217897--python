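"""Sieve-stack particle-size analysis for gari.

Raw retained masses per mesh class are reduced to mass-fraction
distributions, cumulative undersize curves, median diameters (the 50%
crossing of the cumulative curve) and the mass-weighted mean diameter

    x3_bar = sum_i (d_{i-1} + d_i)/2 * mu3_i

where ``mu3_i`` is the mass fraction retained in size class
``(d_{i-1}, d_i)``.  Replicate trials are summarised by arithmetic mean
and sample standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateInputError, GariQCError, SchemaError

#: Apertures (um) of the standard nine-sieve stack used for gari.
DEFAULT_MESHES_UM: tuple[float, ...] = (
    125.0, 180.0, 250.0, 355.0, 500.0, 710.0, 1000.0, 1400.0, 2000.0,
)

#: Ratio applied to the largest mesh to bound the oversize class,
#: following the ~sqrt(2) progression of the sieve series.
OVERSIZE_BOUND_RATIO = 1.4


@dataclass(frozen=True)
class SieveSpec:
    """Geometry of a sieve stack: apertures plus pan/oversize bounds.

    The pan class is bounded below by ``pan_lower_bound_um`` (default 0,
    diameters are physically non-negative); material retained on the
    largest sieve is assigned the class
    ``(largest mesh, top_upper_bound_um)`` with the upper bound
    defaulting to 1.4x the largest mesh.
    """

    mesh_sizes_um: tuple[float, ...] = DEFAULT_MESHES_UM
    pan_lower_bound_um: float = 0.0
    top_upper_bound_um: Optional[float] = None

    def __post_init__(self) -> None:
        meshes = tuple(float(m) for m in self.mesh_sizes_um)
        object.__setattr__(self, "mesh_sizes_um", meshes)
        if len(meshes) < 1:
            raise ValueError("at least one mesh size is required")
        if any(m <= 0 for m in meshes):
            raise ValueError("mesh sizes must be positive")
        if any(b <= a for a, b in zip(meshes, meshes[1:])):
            raise ValueError("mesh sizes must be strictly increasing")
        if not 0 <= self.pan_lower_bound_um < meshes[0]:
            raise ValueError("pan lower bound must lie in [0, smallest mesh)")
        top = self.top_upper_bound_um
        if top is None:
            top = OVERSIZE_BOUND_RATIO * meshes[-1]
            object.__setattr__(self, "top_upper_bound_um", top)
        if top <= meshes[-1]:
            raise ValueError("top upper bound must exceed the largest mesh")

    @property
    def n_classes(self) -> int:
        return len(self.mesh_sizes_um) + 1

    @property
    def class_bounds_um(self) -> list[tuple[float, float]]:
        """(lower, upper) per class, pan first, ascending diameter."""
        edges = (self.pan_lower_bound_um, *self.mesh_sizes_um,
                 self.top_upper_bound_um)
        return list(zip(edges[:-1], edges[1:]))


@dataclass(frozen=True)
class SieveTrial:
    """Retained masses for one sieving run of one sample.

    ``retained_mass_g`` is aligned to :class:`SieveSpec` classes, pan
    first, ascending diameter.  ``sieving_time_min`` is metadata only
    (its effect was found non-significant and no correction is applied).
    """

    sample_id: str
    retained_mass_g: tuple[float, ...]
    sieving_time_min: float = 10.0

    def __post_init__(self) -> None:
        masses = tuple(float(m) for m in self.retained_mass_g)
        object.__setattr__(self, "retained_mass_g", masses)
        if any(m < 0 for m in masses):
            raise ValueError("retained masses must be non-negative")
        if sum(masses) <= 0:
            raise DegenerateInputError("total retained mass must be > 0")


_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class SizeDistribution:
    """Mass-fraction distribution over contiguous size classes."""

    class_bounds_um: tuple[tuple[float, float], ...]
    mass_fraction: tuple[float, ...]
    cumulative: tuple[float, ...]

    def __post_init__(self) -> None:
        bounds = tuple((float(a), float(b)) for a, b in self.class_bounds_um)
        frac = tuple(float(f) for f in self.mass_fraction)
        cum = tuple(float(c) for c in self.cumulative)
        object.__setattr__(self, "class_bounds_um", bounds)
        object.__setattr__(self, "mass_fraction", frac)
        object.__setattr__(self, "cumulative", cum)
        if not len(bounds) == len(frac) == len(cum):
            raise SchemaError("bounds, fractions and cumulative must align")
        if any(f < -_FRACTION_TOL for f in frac):
            raise ValueError("mass fractions must be non-negative")
        if abs(sum(frac) - 1.0) > _FRACTION_TOL:
            raise ValueError("mass fractions must sum to 1")
        if any(c2 < c1 - _FRACTION_TOL for c1, c2 in zip(cum, cum[1:])):
            raise ValueError("cumulative curve must be non-decreasing")
        if abs(cum[-1] - 1.0) > _FRACTION_TOL:
            raise ValueError("cumulative curve must end at 1")
        for (_, hi), (lo2, _) in zip(bounds, bounds[1:]):
            if hi != lo2:
                raise ValueError("class bounds must tile without gaps")
        if any(hi <= lo for lo, hi in bounds):
            raise ValueError("class bounds must have positive width")


def mass_fractions(trial: SieveTrial, spec: SieveSpec) -> SizeDistribution:
    """Normalise retained masses to mass fractions and cumulative curve.

    Raises
    ------
    SchemaError
        If the trial's class count does not match the spec.
    DegenerateInputError
        If the total retained mass is not positive.
    """
    masses = np.asarray(trial.retained_mass_g, dtype=float)
    if masses.size != spec.n_classes:
        raise SchemaError(
            f"trial has {masses.size} classes, spec defines {spec.n_classes}"
        )
    total = masses.sum()
    if total <= 0:
        raise DegenerateInputError("total retained mass must be > 0")
    frac = masses / total
    return SizeDistribution(
        class_bounds_um=tuple(spec.class_bounds_um),
        mass_fraction=tuple(frac),
        cumulative=tuple(np.cumsum(frac)),
    )


def median_diameter(dist: SizeDistribution) -> float:
    """Diameter (um) where the cumulative curve crosses 50%.

    The cumulative undersize curve is taken piecewise-linear through the
    points (class upper bound, cumulative fraction), anchored on the
    left at (pan lower bound, 0).
    """
    x = np.array([dist.class_bounds_um[0][0]]
                 + [hi for _, hi in dist.class_bounds_um])
    y = np.array([0.0, *dist.cumulative])
    if y[-1] < 0.5 - _FRACTION_TOL:  # pragma: no cover - invariant guard
        raise GariQCError("cumulative curve never reaches 50%")
    i = int(np.searchsorted(y, 0.5))
    if y[i - 1] >= 0.5:  # crossing exactly at the previous node
        return float(x[i - 1])
    if y[i] == y[i - 1]:  # pragma: no cover - excluded by branch above
        return float(x[i])
    t = (0.5 - y[i - 1]) / (y[i] - y[i - 1])
    return float(x[i - 1] + t * (x[i] - x[i - 1]))


def weighted_mean_diameter(dist: SizeDistribution) -> float:
    """Mass-weighted mean of class midpoint diameters (um)."""
    mids = np.array([(lo + hi) / 2.0 for lo, hi in dist.class_bounds_um])
    return float(mids @ np.asarray(dist.mass_fraction))


@dataclass(frozen=True)
class ReplicateStats:
    """Arithmetic mean, sample (n-1) SD and count of replicate values."""

    mean: float
    sd: Optional[float]
    n: int


def average_over_trials(values: Sequence[float]) -> ReplicateStats:
    """Mean and sample standard deviation over replicate measurements.

    With a single value the SD is undefined and reported as ``None``.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise DegenerateInputError("cannot average an empty replicate set")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else None
    return ReplicateStats(mean=mean, sd=sd, n=int(vals.size))
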