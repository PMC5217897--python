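"""Static-jacket bomb-calorimeter data reduction.

The chain runs in three steps:

1. ``extract_delta_T`` reduces a raw temperature trace to the corrected
   temperature rise dT: linear drift lines are fitted to the fore period
   (before ignition) and the after period (once the rise has settled),
   both are extrapolated to the mid-rise time, and dT is their
   difference there.
2. ``calorimeter_constant`` calibrates the apparatus heat capacity K
   from a benzoic-acid firing:
       K = (H_B*m_B + H_I*m_I) / dT - m_W*c_W
3. ``gcv_mixture`` / ``gcv_sample`` convert a sample firing into the
   gross calorific value of the gari-fuel mixture and then of the gari
   itself, subtracting the spiking fuel and ignition wire:
       H_M = ((m_W*c_W + K)*dT - H_I*m_I) / m_M
       H_G = (H_M*m_M - H_F*m_F) / m_G

All energies are in J internally; pipeline outputs report kJ/g.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import FailedCombustionError, InsufficientTraceError

#: Smoothed-slope magnitude (K/s) above which the trace is considered
#: to be rising; used to auto-detect the fore/after drift windows.
DEFAULT_SLOPE_THRESHOLD_K_PER_S = 5e-4

#: Width (s) of the boxcar used to smooth the trace before slope
#: estimation; sets the margin excluded around the detected rise.
DEFAULT_SMOOTH_WINDOW_S = 60.0


@dataclass(frozen=True)
class TemperatureTrace:
    """Time-stamped water-bath temperatures around one bomb firing.

    Only temperature differences are used, so the temperature unit may
    be K or degrees C as long as it is consistent.
    """

    times_s: tuple[float, ...]
    temps_K: tuple[float, ...]
    ignition_time_s: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        y = np.asarray(self.temps_K, dtype=float)
        object.__setattr__(self, "times_s", tuple(t))
        object.__setattr__(self, "temps_K", tuple(y))
        if t.size != y.size:
            raise ValueError("times and temperatures must align")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.sum(t < self.ignition_time_s) < 3 or \
                np.sum(t > self.ignition_time_s) < 3:
            raise InsufficientTraceError(
                "need at least 3 points before and after ignition"
            )


@dataclass(frozen=True)
class CalorimeterConfig:
    """Fixed apparatus parameters for one calorimeter setup."""

    water_mass_g: float = 1000.0
    water_heat_capacity_J_per_gK: float = 4.184
    wire_gcv_J_per_g: float = 5000.0
    wire_mass_g: float = 0.010
    fuel_gcv_J_per_g: float = 45400.0

    def __post_init__(self) -> None:
        for name in ("water_mass_g", "water_heat_capacity_J_per_gK",
                     "wire_gcv_J_per_g", "fuel_gcv_J_per_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.wire_mass_g < 0:  # a wireless ignition is a valid limit
            raise ValueError("wire_mass_g must be >= 0")

    @property
    def water_heat_capacity_total_J_per_K(self) -> float:
        return self.water_mass_g * self.water_heat_capacity_J_per_gK

    @property
    def wire_heat_J(self) -> float:
        return self.wire_gcv_J_per_g * self.wire_mass_g


@dataclass(frozen=True)
class CalibrationRun:
    """A benzoic-acid firing used to calibrate the calorimeter."""

    trace: TemperatureTrace
    benzoic_mass_g: float
    benzoic_gcv_J_per_g: float = 26460.0

    def __post_init__(self) -> None:
        if self.benzoic_mass_g <= 0 or self.benzoic_gcv_J_per_g <= 0:
            raise ValueError("benzoic mass and GCV must be > 0")


@dataclass(frozen=True)
class SampleRun:
    """A gari(+fuel-oil) firing."""

    trace: TemperatureTrace
    sample_mass_g: float
    fuel_mass_g: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_mass_g <= 0:
            raise ValueError("sample mass must be > 0")
        if self.fuel_mass_g < 0:
            raise ValueError("fuel mass must be >= 0")

    @property
    def mixture_mass_g(self) -> float:
        return self.sample_mass_g + self.fuel_mass_g


def _smoothed_slope(t: np.ndarray, y: np.ndarray,
                    smooth_window_s: float) -> tuple[np.ndarray, float]:
    """Boxcar-smoothed centred-difference slope estimate per point.

    Returns the slope array (edges padded with 0) and the margin (s) to
    exclude around any detected rise, covering the smoothing extent.
    """
    dt = float(np.median(np.diff(t)))
    half = max(1, int(round(smooth_window_s / 2.0 / dt)))
    # partial-window boxcar mean via cumulative sums
    csum = np.concatenate([[0.0], np.cumsum(y)])
    n = y.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    ysm = (csum[hi] - csum[lo]) / (hi - lo)
    slope = np.zeros(n)
    idx = np.arange(half, n - half)
    if idx.size:
        slope[idx] = (ysm[idx + half] - ysm[idx - half]) / \
            (t[idx + half] - t[idx - half])
    # exclude twice the smoothing extent around the rise: the settle
    # tail below the slope threshold decays across the extra margin
    margin_s = 2 * (2 * half + 1) * dt
    return slope, margin_s


def _fit_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares (slope, intercept)."""
    slope, intercept = np.polyfit(t, y, 1)
    return float(slope), float(intercept)


def extract_delta_T(
    trace: TemperatureTrace,
    *,
    slope_threshold_K_per_s: float = DEFAULT_SLOPE_THRESHOLD_K_PER_S,
    smooth_window_s: float = DEFAULT_SMOOTH_WINDOW_S,
    fore_window_s: Optional[tuple[float, float]] = None,
    after_window_s: Optional[tuple[float, float]] = None,
) -> float:
    """Corrected temperature rise (K) from a combustion trace.

    Fore and after drift windows are auto-detected as the spans where
    the smoothed slope magnitude stays below ``slope_threshold_K_per_s``
    (before ignition / after the rise has settled), or may be given
    explicitly as (start, end) times.  Linear fits to both windows are
    extrapolated to the mid-rise time (where the trace crosses halfway
    between the two drift lines); dT is their difference there.

    Raises
    ------
    InsufficientTraceError
        If a drift window holds fewer than 2 points.
    FailedCombustionError
        If the extracted rise is not positive.
    """
    t = np.asarray(trace.times_s)
    y = np.asarray(trace.temps_K)
    tig = trace.ignition_time_s

    if fore_window_s is not None:
        fore_mask = (t >= fore_window_s[0]) & (t <= fore_window_s[1])
    else:
        fore_mask = None
    if after_window_s is not None:
        after_mask = (t >= after_window_s[0]) & (t <= after_window_s[1])
    else:
        after_mask = None

    if fore_mask is None or after_mask is None:
        slope, margin_s = _smoothed_slope(t, y, smooth_window_s)
        rising = np.abs(slope) > slope_threshold_K_per_s
        rise_idx = np.nonzero(rising)[0]
        if rise_idx.size:
            t_first = t[rise_idx[0]] - margin_s
            t_last = t[rise_idx[-1]] + margin_s
        else:  # no detectable rise: split at ignition
            t_first, t_last = tig, tig
        if fore_mask is None:
            fore_mask = t <= min(tig, t_first)
            if fore_mask.sum() < 2:  # margin ate the window; fall back
                fore_mask = t <= tig
        if after_mask is None:
            after_mask = t >= max(tig, t_last)
            if after_mask.sum() < 2:
                after_mask = t >= max(tig, t[rise_idx[-1]] if rise_idx.size
                                      else tig)

    if fore_mask.sum() < 2 or after_mask.sum() < 2:
        raise InsufficientTraceError(
            f"drift windows too small: {int(fore_mask.sum())} fore, "
            f"{int(after_mask.sum())} after points"
        )

    fs, fi = _fit_line(t[fore_mask], y[fore_mask])
    as_, ai = _fit_line(t[after_mask], y[after_mask])

    # mid-rise time: first crossing of the midline between the two fits
    t_fore_end = t[fore_mask][-1]
    t_after_start = t[after_mask][0]
    rise = (t >= t_fore_end) & (t <= t_after_start)
    tr, yr = t[rise], y[rise]
    midline = ((fs + as_) * tr + fi + ai) / 2.0
    above = yr >= midline
    if above.any() and not above[0]:
        j = int(np.argmax(above))
        num = midline[j - 1] - yr[j - 1]
        den = (yr[j] - yr[j - 1]) - (midline[j] - midline[j - 1])
        frac = num / den if den != 0 else 0.5
        t_mid = float(tr[j - 1] + frac * (tr[j] - tr[j - 1]))
    else:
        t_mid = (t_fore_end + t_after_start) / 2.0

    dT = (as_ * t_mid + ai) - (fs * t_mid + fi)
    if dT <= 0:
        raise FailedCombustionError(
            f"non-positive temperature rise ({dT:.4f} K)"
        )
    return float(dT)


def calorimeter_constant(run: CalibrationRun, cfg: CalorimeterConfig,
                         dT: float) -> float:
    """Calorimeter constant K (J/K) from a benzoic-acid firing."""
    if dT <= 0:
        raise ValueError("temperature rise must be > 0")
    heat = run.benzoic_gcv_J_per_g * run.benzoic_mass_g + cfg.wire_heat_J
    K = heat / dT - cfg.water_heat_capacity_total_J_per_K
    if K < 0:
        warnings.warn(
            f"negative calorimeter constant ({K:.1f} J/K): calibration "
            "energy smaller than the water charge alone", stacklevel=2,
        )
    return K


def gcv_mixture(run: SampleRun, cfg: CalorimeterConfig, K: float,
                dT: float) -> float:
    """Gross calorific value (J/g) of the gari-fuel mixture."""
    if dT <= 0:
        raise ValueError("temperature rise must be > 0")
    if run.mixture_mass_g <= 0:
        raise ValueError("mixture mass must be > 0")
    heat = (cfg.water_heat_capacity_total_J_per_K + K) * dT - cfg.wire_heat_J
    hhm = heat / run.mixture_mass_g
    if hhm < 0:
        warnings.warn(
            f"negative mixture GCV ({hhm:.1f} J/g) is physically "
            "implausible", stacklevel=2,
        )
    return hhm


def gcv_sample(h_mixture_J_per_g: float, run: SampleRun,
               cfg: CalorimeterConfig) -> float:
    """Gross calorific value (J/g) of the gari sample net of fuel oil."""
    if run.sample_mass_g <= 0:
        raise ValueError("sample mass must be > 0")
    heat = h_mixture_J_per_g * run.mixture_mass_g \
        - cfg.fuel_gcv_J_per_g * run.fuel_mass_g
    return heat / run.sample_mass_g


def reduce_sample_run(run: SampleRun, cfg: CalorimeterConfig,
                      K: float, **delta_t_kwargs) -> float:
    """Full trace-to-sample-GCV reduction (J/g) for one firing."""
    dT = extract_delta_T(run.trace, **delta_t_kwargs)
    hhm = gcv_mixture(run, cfg, K, dT)
    return gcv_sample(hhm, run, cfg)
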