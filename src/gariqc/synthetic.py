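"""Synthetic raw lab readings generated from declared ground truth.

Every assay in the pipeline gets a generator that inverts the
measurement model: declared truths (median grain size and lognormal
width, bulk density, swelling index, moisture fraction, gross calorific
value, cyanide content, acidity) are back-computed into the raw
readings the instruments would report, then perturbed with Gaussian
noise on the raw instrument scale (masses, volumes, temperatures,
absorbances), truncated at physical bounds.  This gives each reduction
stage a parameter-recovery test bed with no external data.

The ``togo_maritime`` preset ships 14 sample truths spanning the
observed ranges of a south-Togo market survey, for demonstration only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import stats

from .acidity import TTA_COEFFICIENT
from .calorimetry import CalibrationRun, CalorimeterConfig, SampleRun, \
    TemperatureTrace
from .cyanide import AbsorbanceReading, NOMINAL_ELUTION_VOLUME_ML, \
    NOMINAL_SAMPLE_MASS_MG, PICRATE_FACTOR_PPM
from .errors import InconsistentTruthError
from .granulometry import SieveSpec, SieveTrial
from .physical_props import BulkDensityReading, MoistureReading, \
    SwellingReading

RngLike = Union[int, np.random.Generator]


def _as_rng(rng: RngLike) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement-noise SDs on the raw instrument scale."""

    sieve_mass_g: float = 0.1
    density_mass_g: float = 0.01
    density_volume_cm3: float = 0.2
    swelling_volume_ml: float = 0.3
    moisture_fresh_g: float = 0.01
    moisture_dry_g: float = 0.02
    trace_temp_K: float = 0.02
    absorbance: float = 0.002
    titration_ml: float = 0.02


@dataclass(frozen=True)
class Replication:
    """Replicate counts per assay (survey protocol defaults)."""

    sieve: int = 4
    density: int = 3
    swelling: int = 3
    moisture: int = 5
    calorimetry: int = 4
    cyanide: int = 3
    acidity: int = 3


@dataclass(frozen=True)
class TraceParams:
    """Shape of a simulated calorimeter temperature trace."""

    t0_K: float = 295.0
    fore_period_s: float = 600.0
    total_s: float = 1500.0
    dt_s: float = 1.0
    tau_s: float = 35.0
    drift_K_per_s: float = 2e-5


# documented plausibility bounds for declared truths
_TRUTH_BOUNDS = {
    "median_um": (100.0, 2500.0),
    "sigma_ln": (1e-6, 2.0),
    "bulk_density_g_cm3": (0.3, 1.0),
    "swelling_index": (1.0, 8.0),
    "moisture_fraction": (0.0, 0.3),
    "gcv_kJ_g": (10.0, 25.0),
    "cyanide_ppm": (0.0, 800.0),
    "tta_percent": (0.0, 5.0),
}


@dataclass(frozen=True)
class SampleTruth:
    """Declared ground truth for one synthetic gari sample.

    Grain size is a mass-weighted lognormal with median ``median_um``
    and log-space SD ``sigma_ln``; the remaining truths are the scalar
    quantities each assay targets.
    """

    sample_id: str
    median_um: float
    sigma_ln: float
    bulk_density_g_cm3: float
    swelling_index: float
    moisture_fraction: float
    gcv_kJ_g: float
    cyanide_ppm: float
    tta_percent: float
    noise: NoiseModel = field(default_factory=NoiseModel)
    replicates: Replication = field(default_factory=Replication)

    def __post_init__(self) -> None:
        for name, (lo, hi) in _TRUTH_BOUNDS.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise InconsistentTruthError(
                    f"{name}={v} outside plausible bounds [{lo}, {hi}]"
                )


# ---------------------------------------------------------------------------
# granulometry

def discretized_size_fractions(truth: SampleTruth,
                               spec: SieveSpec) -> np.ndarray:
    """Noise-free mass fractions of the truth lognormal on the spec
    classes (tails below the pan bound / above the top bound fold into
    the pan and oversize classes)."""
    dist = stats.lognorm(s=truth.sigma_ln, scale=truth.median_um)
    edges = np.array([0.0, *spec.mesh_sizes_um, np.inf])
    cdf = dist.cdf(edges)
    return np.diff(cdf)


def simulate_sieve_trial(truth: SampleTruth, spec: SieveSpec,
                         rng: RngLike, *, total_mass_g: float = 100.0,
                         sieving_time_min: float = 10.0,
                         noise_sd_g: Optional[float] = None) -> SieveTrial:
    """One sieving run: discretized lognormal masses plus truncated
    Gaussian class-mass noise, renormalised to the total mass."""
    rng = _as_rng(rng)
    if truth.sigma_ln <= 0:
        raise InconsistentTruthError("sigma_ln must be > 0")
    sd = truth.noise.sieve_mass_g if noise_sd_g is None else noise_sd_g
    masses = total_mass_g * discretized_size_fractions(truth, spec)
    masses = np.clip(masses + rng.normal(0.0, sd, masses.size), 0.0, None)
    if masses.sum() <= 0:  # pragma: no cover - needs pathological noise
        raise InconsistentTruthError("noise wiped out all class masses")
    masses *= total_mass_g / masses.sum()
    return SieveTrial(sample_id=truth.sample_id,
                      retained_mass_g=tuple(masses),
                      sieving_time_min=sieving_time_min)


# ---------------------------------------------------------------------------
# calorimetry

def simulate_trace(delta_T: float, rng: RngLike, *,
                   params: TraceParams = TraceParams(),
                   noise_K: float = 0.02) -> TemperatureTrace:
    """A combustion temperature trace: linear drift, exponential
    approach to the post-ignition plateau, Gaussian sensor noise."""
    rng = _as_rng(rng)
    if delta_T <= 0:
        raise InconsistentTruthError("implied temperature rise must be > 0")
    t = np.arange(0.0, params.total_s + params.dt_s / 2, params.dt_s)
    tig = params.fore_period_s
    temp = params.t0_K + params.drift_K_per_s * t
    after = t > tig
    temp = temp + np.where(
        after, delta_T * (1.0 - np.exp(-(np.maximum(t - tig, 0.0))
                                       / params.tau_s)), 0.0)
    if noise_K > 0:
        temp = temp + rng.normal(0.0, noise_K, t.size)
    return TemperatureTrace(times_s=tuple(t), temps_K=tuple(temp),
                            ignition_time_s=tig)


def implied_delta_T(energy_J: float, cfg: CalorimeterConfig,
                    k_true_J_per_K: float) -> float:
    """Temperature rise implied by a released energy and apparatus."""
    dT = energy_J / (cfg.water_heat_capacity_total_J_per_K + k_true_J_per_K)
    if dT <= 0:
        raise InconsistentTruthError("implied temperature rise must be > 0")
    return dT


def simulate_calibration_run(cfg: CalorimeterConfig, k_true_J_per_K: float,
                             rng: RngLike, *,
                             benzoic_mass_g: float = 1.000,
                             benzoic_gcv_J_per_g: float = 26460.0,
                             params: TraceParams = TraceParams(),
                             noise_K: float = 0.02) -> CalibrationRun:
    """A benzoic-acid firing consistent with the declared constant."""
    energy = benzoic_gcv_J_per_g * benzoic_mass_g + cfg.wire_heat_J
    dT = implied_delta_T(energy, cfg, k_true_J_per_K)
    trace = simulate_trace(dT, rng, params=params, noise_K=noise_K)
    return CalibrationRun(trace=trace, benzoic_mass_g=benzoic_mass_g,
                          benzoic_gcv_J_per_g=benzoic_gcv_J_per_g)


def simulate_sample_run(gcv_J_per_g: float, cfg: CalorimeterConfig,
                        k_true_J_per_K: float, rng: RngLike, *,
                        sample_mass_g: float = 0.320,
                        fuel_mass_g: float = 0.080,
                        params: TraceParams = TraceParams(),
                        noise_K: float = 0.02) -> SampleRun:
    """A gari+fuel firing consistent with the declared sample GCV."""
    energy = gcv_J_per_g * sample_mass_g \
        + cfg.fuel_gcv_J_per_g * fuel_mass_g + cfg.wire_heat_J
    dT = implied_delta_T(energy, cfg, k_true_J_per_K)
    trace = simulate_trace(dT, rng, params=params, noise_K=noise_K)
    return SampleRun(trace=trace, sample_mass_g=sample_mass_g,
                     fuel_mass_g=fuel_mass_g)


def simulate_calorimeter_run(truth: SampleTruth, cfg: CalorimeterConfig,
                             kind: str, rng: RngLike, *,
                             k_true_J_per_K: float = 190.0,
                             **kwargs) -> Union[CalibrationRun, SampleRun]:
    """Dispatch to the calibration or sample-run generator.

    ``kind`` is ``"calibration"`` or ``"sample"``; temperature noise
    defaults to the truth's noise model.
    """
    kwargs.setdefault("noise_K", truth.noise.trace_temp_K)
    if kind == "calibration":
        return simulate_calibration_run(cfg, k_true_J_per_K, rng, **kwargs)
    if kind == "sample":
        return simulate_sample_run(truth.gcv_kJ_g * 1000.0, cfg,
                                   k_true_J_per_K, rng, **kwargs)
    raise ValueError(f"unknown run kind {kind!r}")


# ---------------------------------------------------------------------------
# scalar assays

def simulate_scalar_assays(truth: SampleTruth, rng: RngLike) -> dict:
    """Replicated raw readings for the five scalar assays.

    Returns a dict with keys ``bulk_density``, ``swelling``,
    ``moisture``, ``cyanide`` (lists of reading objects) and
    ``titration_volume_ml`` (list of floats; moisture is joined to the
    titration at reduction time, as in the real pipeline).
    """
    rng = _as_rng(rng)
    nz, rep = truth.noise, truth.replicates

    density = []
    v_true = 10.0 / truth.bulk_density_g_cm3
    for _ in range(rep.density):
        m = max(1e-6, 10.0 + rng.normal(0.0, nz.density_mass_g))
        v = max(1e-6, v_true + rng.normal(0.0, nz.density_volume_cm3))
        density.append(BulkDensityReading(sample_mass_g=m,
                                          tapped_volume_cm3=v))

    swelling = []
    for _ in range(rep.swelling):
        vi = max(1e-6, v_true + rng.normal(0.0, nz.swelling_volume_ml))
        vs = max(1e-6, v_true * truth.swelling_index
                 + rng.normal(0.0, nz.swelling_volume_ml))
        swelling.append(SwellingReading(initial_volume_ml=vi,
                                        swollen_volume_ml=vs))

    moisture = []
    dwt_true = 10.0 * (1.0 - truth.moisture_fraction)
    for _ in range(rep.moisture):
        fwt = max(1e-6, 10.0 + rng.normal(0.0, nz.moisture_fresh_g))
        dwt = float(np.clip(dwt_true + rng.normal(0.0, nz.moisture_dry_g),
                            1e-6, fwt))
        # samples are emulated as dried to constant weight: the 24 h
        # check weight sits well inside the stability tolerance
        m24 = float(np.clip(dwt + rng.normal(0.0, nz.moisture_dry_g / 10),
                            1e-6, fwt))
        moisture.append(MoistureReading(fresh_weight_g=fwt,
                                        dry_weight_g=dwt, mass_24h_g=m24))

    cyanide = []
    a_true = truth.cyanide_ppm / PICRATE_FACTOR_PPM
    for _ in range(rep.cyanide):
        a = max(0.0, a_true + rng.normal(0.0, nz.absorbance))
        cyanide.append(AbsorbanceReading(
            absorbance_510nm=a,
            sample_mass_mg=NOMINAL_SAMPLE_MASS_MG,
            elution_volume_ml=NOMINAL_ELUTION_VOLUME_ML))

    v_titr_true = truth.tta_percent * (1.0 - truth.moisture_fraction) \
        / TTA_COEFFICIENT
    titration = [max(0.0, v_titr_true + rng.normal(0.0, nz.titration_ml))
                 for _ in range(rep.acidity)]

    return {"bulk_density": density, "swelling": swelling,
            "moisture": moisture, "cyanide": cyanide,
            "titration_volume_ml": titration}


# ---------------------------------------------------------------------------
# factorial experiment

def simulate_factorial(rng: RngLike, *, grand_mean: float = 0.90,
                       effect_a: float = 0.05, effect_b: float = 0.15,
                       interaction: float = 0.01, r: int = 4,
                       sigma: float = 0.03,
                       factor_a_name: str = "grain size",
                       factor_a_levels: tuple[str, str] = ("fine", "coarse"),
                       factor_b_name: str = "moisture",
                       factor_b_levels: tuple[str, str] = ("dry", "humid")):
    """Balanced 2x2xr responses from declared effects plus noise.

    ``effect_a``/``effect_b`` are the half-differences between levels
    (level 1 gets -effect, level 2 +effect); ``interaction`` follows
    the +/- checkerboard convention.  Defaults emulate the acidity
    correlation experiment (responses in % lactic acid; the study
    displays them x 100).
    """
    from .doe import FactorialDataset  # local import to avoid cycle
    rng = _as_rng(rng)
    if r < 2:
        raise ValueError("need r >= 2 replicates")
    a = np.array([-effect_a, effect_a])
    b = np.array([-effect_b, effect_b])
    ab = np.array([[interaction, -interaction],
                   [-interaction, interaction]])
    mean = grand_mean + a[:, None] + b[None, :] + ab
    resp = mean[:, :, None] + rng.normal(0.0, sigma, (2, 2, r))
    return FactorialDataset(responses=resp,
                            factor_a_name=factor_a_name,
                            factor_a_levels=factor_a_levels,
                            factor_b_name=factor_b_name,
                            factor_b_levels=factor_b_levels,
                            response_scale=100.0)


# ---------------------------------------------------------------------------
# demonstration preset

def togo_maritime_truths() -> list[SampleTruth]:
    """14 demonstration truths spanning a south-Togo market survey's
    observed ranges (set interior to the range endpoints so replicate
    means stay in range under the default noise model).

    Demonstration only: these are declared truths, not measured values.
    """
    rows = [
        # id,           median, bd,    si,   h(%),  gcv,   hcn,  tta
        ("Agoe I",        668, 0.613, 3.56, 6.55, 15.62, 1.6, 1.27),
        ("Agoe II",       667, 0.625, 3.59, 6.32, 15.58, 1.8, 0.82),
        ("Agoe III",      785, 0.606, 3.58, 6.75, 15.62, 0.4, 1.11),
        ("Agoe IV",       669, 0.667, 4.20, 7.10, 15.56, 0.9, 0.73),
        ("Davie I",       706, 0.680, 4.13, 6.15, 15.70, 0.7, 0.62),
        ("Davie II",      600, 0.680, 4.07, 6.90, 15.56, 2.4, 1.33),
        ("Gape-Batekpo",  627, 0.625, 3.50, 4.65, 15.60, 0.4, 0.62),
        ("Gape-Nyassive", 602, 0.633, 3.54, 4.65, 15.70, 3.2, 0.66),
        ("Tabligbo I",    678, 0.633, 3.67, 8.28, 15.56, 1.9, 1.04),
        ("Tabligbo II",   687, 0.645, 3.42, 8.15, 15.65, 0.5, 0.99),
        ("Tabligbo III",  619, 0.667, 3.35, 9.00, 15.68, 2.7, 1.55),
        ("Vogan I",       529, 0.645, 3.81, 7.18, 15.60, 2.0, 0.97),
        ("Vogan II",      831, 0.560, 3.46, 7.62, 15.70, 2.0, 1.10),
        ("Vogan VI",      524, 0.606, 3.35, 9.05, 15.56, 0.4, 1.05),
    ]
    return [
        SampleTruth(sample_id=sid, median_um=med, sigma_ln=0.45,
                    bulk_density_g_cm3=bd, swelling_index=si,
                    moisture_fraction=h / 100.0, gcv_kJ_g=gcv,
                    cyanide_ppm=hcn, tta_percent=tta)
        for sid, med, bd, si, h, gcv, hcn, tta in rows
    ]
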