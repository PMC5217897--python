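"""CSV schemas, readers/writers, per-assay reducers and the results
aggregator for the gari QC pipeline.

All tabular interchange is comma-separated text with "." decimals and
locale-independent ``%.10g`` number formatting.  Output files carry a
comment header recording the package version and SHA-256 digests of
their inputs for audit.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acidity import TitrationReading, corrected_tta
from .calorimetry import CalibrationRun, CalorimeterConfig, SampleRun, \
    TemperatureTrace, calorimeter_constant, extract_delta_T, gcv_mixture, \
    gcv_sample
from .cyanide import AbsorbanceReading, ColorChart, DEFAULT_CHART, \
    chart_class, cyanide_ppm
from .errors import SchemaError
from .granulometry import SieveSpec, SieveTrial, \
    average_over_trials, mass_fractions, median_diameter, \
    weighted_mean_diameter
from .physical_props import BulkDensityReading, MoistureReading, \
    SwellingReading, bulk_density, drying_converged, moisture_content, \
    swelling_index
from . import synthetic
from .synthetic import NoiseModel, SampleTruth, TraceParams, \
    simulate_calibration_run, simulate_sample_run, simulate_scalar_assays, \
    simulate_sieve_trial

logger = logging.getLogger("gariqc")

FLOAT_FORMAT = "%.10g"

# required columns per schema; (column, must_be_nonnegative, must_be_positive)
SCHEMAS: dict[str, list[tuple[str, bool, bool]]] = {
    "sieve": [("sample_id", False, False), ("trial_id", False, False),
              ("sieving_time_min", False, True),
              ("class_lower_um", True, False),
              ("class_upper_um", False, True),
              ("retained_mass_g", True, False)],
    "bulk_density": [("sample_id", False, False), ("trial_id", False, False),
                     ("sample_mass_g", False, True),
                     ("tapped_volume_cm3", False, True)],
    "swelling": [("sample_id", False, False), ("trial_id", False, False),
                 ("initial_volume_ml", False, True),
                 ("swollen_volume_ml", False, True)],
    "moisture": [("sample_id", False, False), ("trial_id", False, False),
                 ("fresh_weight_g", False, True),
                 ("dry_weight_g", False, True)],
    "cyanide": [("sample_id", False, False), ("trial_id", False, False),
                ("absorbance_510nm", True, False),
                ("sample_mass_mg", False, True),
                ("elution_volume_ml", False, True)],
    "titration": [("sample_id", False, False), ("trial_id", False, False),
                  ("titration_volume_ml", True, False)],
    "calorimetry_manifest": [("run_id", False, False),
                             ("kind", False, False),
                             ("sample_id", False, False),
                             ("ignition_time_s", True, False)],
    "trace": [("time_s", True, False), ("temp_K", False, False)],
    "factorial": [("factor_a_level", False, False),
                  ("factor_b_level", False, False),
                  ("replicate", False, False), ("response", False, False)],
}

_ID_COLUMNS = {"sample_id", "trial_id", "run_id", "kind",
               "factor_a_level", "factor_b_level", "replicate"}


def file_digest(path: Union[str, Path]) -> str:
    """SHA-256 hex digest of a file's bytes."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_table(df: pd.DataFrame, path: Union[str, Path],
                inputs: Sequence[Union[str, Path]] = ()) -> None:
    """Write a CSV with an audit comment header (version + input digests)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# gariqc {__version__}"]
    for src in inputs:
        lines.append(f"# input sha256:{file_digest(src)} {Path(src).name}")
    body = df.to_csv(index=False, float_format=FLOAT_FORMAT)
    path.write_text("\n".join(lines) + "\n" + body)
    logger.info("wrote %s (%d rows)", path, len(df))


def read_trials(path: Union[str, Path], schema_id: str) -> pd.DataFrame:
    """Read and validate a raw-readings CSV against a named schema.

    Malformed rows are reported with their 1-based line numbers in the
    file (comment/header lines included).

    Raises
    ------
    SchemaError
        On missing columns, non-numeric cells or sign violations.
    """
    if schema_id not in SCHEMAS:
        raise KeyError(f"unknown schema {schema_id!r}")
    path = Path(path)
    # count leading comment lines so reported line numbers match the file
    n_comments = 0
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                n_comments += 1
            else:
                break
    df = pd.read_csv(path, comment="#")
    spec = SCHEMAS[schema_id]
    missing = [c for c, _, _ in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    first_data_line = n_comments + 2  # header occupies one line

    def _lines(mask: pd.Series) -> list[int]:
        return [int(i) + first_data_line for i in df.index[mask]]

    for col, nonneg, positive in spec:
        if col in _ID_COLUMNS:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            raise SchemaError(
                f"{path}: non-numeric or missing values in {col!r} "
                f"at lines {_lines(bad | df[col].isna())}"
            )
        df[col] = coerced
        if nonneg and (coerced < 0).any():
            raise SchemaError(
                f"{path}: negative values in {col!r} at lines "
                f"{_lines(coerced < 0)}"
            )
        if positive and (coerced <= 0).any():
            raise SchemaError(
                f"{path}: non-positive values in {col!r} at lines "
                f"{_lines(coerced <= 0)}"
            )
    return df


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class PipelineConfig:
    """Structured configuration for every pipeline stage."""

    calorimeter: CalorimeterConfig = field(default_factory=CalorimeterConfig)
    sieve: SieveSpec = field(default_factory=SieveSpec)
    chart: ColorChart = DEFAULT_CHART
    noise: NoiseModel = field(default_factory=NoiseModel)
    calorimeter_k_true_J_per_K: float = 190.0  # simulator ground truth


def load_config(path: Union[str, Path, None]) -> PipelineConfig:
    """Load a YAML config; absent path or keys fall back to defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "calorimeter" in raw:
        kwargs["calorimeter"] = CalorimeterConfig(**raw["calorimeter"])
    if "sieve" in raw:
        s = dict(raw["sieve"])
        if "mesh_sizes_um" in s:
            s["mesh_sizes_um"] = tuple(s["mesh_sizes_um"])
        kwargs["sieve"] = SieveSpec(**s)
    if "chart_levels_ppm" in raw:
        kwargs["chart"] = ColorChart(tuple(raw["chart_levels_ppm"]))
    if "noise" in raw:
        kwargs["noise"] = NoiseModel(**raw["noise"])
    if "calorimeter_k_true_J_per_K" in raw:
        kwargs["calorimeter_k_true_J_per_K"] = \
            float(raw["calorimeter_k_true_J_per_K"])
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# per-assay reducers: raw readings -> per-trial quantities

def reduce_granulometry(df: pd.DataFrame, spec: SieveSpec) -> pd.DataFrame:
    """Per-trial median and weighted-mean diameters from long-format
    sieve rows (one row per class)."""
    out = []
    expected = np.array([lo for lo, _ in spec.class_bounds_um])
    for (sid, tid), grp in df.groupby(["sample_id", "trial_id"], sort=True):
        grp = grp.sort_values("class_lower_um")
        if len(grp) != spec.n_classes or not np.allclose(
                grp["class_lower_um"].values, expected):
            raise SchemaError(
                f"sieve classes for {sid}/{tid} do not match the spec"
            )
        trial = SieveTrial(sample_id=str(sid),
                           retained_mass_g=tuple(grp["retained_mass_g"]),
                           sieving_time_min=float(
                               grp["sieving_time_min"].iloc[0]))
        dist = mass_fractions(trial, spec)
        out.append({"sample_id": sid, "trial_id": tid,
                    "median_um": median_diameter(dist),
                    "weighted_mean_um": weighted_mean_diameter(dist)})
    return pd.DataFrame(out)


def reduce_bulk_density(df: pd.DataFrame) -> pd.DataFrame:
    vals = [bulk_density(BulkDensityReading(r.sample_mass_g,
                                            r.tapped_volume_cm3))
            for r in df.itertuples()]
    return df[["sample_id", "trial_id"]].assign(bulk_density_g_cm3=vals)


def reduce_swelling(df: pd.DataFrame) -> pd.DataFrame:
    vals = [swelling_index(SwellingReading(r.initial_volume_ml,
                                           r.swollen_volume_ml))
            for r in df.itertuples()]
    return df[["sample_id", "trial_id"]].assign(swelling_index=vals)


def reduce_moisture(df: pd.DataFrame) -> pd.DataFrame:
    """Per-trial moisture fraction; flags trials whose 24 h check
    weight shows the sample was not dried to constant weight."""
    rows = []
    for r in df.itertuples():
        m24 = getattr(r, "mass_24h_g", None)
        reading = MoistureReading(
            fresh_weight_g=r.fresh_weight_g, dry_weight_g=r.dry_weight_g,
            mass_24h_g=None if m24 is None or pd.isna(m24) else float(m24))
        rows.append({"sample_id": r.sample_id, "trial_id": r.trial_id,
                     "moisture_fraction": moisture_content(reading),
                     "drying_converged": drying_converged(reading)})
    out = pd.DataFrame(rows)
    for r in out[~out["drying_converged"]].itertuples():
        logger.warning("moisture trial %s/%s not at constant weight",
                       r.sample_id, r.trial_id)
    return out


def reduce_cyanide(df: pd.DataFrame,
                   chart: ColorChart = DEFAULT_CHART) -> pd.DataFrame:
    rows = []
    for r in df.itertuples():
        reading = AbsorbanceReading(absorbance_510nm=r.absorbance_510nm,
                                    sample_mass_mg=r.sample_mass_mg,
                                    elution_volume_ml=r.elution_volume_ml)
        ppm = cyanide_ppm(reading)
        rows.append({"sample_id": r.sample_id, "trial_id": r.trial_id,
                     "cyanide_ppm": ppm,
                     "chart_class_ppm": chart_class(ppm, chart)})
    return pd.DataFrame(rows)


def reduce_acidity(titration_df: pd.DataFrame,
                   moisture_by_sample: Mapping[str, float]) -> pd.DataFrame:
    """Moisture-corrected TTA per trial.

    ``moisture_by_sample`` maps sample_id to the per-sample mean
    moisture fraction (the default correction basis; pass per-trial
    values through a custom mapping to override).
    """
    rows = []
    for r in titration_df.itertuples():
        h = float(moisture_by_sample[r.sample_id])
        reading = TitrationReading(titration_volume_ml=r.titration_volume_ml,
                                   moisture_fraction=h)
        rows.append({"sample_id": r.sample_id, "trial_id": r.trial_id,
                     "acidity_g_per_100g": corrected_tta(reading)})
    return pd.DataFrame(rows)


def reduce_calorimetry(manifest: pd.DataFrame,
                       trace_loader: Callable[[str], TemperatureTrace],
                       cfg: CalorimeterConfig) -> pd.DataFrame:
    """Reduce a run manifest: calibrations yield the calorimeter
    constant, sample runs yield the sample GCV using the mean constant
    over all calibration runs in the manifest."""
    records = []
    calibrations = manifest[manifest["kind"] == "calibration"]
    if len(calibrations) == 0:
        raise SchemaError("manifest contains no calibration run")
    k_values = {}
    for r in calibrations.itertuples():
        trace = trace_loader(str(r.run_id))
        dT = extract_delta_T(trace)
        run = CalibrationRun(trace=trace,
                             benzoic_mass_g=float(r.benzoic_mass_g),
                             benzoic_gcv_J_per_g=float(r.benzoic_gcv_J_per_g))
        k_values[str(r.run_id)] = calorimeter_constant(run, cfg, dT)
        records.append({"run_id": r.run_id, "kind": "calibration",
                        "sample_id": r.sample_id, "delta_T_K": dT,
                        "K_J_per_K": k_values[str(r.run_id)],
                        "Hh_G_kJ_per_g": np.nan})
    k_mean = float(np.mean(list(k_values.values())))
    for r in manifest[manifest["kind"] == "sample"].itertuples():
        trace = trace_loader(str(r.run_id))
        dT = extract_delta_T(trace)
        run = SampleRun(trace=trace, sample_mass_g=float(r.sample_mass_g),
                        fuel_mass_g=float(r.fuel_mass_g))
        hhm = gcv_mixture(run, cfg, k_mean, dT)
        hhg = gcv_sample(hhm, run, cfg)
        records.append({"run_id": r.run_id, "kind": "sample",
                        "sample_id": r.sample_id, "delta_T_K": dT,
                        "K_J_per_K": np.nan,
                        "Hh_G_kJ_per_g": hhg / 1000.0})
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# aggregation

def aggregate_replicates(per_trial: pd.DataFrame,
                         value_cols: Sequence[str],
                         by: str = "sample_id") -> pd.DataFrame:
    """Per-sample mean, sample SD and n for each value column."""
    rows = []
    for sid, grp in per_trial.groupby(by, sort=True):
        row: dict = {by: sid}
        for col in value_cols:
            vals = grp[col].dropna()
            if len(vals) == 0:
                logger.warning("no %s replicates for %s; skipped", col, sid)
                continue
            st = average_over_trials(vals.tolist())
            row[col] = st.mean
            row[f"{col}_sd"] = np.nan if st.sd is None else st.sd
            row[f"{col}_n"] = st.n
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class QCResultRow:
    """One sample's averaged quality parameters (the survey schema)."""

    sample_id: str
    weighted_mean_um: Optional[float] = None
    median_um: Optional[float] = None
    bulk_density_g_cm3: Optional[float] = None
    swelling_index: Optional[float] = None
    moisture_percent: Optional[float] = None
    gcv_kJ_g: Optional[float] = None
    cyanide_ppm: Optional[float] = None
    acidity_g_per_100g: Optional[float] = None


QC_VALUE_COLUMNS = [f.name for f in dc_fields(QCResultRow)
                    if f.name != "sample_id"]


def build_qc_table(aggregates: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Outer-merge per-assay aggregates into one row per sample."""
    out: Optional[pd.DataFrame] = None
    for agg in aggregates:
        if agg is None or len(agg) == 0:
            continue
        out = agg if out is None else out.merge(agg, on="sample_id",
                                                how="outer")
    if out is None:
        raise SchemaError("no aggregates to merge")
    lead = ["sample_id"] + [c for c in QC_VALUE_COLUMNS if c in out.columns]
    rest = [c for c in out.columns if c not in lead]
    return out[lead + rest].sort_values("sample_id").reset_index(drop=True)


def qc_rows(table: pd.DataFrame) -> list[QCResultRow]:
    """Typed view of a QC results table."""
    rows = []
    for r in table.itertuples():
        kwargs = {c: getattr(r, c) for c in QC_VALUE_COLUMNS
                  if hasattr(r, c) and pd.notna(getattr(r, c))}
        rows.append(QCResultRow(sample_id=str(r.sample_id), **kwargs))
    return rows


# ---------------------------------------------------------------------------
# synthetic dataset writer and end-to-end pipeline

def load_trace(path: Union[str, Path],
               ignition_time_s: float) -> TemperatureTrace:
    df = read_trials(path, "trace")
    return TemperatureTrace(times_s=tuple(df["time_s"]),
                            temps_K=tuple(df["temp_K"]),
                            ignition_time_s=ignition_time_s)


def write_synthetic_dataset(out_dir: Union[str, Path],
                            truths: Sequence[SampleTruth], seed: int,
                            cfg: Optional[PipelineConfig] = None,
                            n_calibrations: int = 1) -> None:
    """Generate the full set of raw-reading CSVs and trace files for a
    list of sample truths.  Deterministic: identical seed and truths
    give byte-identical files."""
    cfg = cfg or PipelineConfig()
    out_dir = Path(out_dir)
    (out_dir / "traces").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    params = TraceParams()

    sieve_rows, dens_rows, swell_rows, moist_rows = [], [], [], []
    cn_rows, titr_rows, manifest_rows = [], [], []

    def _write_trace(run_id: str, trace: TemperatureTrace) -> None:
        tdf = pd.DataFrame({"time_s": trace.times_s,
                            "temp_K": trace.temps_K})
        write_table(tdf, out_dir / "traces" / f"{run_id}.csv")

    for i in range(n_calibrations):
        run_id = f"cal_{i + 1}"
        run = simulate_calibration_run(
            cfg.calorimeter, cfg.calorimeter_k_true_J_per_K, rng,
            params=params, noise_K=cfg.noise.trace_temp_K)
        _write_trace(run_id, run.trace)
        manifest_rows.append({
            "run_id": run_id, "kind": "calibration", "sample_id": "",
            "sample_mass_g": np.nan, "fuel_mass_g": np.nan,
            "benzoic_mass_g": run.benzoic_mass_g,
            "benzoic_gcv_J_per_g": run.benzoic_gcv_J_per_g,
            "ignition_time_s": run.trace.ignition_time_s})

    for truth in truths:
        for t in range(truth.replicates.sieve):
            time_min = 10.0 if t % 2 == 0 else 15.0  # alternating protocol
            trial = simulate_sieve_trial(truth, cfg.sieve, rng,
                                         sieving_time_min=time_min)
            for (lo, hi), m in zip(cfg.sieve.class_bounds_um,
                                   trial.retained_mass_g):
                sieve_rows.append({
                    "sample_id": truth.sample_id, "trial_id": t + 1,
                    "sieving_time_min": time_min, "class_lower_um": lo,
                    "class_upper_um": hi, "retained_mass_g": m})
        assays = simulate_scalar_assays(truth, rng)
        for t, r in enumerate(assays["bulk_density"], 1):
            dens_rows.append({"sample_id": truth.sample_id, "trial_id": t,
                              "sample_mass_g": r.sample_mass_g,
                              "tapped_volume_cm3": r.tapped_volume_cm3})
        for t, r in enumerate(assays["swelling"], 1):
            swell_rows.append({"sample_id": truth.sample_id, "trial_id": t,
                               "initial_volume_ml": r.initial_volume_ml,
                               "swollen_volume_ml": r.swollen_volume_ml})
        for t, r in enumerate(assays["moisture"], 1):
            moist_rows.append({"sample_id": truth.sample_id, "trial_id": t,
                               "fresh_weight_g": r.fresh_weight_g,
                               "dry_weight_g": r.dry_weight_g,
                               "mass_24h_g": r.mass_24h_g})
        for t, r in enumerate(assays["cyanide"], 1):
            cn_rows.append({"sample_id": truth.sample_id, "trial_id": t,
                            "absorbance_510nm": r.absorbance_510nm,
                            "sample_mass_mg": r.sample_mass_mg,
                            "elution_volume_ml": r.elution_volume_ml})
        for t, v in enumerate(assays["titration_volume_ml"], 1):
            titr_rows.append({"sample_id": truth.sample_id, "trial_id": t,
                              "titration_volume_ml": v})
        for t in range(truth.replicates.calorimetry):
            run_id = f"{truth.sample_id.replace(' ', '_')}_run{t + 1}"
            run = simulate_sample_run(
                truth.gcv_kJ_g * 1000.0, cfg.calorimeter,
                cfg.calorimeter_k_true_J_per_K, rng, params=params,
                noise_K=cfg.noise.trace_temp_K)
            _write_trace(run_id, run.trace)
            manifest_rows.append({
                "run_id": run_id, "kind": "sample",
                "sample_id": truth.sample_id,
                "sample_mass_g": run.sample_mass_g,
                "fuel_mass_g": run.fuel_mass_g,
                "benzoic_mass_g": np.nan, "benzoic_gcv_J_per_g": np.nan,
                "ignition_time_s": run.trace.ignition_time_s})

    write_table(pd.DataFrame(sieve_rows), out_dir / "sieve_trials.csv")
    write_table(pd.DataFrame(dens_rows), out_dir / "bulk_density.csv")
    write_table(pd.DataFrame(swell_rows), out_dir / "swelling.csv")
    write_table(pd.DataFrame(moist_rows), out_dir / "moisture.csv")
    write_table(pd.DataFrame(cn_rows), out_dir / "cyanide.csv")
    write_table(pd.DataFrame(titr_rows), out_dir / "titration.csv")
    write_table(pd.DataFrame(manifest_rows),
                out_dir / "calorimetry_runs.csv")
    fact = synthetic.simulate_factorial(rng)
    frows = []
    for i, a in enumerate(fact.factor_a_levels):
        for j, b in enumerate(fact.factor_b_levels):
            for k in range(fact.n_replicates):
                frows.append({"factor_a_level": a, "factor_b_level": b,
                              "replicate": k + 1,
                              "response": fact.responses[i, j, k]})
    write_table(pd.DataFrame(frows), out_dir / "factorial.csv")


def process_all(in_dir: Union[str, Path],
                out_dir: Optional[Union[str, Path]] = None,
                cfg: Optional[PipelineConfig] = None) -> pd.DataFrame:
    """Run every assay reduction on a raw dataset directory and return
    the aggregated QC results table (one row per sample).

    Expects the file layout produced by :func:`write_synthetic_dataset`
    (or real data in the same schemas); assay files that are absent are
    skipped.  If ``out_dir`` is given, per-trial and aggregate CSVs are
    written there.
    """
    cfg = cfg or PipelineConfig()
    in_dir = Path(in_dir)
    aggregates = []
    written_inputs: dict[str, Path] = {}

    def _maybe_write(name: str, per_trial: pd.DataFrame,
                     agg: pd.DataFrame, src: Path) -> None:
        if out_dir is not None:
            write_table(per_trial, Path(out_dir) / f"{name}_per_trial.csv",
                        inputs=[src])
            write_table(agg, Path(out_dir) / f"{name}_aggregate.csv",
                        inputs=[src])

    src = in_dir / "sieve_trials.csv"
    if src.exists():
        per = reduce_granulometry(read_trials(src, "sieve"), cfg.sieve)
        agg = aggregate_replicates(per, ["weighted_mean_um", "median_um"])
        aggregates.append(agg)
        _maybe_write("granulometry", per, agg, src)

    src = in_dir / "bulk_density.csv"
    if src.exists():
        per = reduce_bulk_density(read_trials(src, "bulk_density"))
        agg = aggregate_replicates(per, ["bulk_density_g_cm3"])
        aggregates.append(agg)
        _maybe_write("bulk_density", per, agg, src)

    src = in_dir / "swelling.csv"
    if src.exists():
        per = reduce_swelling(read_trials(src, "swelling"))
        agg = aggregate_replicates(per, ["swelling_index"])
        aggregates.append(agg)
        _maybe_write("swelling", per, agg, src)

    moisture_mean: dict[str, float] = {}
    src = in_dir / "moisture.csv"
    if src.exists():
        per = reduce_moisture(read_trials(src, "moisture"))
        agg = aggregate_replicates(per, ["moisture_fraction"])
        moisture_mean = dict(zip(agg["sample_id"], agg["moisture_fraction"]))
        agg_pct = agg.rename(columns={
            "moisture_fraction": "moisture_percent",
            "moisture_fraction_sd": "moisture_percent_sd",
            "moisture_fraction_n": "moisture_percent_n"})
        agg_pct["moisture_percent"] *= 100.0
        agg_pct["moisture_percent_sd"] *= 100.0
        aggregates.append(agg_pct)
        _maybe_write("moisture", per, agg_pct, src)

    src = in_dir / "calorimetry_runs.csv"
    if src.exists():
        manifest = read_trials(src, "calorimetry_manifest")
        ignition = dict(zip(manifest["run_id"].astype(str),
                            manifest["ignition_time_s"]))

        def _loader(run_id: str) -> TemperatureTrace:
            return load_trace(in_dir / "traces" / f"{run_id}.csv",
                              float(ignition[run_id]))

        per = reduce_calorimetry(manifest, _loader, cfg.calorimeter)
        samples = per[per["kind"] == "sample"]
        agg = aggregate_replicates(
            samples.rename(columns={"Hh_G_kJ_per_g": "gcv_kJ_g"}),
            ["gcv_kJ_g"])
        aggregates.append(agg)
        _maybe_write("calorimetry", per, agg, src)

    src = in_dir / "cyanide.csv"
    if src.exists():
        per = reduce_cyanide(read_trials(src, "cyanide"), cfg.chart)
        agg = aggregate_replicates(per, ["cyanide_ppm"])
        aggregates.append(agg)
        _maybe_write("cyanide", per, agg, src)

    src = in_dir / "titration.csv"
    if src.exists():
        if not moisture_mean:
            raise SchemaError(
                "titration data require moisture results for the correction"
            )
        per = reduce_acidity(read_trials(src, "titration"), moisture_mean)
        agg = aggregate_replicates(per, ["acidity_g_per_100g"])
        aggregates.append(agg)
        _maybe_write("acidity", per, agg, src)

    table = build_qc_table(aggregates)
    if out_dir is not None:
        write_table(table, Path(out_dir) / "qc_results.csv")
    return table
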