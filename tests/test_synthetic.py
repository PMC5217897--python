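"""Parameter-recovery checks for the synthetic raw-data generators."""

import dataclasses

import numpy as np
import pytest

from gariqc import (
    CalorimeterConfig, InconsistentTruthError, NoiseModel, SampleTruth,
    anova, bulk_density, calorimeter_constant, decompose,
    cyanide_ppm, extract_delta_T, mass_fractions, median_diameter,
    moisture_content, reduce_sample_run, swelling_index,
    weighted_mean_diameter,
)
from gariqc.acidity import TitrationReading, corrected_tta
from gariqc.synthetic import (
    discretized_size_fractions, simulate_calorimeter_run,
    simulate_factorial, simulate_scalar_assays, simulate_sieve_trial,
    togo_maritime_truths,
)

ZERO_NOISE = NoiseModel(sieve_mass_g=0.0, density_mass_g=0.0,
                        density_volume_cm3=0.0, swelling_volume_ml=0.0,
                        moisture_fresh_g=0.0, moisture_dry_g=0.0,
                        trace_temp_K=0.0, absorbance=0.0, titration_ml=0.0)


def _truth(**overrides) -> SampleTruth:
    base = dict(sample_id="synthetic", median_um=600.0, sigma_ln=0.45,
                bulk_density_g_cm3=0.63, swelling_index=3.6,
                moisture_fraction=0.065, gcv_kJ_g=15.6, cyanide_ppm=2.0,
                tta_percent=0.95)
    base.update(overrides)
    return SampleTruth(**base)


class TestSieveGenerator:
    def test_degenerate_lognormal_collapses_to_one_class(self, sieve_spec):
        truth = _truth(sigma_ln=1e-6, noise=ZERO_NOISE)
        trial = simulate_sieve_trial(truth, sieve_spec, 0)
        masses = np.asarray(trial.retained_mass_g)
        # 600 um point mass lies in the (500, 710) class
        assert masses[5] == pytest.approx(100.0, abs=1e-6)

    def test_zero_noise_recovers_discretised_truth_exactly(self,
                                                           sieve_spec):
        truth = _truth(noise=ZERO_NOISE)
        trial = simulate_sieve_trial(truth, sieve_spec, 0)
        dist = mass_fractions(trial, sieve_spec)
        frac = discretized_size_fractions(truth, sieve_spec)
        mids = [(lo + hi) / 2 for lo, hi in sieve_spec.class_bounds_um]
        assert weighted_mean_diameter(dist) == \
            pytest.approx(float(np.dot(mids, frac)), abs=1e-9)

    def test_monte_carlo_median_recovery_within_2pct(self, sieve_spec):
        truth = _truth()
        rng = np.random.default_rng(3)
        medians = []
        for _ in range(500):
            trial = simulate_sieve_trial(truth, sieve_spec, rng)
            medians.append(median_diameter(mass_fractions(trial,
                                                          sieve_spec)))
        assert np.mean(medians) == pytest.approx(truth.median_um, rel=0.02)

    def test_generated_trials_valid_over_seed_sweep(self, sieve_spec):
        truth = _truth()
        for seed in range(300):
            trial = simulate_sieve_trial(truth, sieve_spec, seed)
            dist = mass_fractions(trial, sieve_spec)  # validates invariants
            assert sum(dist.mass_fraction) == pytest.approx(1.0, abs=1e-9)

    def test_invalid_sigma_rejected(self, sieve_spec):
        with pytest.raises(InconsistentTruthError):
            _truth(sigma_ln=0.0)


class TestCalorimeterGenerator:
    CFG = CalorimeterConfig()

    def test_zero_noise_round_trip_through_traces(self):
        truth = _truth(noise=ZERO_NOISE)
        cal = simulate_calorimeter_run(truth, self.CFG, "calibration", 0)
        K = calorimeter_constant(cal, self.CFG, extract_delta_T(cal.trace))
        assert K == pytest.approx(190.0, abs=1.0)
        run = simulate_calorimeter_run(truth, self.CFG, "sample", 0)
        gcv = reduce_sample_run(run, self.CFG, K)
        assert gcv == pytest.approx(truth.gcv_kJ_g * 1000.0, abs=15.0)

    def test_noisy_recovery_within_band(self):
        truth = _truth()
        rng = np.random.default_rng(8)
        hits = 0
        n = 30
        for _ in range(n):
            cal = simulate_calorimeter_run(truth, self.CFG, "calibration",
                                           rng)
            K = calorimeter_constant(cal, self.CFG,
                                     extract_delta_T(cal.trace))
            run = simulate_calorimeter_run(truth, self.CFG, "sample", rng)
            if abs(reduce_sample_run(run, self.CFG, K)
                   - truth.gcv_kJ_g * 1000.0) <= 150.0:
                hits += 1
        assert hits >= 0.9 * n

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            simulate_calorimeter_run(_truth(), self.CFG, "blank", 0)


class TestScalarAssayGenerator:
    def test_zero_noise_recovers_every_truth_exactly(self):
        truth = _truth(noise=ZERO_NOISE)
        assays = simulate_scalar_assays(truth, 0)
        assert bulk_density(assays["bulk_density"][0]) == \
            pytest.approx(truth.bulk_density_g_cm3, rel=1e-12)
        assert swelling_index(assays["swelling"][0]) == \
            pytest.approx(truth.swelling_index, rel=1e-12)
        assert moisture_content(assays["moisture"][0]) == \
            pytest.approx(truth.moisture_fraction, abs=1e-12)
        assert cyanide_ppm(assays["cyanide"][0]) == \
            pytest.approx(truth.cyanide_ppm, rel=1e-12)
        v = assays["titration_volume_ml"][0]
        rec = corrected_tta(TitrationReading(v, truth.moisture_fraction))
        assert rec == pytest.approx(truth.tta_percent, rel=1e-12)

    def test_moisture_monte_carlo_recovery(self):
        """h=0.08 with five replicates at 0.02 g dry-weight noise stays
        within 0.01 absolute of the truth."""
        truth = _truth(moisture_fraction=0.08,
                       noise=dataclasses.replace(ZERO_NOISE,
                                                 moisture_dry_g=0.02))
        rng = np.random.default_rng(21)
        for _ in range(50):
            assays = simulate_scalar_assays(truth, rng)
            h = np.mean([moisture_content(r) for r in assays["moisture"]])
            assert abs(h - 0.08) <= 0.01

    def test_blank_cyanide_floor(self):
        truth = _truth(cyanide_ppm=0.0, noise=ZERO_NOISE)
        assays = simulate_scalar_assays(truth, 0)
        assert all(r.absorbance_510nm == 0.0 for r in assays["cyanide"])
        assert all(cyanide_ppm(r) == 0.0 for r in assays["cyanide"])

    def test_noisy_cyanide_never_negative(self):
        truth = _truth(cyanide_ppm=0.3)
        for seed in range(50):
            assays = simulate_scalar_assays(truth, seed)
            assert all(cyanide_ppm(r) >= 0.0 for r in assays["cyanide"])

    def test_out_of_bounds_truth_rejected(self):
        with pytest.raises(InconsistentTruthError):
            _truth(gcv_kJ_g=40.0)
        with pytest.raises(InconsistentTruthError):
            _truth(moisture_fraction=0.5)


class TestFactorialGenerator:
    def test_zero_noise_recovers_declared_effects(self):
        data = simulate_factorial(0, effect_a=0.05, effect_b=0.15,
                                  interaction=0.02, sigma=0.0)
        dec = decompose(data)
        np.testing.assert_allclose(dec.effect_a, [-0.05, 0.05], atol=1e-12)
        np.testing.assert_allclose(dec.effect_b, [-0.15, 0.15], atol=1e-12)
        assert dec.interaction_ab[0, 0] == pytest.approx(0.02, abs=1e-12)
        assert np.allclose(dec.residuals, 0.0)

    def test_null_interaction_rarely_flagged(self):
        rng = np.random.default_rng(13)
        n = 200
        retained = sum(
            anova(decompose(simulate_factorial(
                rng, interaction=0.0, sigma=0.03))).loc[2, "p_value"] > 0.05
            for _ in range(n))
        assert retained >= 0.90 * n

    def test_large_effects_detected(self):
        rng = np.random.default_rng(14)
        n = 200
        hits = 0
        for _ in range(n):
            table = anova(decompose(simulate_factorial(
                rng, effect_a=0.10, effect_b=0.20, sigma=0.02)))
            if (table.loc[0, "p_value"] < 0.001
                    and table.loc[1, "p_value"] < 0.001):
                hits += 1
        assert hits >= 0.95 * n


def test_preset_spans_survey_ranges():
    truths = togo_maritime_truths()
    assert len(truths) == 14
    assert len({t.sample_id for t in truths}) == 14
    gcv = [t.gcv_kJ_g for t in truths]
    assert min(gcv) >= 15.45 and max(gcv) <= 15.81
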