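"""Bomb-calorimeter reduction: dT extraction, calibration, GCV chain."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from gariqc import (
    CalibrationRun, CalorimeterConfig, FailedCombustionError,
    InsufficientTraceError, SampleRun, TemperatureTrace,
    calorimeter_constant, extract_delta_T, gcv_mixture, gcv_sample,
    reduce_sample_run,
)
from gariqc.synthetic import (
    implied_delta_T, simulate_calibration_run, simulate_sample_run,
    simulate_trace,
)

CFG = CalorimeterConfig()  # 1000 g water, 50 J wire, fuel oil 45.4 kJ/g


def _step_trace(offset, t_shift=0.0, temp_shift=0.0, drift=0.0):
    t = np.arange(0.0, 301.0, 30.0) + t_shift
    tig = 150.0 + t_shift
    y = 295.0 + temp_shift + drift * (t - t_shift) \
        + np.where(t <= tig, 0.0, offset)
    return TemperatureTrace(tuple(t), tuple(y), tig)


class TestExtractDeltaT:
    def test_ideal_step(self):
        assert extract_delta_T(_step_trace(2.000)) == \
            pytest.approx(2.000, abs=1e-9)

    def test_identical_drift_cancels(self):
        dT = extract_delta_T(_step_trace(1.500, drift=1e-4))
        assert dT == pytest.approx(1.500, abs=1e-9)

    def test_shift_invariance(self):
        base = extract_delta_T(_step_trace(1.8))
        shifted = extract_delta_T(_step_trace(1.8, t_shift=5000.0,
                                              temp_shift=-270.0))
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_recovers_known_rise_from_noisy_trace(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            trace = simulate_trace(1.800, rng, noise_K=0.02)
            assert extract_delta_T(trace) == pytest.approx(1.800, abs=0.05)

    def test_explicit_windows_override(self):
        trace = simulate_trace(1.800, 0, noise_K=0.0)
        dT = extract_delta_T(trace, fore_window_s=(0.0, 590.0),
                             after_window_s=(1000.0, 1500.0))
        assert dT == pytest.approx(1.800, abs=5e-3)

    def test_failed_combustion_detected(self):
        with pytest.raises(FailedCombustionError):
            extract_delta_T(_step_trace(-0.5))

    def test_insufficient_window_detected(self):
        trace = simulate_trace(1.8, 0, noise_K=0.0)
        with pytest.raises(InsufficientTraceError):
            extract_delta_T(trace, fore_window_s=(0.0, 0.5),
                            after_window_s=(1000.0, 1500.0))

    def test_trace_needs_points_both_sides(self):
        with pytest.raises(InsufficientTraceError):
            TemperatureTrace((0.0, 1.0, 2.0, 3.0), (295.0,) * 4, 2.5)


class TestCalorimeterConstant:
    def test_hand_evaluated_example(self):
        # 1 g benzoic at 26460 J/g + 50 J wire over 6 K with 1000 g water
        run = CalibrationRun(trace=_step_trace(6.0), benzoic_mass_g=1.000,
                             benzoic_gcv_J_per_g=26460.0)
        K = calorimeter_constant(run, CFG, dT=6.000)
        assert K == pytest.approx((26460.0 + 50.0) / 6.0 - 4184.0, abs=1e-9)

    def test_perfect_water_only_calorimeter(self):
        # energy exactly m_W*c_W*dT -> K = 0
        dT = 2.0
        m_b = (4184.0 * dT - 50.0) / 26460.0
        run = CalibrationRun(trace=_step_trace(dT), benzoic_mass_g=m_b)
        assert calorimeter_constant(run, CFG, dT) == \
            pytest.approx(0.0, abs=1e-9)

    @given(st.floats(1.2, 5.0))
    def test_homogeneity(self, scale):
        run1 = CalibrationRun(trace=_step_trace(3.0), benzoic_mass_g=1.0)
        run2 = CalibrationRun(trace=_step_trace(3.0),
                              benzoic_mass_g=scale,
                              benzoic_gcv_J_per_g=26460.0)
        cfg2 = CalorimeterConfig(wire_mass_g=CFG.wire_mass_g * scale)
        assert calorimeter_constant(run2, cfg2, 3.0 * scale) == \
            pytest.approx(calorimeter_constant(run1, CFG, 3.0), rel=1e-9)

    def test_nonpositive_rise_rejected(self):
        run = CalibrationRun(trace=_step_trace(3.0), benzoic_mass_g=1.0)
        with pytest.raises(ValueError):
            calorimeter_constant(run, CFG, 0.0)


class TestGcvChain:
    def test_direct_ratio_without_wire_or_constant(self):
        cfg = CalorimeterConfig(wire_mass_g=1e-12)
        run = SampleRun(trace=_step_trace(1.0), sample_mass_g=0.5,
                        fuel_mass_g=0.0)
        dT = 10000.0 / (1000.0 * 4.184)
        assert gcv_mixture(run, cfg, K=0.0, dT=dT) == \
            pytest.approx(20000.0, rel=1e-9)

    def test_unspiked_sample_equals_mixture(self):
        run = SampleRun(trace=_step_trace(1.0), sample_mass_g=0.3,
                        fuel_mass_g=0.0)
        assert gcv_sample(17000.0, run, CFG) == pytest.approx(17000.0)

    def test_equal_mass_mixture_rule(self):
        # H_M midway between fuel and sample -> sample GCV mirrors fuel
        run = SampleRun(trace=_step_trace(1.0), sample_mass_g=0.2,
                        fuel_mass_g=0.2)
        h_m = (15600.0 + CFG.fuel_gcv_J_per_g) / 2.0
        assert gcv_sample(h_m, run, CFG) == pytest.approx(15600.0, rel=1e-12)

    def test_zero_wire_mass_removes_wire_term(self):
        cfg0 = CalorimeterConfig(wire_mass_g=1e-30)
        run = SampleRun(trace=_step_trace(1.0), sample_mass_g=0.4)
        h1 = gcv_mixture(run, cfg0, K=100.0, dT=2.0)
        expected = (1000.0 * 4.184 + 100.0) * 2.0 / 0.4
        assert h1 == pytest.approx(expected, rel=1e-9)

    def test_algebraic_round_trip_machine_precision(self, rng):
        """Calibration, mixture and sample formulas composed with their
        inversions reproduce the declared truths exactly."""
        for _ in range(50):
            k_true = rng.uniform(50.0, 500.0)
            gcv_true = rng.uniform(12000.0, 20000.0)
            m_g = rng.uniform(0.2, 0.5)
            m_f = rng.uniform(0.0, 0.15)
            # forward: truth -> implied rises; inverse: reduction chain
            e_cal = 26460.0 * 1.0 + CFG.wire_heat_J
            dT_cal = implied_delta_T(e_cal, CFG, k_true)
            cal = CalibrationRun(trace=_step_trace(3.0), benzoic_mass_g=1.0)
            K = calorimeter_constant(cal, CFG, dT_cal)
            assert K == pytest.approx(k_true, rel=1e-9)
            e_smp = gcv_true * m_g + CFG.fuel_gcv_J_per_g * m_f \
                + CFG.wire_heat_J
            dT_smp = implied_delta_T(e_smp, CFG, k_true)
            run = SampleRun(trace=_step_trace(3.0), sample_mass_g=m_g,
                            fuel_mass_g=m_f)
            h_m = gcv_mixture(run, CFG, K, dT_smp)
            assert gcv_sample(h_m, run, CFG) == \
                pytest.approx(gcv_true, rel=1e-9)

    def test_gcv_decreases_with_fuel_mass(self):
        """More spiking fuel at fixed mixture GCV lowers the inferred
        sample GCV whenever the fuel is more energetic."""
        h_m = 20000.0  # below the 45.4 kJ/g fuel
        prev = np.inf
        for m_f in (0.0, 0.04, 0.08, 0.12):
            run = SampleRun(trace=_step_trace(1.0), sample_mass_g=0.32,
                            fuel_mass_g=m_f)
            val = gcv_sample(h_m, run, CFG)
            assert val < prev
            prev = val


class TestSyntheticRecovery:
    def test_noise_free_trace_chain_close(self):
        """The full trace path carries only the small settle-tail
        systematic at zero noise (well under 0.01 kJ/g)."""
        run = simulate_sample_run(15600.0, CFG, 190.0, 0, noise_K=0.0)
        gcv = reduce_sample_run(run, CFG, K=190.0)
        assert gcv == pytest.approx(15600.0, abs=10.0)
        cal = simulate_calibration_run(CFG, 190.0, 0, noise_K=0.0)
        K = calorimeter_constant(cal, CFG, extract_delta_T(cal.trace))
        assert K == pytest.approx(190.0, abs=1.0)

    def test_noisy_end_to_end_recovery(self):
        """Trace noise of 0.02 K keeps the recovered GCV within
        0.15 kJ/g of the 15.60 kJ/g truth."""
        rng = np.random.default_rng(17)
        within = 0
        n = 40
        for _ in range(n):
            cal = simulate_calibration_run(CFG, 190.0, rng, noise_K=0.02)
            K = calorimeter_constant(cal, CFG, extract_delta_T(cal.trace))
            run = simulate_sample_run(15600.0, CFG, 190.0, rng,
                                      noise_K=0.02)
            if abs(reduce_sample_run(run, CFG, K) - 15600.0) <= 150.0:
                within += 1
        assert within >= 0.95 * n
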