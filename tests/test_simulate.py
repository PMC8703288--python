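"""Synthetic-data generator: areas, envelopes, determinism, scenarios."""

import math

import numpy as np
import pytest

from osmoquant.chem import SULFUR_M2_SHIFT, isotope_pattern
from osmoquant.quant import integrate_peak
from osmoquant.scenarios import get_scenario, tw_xenic
from osmoquant.screening import extract_xic
from osmoquant.simulate import (
    CalibrationDesign,
    NoiseModel,
    ScenarioConfig,
    measured_concentration_um,
    simulate_calibration,
    simulate_experiment,
    simulate_run,
)


class TestSimulateRun:
    def test_noise_free_area_matches_response(self, cys_analyte, fast_settings,
                                              no_noise):
        """XIC trapezoid area equals response factor x concentration within
        0.5% (Gaussian truncation at +-5 sigma)."""
        run = simulate_run([cys_analyte], {"cysteinolic acid": 10.0},
                           noise=no_noise, seed=0, settings=fast_settings)
        xic = extract_xic(run, cys_analyte.mz)
        area = integrate_peak(xic, (1.25, 1.75), baseline="none")
        assert area == pytest.approx(1.27e7 * 10.0, rel=5e-3)

    def test_same_seed_bit_identical(self, cys_analyte, fast_settings):
        a = simulate_run([cys_analyte], {"cysteinolic acid": 3.0}, seed=7,
                         settings=fast_settings)
        b = simulate_run([cys_analyte], {"cysteinolic acid": 3.0}, seed=7,
                         settings=fast_settings)
        np.testing.assert_array_equal(a.mz, b.mz)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        np.testing.assert_array_equal(a.scan_index, b.scan_index)

    def test_sulfur_companion_in_every_in_peak_scan(self, cys_analyte,
                                                    fast_settings, no_noise):
        """Every scan inside the elution window carries a centroid at the
        monoisotopic m/z + 1.995796 (the 34S isotopologue)."""
        run = simulate_run([cys_analyte], {"cysteinolic acid": 5.0},
                           noise=no_noise, seed=0, settings=fast_settings)
        target = cys_analyte.mz + SULFUR_M2_SHIFT
        sigma = fast_settings.peak_sigma_min
        in_peak = np.abs(run.times_min - cys_analyte.rt_min) <= 4.9 * sigma
        for scan in np.nonzero(in_peak)[0]:
            mz, _ = run.spectrum(int(scan))
            assert np.any(np.abs(mz - target) < 1e-4), f"scan {scan}"

    def test_envelope_ratios_match_pattern(self, cys_analyte, fast_settings,
                                           no_noise):
        """Simulated envelope abundances agree with the predicted pattern
        within 1e-3."""
        run = simulate_run([cys_analyte], {"cysteinolic acid": 5.0},
                           noise=no_noise, seed=0, settings=fast_settings)
        apex_scan = int(np.argmin(np.abs(run.times_min - cys_analyte.rt_min)))
        mz, inten = run.spectrum(apex_scan)
        base = inten[np.argmin(np.abs(mz - cys_analyte.mz))]
        for shift, expected in isotope_pattern(cys_analyte.formula).peaks:
            got = inten[np.argmin(np.abs(mz - (cys_analyte.mz + shift)))] / base
            assert abs(got - expected) < 1e-3

    def test_rejects_bad_inputs(self, cys_analyte):
        with pytest.raises(ValueError):
            simulate_run([], {})
        with pytest.raises(ValueError):
            simulate_run([cys_analyte], {"cysteinolic acid": -1.0})


class TestSimulateExperiment:
    def test_packaged_xenic_scenario_has_nine_runs(self):
        samples = simulate_experiment(tw_xenic(), seed=0)
        assert len(samples) == 9  # 3 replicates x 3 conditions
        conditions = {m["condition"] for _, m in samples}
        assert conditions == {"35 PSU", "50 PSU (24 h)", "50 PSU"}

    def test_noise_free_amounts_exact(self, cys_analyte, fast_settings):
        """With zero biological CV and zero noise the rendered concentration
        is exactly the configured per-cell amount through the unit chain."""
        scenario = ScenarioConfig(
            species="test",
            analytes=(cys_analyte,),
            conditions=(("a", {"cysteinolic acid": 10.0}),),
            replicates=2,
            biological_cv=0.0,
            noise=NoiseModel.none(),
            settings=fast_settings,
        )
        for run, meta in simulate_experiment(scenario, seed=1):
            assert meta["true_per_cell_fmol"]["cysteinolic acid"] == 10.0
            expected_um = measured_concentration_um(10.0, scenario)
            xic = extract_xic(run, cys_analyte.mz)
            area = integrate_peak(xic, (1.25, 1.75), baseline="none")
            assert area == pytest.approx(1.27e7 * expected_um, rel=5e-3)

    def test_biological_cv_is_mean_preserving(self, cys_analyte, fast_settings):
        """Jittered true amounts average back to the configured value
        (log-normal with mean 1 multipliers)."""
        scenario = ScenarioConfig(
            species="test",
            analytes=(cys_analyte,),
            conditions=(("a", {"cysteinolic acid": 10.0}),),
            replicates=200,
            biological_cv=0.10,
            noise=NoiseModel.none(),
            settings=fast_settings,
        )
        trues = [m["true_per_cell_fmol"]["cysteinolic acid"]
                 for _, m in simulate_experiment(scenario, seed=3)]
        assert np.mean(trues) == pytest.approx(10.0, rel=0.02)
        assert np.std(trues) / np.mean(trues) == pytest.approx(0.10, rel=0.25)

    def test_inconsistent_analyte_sets_rejected(self, cys_analyte):
        with pytest.raises(ValueError):
            ScenarioConfig(
                species="bad",
                analytes=(cys_analyte,),
                conditions=(("a", {"cysteinolic acid": 1.0}),
                            ("b", {"other": 1.0})),
            )


class TestSimulateCalibration:
    def test_noise_free_series_recovers_slope(self, cys_analyte, fast_settings):
        design = CalibrationDesign(
            analyte=cys_analyte, levels_um=(1.0, 2.0, 5.0, 10.0, 20.0),
            replicates=1, noise=NoiseModel.none(),
        )
        points = []
        for level, run in simulate_calibration(design, seed=0,
                                               settings=fast_settings):
            xic = extract_xic(run, cys_analyte.mz)
            points.append((level, integrate_peak(xic, (1.25, 1.75),
                                                 baseline="none")))
        x = np.array([p[0] for p in points])
        y = np.array([p[1] for p in points])
        slope = float(np.sum(x * y) / np.sum(x * x))
        assert slope == pytest.approx(1.27e7, rel=5e-4)

    def test_design_invariants(self, cys_analyte):
        with pytest.raises(ValueError):
            CalibrationDesign(analyte=cys_analyte, levels_um=(1.0, 1.0))
        with pytest.raises(ValueError):
            CalibrationDesign(analyte=cys_analyte, levels_um=(0.0, 1.0))

    def test_scenario_lookup(self):
        assert get_scenario("tw_xenic").species.startswith("T. weissflogii")
        with pytest.raises(KeyError):
            get_scenario("nope")
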