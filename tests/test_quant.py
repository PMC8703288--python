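"""Peak integration, calibration fitting, and unit normalization."""

import math

import numpy as np
import pytest

from osmoquant.quant import (
    CalibrationCurve,
    CensorFlag,
    SampleContext,
    cell_volume_from_shape,
    concentration_from_area,
    fit_calibration,
    integrate_peak,
    intracellular_concentration,
    per_cell_amount,
    quantify_run,
)
from osmoquant.screening import XIC, extract_xic
from osmoquant.simulate import NoiseModel, ScenarioConfig, simulate_experiment


def _xic(times, intensity):
    return XIC(target_mz=156.0, tol_ppm=5.0, times_min=np.asarray(times),
               intensity=np.asarray(intensity, dtype=float))


class TestIntegratePeak:
    def test_rectangular_pulse(self):
        """A flat pulse of height h over width w integrates to h x w."""
        t = np.linspace(0.0, 1.0, 101)
        y = np.where((t >= 0.2) & (t <= 0.8), 50.0, 0.0)
        area = integrate_peak(_xic(t, y), (0.1, 0.9), baseline="none")
        assert area == pytest.approx(50.0 * 0.6, rel=0.02)

    def test_gaussian_closed_form(self):
        """Gaussian of amplitude A and width sigma integrates to
        A sigma sqrt(2 pi) within 0.5%."""
        t = np.linspace(0.0, 2.0, 401)
        amp, sigma = 1e6, 0.05
        y = amp * np.exp(-0.5 * ((t - 1.0) / sigma) ** 2)
        area = integrate_peak(_xic(t, y), (0.5, 1.5), baseline="none")
        assert area == pytest.approx(amp * sigma * math.sqrt(2 * math.pi),
                                     rel=5e-3)

    def test_zero_signal_window(self):
        t = np.linspace(0.0, 1.0, 50)
        assert integrate_peak(_xic(t, np.zeros(50)), (0.1, 0.9)) == 0.0

    def test_linear_baseline_removes_offset(self):
        t = np.linspace(0.0, 1.0, 101)
        y = np.full(101, 500.0)
        assert integrate_peak(_xic(t, y), (0.0, 1.0)) == pytest.approx(0.0)

    def test_bad_windows_rejected(self):
        t = np.linspace(0.0, 1.0, 50)
        xic = _xic(t, np.ones(50))
        with pytest.raises(ValueError):
            integrate_peak(xic, (0.5, 0.5))
        with pytest.raises(ValueError):
            integrate_peak(xic, (0.5, 2.0))


class TestFitCalibration:
    def test_exact_line_through_origin(self):
        points = [(c, 2.0 * c) for c in (1.0, 2.0, 5.0, 10.0)]
        curve = fit_calibration(points)
        assert curve.slope == pytest.approx(2.0, rel=1e-12)
        assert curve.r == pytest.approx(1.0, abs=1e-12)
        assert curve.lod_um == 0.0 and curve.loq_um == 0.0

    def test_matches_normal_equations_oracle(self):
        """Noisy fit agrees with an independent least-squares solution to
        1e-9 relative."""
        rng = np.random.default_rng(12)
        x = np.array([1.0, 2.0, 5.0, 10.0, 25.0, 50.0])
        y = 3.1e6 * x * rng.lognormal(0, 0.05, x.size)
        curve = fit_calibration(list(zip(x, y)))
        slope_oracle = float(np.linalg.lstsq(x[:, None], y, rcond=None)[0][0])
        r_oracle = float(np.corrcoef(x, y)[0, 1])
        assert curve.slope == pytest.approx(slope_oracle, rel=1e-9)
        assert curve.r == pytest.approx(r_oracle, rel=1e-9)
        assert curve.r < 1.0

    def test_slope_estimate_unbiased(self):
        """Over 200 noisy series the mean slope bias is within 2 standard
        errors of zero."""
        rng = np.random.default_rng(7)
        x = np.array([2.0, 5.0, 10.0, 25.0, 75.0] * 3)
        slopes = []
        for _ in range(200):
            y = 1.27e7 * x * rng.lognormal(-0.5 * math.log(1 + 0.05 ** 2),
                                           math.sqrt(math.log(1 + 0.05 ** 2)),
                                           x.size)
            slopes.append(fit_calibration(list(zip(x, y))).slope)
        bias = np.mean(slopes) - 1.27e7
        se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
        assert abs(bias) < 2 * se

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 2.0), (2.0, 4.0)])

    def test_identical_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 2.0), (1.0, 2.1), (1.0, 1.9)])


class TestConcentrationFromArea:
    @pytest.fixture()
    def curve(self):
        return CalibrationCurve(analyte="x", slope=1e6, r=0.99,
                                residual_sd=6.58e5, lod_um=2.17, loq_um=6.58,
                                n_points=9)

    def test_inversion_is_identity(self, curve):
        conc, flag = concentration_from_area(curve.slope * 10.0, curve)
        assert conc == pytest.approx(10.0, rel=1e-12)
        assert flag == CensorFlag.QUANTIFIABLE

    def test_between_lod_and_loq_flagged_plus(self, curve):
        conc, flag = concentration_from_area(curve.slope * 4.0, curve)
        assert flag == CensorFlag.BELOW_LOQ

    def test_zero_area_below_lod(self, curve):
        conc, flag = concentration_from_area(0.0, curve)
        assert conc == 0.0 and flag == CensorFlag.BELOW_LOD


class TestUnitChain:
    def test_per_cell_unit_arithmetic(self):
        ctx = SampleContext(cells_filtered=1e7, extract_volume_ml=1.0,
                            dilution_factor=1.0, cell_volume_pl=1.0)
        assert per_cell_amount(1.0, ctx) == pytest.approx(0.1)

    def test_per_cell_inverse_in_cell_count(self):
        ctx1 = SampleContext(1e6, 1.0, 3.0, 1.0)
        ctx2 = SampleContext(2e6, 1.0, 3.0, 1.0)
        assert per_cell_amount(5.0, ctx1) == pytest.approx(
            2 * per_cell_amount(5.0, ctx2))

    def test_intracellular_unit_identity(self):
        assert intracellular_concentration(1.0, 1.0) == 1.0
        assert intracellular_concentration(0.0, 2.0) == 0.0

    def test_survey_row_fmol_to_mm(self):
        """50.6 fmol/cell in a 0.7117 pL cell is ~71.1 mM."""
        assert intracellular_concentration(50.6, 50.6 / 71.1) == pytest.approx(
            71.1, rel=1e-12)

    def test_invalid_context_rejected(self):
        with pytest.raises(ValueError):
            SampleContext(0.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            intracellular_concentration(1.0, 0.0)


class TestCellVolume:
    def test_cylinder(self):
        assert cell_volume_from_shape(
            "cylinder", diameter=10.0, height=10.0
        ) == pytest.approx(0.7854, abs=1e-4)

    def test_sphere(self):
        volume_pl = cell_volume_from_shape("sphere", diameter=6.0)
        assert volume_pl * 1e3 == pytest.approx(113.10, abs=0.01)

    def test_prolate_spheroid(self):
        assert cell_volume_from_shape(
            "prolate_spheroid", diameter=6.0, length=12.0
        ) == pytest.approx(math.pi * 36 * 12 / 6 * 1e-3, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cell_volume_from_shape("cube", diameter=1.0)
        with pytest.raises(ValueError):
            cell_volume_from_shape("sphere", diameter=-1.0)


class TestRoundTrip:
    def test_noise_free_recovery_within_half_percent(self, cys_analyte,
                                                     fast_settings):
        """Noise-free simulate -> quantify recovers configured fmol/cell to
        within 0.5% (integration tolerance only)."""
        scenario = ScenarioConfig(
            species="rt",
            analytes=(cys_analyte,),
            conditions=(("a", {"cysteinolic acid": 22.3}),),
            replicates=2, biological_cv=0.0, noise=NoiseModel.none(),
            settings=fast_settings, cell_volume_pl=22.3 / 8.0,
        )
        curve = CalibrationCurve(analyte="cysteinolic acid", slope=1.27e7,
                                 r=1.0, residual_sd=0.0, lod_um=0.0,
                                 loq_um=0.0, n_points=5)
        ctx = SampleContext(scenario.cells_filtered,
                            scenario.extract_volume_ml,
                            scenario.dilution_factor,
                            scenario.cell_volume_pl)
        for run, meta in simulate_experiment(scenario, seed=0):
            q = quantify_run(run, cys_analyte, curve, ctx)
            assert q.per_cell_fmol == pytest.approx(22.3, rel=5e-3)
            assert q.intracellular_mm == pytest.approx(8.0, rel=5e-3)
            assert q.flag == CensorFlag.QUANTIFIABLE
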