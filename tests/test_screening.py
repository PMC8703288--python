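"""XIC extraction, feature detection, sulfur flagging, differential screen."""

import dataclasses

import numpy as np
import pytest

from osmoquant.chem import parse_formula
from osmoquant.scenarios import ANALYTES, tw_xenic
from osmoquant.screening import (
    Feature,
    attach_isotopologues,
    detect_features,
    differential_screen,
    extract_xic,
    sulfur_flag,
)
from osmoquant.simulate import (
    AnalyteDef,
    NoiseModel,
    ScenarioConfig,
    simulate_experiment,
    simulate_run,
)


@pytest.fixture(scope="module")
def planted_run(cys_analyte, betaine_analyte, fast_settings):
    """Noisy run with three planted analytes."""
    homarine = AnalyteDef("homarine", parse_formula("C7H7NO2"), rt_min=2.6,
                          response_factor=5.26e8)
    return simulate_run(
        [cys_analyte, betaine_analyte, homarine],
        {"cysteinolic acid": 20.0, "glycine betaine": 5.0, "homarine": 2.0},
        seed=5, settings=fast_settings,
    ), (cys_analyte, betaine_analyte, homarine)


class TestExtractXic:
    def test_single_peak_at_planted_rt(self, planted_run):
        run, (cys, *_ ) = planted_run
        xic = extract_xic(run, cys.mz, tol_ppm=5.0)
        apex = xic.times_min[np.argmax(xic.intensity)]
        assert apex == pytest.approx(cys.rt_min, abs=0.02)

    def test_off_target_window_is_empty(self, cys_analyte, fast_settings,
                                        no_noise):
        run = simulate_run([cys_analyte], {"cysteinolic acid": 10.0},
                           noise=no_noise, seed=0, settings=fast_settings)
        xic = extract_xic(run, 160.0, tol_ppm=5.0)
        assert np.all(xic.intensity == 0)

    def test_coeluting_analytes_50ppm_apart_resolved(self, fast_settings,
                                                     no_noise):
        """Two analytes 50 ppm apart at the same RT: each 5-ppm XIC sees
        only its own analyte."""
        base = AnalyteDef("a", parse_formula("C5H11NO2"), rt_min=1.5,
                          response_factor=1e7)
        shifted_mz = base.mz * (1 + 50e-6)
        run = simulate_run([base], {"a": 10.0}, noise=no_noise, seed=0,
                           settings=fast_settings)
        xic_own = extract_xic(run, base.mz, tol_ppm=5.0)
        xic_other = extract_xic(run, shifted_mz, tol_ppm=5.0)
        assert xic_own.intensity.max() > 0
        assert np.all(xic_other.intensity == 0)

    def test_rejects_bad_tolerance(self, planted_run):
        run, _ = planted_run
        with pytest.raises(ValueError):
            extract_xic(run, 156.0, tol_ppm=0.0)


class TestDetectFeatures:
    def test_recovers_exactly_planted_analytes(self, planted_run):
        """All three planted analytes (and nothing else) survive after
        isotopologue children and noise are filtered out."""
        run, analytes = planted_run
        features = [f for f in detect_features(run) if not f.is_isotopologue]
        assert len(features) == 3
        found = sorted(f.mz for f in features)
        expected = sorted(a.mz for a in analytes)
        np.testing.assert_allclose(found, expected, rtol=1e-6)
        for f in features:
            target = min(analytes, key=lambda a: abs(a.mz - f.mz))
            assert f.rt_min == pytest.approx(target.rt_min, abs=0.02)

    def test_area_matches_xic_integration(self, cys_analyte, fast_settings,
                                          no_noise):
        """Feature area equals direct XIC integration within 1% on a
        noise-free run."""
        run = simulate_run([cys_analyte], {"cysteinolic acid": 10.0},
                           noise=no_noise, seed=0, settings=fast_settings)
        feature = detect_features(run)[0]
        xic = extract_xic(run, cys_analyte.mz)
        from osmoquant.quant import integrate_peak
        direct = integrate_peak(xic, (1.25, 1.75), baseline="none")
        assert feature.area == pytest.approx(direct, rel=0.01)

    def test_below_snr_excluded(self, cys_analyte, fast_settings):
        """An analyte whose apex sits below min_snr x noise floor is not
        reported."""
        noise = NoiseModel(technical_cv=0.02, baseline_rate=3.0,
                           baseline_intensity=5e4)
        tiny = 1e-4  # apex ~ 1e4, below 3x the ~5e4 noise floor
        run = simulate_run([cys_analyte], {"cysteinolic acid": tiny},
                           noise=noise, seed=9, settings=fast_settings)
        features = detect_features(run, min_snr=3.0)
        assert not any(abs(f.mz - cys_analyte.mz) < 0.01 for f in features)

    def test_false_positive_rate_on_pure_noise(self, cys_analyte,
                                               fast_settings):
        """Pure-noise runs yield on average < 1 false feature at S/N 3
        (20 seeds)."""
        noise = NoiseModel(technical_cv=0.02, baseline_rate=2.0)
        total = 0
        for seed in range(20):
            run = simulate_run([cys_analyte], {"cysteinolic acid": 0.0},
                               noise=noise, seed=seed, settings=fast_settings)
            total += len(detect_features(run, min_snr=3.0))
        assert total / 20 < 1.0

    def test_empty_run_yields_no_features(self, cys_analyte, fast_settings):
        run = simulate_run([cys_analyte], {"cysteinolic acid": 0.0},
                           noise=NoiseModel.none(), seed=0,
                           settings=fast_settings)
        assert detect_features(run) == []

    def test_parameter_validation(self, planted_run):
        run, _ = planted_run
        with pytest.raises(ValueError):
            detect_features(run, min_snr=0.0)
        with pytest.raises(ValueError):
            detect_features(run, min_scans=2)


class TestSulfurFlag:
    def test_planted_sulfur_analyte_flagged(self, planted_run):
        run, (cys, *_ ) = planted_run
        features = attach_isotopologues(detect_features(run), run)
        cys_feature = next(f for f in features
                           if abs(f.mz - cys.mz) < 0.01
                           and not f.is_isotopologue)
        m2 = [e for e in cys_feature.envelope if e[0] > 1.5]
        assert m2 and m2[0][1] == pytest.approx(0.045, abs=0.005)
        assert sulfur_flag(cys_feature)

    def test_sulfur_free_analyte_not_flagged(self, planted_run):
        run, (_, betaine, _) = planted_run
        features = attach_isotopologues(detect_features(run), run)
        bet_feature = next(f for f in features
                           if abs(f.mz - betaine.mz) < 0.01
                           and not f.is_isotopologue)
        assert not sulfur_flag(bet_feature)
        m2 = [e for e in bet_feature.envelope
              if abs(e[0] - 1.9958) < 0.0005]
        assert not m2 or m2[0][1] < 0.01

    def test_carbon_only_m2_rejected(self):
        """An M+2 from two 13C (wrong spacing, low abundance) is not a
        sulfur signature."""
        feature = Feature(mz=150.0, rt_min=1.0, area=1.0, snr=10.0,
                          height=1.0, t_left=0.9, t_right=1.1,
                          envelope=((0.0, 1.0), (2.00671, 0.005)))
        assert not sulfur_flag(feature)

    @pytest.mark.parametrize("scale", [1e-3, 1.0, 1e6])
    def test_invariant_to_intensity_scaling(self, scale):
        """The flag depends only on envelope ratios, not absolute signal."""
        feature = Feature(mz=156.03, rt_min=1.0, area=scale, snr=10.0,
                          height=scale, t_left=0.9, t_right=1.1,
                          envelope=((0.0, 1.0), (1.99580, 0.0447)))
        assert sulfur_flag(feature)

    def test_bare_feature_unflagged(self):
        feature = Feature(mz=156.03, rt_min=1.0, area=1.0, snr=1.0,
                          height=1.0, t_left=0.9, t_right=1.1)
        assert not sulfur_flag(feature)


def _feature_tables(scenario, seed, conditions):
    by_condition = {}
    for run, meta in simulate_experiment(scenario, seed=seed):
        feats = attach_isotopologues(detect_features(run), run)
        by_condition.setdefault(meta["condition"], []).append(feats)
    return [by_condition[c] for c in conditions]


class TestDifferentialScreen:
    def test_mining_fixture_returns_exactly_cysteinolic_acid(self):
        """On the salinity fixture the only up-regulated, sulfur-flagged
        candidate is the cysteinolic acid feature."""
        low, high = _feature_tables(tw_xenic(), 5, ["35 PSU", "50 PSU"])
        candidates = differential_screen(low, high, fc_min=1.5, p_max=0.05)
        assert len(candidates) == 1
        hit = candidates[0]
        assert hit.mz == pytest.approx(ANALYTES["cysteinolic acid"].mz,
                                       abs=0.001)
        assert hit.sulfur
        assert hit.fold_change == pytest.approx(2.4, rel=0.25)

    def test_equal_abundance_feature_absent(self, cys_analyte, fast_settings):
        scenario = ScenarioConfig(
            species="flat",
            analytes=(cys_analyte,),
            conditions=(("lo", {"cysteinolic acid": 20.0}),
                        ("hi", {"cysteinolic acid": 20.0})),
            replicates=3, biological_cv=0.05, settings=fast_settings,
        )
        low, high = _feature_tables(scenario, 2, ["lo", "hi"])
        assert differential_screen(low, high) == []

    def test_single_replicate_skips_test(self, cys_analyte, fast_settings):
        scenario = ScenarioConfig(
            species="n1",
            analytes=(cys_analyte,),
            conditions=(("lo", {"cysteinolic acid": 10.0}),
                        ("hi", {"cysteinolic acid": 40.0})),
            replicates=1, biological_cv=0.0, settings=fast_settings,
        )
        low, high = _feature_tables(scenario, 2, ["lo", "hi"])
        candidates = differential_screen(low, high)
        assert len(candidates) == 1
        assert candidates[0].test_skipped
        assert np.isnan(candidates[0].p_value)

    def test_recall_on_upregulated_feature(self, cys_analyte, fast_settings):
        """A true 2.4-fold change at 10% CV, N=3 is recovered in most
        seeds (Monte-Carlo power check)."""
        scenario = ScenarioConfig(
            species="up",
            analytes=(cys_analyte,),
            conditions=(("lo", {"cysteinolic acid": 20.0}),
                        ("hi", {"cysteinolic acid": 48.0})),
            replicates=3, biological_cv=0.10, settings=fast_settings,
        )
        hits = 0
        for seed in range(10):
            low, high = _feature_tables(scenario, seed, ["lo", "hi"])
            candidates = differential_screen(low, high)
            hits += any(abs(c.mz - cys_analyte.mz) < 0.01 for c in candidates)
        assert hits >= 8
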