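"""Validation statistics: T, Fm, ccβ, precision limits, stability, ruggedness."""

import math
import statistics

import numpy as np
import pytest

from milkscreen.quantify import fit_calibration
from milkscreen.simulate import NoiseModel, gen_blank_run, gen_validation_study
from milkscreen.validation import (
    BlankStats,
    SpikeStats,
    assess_ccbeta,
    cutoff_factor,
    cv_within_lab,
    horwitz_cv,
    max_allowed_cv,
    ruggedness_ttest,
    run_validation,
    specificity_check,
    stability_assess,
    threshold_value,
)

LEVELS = (0.1, 0.5, 1.0, 5.0, 10.0)


class TestThresholdValue:
    @pytest.mark.parametrize(
        "readings, expected",
        [
            ([0.0, 0.0, 0.0], 0.0),
            ([1.0, 2.0, 3.0], 3.64),     # B = 2, sample SD = 1
            ([5.0, 5.0, 5.0, 5.0], 5.0),
        ],
    )
    def test_hand_values(self, readings, expected):
        assert threshold_value(BlankStats.from_readings(readings)) == \
            pytest.approx(expected, abs=1e-12)

    def test_single_reading_rejected(self):
        with pytest.raises(ValueError, match="2 replicates"):
            BlankStats.from_readings([1.0])


class TestCutoffFactor:
    def test_hand_value(self):
        # mean 50, sample SD 2 -> 50 - 1.64 * 2
        assert cutoff_factor(SpikeStats.from_readings([48.0, 50.0, 52.0])) == \
            pytest.approx(46.72, abs=1e-12)

    def test_constant_spikes(self):
        assert cutoff_factor(SpikeStats.from_readings([50.0] * 5)) == 50.0

    def test_negative_cutoff_warns(self):
        noisy = SpikeStats.from_readings([1.0, 100.0, 1.0, 100.0])
        with pytest.warns(UserWarning, match="negative"):
            assert cutoff_factor(noisy) < 0


class TestOracleEquivalence:
    def test_against_independent_mean_sd_on_random_vectors(self):
        """T and Fm equal brute-force mean/SD formulas (statistics module)."""
        import warnings

        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(2, 51))
            x = rng.normal(rng.uniform(0, 100), rng.uniform(0.1, 20), n)
            data = [float(v) for v in x]
            mean = statistics.fmean(data)
            sd = statistics.stdev(data)
            t = threshold_value(BlankStats.from_readings(data))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fm = cutoff_factor(SpikeStats.from_readings(data))
            assert t == pytest.approx(mean + 1.64 * sd, rel=1e-12)
            assert fm == pytest.approx(mean - 1.64 * sd, rel=1e-12)


class TestAssessCcbeta:
    def test_pass_when_cutoff_clears_threshold(self):
        ok, msg = assess_ccbeta(3.64, 46.72, 50.0)
        assert ok and "ccβ <= STC" in msg

    def test_fail_when_threshold_wins(self):
        ok, msg = assess_ccbeta(50.0, 46.72, 50.0)
        assert not ok and "new experiments" in msg

    def test_tie_fails_strictly(self):
        ok, _ = assess_ccbeta(10.0, 10.0, 50.0)
        assert not ok

    def test_monotone_in_cutoff(self):
        passes = [assess_ccbeta(10.0, fm, 50.0)[0]
                  for fm in (5.0, 10.0, 10.1, 20.0)]
        assert passes == sorted(passes)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            assess_ccbeta(math.nan, 1.0, 50.0)


class TestPrecision:
    @pytest.mark.parametrize(
        "readings, expected_cv",
        [
            ([50.0] * 5, 0.0),
            ([4.0 - 0.648, 4.0, 4.0 + 0.648], None),  # SD/M = 0.648/4
        ],
    )
    def test_cv_within_lab(self, readings, expected_cv):
        stats = SpikeStats.from_readings(readings)
        if expected_cv is None:
            assert cv_within_lab(stats) == pytest.approx(16.2, abs=0.01)
        else:
            assert cv_within_lab(stats) == expected_cv

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            cv_within_lab(SpikeStats.from_readings([0.0, 0.0]))

    @pytest.mark.parametrize(
        "mass_fraction, expected",
        [(1.0, 2.0), (0.01, 4.0), (1e-7, 22.627)],
    )
    def test_horwitz_values(self, mass_fraction, expected):
        assert horwitz_cv(mass_fraction) == pytest.approx(expected, abs=1e-3)

    def test_horwitz_quarters_every_four_decades(self):
        for c in (1e-9, 1e-7, 1e-4):
            assert horwitz_cv(c * 1e4) == pytest.approx(horwitz_cv(c) / 4,
                                                        rel=1e-12)

    @pytest.mark.parametrize(
        "stc, limit", [(4.0, 30.0), (9.99, 30.0), (10.0, 25.0), (50.0, 25.0),
                       (119.9, 25.0)],
    )
    def test_guide_values(self, stc, limit):
        assert max_allowed_cv(stc) == limit

    def test_horwitz_applies_above_guide_range(self):
        assert max_allowed_cv(200.0) == pytest.approx(
            horwitz_cv(200e-9), rel=1e-12
        )

    def test_every_panel_cv_sits_below_its_limit(self, db):
        for c in db:
            assert c.cv_r is not None
            assert 100 * c.cv_r < max_allowed_cv(c.stc), c.name


class TestSpecificity:
    def test_clean_blanks_pass_everywhere(self, db):
        noise = NoiseModel(blank_false_rate=0.0)
        blanks = [gen_blank_run(db, noise, seed=s) for s in range(5)]
        counts = specificity_check(blanks, db)
        assert set(counts.values()) == {0}

    def test_injected_coeluting_ion_is_counted(self, db):
        from milkscreen.identify import FeatureObservation

        noise = NoiseModel(blank_false_rate=0.0)
        blanks = [gen_blank_run(db, noise, seed=s) for s in range(3)]
        amox = db["Amoxicillin"]
        blanks[1].features.append(
            FeatureObservation(amox.precursor_mz, amox.expected_rt, 500.0)
        )
        counts = specificity_check(blanks, db)
        assert counts["Amoxicillin"] == 1
        assert sum(counts.values()) == 1

    def test_feature_outside_rt_window_not_counted(self, db):
        from milkscreen.identify import FeatureObservation

        noise = NoiseModel(blank_false_rate=0.0)
        blanks = [gen_blank_run(db, noise, seed=s) for s in range(3)]
        amox = db["Amoxicillin"]
        blanks[1].features.append(
            FeatureObservation(amox.precursor_mz, amox.expected_rt * 1.10,
                               500.0)
        )
        assert specificity_check(blanks, db)["Amoxicillin"] == 0

    def test_no_blanks_rejected(self, db):
        with pytest.raises(ValueError):
            specificity_check([], db)


def _line(slope, intercept, r2_perfect=True, noise=0.0):
    rng = np.random.default_rng(5)
    responses = [slope * x + intercept + (rng.normal(0, noise) if noise else 0)
                 for x in LEVELS]
    return fit_calibration(LEVELS, responses)


class TestStability:
    def test_identical_curves_pass_with_zero_drift(self):
        curves = [_line(5000.0, 50.0) for _ in range(4)]
        record = stability_assess(curves)
        assert record.all_pass
        assert record.yx_rel_change == [0.0] * 4

    def test_yx_drift_beyond_20_percent_fails(self):
        curves = [_line(5000.0, 50.0), _line(5000.0, 62.5)]  # +25% y/x
        record = stability_assess(curves)
        assert record.passed == [True, False]
        assert record.yx_rel_change[1] == pytest.approx(0.25, abs=1e-9)

    def test_poor_linearity_fails(self):
        good = _line(5000.0, 50.0)
        noisy = _line(5000.0, 50.0, noise=2500.0)
        assert noisy.r2 < 0.999
        record = stability_assess([good, noisy])
        assert record.linearity_ok == [True, False]
        assert record.passed[1] is False

    def test_drift_at_exactly_20_percent_passes(self):
        curves = [_line(5000.0, 50.0), _line(5000.0, 60.0)]  # +20% inclusive
        assert stability_assess(curves).all_pass

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            stability_assess([])


class TestRuggedness:
    def test_identical_groups_not_significant(self):
        res = ruggedness_ttest([50.0, 51.0, 49.0], [50.0, 51.0, 49.0])
        assert res.t_stat == 0.0 and not res.significant

    def test_constant_equal_groups_give_t_zero(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = ruggedness_ttest([50.0, 50.0], [50.0, 50.0])
        assert res.t_stat == 0.0 and res.p_value == 1.0

    def test_shifted_groups_significant_with_hand_computed_t(self):
        # Welch: means 50 vs 55, sample variances 0.5 each, n = 5
        # t = -5 / sqrt(0.5/5 + 0.5/5) = -11.1803
        res = ruggedness_ttest([49.0, 50.0, 51.0, 50.0, 50.0],
                               [54.0, 55.0, 56.0, 55.0, 55.0])
        assert res.t_stat == pytest.approx(-5 / math.sqrt(0.2), rel=1e-12)
        assert res.significant

    def test_tiny_alpha_turns_significance_off(self):
        res = ruggedness_ttest([49.0, 50.0, 51.0, 50.0, 50.0],
                               [54.0, 55.0, 56.0, 55.0, 55.0], alpha=1e-9)
        assert not res.significant

    def test_single_reading_groups_rejected(self):
        with pytest.raises(ValueError):
            ruggedness_ttest([50.0], [51.0, 52.0])


class TestRunValidation:
    def test_default_study_passes_panel_wide(self, db):
        study = gen_validation_study(db, seed=42)
        report = run_validation(study, db)
        assert len(report.verdicts) == 57
        assert report.all_pass
        for v in report:
            assert v.cutoff > v.threshold
            assert v.cutoff < v.stc  # Fm = M - 1.64 SD sits below the spike level

    def test_zero_spike_study_fails_everywhere(self, db):
        study = gen_validation_study(
            db, seed=42, spike_levels={c.name: 0.0 for c in db}
        )
        report = run_validation(study, db)
        assert not any(v.passed for v in report)

    def test_same_seed_same_report(self, db):
        r1 = run_validation(gen_validation_study(db, seed=9), db)
        r2 = run_validation(gen_validation_study(db, seed=9), db)
        for v1, v2 in zip(r1, r2):
            assert (v1.threshold, v1.cutoff, v1.cv_r_pct) == \
                (v2.threshold, v2.cutoff, v2.cv_r_pct)

    def test_too_small_study_rejected(self, db):
        study = gen_validation_study(db, seed=1, n_sheep=1, n_cow=1, n_goat=0)
        study.blank_runs = study.blank_runs[:1]
        with pytest.raises(ValueError):
            run_validation(study, db)


class TestFalseNegativeQuantile:
    def test_five_percent_of_true_spikes_fall_below_fm(self):
        """Fm from the true normal parameters leaves ~Φ(-1.64) = 5.05%
        of spiked samples below the cut-off."""
        rng = np.random.default_rng(31)
        mean, cv = 50.0, 0.10
        fm = mean - 1.64 * cv * mean
        from milkscreen.simulate import draw_concentration_readings

        reads = draw_concentration_readings(rng, mean, cv, 100_000)
        frac = float((reads < fm).mean())
        assert 0.045 <= frac <= 0.056
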