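"""Generator behaviour: schedules, covariates, class assignment, trajectories."""

import io

import numpy as np
import pytest

import respmix as rm
from respmix.synthetic_cohort import (
    assign_classes,
    sample_covariates,
    sample_schedule,
    simulate_trajectories,
)
from respmix.trial_data import impute_covariates, standardize_covariates, write_long_csv

from conftest import RECOVERY_SPECS, make_separated_config


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestSchedule:
    def test_degenerate_duration_range(self):
        cfg = rm.GeneratorConfig(seed=0, n_subjects=20, duration_range=(5.0, 5.0),
                                 max_occasions=6)
        for times in sample_schedule(cfg, _rng(1)):
            assert times[-1] == pytest.approx(5.0)

    def test_total_dropout_leaves_two_occasions(self):
        cfg = rm.GeneratorConfig(seed=0, n_subjects=30, dropout_hazard=1.0)
        assert all(len(ts) == 2 for ts in sample_schedule(cfg, _rng(2)))

    def test_default_span_matches_truncated_normal_mean(self):
        # Monte-Carlo check of the truncated-normal duration model
        cfg = rm.GeneratorConfig(seed=0, n_subjects=82)
        spans = [ts[-1] for ts in sample_schedule(cfg, _rng(3))]
        assert 8.3 <= np.mean(spans) <= 10.9

    def test_grids_start_at_zero_and_increase(self):
        cfg = rm.GeneratorConfig(seed=0, n_subjects=25)
        for ts in sample_schedule(cfg, _rng(4)):
            assert ts[0] == 0.0
            assert np.all(np.diff(ts) > 0)
            assert len(ts) <= cfg.max_occasions


class TestCovariates:
    def test_binary_p_one_is_all_ones(self):
        cfg = rm.GeneratorConfig(
            seed=0, n_subjects=40,
            covariate_specs=[rm.CovariateSpec("m", "binary", p=1.0)],
        )
        table = sample_covariates(cfg, _rng(0))
        np.testing.assert_array_equal(table.column("m"), 1.0)

    def test_missingness_rate_recovered(self):
        cfg = rm.GeneratorConfig(
            seed=0, n_subjects=1000,
            covariate_specs=[rm.CovariateSpec("x", "continuous", mean=0, sd=1,
                                              missing_rate=0.1)],
        )
        table = sample_covariates(cfg, _rng(5))
        frac = np.mean(np.isnan(table.column("x")))
        assert 0.07 <= frac <= 0.13

    def test_default_female_fraction(self):
        cfg = rm.GeneratorConfig(seed=0, n_subjects=4000)
        table = sample_covariates(cfg, _rng(6))
        assert abs(np.nanmean(table.column("gender_female")) - 0.73) < 0.03

    def test_bad_probability_rejected(self):
        with pytest.raises(ValueError):
            rm.CovariateSpec("m", "binary", p=1.5)


class TestAssignClasses:
    def _table(self, n, rng):
        cfg = rm.GeneratorConfig(seed=0, n_subjects=n, covariate_specs=RECOVERY_SPECS)
        table = sample_covariates(cfg, rng)
        std, _ = standardize_covariates(table)
        return impute_covariates(std, "mean"), cfg

    def test_neutral_intercept_gives_half(self):
        std, _ = self._table(4000, _rng(7))
        cfg = rm.GeneratorConfig(seed=0, n_subjects=4000, responder_intercept=0.0,
                                 covariate_specs=RECOVERY_SPECS)
        labels, probs = assign_classes(std, cfg, _rng(8))
        np.testing.assert_allclose(probs, 0.5)
        assert abs(labels.mean() - 0.5) < 0.03

    def test_log3_intercept_gives_three_quarters_exactly(self):
        std, _ = self._table(50, _rng(9))
        cfg = rm.GeneratorConfig(seed=0, n_subjects=50,
                                 responder_intercept=float(np.log(3)),
                                 covariate_specs=RECOVERY_SPECS)
        _, probs = assign_classes(std, cfg, _rng(10))
        np.testing.assert_allclose(probs, 0.75)

    def test_saturating_coefficient(self):
        std, _ = self._table(200, _rng(11))
        cfg = rm.GeneratorConfig(seed=0, n_subjects=200, responder_intercept=0.0,
                                 true_beta={"marital": 20.0},
                                 covariate_specs=RECOVERY_SPECS)
        labels, probs = assign_classes(std, cfg, _rng(12))
        carriers = std.column("marital") > 0
        assert labels[carriers].all()

    def test_missing_values_rejected(self):
        cfg = rm.GeneratorConfig(seed=0, n_subjects=10,
                                 true_beta={"swls": 1.0},
                                 covariate_specs=[rm.CovariateSpec(
                                     "swls", "continuous", mean=0, sd=1, missing_rate=0.15)])
        table = sample_covariates(cfg, _rng(20))
        assert np.isnan(table.column("swls")).any()
        with pytest.raises(rm.ValidationError, match="impute"):
            assign_classes(table, cfg, _rng(21))

    def test_fraction_converges_to_logistic_expectation(self):
        cfg = make_separated_config(seed=99, n=5000)
        _, truth = rm.generate(cfg)
        expected = truth.responder_probs.mean()
        se = np.sqrt(expected * (1 - expected) / 5000)
        assert abs(truth.responder_fraction - expected) < 3 * se


class TestTrajectories:
    def test_flat_class_scores_equal_rounded_baseline(self):
        cfg = rm.GeneratorConfig(seed=0, n_subjects=15, residual_sd=1e-9,
                                 nonresponder_decay_mean=0.0, nonresponder_decay_sd=1e-9,
                                 covariate_specs=RECOVERY_SPECS)
        rng = _rng(13)
        schedules = sample_schedule(cfg, rng)
        cov = sample_covariates(cfg, rng)
        labels = np.zeros(15, dtype=bool)  # all nonresponders
        ds, truth = simulate_trajectories(labels, schedules, cov, cfg, rng)
        for i, s in enumerate(ds.series):
            np.testing.assert_array_equal(s.scores, np.round(truth.subject_params["b0"][i]))

    def test_half_life_closed_form(self):
        # baseline 20, decay ln2/5: after 5 weeks the expected score halves
        cfg = rm.GeneratorConfig(seed=0, n_subjects=5, residual_sd=1e-9,
                                 baseline_mean=20.0, baseline_sd=1e-9,
                                 responder_decay_mean=float(np.log(2) / 5),
                                 responder_decay_sd=1e-12,
                                 covariate_specs=RECOVERY_SPECS)
        rng = _rng(14)
        schedules = [np.array([0.0, 5.0])] * 5
        cov = sample_covariates(cfg, rng)
        labels = np.ones(5, dtype=bool)
        ds, _ = simulate_trajectories(labels, schedules, cov, cfg, rng)
        for s in ds.series:
            assert s.scores[0] == 20
            assert s.scores[1] == 10

    @pytest.mark.parametrize("seed", [1, 17, 123])
    def test_scores_and_baselines_bounded(self, seed):
        ds, truth = rm.generate(rm.GeneratorConfig(seed=seed, n_subjects=40,
                                                   covariate_specs=RECOVERY_SPECS))
        b0 = truth.subject_params["b0"]
        assert np.all((b0 >= 10) & (b0 <= 40))
        for s in ds.series:
            assert np.all((s.scores >= 0) & (s.scores <= 63))


class TestGenerate:
    def test_same_seed_byte_identical(self):
        cfg = rm.GeneratorConfig(seed=42, n_subjects=25)
        buf = []
        for _ in range(2):
            ds, _ = rm.generate(cfg)
            b = io.StringIO()
            write_long_csv(ds, b)
            buf.append(b.getvalue())
        assert buf[0] == buf[1]

    def test_default_config_shape(self):
        ds, _ = rm.generate(rm.GeneratorConfig(seed=1))
        assert ds.n_subjects == 82
        assert all(len(s) >= 2 for s in ds.series)

    def test_empty_cohort(self):
        ds, truth = rm.generate(rm.GeneratorConfig(seed=1, n_subjects=0))
        assert ds.n_subjects == 0
        assert truth.class_labels == []

    def test_emitted_datasets_pass_validation(self):
        for seed in (3, 5):
            ds, _ = rm.generate(rm.GeneratorConfig(seed=seed, n_subjects=60,
                                                   covariate_specs=RECOVERY_SPECS))
            ds.validate()  # raises on failure

    def test_classes_separable_in_observed_change(self, separated_cohort):
        # precondition for mixture identifiability: last-minus-first change
        # separates the true classes almost perfectly
        from sklearn.metrics import roc_auc_score

        ds, truth = separated_cohort
        change = np.array([s.scores[0] - s.scores[-1] for s in ds.series])
        labels = np.array([c == "responder" for c in truth.class_labels])
        assert roc_auc_score(labels, change) > 0.9
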