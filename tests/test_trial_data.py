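"""Domain types, CSV IO, validation, standardization, imputation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import respmix as rm
from respmix.trial_data import (
    CovariateTable,
    FormatError,
    MeasurementSeries,
    StudyDataset,
    ValidationError,
    impute_covariates,
    read_covariates_csv,
    read_long_csv,
    standardize_covariates,
    write_covariates_csv,
    write_long_csv,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestMeasurementSeries:
    def test_valid_construction(self):
        s = MeasurementSeries("s1", [0.0, 1.5, 3.0], [21, 18, 15])
        assert len(s) == 3

    @pytest.mark.parametrize(
        "times, scores, message",
        [
            ([0.0, 1.0], [21, 70], "out of range"),
            ([0.0, 1.0, 1.0], [20, 19, 18], "strictly increasing"),
            ([1.0, 2.0], [20, 19], "first time"),
            ([0.0], [20], "at least 2"),
            ([0.0, 1.0], [20.5, 19], "integers"),
        ],
    )
    def test_invariant_violations(self, times, scores, message):
        with pytest.raises(ValidationError, match=message):
            MeasurementSeries("s1", times, scores)


class TestLongCsv:
    def test_read_groups_and_sorts(self, tmp_path):
        p = _write(tmp_path, "scores.csv",
                   "subject,time_weeks,bdi2\ns1,0,21\ns1,1,18\ns2,0,30\ns2,2,25\n")
        ds = read_long_csv(p)
        assert ds.n_subjects == 2
        assert all(len(s) == 2 for s in ds.series)

    def test_score_out_of_range_names_subject(self, tmp_path):
        p = _write(tmp_path, "bad.csv", "subject,time_weeks,bdi2\ns1,0,70\ns1,1,20\n")
        with pytest.raises(ValidationError, match="s1.*out of range"):
            read_long_csv(p)

    def test_duplicate_times_rejected(self, tmp_path):
        p = _write(tmp_path, "dup.csv", "subject,time_weeks,bdi2\ns1,0,21\ns1,1,20\ns1,1,19\n")
        with pytest.raises(ValidationError, match="strictly increasing"):
            read_long_csv(p)

    def test_missing_column_is_format_error(self, tmp_path):
        p = _write(tmp_path, "cols.csv", "subject,week,bdi2\ns1,0,21\n")
        with pytest.raises(FormatError, match="time_weeks"):
            read_long_csv(p)

    def test_round_trip_identity(self, tmp_path):
        cfg = rm.GeneratorConfig(seed=3, n_subjects=12)
        ds, _ = rm.generate(cfg)
        p = tmp_path / "rt.csv"
        write_long_csv(ds, p)
        back = read_long_csv(p)
        assert back.subject_ids == ds.subject_ids
        for a, b in zip(ds.series, back.series):
            np.testing.assert_array_equal(a.scores, b.scores)
            np.testing.assert_array_equal(a.times, b.times)  # full precision


class TestCovariatesCsv:
    def test_read_with_kinds(self, tmp_path):
        rows = "".join(f"s{i},1,{10 + i}\n" for i in range(9))
        p = _write(tmp_path, "cov.csv", "subject,marital,swls\n" + rows + "s9,0,\n")
        table = read_covariates_csv(p, kinds={"marital": "binary", "swls": "continuous"})
        assert table.values.shape == (10, 2)
        assert np.isnan(table.column("swls")[9])  # empty cell is missing, not 0

    def test_invalid_binary_value(self, tmp_path):
        p = _write(tmp_path, "cov.csv", "subject,marital\ns1,2\n")
        with pytest.raises(ValidationError, match="marital"):
            read_covariates_csv(p, kinds={"marital": "binary"})

    def test_uncovered_column_is_format_error(self, tmp_path):
        p = _write(tmp_path, "cov.csv", "subject,marital,extra\ns1,1,2\n")
        with pytest.raises(FormatError, match="extra"):
            read_covariates_csv(p, kinds={"marital": "binary"})

    def test_round_trip(self, tmp_path):
        vals = np.column_stack([np.arange(10) % 2.0, np.linspace(8, 25, 10)])
        vals[4, 1] = np.nan
        table = CovariateTable(
            [f"s{i}" for i in range(10)], ["marital", "swls"],
            {"marital": "binary", "swls": "continuous"}, vals,
        )
        p = tmp_path / "cov.csv"
        write_covariates_csv(table, p)
        back = read_covariates_csv(p, kinds=table.kinds)
        np.testing.assert_array_equal(back.values, table.values)

    def test_excess_missingness_is_hard_error(self):
        vals = np.full((10, 1), 1.0)
        vals[:3, 0] = np.nan  # 30% missing
        table = CovariateTable(list("abcdefghij"), ["x"], {"x": "continuous"}, vals)
        with pytest.raises(ValidationError, match="missingness"):
            table.validate()


class TestStandardize:
    def test_continuous_zscore(self):
        table = CovariateTable(["a", "b", "c"], ["x"], {"x": "continuous"},
                               np.array([[1.0], [2.0], [3.0]]))
        out, rec = standardize_covariates(table)
        np.testing.assert_allclose(out.column("x"), [-1.2247448, 0.0, 1.2247448], atol=1e-6)
        np.testing.assert_allclose(rec.invert("x", out.column("x")), [1, 2, 3], atol=1e-12)

    def test_binary_centered_only(self):
        table = CovariateTable(["a", "b", "c"], ["m"], {"m": "binary"},
                               np.array([[0.0], [1.0], [1.0]]))
        out, rec = standardize_covariates(table)
        np.testing.assert_allclose(out.column("m"), [-2 / 3, 1 / 3, 1 / 3])
        assert rec.scale["m"] == 1.0

    def test_constant_column_errors(self):
        table = CovariateTable(["a", "b"], ["x"], {"x": "continuous"},
                               np.array([[5.0], [5.0]]))
        with pytest.raises(ValidationError, match="x.*zero variance"):
            standardize_covariates(table)

    def test_means_zero_sds_one(self):
        rng = np.random.default_rng(0)
        vals = np.column_stack([rng.normal(10, 3, 50), rng.integers(0, 2, 50).astype(float)])
        vals[3, 0] = np.nan
        table = CovariateTable([f"s{i}" for i in range(50)], ["x", "m"],
                               {"x": "continuous", "m": "binary"}, vals)
        out, _ = standardize_covariates(table)
        x = out.column("x")
        assert abs(np.nanmean(x)) < 1e-10
        assert abs(np.nanstd(x) - 1.0) < 1e-10
        assert abs(np.nanmean(out.column("m"))) < 1e-10


class TestImpute:
    def test_mean_fills_with_zero_after_standardization(self):
        table = CovariateTable(["a", "b", "c"], ["x"], {"x": "continuous"},
                               np.array([[-1.0], [np.nan], [1.0]]))
        out = impute_covariates(table, "mean")
        np.testing.assert_allclose(out.column("x"), [-1.0, 0.0, 1.0])

    def test_none_is_identity(self):
        table = CovariateTable(["a", "b"], ["x"], {"x": "continuous"},
                               np.array([[1.0], [np.nan]]))
        out = impute_covariates(table, "none")
        np.testing.assert_array_equal(out.values, table.values)

    def test_all_missing_errors(self):
        table = CovariateTable(["a", "b"], ["x"], {"x": "continuous"},
                               np.full((2, 1), np.nan))
        with pytest.raises(ValidationError, match="all values missing"):
            impute_covariates(table, "mean")


class TestDatasetConsistency:
    def test_id_mismatch_rejected(self):
        series = [MeasurementSeries("s1", [0, 1], [20, 18])]
        cov = CovariateTable(["s2"], ["x"], {"x": "continuous"}, np.array([[1.0]]))
        with pytest.raises(ValidationError, match="differ"):
            StudyDataset(series=series, covariates=cov)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_fuzzed_corruptions_rejected(self, data):
        """Any corruption of a valid series (shuffled times, bad score) fails."""
        n = data.draw(st.integers(3, 8))
        times = np.cumsum(np.r_[0.0, data.draw(
            st.lists(st.floats(0.1, 5.0), min_size=n - 1, max_size=n - 1))])
        scores = data.draw(st.lists(st.integers(0, 63), min_size=n, max_size=n))
        kind = data.draw(st.sampled_from(["shuffle", "score_high", "score_low", "neg_time"]))
        times, scores = list(times), list(scores)
        if kind == "shuffle":
            times = times[::-1]
        elif kind == "score_high":
            scores[data.draw(st.integers(0, n - 1))] = 64
        elif kind == "score_low":
            scores[data.draw(st.integers(0, n - 1))] = -1
        else:
            times[0] = -1.0
        with pytest.raises(ValidationError):
            MeasurementSeries("s", times, scores)
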