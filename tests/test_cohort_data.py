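import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from aaarisk import (
    NormalizationStats,
    forward_feature_selection,
    preprocess,
    read_cohort,
    spearman_correlations,
    write_cohort,
)
from aaarisk.cohort_data import (
    FEATURE_COLUMNS,
    CohortAlignmentError,
    CohortParseError,
    EmptyCohortError,
)
from conftest import make_dataset


def _write_pair(tmp_path, ids, features, properties):
    feat = pd.DataFrame(features, columns=FEATURE_COLUMNS[: np.shape(features)[1]])
    feat.insert(0, "patient_id", ids)
    prop = pd.DataFrame(properties, columns=["t", "alpha", "beta", "sigma_gamma"])
    prop.insert(0, "patient_id", ids)
    fp, pp = tmp_path / "s2.csv", tmp_path / "s3.csv"
    feat.to_csv(fp, index=False)
    prop.to_csv(pp, index=False)
    return fp, pp


class TestReadCohort:
    def test_reads_paired_tables_preserving_patient_grouping(self, tmp_path):
        fp, pp = _write_pair(
            tmp_path, [1, 1, 2], np.ones((3, 8)), np.full((3, 4), 2.0)
        )
        ds = read_cohort(fp, pp)
        assert ds.n_records == 3
        assert ds.n_patients == 2
        assert list(ds.records_of(1)) == [0, 1]

    def test_mismatched_patient_indices_raise_alignment_error(self, tmp_path):
        fp, pp = _write_pair(tmp_path, [1, 2], np.ones((2, 8)), np.ones((2, 4)))
        prop = pd.read_csv(pp)
        prop.loc[1, "patient_id"] = 3
        prop.to_csv(pp, index=False)
        with pytest.raises(CohortAlignmentError, match="row 1"):
            read_cohort(fp, pp)

    def test_mismatched_row_counts_raise_alignment_error(self, tmp_path):
        fp, pp = _write_pair(tmp_path, [1, 1, 2], np.ones((3, 8)), np.ones((3, 4)))
        pd.read_csv(pp).iloc[:2].to_csv(pp, index=False)
        with pytest.raises(CohortAlignmentError, match="row-count"):
            read_cohort(fp, pp)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        fp, pp = _write_pair(tmp_path, [1, 2], np.ones((2, 8)), np.ones((2, 4)))
        feat = pd.read_csv(fp).astype(object)
        feat.loc[1, "hemoglobin"] = "low"
        feat.to_csv(fp, index=False)
        with pytest.raises(CohortParseError, match="row 1.*'hemoglobin'"):
            read_cohort(fp, pp)

    def test_round_trip_is_bit_identical_for_finite_values(self, tmp_path, small_cohort):
        write_cohort(small_cohort, tmp_path / "a.csv", tmp_path / "b.csv")
        back = read_cohort(tmp_path / "a.csv", tmp_path / "b.csv")
        again = tmp_path / "a2.csv", tmp_path / "b2.csv"
        write_cohort(back, *again)
        assert (tmp_path / "a.csv").read_text() == again[0].read_text()
        assert (tmp_path / "b.csv").read_text() == again[1].read_text()


class TestPreprocess:
    def _toy(self, missing_rows, n=10):
        feats = np.arange(n * 5, dtype=float).reshape(n, 5) + 1
        feats[missing_rows, 0] = np.nan
        props = np.full((n, 4), 2.0)
        return make_dataset(feats, props)

    def test_feature_above_threshold_is_dropped(self):
        ds = self._toy(missing_rows=[0, 1, 2, 3])  # 40% missing
        out, _ = preprocess(ds)
        assert FEATURE_COLUMNS[0] not in out.features.columns
        assert out.n_records == 10

    def test_missing_cells_imputed_with_observed_median(self):
        ds = self._toy(missing_rows=[0, 1])  # 20%: kept, imputed
        observed = ds.features[FEATURE_COLUMNS[0]].dropna()
        median = float(np.median(observed))
        out, stats_ = preprocess(ds)
        assert stats_.median[FEATURE_COLUMNS[0]] == pytest.approx(median)
        # imputed cells sit exactly at the (normalized) median
        z_med = (median - stats_.mean[FEATURE_COLUMNS[0]]) / stats_.scale[FEATURE_COLUMNS[0]]
        assert out.features.iloc[0, 0] == pytest.approx(z_med)

    def test_record_missing_too_many_features_is_dropped(self):
        feats = np.ones((10, 4)) * np.arange(1, 11)[:, None]
        feats[3, :2] = np.nan  # 50% of surviving features missing
        ds = make_dataset(feats, np.full((10, 4), 2.0))
        out, _ = preprocess(ds)
        assert out.n_records == 9
        assert 4 not in out.patient_ids  # patient 4 (row 3) removed

    def test_complete_dataset_yields_standardized_columns(self, small_cohort):
        out, _ = preprocess(small_cohort)
        mat = out.feature_matrix()
        assert np.abs(mat.mean(axis=0)).max() < 1e-10
        assert np.abs(mat.std(axis=0, ddof=0) - 1).max() < 1e-10

    def test_preprocess_is_idempotent(self, small_cohort):
        once, _ = preprocess(small_cohort)
        twice, _ = preprocess(once)
        np.testing.assert_allclose(
            twice.feature_matrix(), once.feature_matrix(), atol=1e-12
        )

    def test_all_records_dropped_raises_empty_cohort(self):
        # each feature 50% missing (kept at threshold 0.6), every record
        # missing 50% of surviving features (> 0.3) -> cohort empties
        feats = np.arange(8, dtype=float).reshape(4, 2) + 1
        feats[::2, 0] = np.nan
        feats[1::2, 1] = np.nan
        ds = make_dataset(feats, np.full((4, 4), 2.0))
        with pytest.raises(EmptyCohortError, match="records"):
            preprocess(ds, feature_missing_threshold=0.6)

    def test_normalization_stats_round_trip_json(self, small_cohort):
        _, stats_ = preprocess(small_cohort)
        back = NormalizationStats.from_json(stats_.to_json())
        assert back.median == stats_.median
        assert back.scale == stats_.scale


class TestSpearman:
    def _with_props(self, x, y):
        n = len(x)
        feats = np.column_stack([x, np.linspace(5, 6, n)])
        props = np.column_stack([y, np.full(n, 2.0), np.full(n, 3.0), np.full(n, 4.0)])
        return make_dataset(feats, props)

    def test_perfect_monotone_gives_plus_one(self):
        ds = self._with_props([1, 2, 3, 4, 5], [10, 20, 22, 40, 100])
        assert spearman_correlations(ds).loc[FEATURE_COLUMNS[0], "t"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        ds = self._with_props([1, 2, 3, 4, 5], [100, 40, 22, 20, 10])
        assert spearman_correlations(ds).loc[FEATURE_COLUMNS[0], "t"] == pytest.approx(-1.0)

    def test_ties_match_pearson_of_average_ranks(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 5.0])
        ds = self._with_props(x, y)
        rho = spearman_correlations(ds).loc[FEATURE_COLUMNS[0], "t"]
        oracle = np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_column_reports_missing_not_zero(self):
        ds = self._with_props([1, 2, 3, 4, 5], [10, 20, 22, 40, 100])
        # sigma_gamma column is constant in this toy
        assert np.isnan(spearman_correlations(ds).loc[FEATURE_COLUMNS[0], "sigma_gamma"])

    @settings(max_examples=25, deadline=None)
    @given(st.sampled_from(["exp", "cube", "affine"]))
    def test_invariant_under_strictly_monotone_transforms(self, kind):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(12)
        y = rng.uniform(1.0, 2.0, 12)  # positive: feeds a property column
        f = {"exp": np.exp, "cube": lambda v: v**3, "affine": lambda v: 3 * v + 1}[kind]
        base = spearman_correlations(self._with_props(x, y)).iloc[0, 0]
        trans = spearman_correlations(self._with_props(f(x), y)).iloc[0, 0]
        assert trans == pytest.approx(base, abs=1e-12)


class TestForwardSelection:
    def _cohort(self):
        rng = np.random.default_rng(7)
        feats = rng.standard_normal((30, 4))
        props = np.exp(rng.standard_normal((30, 4)) * 0.1 + 1)
        return make_dataset(feats, props)

    def test_stops_at_first_non_improvement(self):
        scores = {1: 5.0, 2: 3.0, 3: 3.5}

        def score(ds, subset):
            return scores[len(subset)]

        sel = forward_feature_selection(self._cohort(), FEATURE_COLUMNS[:4], score)
        assert len(sel) == 2

    def test_constant_score_selects_exactly_first_candidate(self):
        sel = forward_feature_selection(
            self._cohort(), FEATURE_COLUMNS[:4], lambda ds, subset: 1.0
        )
        assert sel == [FEATURE_COLUMNS[0]]

    def test_empty_candidates_raise(self):
        with pytest.raises(ValueError):
            forward_feature_selection(self._cohort(), [], lambda ds, s: 0.0)

    def test_recovers_informative_features_with_cv_linear_score(self):
        # only features 0 and 2 drive the log properties
        rng = np.random.default_rng(3)
        feats = rng.standard_normal((60, 5))
        signal = 1.5 * feats[:, 0:1] - 1.0 * feats[:, 2:3]
        logp = signal + 0.1 * rng.standard_normal((60, 4))
        ds = make_dataset(feats, np.exp(logp))

        def cv_linear_score(dataset, subset):
            X = dataset.features[subset].to_numpy()
            Y = np.log(dataset.properties.to_numpy())
            err = 0.0
            for fold in range(3):
                test = np.arange(len(X)) % 3 == fold
                Xtr = np.column_stack([np.ones((~test).sum()), X[~test]])
                Xte = np.column_stack([np.ones(test.sum()), X[test]])
                coef, *_ = np.linalg.lstsq(Xtr, Y[~test], rcond=None)
                err += float(np.mean((Xte @ coef - Y[test]) ** 2))
            return err

        ordered = [FEATURE_COLUMNS[i] for i in (0, 2, 1, 3, 4)]
        sel = forward_feature_selection(ds, ordered, cv_linear_score)
        assert {FEATURE_COLUMNS[0], FEATURE_COLUMNS[2]} <= set(sel)
        assert len(sel) <= 3
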