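"""Normalization, fold-change and differential-calling behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from succinylome.io import FormatError
from succinylome.quantify import (
    CALL_DOWN,
    CALL_NOT_TESTABLE,
    CALL_UNCHANGED,
    CALL_UP,
    DssThresholds,
    adjust_bh_series,
    aggregate,
    call_dss,
    centralize,
    differential_sites,
    fold_change,
    median_normalize,
    test_significance as compute_significance,
)

from conftest import make_matrix
from oracles import naive_fold_change, naive_relative_quant, pooled_t_p_value

SAMPLES = ["0h_r1", "0h_r2", "0h_r3", "8h_r1", "8h_r2", "8h_r3"]


class TestCentralize:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ([5.0, 5.0, 5.0], [1.0, 1.0, 1.0]),
            ([2.0, 4.0], [2 / 3, 4 / 3]),
            ([3.0, np.nan, 3.0], [1.0, np.nan, 1.0]),
        ],
    )
    def test_row_divided_by_observed_mean(self, row, expected):
        samples = SAMPLES[: len(row)]
        sheet_vals = np.array([row])
        matrix = make_matrix(sheet_vals, samples)
        out = centralize(matrix)
        np.testing.assert_allclose(out.values.to_numpy()[0], expected, rtol=1e-15)

    def test_observed_row_means_are_one(self, random_matrix_factory):
        out = centralize(random_matrix_factory(seed=3))
        means = out.values.mean(axis=1, skipna=True)
        np.testing.assert_allclose(means, 1.0, atol=1e-9)

    def test_all_missing_row_dropped_with_warning(self):
        values = np.array([[1.0, 2.0, 3.0], [np.nan, np.nan, np.nan]])
        matrix = make_matrix(values, SAMPLES[:3])
        with pytest.warns(UserWarning, match="all-missing"):
            out = centralize(matrix)
        assert out.values.shape[0] == 1


class TestMedianNormalize:
    @pytest.mark.parametrize(
        "column,expected",
        [
            ([0.5, 1.0, 2.0], [0.5, 1.0, 2.0]),   # median already 1
            ([2.0, 4.0, 8.0], [0.5, 1.0, 2.0]),
        ],
    )
    def test_column_divided_by_median(self, column, expected):
        matrix = make_matrix(np.array(column)[:, None], SAMPLES[:1])
        centered = centralize(matrix)
        # bypass row-centering for the column check: inject directly
        centered.values.iloc[:, 0] = column
        out = median_normalize(centered)
        np.testing.assert_allclose(out.values.iloc[:, 0], expected, rtol=1e-15)

    def test_every_output_column_has_unit_median(self, random_matrix_factory):
        out = median_normalize(centralize(random_matrix_factory(seed=5)))
        medians = out.values.median(axis=0, skipna=True)
        np.testing.assert_allclose(medians, 1.0, atol=1e-9)

    def test_requires_centralized_stage(self, random_matrix_factory):
        rq = median_normalize(centralize(random_matrix_factory(seed=1)))
        with pytest.raises(ValueError, match="stage"):
            median_normalize(rq)

    def test_empty_sample_column_is_an_error(self):
        values = np.array([[1.0, np.nan], [2.0, np.nan]])
        centered = centralize(make_matrix(values, SAMPLES[:2]))
        with pytest.raises(FormatError, match="0h_r2"):
            median_normalize(centered)


class TestAggregate:
    def test_identity_with_one_peptide_per_site(self, random_matrix_factory):
        rq = median_normalize(centralize(random_matrix_factory(seed=2)))
        out = aggregate(rq)
        pd.testing.assert_frame_equal(out, rq.values)

    @pytest.mark.parametrize(
        "peptide_values,expected",
        [([0.8, 1.0, 1.4], 1.0), ([1.0, 2.0], 1.5)],
    )
    def test_median_over_contributing_peptides(self, peptide_values, expected):
        values = np.array(peptide_values)[:, None]
        matrix = make_matrix(values, SAMPLES[:1])
        rq = median_normalize(centralize(matrix))
        rq.values.iloc[:, 0] = peptide_values  # exact inputs for the median
        mapping = {row: "site1" for row in rq.values.index}
        out = aggregate(rq, mapping)
        assert out.loc["site1"].iloc[0] == pytest.approx(expected, rel=1e-15)

    def test_empty_mapping_rejected(self, random_matrix_factory):
        rq = median_normalize(centralize(random_matrix_factory(seed=2)))
        with pytest.raises(ValueError, match="empty"):
            aggregate(rq, {})


class TestFoldChange:
    def test_simple_ratio_and_symmetry(self, six_sample_sheet):
        values = np.array([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0], [3.0, 3.0, 3.0, 3.0, 3.0, 3.0]])
        site_values = pd.DataFrame(values, index=["s1", "s2"], columns=SAMPLES)
        fc = fold_change(site_values, six_sample_sheet, "8h", "0h")
        assert fc["s1"] == pytest.approx(2.0)
        assert fc["s2"] == pytest.approx(1.0)
        swapped = fold_change(site_values, six_sample_sheet, "0h", "8h")
        np.testing.assert_allclose(swapped, 1.0 / fc, rtol=1e-15)

    def test_insufficient_observations_not_testable(self, six_sample_sheet):
        values = np.array([[1.0, np.nan, np.nan, 2.0, 2.0, 2.0]])
        site_values = pd.DataFrame(values, index=["s1"], columns=SAMPLES)
        fc = fold_change(site_values, six_sample_sheet, "8h", "0h", min_obs_per_group=2)
        assert np.isnan(fc["s1"])


class TestSignificance:
    def test_identical_groups_give_p_one(self, six_sample_sheet):
        values = np.array([[1.0] * 6])
        p = compute_significance(
            pd.DataFrame(values, index=["s1"], columns=SAMPLES), six_sample_sheet, "8h", "0h"
        )
        assert p.loc["s1", "p_value"] == 1.0
        assert bool(p.loc["s1", "degenerate"])

    def test_matches_textbook_pooled_t(self, six_sample_sheet):
        control, treated = [1.0, 1.2, 0.9], [2.0, 2.2, 1.9]
        values = np.array([control + treated])
        p = compute_significance(
            pd.DataFrame(values, index=["s1"], columns=SAMPLES), six_sample_sheet, "8h", "0h"
        )
        expected = pooled_t_p_value(treated, control)
        assert p.loc["s1", "p_value"] == pytest.approx(expected, rel=1e-12)

    def test_within_group_permutation_invariance(self, six_sample_sheet):
        base = [1.0, 1.3, 0.8, 2.1, 1.9, 2.4]
        shuffled = [1.3, 0.8, 1.0, 2.4, 2.1, 1.9]
        frame = pd.DataFrame([base, shuffled], index=["a", "b"], columns=SAMPLES)
        p = compute_significance(frame, six_sample_sheet, "8h", "0h")
        assert p.loc["a", "p_value"] == pytest.approx(p.loc["b", "p_value"], rel=1e-12)

    def test_zero_variance_unequal_means_degenerate(self, six_sample_sheet):
        values = np.array([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]])
        p = compute_significance(
            pd.DataFrame(values, index=["s1"], columns=SAMPLES), six_sample_sheet, "8h", "0h"
        )
        assert 0 < p.loc["s1", "p_value"] < 1e-300
        assert bool(p.loc["s1", "degenerate"])


class TestCallDss:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [
            (2.01, 0.01, CALL_UP),        # strongest published up-site
            (0.57, 0.01, CALL_DOWN),      # strongest published down-site
            (1.2, 0.001, CALL_UNCHANGED),
            (1.8, 0.2, CALL_UNCHANGED),
            (1.5, 0.01, CALL_UNCHANGED),  # boundary: strict inequality
            (0.67, 0.01, CALL_UNCHANGED),
            (2.0, 0.05, CALL_UNCHANGED),  # alpha boundary is strict too
            (np.nan, 0.01, CALL_NOT_TESTABLE),
        ],
    )
    def test_threshold_semantics(self, fc, p, expected):
        assert call_dss(fc, p, DssThresholds()) == expected

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            DssThresholds(fc_up=0.9)
        with pytest.raises(ValueError):
            DssThresholds(alpha=1.5)


class TestPipelineAgainstOracle:
    """The assembled pipeline vs the independent loop-based evaluation."""

    @pytest.mark.parametrize("seed", range(10))
    def test_normalized_values_fc_and_p(self, seed, six_sample_sheet, random_matrix_factory):
        matrix = random_matrix_factory(seed=seed)
        report = differential_sites(matrix, six_sample_sheet, "8h", "0h")

        normalized = naive_relative_quant(matrix.values.to_numpy())
        treated_cols, control_cols = [3, 4, 5], [0, 1, 2]
        for row, site in enumerate(matrix.values.index):
            expected_fc = naive_fold_change(normalized[row], treated_cols, control_cols)
            assert report.loc[site, "fold_change"] == pytest.approx(expected_fc, rel=1e-12)
            x = [normalized[row, i] for i in treated_cols if not np.isnan(normalized[row, i])]
            y = [normalized[row, i] for i in control_cols if not np.isnan(normalized[row, i])]
            assert report.loc[site, "p_value"] == pytest.approx(
                pooled_t_p_value(x, y), rel=1e-9
            )

    @given(
        scale=st.lists(st.floats(min_value=0.01, max_value=100.0), min_size=6, max_size=6),
        seed=st.integers(min_value=0, max_value=50),
    )
    def test_median_normalization_step_cancels_column_scaling_exactly(
        self, scale, seed, six_sample_sheet, random_matrix_factory
    ):
        """The per-sample median division is exactly invariant to rescaling
        its input columns, whatever the data or missingness pattern."""
        rq = centralize(random_matrix_factory(seed=seed))
        baseline = median_normalize(rq)
        from succinylome.quantify import RelativeQuantMatrix, STAGE_CENTRALIZED

        scaled = RelativeQuantMatrix(
            values=rq.values * np.array(scale)[None, :],
            features=rq.features,
            stage=STAGE_CENTRALIZED,
        )
        np.testing.assert_allclose(
            median_normalize(scaled).values, baseline.values, rtol=1e-12
        )

    def test_row_and_column_permutation_invariance(self, six_sample_sheet, random_matrix_factory):
        matrix = random_matrix_factory(seed=17)
        report = differential_sites(matrix, six_sample_sheet, "8h", "0h")
        rng = np.random.default_rng(0)
        row_perm = rng.permutation(matrix.values.index)
        col_perm = ["0h_r2", "0h_r3", "0h_r1", "8h_r3", "8h_r1", "8h_r2"]
        permuted = make_matrix(
            matrix.values.loc[row_perm, col_perm].to_numpy(), col_perm
        )
        permuted.values.index = row_perm
        permuted.features = matrix.features.loc[row_perm]
        report2 = differential_sites(permuted, six_sample_sheet, "8h", "0h")
        np.testing.assert_allclose(
            report.loc[row_perm, "fold_change"], report2["fold_change"], rtol=1e-12
        )


def test_bh_adjustment_nan_preserving():
    p = pd.Series([0.01, np.nan, 0.02, 0.03])
    adjusted = adjust_bh_series(p)
    assert np.isnan(adjusted.iloc[1])
    np.testing.assert_allclose(adjusted.dropna(), [0.03, 0.03, 0.03], rtol=1e-12)
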