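"""Dichotomization, contingency tables, chi-square, and the composed model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from comparetx import (
    DataError,
    ResponseAssociationModel,
    chi_square,
    contingency,
    cut,
    dichotomize,
    predict_response,
)
from comparetx.cluster import ClusterAssignment
from comparetx.published import cluster_sensitivity_counts

from conftest import make_response


def chi_square_oracle(counts):
    """Cell-by-cell sum (O - E)^2 / E over the margins."""
    O = np.asarray(counts, dtype=float)
    row = O.sum(axis=1)
    col = O.sum(axis=0)
    total = O.sum()
    stat = 0.0
    for i in range(O.shape[0]):
        for j in range(O.shape[1]):
            e = row[i] * col[j] / total
            stat += (O[i, j] - e) ** 2 / e
    return stat


def assignment_from_labels(labels: dict) -> ClusterAssignment:
    series = pd.Series(labels, name="cluster")
    return ClusterAssignment(k=len(set(labels.values())), labels=series, cut_height=1.0)


class TestDichotomize:
    @pytest.mark.parametrize(
        "value,expected",
        [(-7.0, "sensitive"), (-6.0, "resistant"), (-6.5, "resistant")],
    )
    def test_boundary_rule_at_fixed_cutoff(self, value, expected):
        resp = make_response([[value], [-8.0], [-5.0]])
        part = dichotomize(resp, "D1", cutoff=-6.5)
        assert part.labels["L1"] == expected

    def test_median_cutoff_midpoint_convention(self):
        resp = make_response([[-8.0], [-7.0], [-6.0], [-5.0]])
        part = dichotomize(resp, "D1")
        assert part.cutoff == pytest.approx(-6.5)
        assert list(part.labels) == ["sensitive", "sensitive", "resistant", "resistant"]

    def test_missing_response_unclassified(self):
        resp = make_response([[-7.0], [np.nan], [-6.0]])
        part = dichotomize(resp, "D1", cutoff=-6.5)
        assert part.labels["L2"] == "unclassified"
        assert part.n_classified == 2

    def test_all_missing_is_error(self):
        resp = make_response([[np.nan], [np.nan], [np.nan]])
        with pytest.raises(DataError):
            dichotomize(resp, "D1")


class TestContingency:
    def test_degenerate_column_all_sensitive(self):
        resp = make_response([[-8.0], [-8.0], [-8.0], [-8.0]])
        part = dichotomize(resp, "D1", cutoff=-6.5)
        assignment = assignment_from_labels({"L1": 1, "L2": 1, "L3": 2, "L4": 2})
        counts = contingency(part, assignment)
        assert (counts["resistant"] == 0).all()
        assert counts["sensitive"].sum() == 4

    def test_counts_match_tally_oracle(self, rng):
        n = 30
        values = rng.normal(-6.5, 1, size=(n, 1))
        resp = make_response(values)
        part = dichotomize(resp, "D1")
        labels = {f"L{i + 1}": int(rng.integers(1, 4)) for i in range(n)}
        labels["L1"] = 1
        labels["L2"] = 2
        labels["L3"] = 3
        assignment = assignment_from_labels(labels)
        counts = contingency(part, assignment)
        tally = {}
        for line, cluster in labels.items():
            cls = part.labels[line]
            tally[(cluster, cls)] = tally.get((cluster, cls), 0) + 1
        for cluster in sorted(set(labels.values())):
            for cls in ("sensitive", "resistant"):
                assert counts.at[cluster, cls] == tally.get((cluster, cls), 0)

    def test_published_counts_sum_to_fifty_nine(self):
        counts = cluster_sensitivity_counts()
        assert int(counts.to_numpy().sum()) == 59

    def test_unclassified_lines_excluded(self):
        resp = make_response([[-8.0], [np.nan], [-5.0], [-6.0]])
        part = dichotomize(resp, "D1", cutoff=-6.5)
        assignment = assignment_from_labels({f"L{i + 1}": 1 + i % 2 for i in range(4)})
        counts = contingency(part, assignment)
        assert int(counts.to_numpy().sum()) == 3

    def test_empty_intersection_is_error(self):
        resp = make_response([[-8.0], [-5.0], [-6.0]])
        part = dichotomize(resp, "D1", cutoff=-6.5)
        assignment = assignment_from_labels({"X1": 1, "X2": 2})
        with pytest.raises(DataError):
            contingency(part, assignment)


class TestChiSquare:
    def test_proportional_rows_give_zero_statistic(self):
        counts = pd.DataFrame({"sensitive": [10, 10], "resistant": [10, 10]})
        res = chi_square(counts)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_published_table_reproduces_reported_p(self):
        res = chi_square(cluster_sensitivity_counts())
        assert res.df == 3
        assert f"{res.p:.3g}" == "0.00208"
        assert res.chi2 == pytest.approx(14.7077, abs=1e-3)
        assert abs(res.chi2 - chi_square_oracle(cluster_sensitivity_counts())) < 1e-10

    def test_agrees_with_scipy_and_oracle_on_random_tables(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 6))
            counts = pd.DataFrame(
                rng.integers(1, 30, size=(k, 2)), columns=["sensitive", "resistant"]
            )
            res = chi_square(counts)
            assert abs(res.chi2 - chi_square_oracle(counts)) < 1e-10
            ref_chi2, ref_p, ref_df, _ = stats.chi2_contingency(
                counts.to_numpy(), correction=False
            )
            assert res.chi2 == pytest.approx(ref_chi2, abs=1e-10)
            assert res.p == pytest.approx(ref_p, rel=1e-10)
            assert res.df == ref_df

    def test_row_permutation_invariance(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 20, size=(4, 2)), columns=["sensitive", "resistant"]
        )
        perm = counts.iloc[[2, 0, 3, 1]]
        assert chi_square(counts).chi2 == pytest.approx(
            chi_square(perm).chi2, abs=1e-12
        )

    def test_collapsing_clusters_consistent_with_remargined_oracle(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 20, size=(4, 2)), columns=["sensitive", "resistant"]
        )
        collapsed = pd.concat(
            [counts.iloc[:2].sum().to_frame().T, counts.iloc[2:]], ignore_index=True
        )
        res = chi_square(collapsed)
        assert res.df == 2
        assert abs(res.chi2 - chi_square_oracle(collapsed)) < 1e-10

    def test_empty_cluster_dropped_with_df_adjustment(self):
        counts = pd.DataFrame({"sensitive": [5, 0, 7], "resistant": [2, 0, 1]})
        with pytest.warns(UserWarning, match="empty cluster"):
            res = chi_square(counts)
        assert res.df == 1
        assert res.dropped_clusters == (1,)

    def test_degenerate_table_is_error(self):
        with pytest.raises(DataError):
            chi_square(pd.DataFrame({"sensitive": [5], "resistant": [3]}))
        with pytest.raises(DataError):
            chi_square(pd.DataFrame({"sensitive": [5, 3], "resistant": [0, 0]}))

    def test_low_expected_cells_flagged(self):
        res = chi_square(cluster_sensitivity_counts())
        assert len(res.low_expected_cells) > 0
        assert all(e in res.counts.columns for _, e in res.low_expected_cells)


class TestComposedModel:
    def test_planted_signal_yields_small_p(self, small_dataset):
        _, response, expression, _ = small_dataset
        results = predict_response(expression, response, "withanolide_1")
        assert results.pvalue < 0.05
        assert len(results.candidate_ids) >= 15

    def test_end_to_end_determinism(self, small_dataset):
        _, response, expression, _ = small_dataset
        a = predict_response(expression, response, "withanolide_1")
        b = predict_response(expression, response, "withanolide_1")
        assert a.chi2 == b.chi2 and a.pvalue == b.pvalue
        pd.testing.assert_series_equal(a.assignment.labels, b.assignment.labels)
        pd.testing.assert_frame_equal(a.association.counts, b.association.counts)

    def test_results_consistent_across_stages(self, small_dataset):
        _, response, expression, _ = small_dataset
        results = predict_response(expression, response, "withanolide_1")
        assert set(results.candidate_ids) == set(
            results.compare_result.standard_list.index
        ) | set(results.compare_result.reverse_list.index)
        assert results.association.grand_total == results.partition.n_classified
        assert results.dendrogram.n_leaves == len(response.line_ids)
        recut = cut(results.dendrogram, results.assignment.k)
        pd.testing.assert_series_equal(recut.labels, results.assignment.labels)

    def test_too_few_candidates_is_informative_error(self, small_dataset):
        _, response, expression, _ = small_dataset
        with pytest.raises(DataError, match="expression profile undefined"):
            predict_response(expression, response, "withanolide_1", threshold=0.999)

    def test_from_dataframes_constructor(self, small_dataset):
        _, response, expression, _ = small_dataset
        model = ResponseAssociationModel.from_dataframes(
            expression.values, response.values, "withanolide_1"
        )
        results = model.fit()
        direct = predict_response(expression, response, "withanolide_1")
        assert results.chi2 == direct.chi2

    def test_summary_reports_key_quantities(self, small_dataset):
        _, response, expression, _ = small_dataset
        results = predict_response(expression, response, "withanolide_1")
        text = results.summary()
        assert "withanolide_1" in text
        assert "chi2" in text and f"df = {results.df}" in text
        assert "standard list" in text and "reverse list" in text
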