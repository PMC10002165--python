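"""Permutation plans and differential network tests."""

import numpy as np
import pytest

from iegnet import (
    NetworkComparison,
    build_network,
    centrality_test,
    compare_groups,
    edge_difference_test,
    generate,
    global_strength,
    global_strength_test,
    make_study_template,
    node_centralities,
    pearson_matrix,
    permute_labels,
)
from iegnet.data import ExpressionTable


@pytest.fixture(scope="module")
def null_pair(small_registry):
    _, ds = generate(make_study_template("null", registry=small_registry, seed=19))
    return ds.table("VEH/VEH"), ds.table("VEH/ASE")


class TestPermuteLabels:
    def test_exhaustive_three_vs_three(self):
        plan = permute_labels(3, 3, B=1000)
        assert plan.exhaustive
        assert plan.n_assignments == 20
        rows = {tuple(r) for r in plan.assignments}
        assert len(rows) == 20  # every assignment exactly once

    def test_five_vs_five_is_exhaustive_below_default_budget(self):
        plan = permute_labels(5, 5, B=1000)
        assert plan.exhaustive
        assert plan.n_assignments == 252

    def test_force_monte_carlo(self):
        plan = permute_labels(5, 5, B=1000, seed=0, force_monte_carlo=True)
        assert not plan.exhaustive
        assert plan.n_assignments == 1000

    def test_monte_carlo_seeded_and_reproducible(self):
        a = permute_labels(8, 8, B=200, seed=1)
        b = permute_labels(8, 8, B=200, seed=1)
        c = permute_labels(8, 8, B=200, seed=2)
        assert not a.exhaustive
        np.testing.assert_array_equal(a.assignments, b.assignments)
        assert not np.array_equal(a.assignments, c.assignments)

    def test_degenerate_sizes_rejected(self):
        with pytest.raises(ValueError):
            permute_labels(2, 5)


class TestSelfComparison:
    def test_identical_tables_yield_p_one_everywhere(self, null_pair):
        table_a, _ = null_pair
        twin = ExpressionTable(
            group="twin", animals=[f"t{i}" for i in range(table_a.n)],
            rois=list(table_a.rois), values=table_a.values.copy(),
        )
        report = compare_groups(table_a, twin, B=252)
        m = len(report.edges.rois)
        iu = np.triu_indices(m, 1)
        np.testing.assert_allclose(report.edges.observed[iu], 0.0, atol=1e-12)
        np.testing.assert_allclose(report.edges.p[iu], 1.0)
        assert report.global_strength.p == 1.0
        assert report.global_strength.observed == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(report.degree.p, 1.0)
        np.testing.assert_allclose(report.betweenness.p, 1.0)


class TestObservedStatisticsMatchDirectComputation:
    def test_edge_and_global_observed(self, null_pair):
        table_a, table_b = null_pair
        report = compare_groups(table_a, table_b, B=252, seed=0)
        cm_a, cm_b = pearson_matrix(table_a), pearson_matrix(table_b)
        np.testing.assert_allclose(
            report.edges.observed, cm_a.r - cm_b.r, atol=1e-10
        )
        assert report.global_strength.observed == pytest.approx(
            global_strength(cm_a) - global_strength(cm_b), abs=1e-10
        )

    def test_centrality_observed_matches_thresholded_networks(self, null_pair):
        """The fast permutation path must agree with the networkx-based
        build_network -> node_centralities route, isolated nodes as 0."""
        table_a, table_b = null_pair
        report = compare_groups(table_a, table_b, B=252, seed=0, threshold_p=0.05)
        deg_a, btw_a = node_centralities(build_network(pearson_matrix(table_a), 0.05))
        deg_b, btw_b = node_centralities(build_network(pearson_matrix(table_b), 0.05))
        for i, roi in enumerate(report.degree.rois):
            assert report.degree.observed[i] == deg_a.get(roi, 0) - deg_b.get(roi, 0)
            assert report.betweenness.observed[i] == pytest.approx(
                btw_a.get(roi, 0.0) - btw_b.get(roi, 0.0), abs=1e-9
            )


class TestPValueConventions:
    def test_p_in_unit_interval_and_never_zero(self, null_pair):
        table_a, table_b = null_pair
        report = compare_groups(table_a, table_b, B=252, seed=0)
        m = len(report.edges.rois)
        iu = np.triu_indices(m, 1)
        for p in (report.edges.p[iu], report.degree.p, report.betweenness.p,
                  np.array([report.global_strength.p])):
            assert np.all(p > 0)
            assert np.all(p <= 1)
        assert np.all(report.edges.p[iu] >= 1 / report.B)

    def test_monte_carlo_add_one_grid(self, null_pair):
        table_a, table_b = null_pair
        res = global_strength_test(
            table_a, table_b, B=99, seed=3, force_monte_carlo=True
        )
        assert not res.exhaustive
        assert res.B == 100  # evaluated assignments include the observed one
        assert (res.p * 100) == pytest.approx(round(res.p * 100))

    def test_swapping_groups_negates_observed_keeps_p(self, null_pair):
        table_a, table_b = null_pair
        fwd = compare_groups(table_a, table_b, B=252)
        rev = compare_groups(table_b, table_a, B=252)
        np.testing.assert_allclose(
            fwd.edges.observed, -rev.edges.observed, atol=1e-10
        )
        np.testing.assert_allclose(fwd.edges.p, rev.edges.p, atol=1e-12)
        assert fwd.global_strength.p == pytest.approx(rev.global_strength.p)
        np.testing.assert_allclose(fwd.degree.p, rev.degree.p)
        np.testing.assert_allclose(fwd.betweenness.p, rev.betweenness.p)


class TestStandaloneTests:
    def test_edge_test_result_accessors(self, null_pair):
        table_a, table_b = null_pair
        res = edge_difference_test(table_a, table_b, B=252, keep_null=True)
        assert res.exhaustive
        unit = res.result(res.rois[0], res.rois[1])
        assert unit.statistic_name == "edge_r_diff"
        assert unit.null_values.shape == (252,)
        frame = res.to_frame()
        assert len(frame) == len(res.rois) * (len(res.rois) - 1) // 2

    def test_centrality_test_metric_validation(self, null_pair):
        table_a, table_b = null_pair
        with pytest.raises(ValueError, match="metric"):
            centrality_test(table_a, table_b, metric="closeness")
        res = centrality_test(table_a, table_b, metric="betweenness", B=252)
        assert res.statistic_name == "betweenness_diff"
        assert res.null.shape == (252, len(res.rois))

    def test_mismatched_roi_order_rejected(self, null_pair, small_registry):
        table_a, _ = null_pair
        scrambled = ExpressionTable(
            group="X", animals=[f"x{i}" for i in range(4)],
            rois=list(reversed(table_a.rois)), values=np.random.default_rng(0).normal(size=(4, 5)),
        )
        with pytest.raises(ValueError, match="ROI ordering"):
            edge_difference_test(table_a, scrambled)

    def test_degenerate_constant_column_counted_not_dropped(self, small_registry):
        rng = np.random.default_rng(6)
        values_a = rng.normal(size=(5, 5))
        values_a[:, 2] = 1.0  # constant ROI in group A
        table_a = ExpressionTable(
            "A", [f"a{i}" for i in range(5)],
            list(small_registry.abbreviations), values_a,
        )
        table_b = ExpressionTable(
            "B", [f"b{i}" for i in range(5)],
            list(small_registry.abbreviations), rng.normal(size=(5, 5)),
        )
        report = compare_groups(table_a, table_b, B=252)
        assert report.n_degenerate > 0
        assert np.all(np.isfinite(report.edges.p))


class TestComparisonReport:
    def test_unit_bookkeeping_528_edges_one_global_66_nodes(self):
        _, ds = generate(make_study_template("null", seed=29))
        report = NetworkComparison.from_dataset(ds, "VEH/VEH", "KET/ASE").fit(
            B=252, seed=0
        )
        assert report.n_units == 528 + 1 + 2 * 33
        assert report.exhaustive and report.B == 252

    def test_signed_difference_matrix_and_frames(self, null_pair):
        table_a, table_b = null_pair
        report = compare_groups(table_a, table_b, B=252)
        signed = report.signed_difference()
        sig = report.edges.p < report.alpha
        assert np.all(signed[~sig] == 0)
        assert np.all(np.isin(signed[sig], [-1, 1]))
        nodes = report.node_frame()
        assert list(nodes["roi"]) == list(report.degree.rois)
        assert "global strength" in report.summary()
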