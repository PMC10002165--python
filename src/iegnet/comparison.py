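"""Permutation-based differential network tests between treatment groups.

Whole animals are the exchangeable unit: the pooled animals of two
groups are reassigned to pseudo-groups of the original sizes, both
correlation matrices are recomputed per reassignment, and each
statistic's two-sided p-value is the fraction of reassignments whose
absolute statistic is at least the observed one.

Three statistic families share one permutation pass:

* edge-wise correlation differences r_A - r_B (528 ROI pairs),
* the global-strength difference (sum of |r| over all pairs of the
  full matrices),
* per-node degree and betweenness differences of the thresholded
  networks (isolated or absent nodes carry metric 0).

When C(n_A + n_B, n_A) does not exceed the requested number of
permutations, all distinct label assignments are enumerated exactly
once (exhaustive mode; for the study's 5+5 design, 252 assignments
replace 1000 random draws) and the p-value is exact, including the
identity assignment so p >= 1/K.  Monte-Carlo mode uses the add-one
estimate (count+1)/(B+1), which can never be 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import itertools

import numpy as np
import pandas as pd

from ._fastgraph import betweenness_from_adjacency, degrees_from_adjacency
from .connectome import significance_r_threshold
from .data import ExpressionTable, StudyDataset

__all__ = [
    "PermutationPlan",
    "PermutationResult",
    "EdgeTestResult",
    "NodeTestResult",
    "ComparisonReport",
    "permute_labels",
    "edge_difference_test",
    "global_strength_test",
    "centrality_test",
    "compare_groups",
    "NetworkComparison",
]

_CHUNK = 2048


@dataclass
class PermutationPlan:
    """Label reassignments for one two-group comparison."""

    n_a: int
    n_b: int
    assignments: np.ndarray  # (K, n_a) sorted indices into the pooled animals
    exhaustive: bool
    B: int
    seed: int | None

    @property
    def n_assignments(self) -> int:
        return len(self.assignments)


def permute_labels(
    n_a: int,
    n_b: int,
    B: int = 1000,
    seed: int | None = None,
    force_monte_carlo: bool = False,
) -> PermutationPlan:
    """Enumerate or sample pseudo-group assignments of the pooled animals.

    Exhaustive when C(n_a+n_b, n_a) <= B (every distinct assignment
    once, identity first); otherwise B uniform random assignments drawn
    with the given seed.
    """
    if n_a < 3 or n_b < 3:
        raise ValueError(f"need at least 3 animals per group, got {n_a} and {n_b}")
    if B < 1:
        raise ValueError("B must be >= 1")
    n = n_a + n_b
    total = comb(n, n_a)
    if total <= B and not force_monte_carlo:
        assignments = np.array(
            list(itertools.combinations(range(n), n_a)), dtype=np.int64
        )
        return PermutationPlan(n_a, n_b, assignments, True, B, seed)
    rng = np.random.default_rng(seed)
    order = np.argsort(rng.random((B, n)), axis=1)
    assignments = np.sort(order[:, :n_a], axis=1).astype(np.int64)
    return PermutationPlan(n_a, n_b, assignments, False, B, seed)


def _batched_corr(X: np.ndarray, idx: np.ndarray) -> tuple[np.ndarray, int]:
    """Correlation matrices of the rows indexed by each assignment.

    Pairs undefined under a permutation (constant column) are recorded
    as 0, counted; dropping the permutation instead would bias the null.
    """
    sub = X[idx].astype(float)
    sub -= sub.mean(axis=1, keepdims=True)
    cov = np.einsum("kij,kil->kjl", sub, sub, optimize=True)
    var = np.einsum("kjj->kj", cov)
    denom = np.sqrt(var[:, :, None] * var[:, None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        r = cov / denom
    bad = ~np.isfinite(r)
    m = X.shape[1]
    iu = np.triu_indices(m, k=1)
    n_degenerate = int(bad[:, iu[0], iu[1]].sum())
    r[bad] = 0.0
    np.clip(r, -1.0, 1.0, out=r)
    r[:, np.arange(m), np.arange(m)] = 1.0
    return r, n_degenerate


def _run_engine(
    Xa: np.ndarray,
    Xb: np.ndarray,
    plan: PermutationPlan,
    threshold_p: float = 0.05,
    want_centrality: bool = True,
    keep_edge_null: bool = False,
):
    """One shared permutation pass producing all statistic families.

    Row 0 of the evaluated assignments is always the observed labeling
    (it is the lexicographic first combination in exhaustive mode and is
    prepended in Monte-Carlo mode), so observed statistics and their
    null ties are computed through the identical code path, and
    p = #(|null| >= |observed|) / K with the observed row counted once.
    """
    n_a, n_b = plan.n_a, plan.n_b
    pooled = np.vstack([Xa, Xb])
    n, m = pooled.shape
    if plan.exhaustive:
        idx = plan.assignments
        assert np.array_equal(idx[0], np.arange(n_a))
    else:
        idx = np.vstack([np.arange(n_a, dtype=np.int64)[None, :], plan.assignments])
    K = len(idx)
    in_a = np.zeros((K, n), dtype=bool)
    np.put_along_axis(in_a, idx, True, axis=1)
    idx_b = np.nonzero(~in_a)[1].reshape(K, n_b)

    r_crit_a = significance_r_threshold(n_a, threshold_p)
    r_crit_b = significance_r_threshold(n_b, threshold_p)
    eye = np.eye(m, dtype=bool)

    obs: dict[str, np.ndarray | float] = {}
    edge_geq = np.zeros((m, m), dtype=np.int64)
    gs_null = np.empty(K)
    deg_null = np.empty((K, m)) if want_centrality else None
    btw_null = np.empty((K, m)) if want_centrality else None
    edge_null = np.empty((K, m, m)) if keep_edge_null else None
    node_geq = {"degree": np.zeros(m, np.int64), "betweenness": np.zeros(m, np.int64)}
    n_degenerate = 0

    for start in range(0, K, _CHUNK):
        rows = slice(start, min(start + _CHUNK, K))
        rA, dA = _batched_corr(pooled, idx[rows])
        rB, dB = _batched_corr(pooled, idx_b[rows])
        n_degenerate += dA + dB
        D = rA - rB
        gs = (np.abs(rA).sum(axis=(1, 2)) - np.abs(rB).sum(axis=(1, 2))) / 2.0
        gs_null[rows] = gs
        if start == 0:
            obs["edge"] = D[0].copy()
            obs["global"] = float(gs[0])
        edge_geq += (np.abs(D) >= np.abs(obs["edge"])).sum(axis=0)
        if keep_edge_null:
            edge_null[rows] = D
        if want_centrality:
            for k in range(len(D)):
                adj_a = (np.abs(rA[k]) > r_crit_a) & ~eye
                adj_b = (np.abs(rB[k]) > r_crit_b) & ~eye
                deg_null[start + k] = degrees_from_adjacency(adj_a) - \
                    degrees_from_adjacency(adj_b)
                btw_null[start + k] = betweenness_from_adjacency(adj_a) - \
                    betweenness_from_adjacency(adj_b)

    out = {
        "K": K,
        "exhaustive": plan.exhaustive,
        "n_degenerate": n_degenerate,
        "edge_observed": obs["edge"],
        "edge_p": edge_geq / K,
        "edge_null": edge_null,
        "global_observed": obs["global"],
        "global_null": gs_null,
        "global_p": float((np.abs(gs_null) >= abs(obs["global"])).sum() / K),
    }
    if want_centrality:
        out["degree_observed"] = deg_null[0].copy()
        out["betweenness_observed"] = btw_null[0].copy()
        out["degree_null"] = deg_null
        out["betweenness_null"] = btw_null
        out["degree_p"] = (
            (np.abs(deg_null) >= np.abs(deg_null[0])).sum(axis=0) / K
        )
        out["betweenness_p"] = (
            (np.abs(btw_null) >= np.abs(btw_null[0])).sum(axis=0) / K
        )
    np.fill_diagonal(out["edge_p"], 1.0)
    return out


@dataclass
class PermutationResult:
    """Observed statistic, permutation null, and p-value for one unit."""

    statistic_name: str
    unit: str
    observed: float
    null_values: np.ndarray | None
    p: float
    B: int
    exhaustive: bool
    seed: int | None


def _check_tables(table_a: ExpressionTable, table_b: ExpressionTable) -> None:
    if table_a.rois != table_b.rois:
        raise ValueError("tables must share the same ROI ordering")


@dataclass
class EdgeTestResult:
    """Edge-wise correlation-difference test over all ROI pairs."""

    rois: list[str]
    observed: np.ndarray  # (m, m) r_A - r_B
    p: np.ndarray  # (m, m)
    B: int
    exhaustive: bool
    seed: int | None
    n_degenerate: int = 0
    null: np.ndarray | None = None
    statistic_name: str = "edge_r_diff"

    def result(self, roi_a: str, roi_b: str) -> PermutationResult:
        i, j = self.rois.index(roi_a), self.rois.index(roi_b)
        null = None if self.null is None else self.null[:, i, j]
        return PermutationResult(
            self.statistic_name, f"{roi_a}~{roi_b}", float(self.observed[i, j]),
            null, float(self.p[i, j]), self.B, self.exhaustive, self.seed,
        )

    def to_frame(self) -> pd.DataFrame:
        m = len(self.rois)
        iu, ju = np.triu_indices(m, k=1)
        return pd.DataFrame(
            {
                "roi_a": [self.rois[i] for i in iu],
                "roi_b": [self.rois[j] for j in ju],
                "observed_diff": self.observed[iu, ju],
                "p": self.p[iu, ju],
            }
        )


@dataclass
class NodeTestResult:
    """Per-node centrality-difference test (degree or betweenness)."""

    statistic_name: str
    rois: list[str]
    observed: np.ndarray  # (m,)
    p: np.ndarray  # (m,)
    B: int
    exhaustive: bool
    seed: int | None
    threshold_p: float = 0.05
    null: np.ndarray | None = None

    def result(self, roi: str) -> PermutationResult:
        i = self.rois.index(roi)
        null = None if self.null is None else self.null[:, i]
        return PermutationResult(
            self.statistic_name, roi, float(self.observed[i]), null,
            float(self.p[i]), self.B, self.exhaustive, self.seed,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"roi": self.rois, "observed_diff": self.observed, "p": self.p}
        )


def _plan_for(table_a, table_b, B, seed, force_monte_carlo):
    _check_tables(table_a, table_b)
    return permute_labels(table_a.n, table_b.n, B, seed, force_monte_carlo)


def edge_difference_test(
    table_a: ExpressionTable,
    table_b: ExpressionTable,
    B: int = 1000,
    seed: int | None = None,
    force_monte_carlo: bool = False,
    keep_null: bool = False,
) -> EdgeTestResult:
    """Permutation test of r_A - r_B for every ROI pair."""
    plan = _plan_for(table_a, table_b, B, seed, force_monte_carlo)
    eng = _run_engine(
        table_a.values, table_b.values, plan,
        want_centrality=False, keep_edge_null=keep_null,
    )
    return EdgeTestResult(
        rois=list(table_a.rois),
        observed=eng["edge_observed"],
        p=eng["edge_p"],
        B=eng["K"],
        exhaustive=eng["exhaustive"],
        seed=seed,
        n_degenerate=eng["n_degenerate"],
        null=eng["edge_null"],
    )


def global_strength_test(
    table_a: ExpressionTable,
    table_b: ExpressionTable,
    B: int = 1000,
    seed: int | None = None,
    force_monte_carlo: bool = False,
) -> PermutationResult:
    """Permutation test of the full-matrix global-strength difference."""
    plan = _plan_for(table_a, table_b, B, seed, force_monte_carlo)
    eng = _run_engine(table_a.values, table_b.values, plan, want_centrality=False)
    return PermutationResult(
        statistic_name="global_strength_diff",
        unit="network",
        observed=eng["global_observed"],
        null_values=eng["global_null"],
        p=eng["global_p"],
        B=eng["K"],
        exhaustive=eng["exhaustive"],
        seed=seed,
    )


def centrality_test(
    table_a: ExpressionTable,
    table_b: ExpressionTable,
    metric: str = "degree",
    threshold_p: float = 0.05,
    B: int = 1000,
    seed: int | None = None,
    force_monte_carlo: bool = False,
) -> NodeTestResult:
    """Permutation test of per-node degree or betweenness differences.

    Per reassignment both pseudo-group matrices are thresholded into
    networks and the metric recomputed; a node without retained edges
    carries metric 0.
    """
    if metric not in {"degree", "betweenness"}:
        raise ValueError(f"unknown centrality metric {metric!r}")
    plan = _plan_for(table_a, table_b, B, seed, force_monte_carlo)
    eng = _run_engine(
        table_a.values, table_b.values, plan, threshold_p=threshold_p
    )
    return NodeTestResult(
        statistic_name=f"{metric}_diff",
        rois=list(table_a.rois),
        observed=eng[f"{metric}_observed"],
        p=eng[f"{metric}_p"],
        B=eng["K"],
        exhaustive=eng["exhaustive"],
        seed=seed,
        threshold_p=threshold_p,
        null=eng[f"{metric}_null"],
    )


@dataclass
class ComparisonReport:
    """All differential tests for one group pair, from one shared null."""

    group_a: str
    group_b: str
    alpha: float
    threshold_p: float
    B: int
    exhaustive: bool
    seed: int | None
    edges: EdgeTestResult
    global_strength: PermutationResult
    degree: NodeTestResult
    betweenness: NodeTestResult
    n_degenerate: int = 0

    @property
    def n_units(self) -> int:
        m = len(self.edges.rois)
        return m * (m - 1) // 2 + 1 + 2 * m

    def signed_difference(self) -> np.ndarray:
        """Fig-3-style matrix: sign of the observed difference where
        the edge test is significant at alpha, 0 elsewhere."""
        sig = self.edges.p < self.alpha
        return (np.sign(self.edges.observed) * sig).astype(np.int8)

    def significant_edges(self) -> pd.DataFrame:
        frame = self.edges.to_frame()
        frame["sign"] = np.sign(frame["observed_diff"]).astype(int)
        return frame.loc[frame["p"] < self.alpha].reset_index(drop=True)

    def node_frame(self) -> pd.DataFrame:
        deg = self.degree.to_frame().rename(
            columns={"observed_diff": "degree_diff", "p": "degree_p"}
        )
        btw = self.betweenness.to_frame().rename(
            columns={"observed_diff": "betweenness_diff", "p": "betweenness_p"}
        )
        out = deg.merge(btw, on="roi")
        out["degree_significant"] = out["degree_p"] < self.alpha
        out["betweenness_significant"] = out["betweenness_p"] < self.alpha
        return out

    def to_dict(self) -> dict:
        nodes = self.node_frame()
        return {
            "group_a": self.group_a,
            "group_b": self.group_b,
            "alpha": self.alpha,
            "threshold_p": self.threshold_p,
            "n_assignments": self.B,
            "exhaustive": self.exhaustive,
            "seed": self.seed,
            "n_units": self.n_units,
            "n_significant_edges": int((self.edges.to_frame()["p"] < self.alpha).sum()),
            "global_strength": {
                "observed": self.global_strength.observed,
                "p": self.global_strength.p,
            },
            "n_significant_degree": int(nodes["degree_significant"].sum()),
            "n_significant_betweenness": int(nodes["betweenness_significant"].sum()),
            "n_degenerate_permutation_pairs": self.n_degenerate,
        }

    def summary(self) -> str:
        d = self.to_dict()
        mode = "exhaustive" if self.exhaustive else "Monte-Carlo"
        return "\n".join(
            [
                f"Network comparison: {self.group_a} vs {self.group_b} "
                f"({mode}, {self.B} assignments, alpha = {self.alpha})",
                f"  significant edge differences:  "
                f"{d['n_significant_edges']} / {len(self.edges.to_frame())}",
                f"  global strength: diff = {self.global_strength.observed:+.3f}, "
                f"p = {self.global_strength.p:.4f}",
                f"  significant degree nodes:      {d['n_significant_degree']}",
                f"  significant betweenness nodes: {d['n_significant_betweenness']}",
            ]
        )


def compare_groups(
    dataset_or_table_a,
    group_a_or_table_b,
    group_b: str | None = None,
    threshold_p: float = 0.05,
    alpha: float = 0.05,
    B: int = 1000,
    seed: int | None = None,
    force_monte_carlo: bool = False,
) -> ComparisonReport:
    """Full differential report for one group pair from one shared null.

    Accepts either ``(dataset, group_a, group_b)`` or two expression
    tables directly.  All three statistic families are evaluated on the
    same permutation assignments.
    """
    if isinstance(dataset_or_table_a, StudyDataset):
        dataset = dataset_or_table_a
        table_a = dataset.table(group_a_or_table_b)
        table_b = dataset.table(group_b)
    else:
        table_a = dataset_or_table_a
        table_b = group_a_or_table_b
    plan = _plan_for(table_a, table_b, B, seed, force_monte_carlo)
    eng = _run_engine(table_a.values, table_b.values, plan, threshold_p=threshold_p)
    rois = list(table_a.rois)
    edges = EdgeTestResult(
        rois=rois, observed=eng["edge_observed"], p=eng["edge_p"],
        B=eng["K"], exhaustive=eng["exhaustive"], seed=seed,
        n_degenerate=eng["n_degenerate"],
    )
    gs = PermutationResult(
        "global_strength_diff", "network", eng["global_observed"],
        eng["global_null"], eng["global_p"], eng["K"], eng["exhaustive"], seed,
    )
    degree = NodeTestResult(
        "degree_diff", rois, eng["degree_observed"], eng["degree_p"],
        eng["K"], eng["exhaustive"], seed, threshold_p, eng["degree_null"],
    )
    betweenness = NodeTestResult(
        "betweenness_diff", rois, eng["betweenness_observed"],
        eng["betweenness_p"], eng["K"], eng["exhaustive"], seed, threshold_p,
        eng["betweenness_null"],
    )
    return ComparisonReport(
        group_a=table_a.group,
        group_b=table_b.group,
        alpha=alpha,
        threshold_p=threshold_p,
        B=eng["K"],
        exhaustive=eng["exhaustive"],
        seed=seed,
        edges=edges,
        global_strength=gs,
        degree=degree,
        betweenness=betweenness,
        n_degenerate=eng["n_degenerate"],
    )


class NetworkComparison:
    """Model object: permutation comparison of two treatment groups.

    ``NetworkComparison(table_a, table_b).fit(B=1000, seed=0)`` returns
    a :class:`ComparisonReport`; ``from_dataset`` selects groups by
    label.
    """

    def __init__(self, table_a: ExpressionTable, table_b: ExpressionTable):
        _check_tables(table_a, table_b)
        self.table_a = table_a
        self.table_b = table_b

    @classmethod
    def from_dataset(
        cls, dataset: StudyDataset, group_a: str, group_b: str
    ) -> "NetworkComparison":
        return cls(dataset.table(group_a), dataset.table(group_b))

    def fit(
        self,
        B: int = 1000,
        seed: int | None = None,
        threshold_p: float = 0.05,
        alpha: float = 0.05,
        force_monte_carlo: bool = False,
    ) -> ComparisonReport:
        return compare_groups(
            self.table_a, self.table_b,
            threshold_p=threshold_p, alpha=alpha, B=B, seed=seed,
            force_monte_carlo=force_monte_carlo,
        )
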