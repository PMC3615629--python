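import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

import stagepath as sp
from stagepath.screen import (
    bh_fdr,
    map_biomarkers,
    pearson_p_from_r,
    pearson_test,
    screen_transitions,
)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, p = pearson_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_orthogonal_residual_gives_zero_r(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        xc = x - x.mean()
        yc = y - y.mean()
        y_orth = yc - (yc @ xc) / (xc @ xc) * xc
        r, p = pearson_test(x, y_orth)
        assert r == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0])

    def test_vectorized_p_matches_scipy(self):
        rng = np.random.default_rng(9)
        for n in (10, 50, 185):
            x = rng.normal(size=n)
            y = rng.normal(size=n) + 0.3 * x
            r, p = pearson_test(x, y)
            assert pearson_p_from_r(r, n) == pytest.approx(p, rel=1e-9)


class TestBHAdjustment:
    def test_hand_computed_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03]).tolist() == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2]).tolist() == [0.2]

    def test_equal_ps_unchanged(self):
        assert bh_fdr([0.4, 0.4, 0.4]).tolist() == pytest.approx([0.4, 0.4, 0.4])

    def test_empty_input(self):
        assert bh_fdr(np.array([])).size == 0

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            assert bh_fdr(p) == pytest.approx(expected, rel=1e-9)

    def test_matches_manual_step_up_oracle(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1, size=25)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            adj[i] = running
        assert bh_fdr(p) == pytest.approx(adj, rel=1e-12)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 0.0])


class TestMapBiomarkers:
    def test_identity_when_all_present(self, triangle_graph):
        assert map_biomarkers(["A", "C"], triangle_graph) == ["A", "C"]

    def test_empty_when_none_present(self, triangle_graph):
        assert map_biomarkers(["Z1", "Z2"], triangle_graph) == []

    def test_partial_mapping_preserves_order(self, triangle_graph):
        assert map_biomarkers(["C", "Z", "A"], triangle_graph) == ["C", "A"]


def _screen_fixture(seed=0, n_bc=40, rho=0.9):
    """Small cohort + network with one strongly planted early/late pair."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(8)]
    samples = [f"B{i}" for i in range(n_bc // 2)] + [f"C{i}" for i in range(n_bc // 2)]
    samples += ["A0", "A1", "D0", "D1"]
    stages = pd.Series([s[0] for s in samples], index=samples)
    X = rng.normal(size=(8, len(samples)))
    X[1] = rho * X[0] + np.sqrt(1 - rho**2) * rng.normal(size=len(samples))
    cohort = sp.ExpressionCohort(
        values=pd.DataFrame(X, index=genes, columns=samples), stages=stages
    )
    records = [("g0", "t0", 0.95), ("t0", "g1", 0.95)]  # planted path length 100
    records += [("g2", "g5", 0.3), ("g3", "g6", 0.2), ("g4", "g7", 0.25)]
    graph = sp.build_graph(sp.ConfidenceEdgeList.from_records(records))
    return cohort, graph


def test_planted_pair_retained_with_interior_nodes():
    cohort, graph = _screen_fixture()
    early = map_biomarkers(["g0", "g2", "g3"], graph)
    late = map_biomarkers(["g1", "g5", "g6"], graph)
    res = screen_transitions(graph, early, late, cohort)
    assert res.n_pairs_tested == 9
    found = {(p.early_gene, p.late_gene) for p in res.paths}
    assert ("g0", "g1") in found
    path = next(p for p in res.paths if p.early_gene == "g0")
    assert path.node_sequence == ["g0", "t0", "g1"]
    assert path.transition_genes == ["t0"]
    assert path.length == pytest.approx(100.0)


def test_zero_length_cutoff_retains_nothing():
    cohort, graph = _screen_fixture()
    res = screen_transitions(graph, ["g0"], ["g1"], cohort, length_cutoff=0.0)
    assert res.n_paths == 0


def test_relaxing_cutoffs_gives_superset():
    cohort, graph = _screen_fixture(seed=3)
    early, late = ["g0", "g2", "g3"], ["g1", "g5", "g6"]
    strict = screen_transitions(graph, early, late, cohort, 150, 1e-4)
    loose = screen_transitions(graph, early, late, cohort, 1e6, 1.0)
    strict_pairs = {(p.early_gene, p.late_gene) for p in strict.paths}
    loose_pairs = {(p.early_gene, p.late_gene) for p in loose.paths}
    assert strict_pairs <= loose_pairs


def test_retained_set_invariant_to_pair_order():
    cohort, graph = _screen_fixture(seed=5)
    a = screen_transitions(graph, ["g0", "g2"], ["g1", "g5"], cohort, 1e6, 1.0)
    b = screen_transitions(graph, ["g2", "g0"], ["g5", "g1"], cohort, 1e6, 1.0)
    key = lambda r: sorted((p.early_gene, p.late_gene, p.correlation_fdr) for p in r.paths)
    assert key(a) == key(b)


def test_bh_family_is_all_tested_pairs():
    cohort, graph = _screen_fixture(seed=7)
    early, late = ["g0", "g2", "g3"], ["g1", "g5", "g6"]
    res = screen_transitions(graph, early, late, cohort, 1e6, 1.0)
    bc = cohort.samples_in(("B", "C"))
    raw = {}
    for e in early:
        for l in late:
            raw[(e, l)] = scipy_stats.pearsonr(
                cohort.values.loc[e, bc], cohort.values.loc[l, bc]
            ).pvalue
    keys = list(raw)
    adj = dict(zip(keys, bh_fdr([raw[k] for k in keys])))
    for p in res.paths:
        assert p.correlation_fdr == pytest.approx(adj[(p.early_gene, p.late_gene)], rel=1e-6)


def test_self_pairs_excluded():
    cohort, graph = _screen_fixture()
    res = screen_transitions(graph, ["g0", "g1"], ["g1", "g5"], cohort, 1e6, 1.0)
    assert all(p.early_gene != p.late_gene for p in res.paths)
    assert res.n_pairs_tested == 3  # (g1, g1) removed from the 2x2 grid


def test_missing_bc_stage_fails():
    rng = np.random.default_rng(0)
    samples = ["A0", "A1", "B0", "B1", "D0", "D1"]
    cohort = sp.ExpressionCohort(
        values=pd.DataFrame(rng.normal(size=(3, 6)), index=list("xyz"), columns=samples),
        stages=pd.Series([s[0] for s in samples], index=samples),
    )
    graph = sp.build_graph(sp.ConfidenceEdgeList.from_records([("x", "y", 0.9)]))
    with pytest.raises(ValueError, match="Dukes"):
        screen_transitions(graph, ["x"], ["y"], cohort)
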