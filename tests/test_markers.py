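import numpy as np
import pytest
from sklearn.metrics import mutual_info_score

import stagepath as sp
from stagepath.markers import (
    IFSCurve,
    MRMRIFSSelector,
    discretize,
    ifs_curve,
    mrmr_rank,
    mutual_information,
    nna_loocv_accuracy,
)

_EPS = 1e-12


class TestDiscretize:
    def test_single_outlier_gets_plus_one(self):
        # mean 2.5, population SD ~4.33: only the 10 exceeds mean + SD
        assert discretize(np.array([0.0, 0.0, 0.0, 10.0])).tolist() == [0, 0, 0, 1]

    def test_constant_gene_all_zero(self):
        assert discretize(np.array([3.0, 3.0, 3.0])).tolist() == [0, 0, 0]

    def test_boundary_values_map_to_zero(self):
        # mean 0, SD 10: -10 and 10 sit exactly on the boundaries
        assert discretize(np.array([-10.0, 10.0])).tolist() == [0, 0]

    def test_matrix_rows_independent(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(5, 30))
        d = discretize(x)
        for i in range(5):
            assert d[i].tolist() == discretize(x[i]).tolist()

    def test_k_sd_widens_the_zero_band(self):
        x = np.array([-3.0, -1.0, 0.0, 1.0, 3.0])
        assert np.abs(discretize(x, k_sd=5.0)).sum() == 0


class TestMutualInformation:
    def test_identical_uniform_binary_is_ln2(self):
        x = np.array([0, 0, 1, 1, 0, 1])
        assert mutual_information(x, x) == pytest.approx(np.log(2), rel=1e-9)

    def test_constant_gives_zero(self):
        assert mutual_information([1, 1, 1, 1], [0, 1, 0, 1]) == 0.0

    def test_product_joint_gives_zero(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_matches_sklearn_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 3, size=40)
            y = rng.integers(0, 2, size=40)
            assert mutual_information(x, y) == pytest.approx(
                mutual_info_score(x, y), rel=1e-9, abs=1e-12
            )

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0, 1, 0])


def _brute_force_mrmr(values, labels, scheme, k_sd=1.0):
    """Independent greedy-objective oracle using sklearn MI and plain loops."""
    codes = discretize(values, k_sd=k_sd)
    _, y = np.unique(labels, return_inverse=True)
    n_genes = codes.shape[0]
    rel = [mutual_info_score(codes[g], y) for g in range(n_genes)]
    order = [int(np.argmax(rel))]
    while len(order) < n_genes:
        best, best_score = None, None
        for g in range(n_genes):
            if g in order:
                continue
            red = np.mean([mutual_info_score(codes[g], codes[s]) for s in order])
            score = rel[g] / max(red, _EPS) if scheme == "MIQ" else rel[g] - red
            if best_score is None or score > best_score + 1e-12:
                best, best_score = g, score
        order.append(best)
    return order


@pytest.mark.parametrize("scheme", ["MIQ", "MID"])
def test_mrmr_matches_brute_force_objective(scheme):
    rng = np.random.default_rng(3)
    for _ in range(8):
        values = rng.normal(size=(6, 40))
        labels = rng.integers(0, 2, size=40)
        got = mrmr_rank(values, labels, scheme=scheme).tolist()
        assert got == _brute_force_mrmr(values, labels, scheme)


def test_mrmr_planted_marker_ranked_first():
    rng = np.random.default_rng(9)
    hits = 0
    for _ in range(50):
        labels = rng.integers(0, 2, size=60)
        values = rng.normal(size=(20, 60))
        values[7] += 5.0 * labels  # one gene perfectly tracks the label
        hits += mrmr_rank(values, labels, n_top=1)[0] == 7
    assert hits >= 48


def test_mrmr_redundant_duplicate_not_second():
    # gene 0 strong, gene 1 its exact copy, gene 2 independently informative
    rng = np.random.default_rng(21)
    labels = np.repeat([0, 1], 30)
    g0 = 3.0 * labels + rng.normal(size=60)
    g2 = 2.0 * labels + rng.normal(size=60)
    noise = rng.normal(size=60)
    values = np.vstack([g0, g0.copy(), g2, noise])
    for scheme in ("MIQ", "MID"):
        order = mrmr_rank(values, labels, scheme=scheme).tolist()
        assert order[0] == 0
        assert order[1] != 1

def test_mrmr_n_top_one_is_argmax_relevance():
    # compare by relevance value, not index: exact MI ties between genes with
    # identical contingency tables are broken by floating summation order
    rng = np.random.default_rng(2)
    values = rng.normal(size=(10, 30))
    labels = rng.integers(0, 2, size=30)
    codes = discretize(values)
    _, y = np.unique(labels, return_inverse=True)
    rel = [mutual_info_score(codes[g], y) for g in range(10)]
    chosen = mrmr_rank(values, labels, n_top=1)[0]
    assert rel[chosen] == pytest.approx(max(rel), rel=1e-9)


def test_mrmr_truncates_oversized_n_top():
    rng = np.random.default_rng(4)
    order = mrmr_rank(rng.normal(size=(5, 20)), rng.integers(0, 2, size=20), n_top=50)
    assert sorted(order.tolist()) == [0, 1, 2, 3, 4]


class TestNNALoocv:
    def test_separated_clusters_perfect(self):
        values = np.array([[0.0, 0.2, 0.1, 10.0, 10.2, 9.9]])
        labels = ["a", "a", "a", "b", "b", "b"]
        assert nna_loocv_accuracy(values, labels) == 1.0

    def test_hand_traced_single_gene(self):
        assert nna_loocv_accuracy(np.array([[0.0, 1.0, 10.0, 11.0]]), list("aabb")) == 1.0

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(17)
        accs = []
        for _ in range(200):
            values = rng.normal(size=(3, 30))
            labels = np.array([0] * 15 + [1] * 15)
            rng.shuffle(labels)
            accs.append(nna_loocv_accuracy(values, labels))
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_invariant_to_sample_permutation(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(4, 20))
        labels = rng.integers(0, 2, size=20)
        while min(np.bincount(labels)) < 2:
            labels = rng.integers(0, 2, size=20)
        base = nna_loocv_accuracy(values, labels)
        perm = rng.permutation(20)
        assert nna_loocv_accuracy(values[:, perm], labels[perm]) == pytest.approx(base)

    def test_requires_two_per_class(self):
        with pytest.raises(ValueError):
            nna_loocv_accuracy(np.array([[1.0, 2.0, 3.0]]), ["a", "b", "b"])


class TestIFS:
    def test_optimal_k_smallest_argmax(self):
        assert IFSCurve([0.6, 0.9, 0.9, 0.7]).optimal_k == 2

    def test_curve_matches_from_scratch_loocv(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(8, 24))
        labels = rng.integers(0, 2, size=24)
        while min(np.bincount(labels)) < 2:
            labels = rng.integers(0, 2, size=24)
        curve = ifs_curve(values, labels)
        for k in range(1, 9):
            assert curve.accuracies[k - 1] == pytest.approx(
                nna_loocv_accuracy(values[:k], labels)
            )

    def test_max_k_one_selects_top_gene(self, small_instance):
        _, cohort, _, _, _ = small_instance
        bm = sp.select_biomarkers(cohort, ("A", "B"), max_k=1)
        assert bm.optimal_genes == [bm.ranked_genes[0]]

    def test_optimal_set_is_ranking_prefix(self, small_instance):
        _, cohort, _, _, _ = small_instance
        bm = sp.select_biomarkers(cohort, ("A", "B"), max_k=15)
        k = bm.curve.optimal_k
        assert bm.optimal_genes == bm.ranked_genes[:k]
        assert max(bm.curve.accuracies) == bm.curve.accuracies[k - 1]

    def test_rejects_identical_contrast_stages(self, small_instance):
        _, cohort, _, _, _ = small_instance
        with pytest.raises(ValueError):
            sp.select_biomarkers(cohort, ("A", "A"))


class TestSelectorEstimator:
    def test_fit_selects_planted_features(self):
        rng = np.random.default_rng(12)
        y = np.repeat([0, 1], 25)
        X = rng.normal(size=(50, 30))
        X[:, 4] += 2.5 * y
        X[:, 9] += 2.5 * y
        sel = MRMRIFSSelector(max_k=6).fit(X, y)
        support = set(np.flatnonzero(sel.get_support()))
        assert {4, 9} <= support
        assert sel.transform(X).shape == (50, sel.optimal_k_)

    def test_composes_with_sklearn_pipeline(self):
        from sklearn.neighbors import KNeighborsClassifier
        from sklearn.pipeline import Pipeline

        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 20)
        X = rng.normal(size=(40, 15))
        X[:, 2] += 3.0 * y
        pipe = Pipeline(
            [("select", MRMRIFSSelector(max_k=4)), ("knn", KNeighborsClassifier(1))]
        )
        pipe.fit(X, y)
        assert pipe.score(X, y) >= 0.9

    def test_get_set_params_round_trip(self):
        sel = MRMRIFSSelector(scheme="MID", k_sd=0.5, max_k=7)
        assert MRMRIFSSelector(**sel.get_params()).get_params() == sel.get_params()

    def test_requires_two_classes(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            MRMRIFSSelector().fit(rng.normal(size=(9, 4)), [0, 1, 2] * 3)
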