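import numpy as np
import pytest
from cofea import (
    ValidationError,
    baseline_episcanpy,
    baseline_hda,
    baseline_signac,
    cluster_and_score,
    overlap_proportion,
    tfidf_transform,
)
from cofea.evaluation import _clisi
from cofea.simulate import SimulationSpec, simulate
from sklearn.metrics import (
    adjusted_mutual_info_score,
    adjusted_rand_score,
    homogeneity_score,
    normalized_mutual_info_score,
)

from conftest import make_count_matrix, random_count_matrix
from oracle_metrics import ami_oracle, ari_oracle, contingency, homo_oracle, nmi_oracle

@pytest.mark.parametrize("seed", range(5))
def test_metrics_match_textbook_formulas(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 50))
    true = rng.integers(0, 4, size=n)
    pred = rng.integers(0, 3, size=n)
    assert normalized_mutual_info_score(true, pred) == pytest.approx(
        nmi_oracle(true, pred), abs=1e-10
    )
    assert adjusted_mutual_info_score(true, pred) == pytest.approx(
        ami_oracle(true, pred), abs=1e-10
    )
    assert adjusted_rand_score(true, pred) == pytest.approx(
        ari_oracle(true, pred), abs=1e-10
    )
    assert homogeneity_score(true, pred) == pytest.approx(
        homo_oracle(true, pred), abs=1e-10
    )


def test_metrics_on_printed_contingency():
    # partitions realizing the 3x3 contingency [[5,1,0],[1,4,1],[0,2,6]]
    true = np.repeat([0, 1, 2], [6, 6, 8])
    pred = np.concatenate(
        [[0] * 5, [1], [0], [1] * 4, [2], [1] * 2, [2] * 6]
    )
    assert np.array_equal(
        contingency(true, pred), np.array([[5, 1, 0], [1, 4, 1], [0, 2, 6]])
    )
    assert normalized_mutual_info_score(true, pred) == pytest.approx(
        nmi_oracle(true, pred), abs=1e-10
    )
    assert adjusted_rand_score(true, pred) == pytest.approx(
        ari_oracle(true, pred), abs=1e-10
    )


class TestOverlapProportion:
    def test_half_overlap(self):
        assert overlap_proportion({1, 2, 3, 4}, {3, 4, 5, 6}) == 0.5

    def test_identical(self):
        assert overlap_proportion({1, 2}, {1, 2}) == 1.0

    def test_min_denominator(self):
        assert overlap_proportion({1, 2, 3, 4}, {1, 2}) == 1.0

    def test_random_subsets_match_set_arithmetic(self):
        rng = np.random.default_rng(0)
        sel = set(rng.choice(1000, 100, replace=False).tolist())
        truth = set(rng.choice(1000, 200, replace=False).tolist())
        assert overlap_proportion(sel, truth) == len(sel & truth) / 100

    def test_empty_selected_warns(self):
        with pytest.warns(UserWarning):
            assert overlap_proportion(set(), {1}) == 0.0

    def test_empty_truth_errors(self):
        with pytest.raises(ValidationError):
            overlap_proportion({1}, set())


class TestBaselines:
    def test_hda_prefers_prevalent(self):
        cm = make_count_matrix([[1, 1, 1, 0], [0, 1, 0, 0]])
        st = baseline_hda(cm, k=1)
        assert st.selected_set() == {0}

    def test_hda_tie_break(self):
        cm = make_count_matrix(np.ones((4, 3), dtype=int))
        st = baseline_hda(cm, k=2)
        assert st.selected_set() == {0, 1}

    def test_hda_matches_row_scan(self):
        cm = random_count_matrix(500, 40, density=0.3, seed=1)
        st = baseline_hda(cm, k=50)
        nnz = (cm.values.toarray() > 0).sum(axis=1)
        brute = set(sorted(range(500), key=lambda i: (-nnz[i], i))[:50])
        assert st.selected_set() == brute

    def test_hda_k_too_large(self, small_cm):
        with pytest.raises(ValidationError):
            baseline_hda(small_cm, k=small_cm.p + 1)

    def test_signac_identical_peaks_identical_scores(self):
        cm = make_count_matrix([[1, 2, 0], [1, 2, 0], [3, 0, 1]])
        st = baseline_signac(cm, k=3)
        assert st.score[0] == st.score[1]

    def test_signac_k_equals_p(self, small_cm):
        assert baseline_signac(small_cm, k=small_cm.p).selected.all()

    def test_signac_matches_rowsum_ranking(self):
        cm = random_count_matrix(300, 50, density=0.3, seed=2)
        st = baseline_signac(cm, k=30)
        rowsum = np.asarray(tfidf_transform(cm).values.sum(axis=1)).ravel()
        brute = set(sorted(range(300), key=lambda i: (-rowsum[i], i))[:30])
        assert st.selected_set() == brute

    def test_episcanpy_half_open_maximal(self):
        cm = make_count_matrix([[1, 1, 0, 0], [1, 1, 1, 1], [0, 0, 0, 1]])
        st = baseline_episcanpy(cm, k=1)
        assert st.score[0] == 1.0  # open in exactly half the cells
        assert st.score[1] == 0.0  # open in all cells
        assert st.selected_set() == {0}

    def test_episcanpy_symmetry(self):
        n = 20
        for k_open in range(0, 21):
            a = np.zeros((2, n), dtype=int)
            a[0, :k_open] = 1
            a[1, : n - k_open] = 1
            cm = make_count_matrix(np.vstack([a, np.ones((1, n), dtype=int)]))
            st = baseline_episcanpy(cm, k=1)
            assert st.score[0] == pytest.approx(st.score[1])


@pytest.fixture(scope="module")
def perfect_sim():
    spec = SimulationSpec(
        archetype="S1",
        n_cells_per_type=[40, 40, 40],
        n_specific_peaks_per_type=30,
        n_background_peaks=30,
        p_open_specific=1.0,
        p_open_offtype=0.0,
        p_open_background=0.2,
        depth_lambda=0.0,
        seed=0,
    )
    return simulate(spec)


class TestClusterAndScore:
    def test_perfectly_separable(self, perfect_sim):
        ds = perfect_sim
        rep = cluster_and_score(ds.counts, ds.specific_set, seed=0)
        assert rep.nmi == pytest.approx(1.0)
        assert rep.ami == pytest.approx(1.0)
        assert rep.ari == pytest.approx(1.0)
        assert rep.homo == pytest.approx(1.0)
        assert rep.clisi == pytest.approx(1.0)
        assert rep.n_clusters_found == 3
        assert 0 <= rep.asw <= 1

    def test_label_permutation_invariance_of_nmi(self):
        true = np.repeat([0, 1, 2], 10)
        relabeled = np.repeat([2, 0, 1], 10)
        assert normalized_mutual_info_score(true, relabeled) == pytest.approx(1.0)

    def test_requires_labels(self, perfect_sim):
        cm = perfect_sim.counts
        unlabeled = make_count_matrix(cm.values.toarray())
        with pytest.raises(ValidationError, match="labels"):
            cluster_and_score(unlabeled, perfect_sim.specific_set, seed=0)

    def test_too_few_selected(self, perfect_sim):
        with pytest.raises(ValidationError, match="10"):
            cluster_and_score(perfect_sim.counts, {1, 2, 3}, seed=0)

    def test_small_type_warns(self):
        spec = SimulationSpec(
            archetype="S1",
            n_cells_per_type=[30, 2],
            n_specific_peaks_per_type=15,
            n_background_peaks=15,
            p_open_specific=0.9,
            p_open_offtype=0.02,
            p_open_background=0.3,
            seed=1,
        )
        ds = simulate(spec)
        with pytest.warns(UserWarning, match="fewer than 3"):
            cluster_and_score(ds.counts, ds.specific_set, seed=0)


class TestClisi:
    def test_perfect_separation(self):
        emb = np.vstack([np.zeros((20, 2)), np.full((20, 2), 100.0)])
        labels = np.repeat(["a", "b"], 20)
        assert _clisi(emb, labels, n_neighbors=10) == pytest.approx(1.0)

    def test_full_mixing_low(self):
        rng = np.random.default_rng(0)
        emb = rng.normal(size=(200, 2))
        labels = rng.choice(["a", "b"], size=200)
        assert _clisi(emb, labels, n_neighbors=30) < 0.3

    def test_single_type(self):
        emb = np.random.default_rng(0).normal(size=(20, 2))
        assert _clisi(emb, np.repeat(["a"], 20)) == 1.0
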