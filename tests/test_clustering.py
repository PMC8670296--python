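"""UPGMA average linkage, differential scores, and candidate-cluster picks."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

import methpanel as mp


def upgma_oracle(d):
    """Brute-force UPGMA: recompute every inter-cluster average from the raw
    distance matrix at every step (independent of the incremental update)."""
    n = d.shape[0]
    clusters = {i: (i,) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters), 2):
            avg = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
            key = (avg, (a, b))
            if best is None or key < best:
                best = key
        (h, (a, b)) = best
        merges.append((a, b, h, len(clusters[a]) + len(clusters[b])))
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        next_id += 1
    return np.array(merges)


def beta_from_blocks(values, classes, probes=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = [f"s{j}" for j in range(values.shape[1])]
    return mp.BetaMatrix(
        pd.DataFrame(values, index=probes, columns=samples),
        pd.Series(classes, index=samples),
    )


class TestPairwiseEuclidean:
    def test_identical_rows_zero(self):
        d = mp.pairwise_euclidean([[0.2, 0.4], [0.2, 0.4]])
        assert d[0, 1] == 0.0

    def test_three_four_five(self):
        d = mp.pairwise_euclidean([[0.0, 0.0], [3.0, 4.0]])
        assert d[0, 1] == pytest.approx(5.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        x = rng.random((6, 4))
        d = mp.pairwise_euclidean(x)
        for i in range(6):
            for j in range(6):
                expected = np.sqrt(((x[i] - x[j]) ** 2).sum())
                assert d[i, j] == pytest.approx(expected)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)

    def test_single_row_rejected(self):
        with pytest.raises(mp.ValidationError):
            mp.pairwise_euclidean([[1.0, 2.0]])


class TestAverageLinkage:
    def test_three_point_example(self):
        d = np.array([[0, 1, 10], [1, 0, 10], [10, 10, 0]], dtype=float)
        dend = mp.average_linkage(d)
        assert tuple(dend.merges[0][:3]) == (0.0, 1.0, 1.0)
        assert dend.merges[1][2] == pytest.approx(10.0)
        assert dend.merges[1][3] == 3

    def test_duplicate_points_merge_at_zero(self):
        x = np.array([[0.5, 0.5], [0.5, 0.5], [0.9, 0.1]])
        dend = mp.average_linkage(mp.pairwise_euclidean(x))
        assert dend.merges[0][2] == 0.0

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        d = mp.pairwise_euclidean(rng.random((n, 3)))
        dend = mp.average_linkage(d)
        assert np.allclose(dend.merges, upgma_oracle(d))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_average_linkage(self, seed):
        rng = np.random.default_rng(seed)
        d = mp.pairwise_euclidean(rng.random((7, 4)))
        ours = mp.average_linkage(d).merges
        theirs = sch.linkage(squareform(d, checks=False), method="average")
        assert np.allclose(ours[:, 2], theirs[:, 2])
        assert np.allclose(ours[:, 3], theirs[:, 3])

    def test_monotone_merge_heights(self):
        rng = np.random.default_rng(4)
        dend = mp.average_linkage(mp.pairwise_euclidean(rng.random((8, 5))))
        assert (np.diff(dend.merges[:, 2]) >= -1e-12).all()

    def test_row_permutation_invariance_with_distinct_distances(self):
        rng = np.random.default_rng(11)
        x = rng.random((6, 4))
        d = mp.pairwise_euclidean(x)
        perm = rng.permutation(6)
        d_perm = mp.pairwise_euclidean(x[perm])
        a = mp.average_linkage(d)
        b = mp.average_linkage(d_perm)
        assert np.allclose(np.sort(a.merges[:, 2]), np.sort(b.merges[:, 2]))

    def test_tie_events_logged(self):
        # equilateral: every pair at the same distance
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        dend = mp.average_linkage(d)
        assert dend.tie_events
        assert tuple(dend.merges[0][:2]) == (0.0, 1.0)  # lowest pair index


class TestCutAndScores:
    def test_cut_by_k_and_by_height_agree(self):
        rng = np.random.default_rng(6)
        dend = mp.average_linkage(mp.pairwise_euclidean(rng.random((7, 3))))
        k_labels = mp.cut_dendrogram(dend, k=3)
        h = dend.merges[-3, 2]  # cut just below the (n-3+1)-th merge
        h_labels = mp.cut_dendrogram(dend, height=(h + dend.merges[-2, 2]) / 2)
        assert len(set(k_labels)) == 3
        assert (k_labels == h_labels).all()

    def test_differential_score_trivials(self):
        beta = beta_from_blocks(
            [[0.5, 0.5, 0.5, 0.5], [1.0, 1.0, 0.0, 0.0]],
            [mp.CARCINOMA, mp.CARCINOMA, mp.NORMAL, mp.NORMAL],
        )
        scores = mp.differential_score(beta)
        assert scores["p0"] == 0.0 and scores["p1"] == 1.0

    def test_differential_score_matches_hand_means(self):
        rng = np.random.default_rng(8)
        values = rng.random((5, 6))
        classes = [mp.CARCINOMA] * 4 + [mp.NORMAL] * 2
        beta = beta_from_blocks(values, classes)
        scores = mp.differential_score(beta)
        for i in range(5):
            assert scores.iloc[i] == pytest.approx(
                values[i, :4].mean() - values[i, 4:].mean()
            )

    def test_differential_score_linear_in_beta(self):
        rng = np.random.default_rng(13)
        values = rng.random((4, 5))
        classes = [mp.CARCINOMA] * 3 + [mp.NORMAL] * 2
        s1 = mp.differential_score(beta_from_blocks(values, classes))
        s2 = mp.differential_score(beta_from_blocks(0.5 * values, classes))
        assert np.allclose(0.5 * s1, s2)

    def test_single_class_rejected(self):
        beta = beta_from_blocks([[0.1, 0.2]], [mp.CARCINOMA, mp.CARCINOMA])
        with pytest.raises(mp.ValidationError):
            mp.differential_score(beta)


class TestCandidateCluster:
    def test_recovers_differential_block_exactly(self):
        beta = mp.generate_beta_matrix(
            n_diff_probes=6, n_null_probes=8, noise_sd=0.0, seed=1
        )
        result = mp.candidate_cluster(beta, k=2)
        assert set(result.probes) == {f"cg_diff_{i + 1:03d}" for i in range(6)}

    def test_recovers_block_under_noise(self):
        beta = mp.generate_beta_matrix(seed=3)
        result = mp.candidate_cluster(beta, k=2)
        assert set(result.probes) == {f"cg_diff_{i + 1:03d}" for i in range(13)}

    def test_min_score_above_one_yields_empty_with_warning(self):
        beta = mp.generate_beta_matrix(seed=2)
        with pytest.warns(UserWarning, match="min_score"):
            result = mp.candidate_cluster(beta, k=2, min_score=1.5)
        assert result.probes == ()

    def test_every_probe_its_own_cluster_returns_singleton_max(self):
        beta = mp.generate_beta_matrix(
            n_diff_probes=3, n_null_probes=3, noise_sd=0.02, seed=5
        )
        n = len(beta.values)
        result = mp.candidate_cluster(beta, k=n)
        scores = mp.differential_score(beta)
        assert len(result.probes) == 1
        assert result.probes[0] == scores.idxmax()

    def test_manual_include_list(self):
        beta = mp.generate_beta_matrix(seed=4)
        result = mp.candidate_cluster(beta, k=2, include=("cg_null_001",))
        assert "cg_null_001" in result.probes

    def test_probe_to_gene_collapse(self):
        beta = mp.generate_beta_matrix(
            n_diff_probes=4, n_null_probes=4, noise_sd=0.0, seed=6
        )
        beta.probe_to_gene = {
            "cg_diff_001": "TWIST1", "cg_diff_002": "TWIST1",
            "cg_diff_003": "HIN1", "cg_diff_004": "HIN1",
        }
        result = mp.candidate_cluster(beta, k=2)
        assert result.genes == ("TWIST1", "HIN1")


def test_dropping_incomplete_probes_is_logged_not_imputed():
    values = np.array([[0.1, 0.2, 0.3], [np.nan, 0.5, 0.6]])
    beta = beta_from_blocks(values, [mp.CARCINOMA, mp.CARCINOMA, mp.NORMAL])
    clean = beta.drop_incomplete_probes()
    assert list(clean.values.index) == ["p0"]


def test_newick_export_contains_all_leaves():
    rng = np.random.default_rng(7)
    labels = ["A", "B", "C", "D"]
    dend = mp.average_linkage(mp.pairwise_euclidean(rng.random((4, 3))))
    text = mp.to_newick(dend, labels)
    assert text.endswith(";")
    for lab in labels:
        assert lab in text
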