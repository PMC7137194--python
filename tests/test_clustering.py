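"""Strong/relaxed selection, PAM, silhouette, cluster summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from quantdeg import (
    choose_k,
    mean_silhouette,
    pam_cluster,
    strong_relaxed_flags,
    summarize_clusters,
)


class TestStrongRelaxedFlags:
    def test_zero_fp_is_strong_and_relaxed(self):
        strong, relaxed = strong_relaxed_flags(np.array([0.0, 1.0, 9.0]), 8.24)
        np.testing.assert_array_equal(strong, [True, False, False])
        np.testing.assert_array_equal(relaxed, [True, True, False])

    def test_boundary_is_strict(self):
        _, relaxed = strong_relaxed_flags(np.array([8.24]), 8.24)
        assert not relaxed[0]

    def test_strong_subset_of_relaxed(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            fp = np.round(rng.uniform(0, 10, 20), 1)
            fp[rng.random(20) < 0.3] = 0.0
            strong, relaxed = strong_relaxed_flags(fp, rng.uniform(0, 10))
            assert (relaxed | ~strong).all()

    def test_degenerate_zero_reference_keeps_strong_relaxed(self):
        strong, relaxed = strong_relaxed_flags(np.array([0.0, 2.0]), 0.0)
        assert strong[0] and relaxed[0] and not relaxed[1]


def pam_brute_force(points, k):
    """Exhaustive minimum over all medoid subsets (m <= 8)."""
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(points))
    best = (np.inf, None)
    for subset in itertools.combinations(range(len(points)), k):
        cost = D[:, subset].min(axis=1).sum()
        if cost < best[0] - 1e-12:
            best = (cost, subset)
    return best


class TestPamCluster:
    def test_recovers_separated_blobs(self):
        pts = np.array([[0, 0], [0.1, 0], [0, 0.1], [10, 10], [10.1, 10], [10, 10.1]])
        medoids, assignment = pam_cluster(pts, 2)
        assert len(set(assignment[:3])) == 1 and len(set(assignment[3:])) == 1
        assert assignment[0] != assignment[3]
        cost = pam_brute_force(pts, 2)[0]
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(pts))
        assert D[:, medoids].min(axis=1).sum() == pytest.approx(cost)

    @pytest.mark.parametrize("m,k", [(5, 2), (6, 2), (7, 3), (8, 3), (8, 4)])
    def test_matches_exhaustive_optimum(self, m, k):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(m * 10 + k)
        for _ in range(20):
            pts = rng.standard_normal((m, 3))
            medoids, _ = pam_cluster(pts, k)
            D = squareform(pdist(pts))
            cost = D[:, medoids].min(axis=1).sum()
            assert cost == pytest.approx(pam_brute_force(pts, k)[0], abs=1e-9)

    def test_k_equals_m_minus_one(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((6, 2))
        medoids, _ = pam_cluster(pts, 5)
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(pts))
        non_medoid = [i for i in range(6) if i not in medoids]
        assert len(non_medoid) == 1
        assert D[:, medoids].min(axis=1).sum() == pytest.approx(
            D[non_medoid[0], medoids].min()
        )

    def test_duplicated_points_double_the_cost(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(4)
        pts = rng.standard_normal((7, 2))
        medoids, _ = pam_cluster(pts, 3)
        D = squareform(pdist(pts))
        cost = D[:, medoids].min(axis=1).sum()
        doubled = np.vstack([pts, pts])
        med2, _ = pam_cluster(doubled, 3)
        D2 = squareform(pdist(doubled))
        assert D2[:, med2].min(axis=1).sum() == pytest.approx(2 * cost)

    def test_swap_path_reaches_single_swap_local_optimum(self):
        # large enough that the BUILD+SWAP path (not exact enumeration) runs
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(11)
        pts = rng.standard_normal((30, 3))
        medoids, _ = pam_cluster(pts, 3)
        D = squareform(pdist(pts))
        cost = D[:, medoids].min(axis=1).sum()
        for mi in range(3):
            for c in range(30):
                if c in medoids:
                    continue
                trial = medoids.copy()
                trial[mi] = c
                assert D[:, trial].min(axis=1).sum() >= cost - 1e-12

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            pam_cluster(np.zeros((4, 2)), 4)


def silhouette_oracle(points, labels):
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(points))
    vals = []
    for i, li in enumerate(labels):
        own = [D[i, j] for j in range(len(labels)) if labels[j] == li and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean(own)
        b = min(
            np.mean([D[i, j] for j in range(len(labels)) if labels[j] == lo])
            for lo in set(labels) if lo != li
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


class TestMeanSilhouette:
    def test_far_blobs_approach_one(self):
        pts = np.vstack([np.random.default_rng(0).normal(0, 0.01, (5, 2)),
                         np.random.default_rng(1).normal(1000, 0.01, (5, 2))])
        labels = np.array([0] * 5 + [1] * 5)
        assert mean_silhouette(pts, labels) > 0.999

    def test_regular_simplex_scores_zero(self):
        # 4 mutually equidistant points, arbitrary 2/2 split: a = b everywhere
        pts = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]])
        assert mean_silhouette(pts, np.array([0, 0, 1, 1])) == pytest.approx(0.0)

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(2)
        pts = rng.standard_normal((6, 2))
        labels = np.array([0, 0, 1, 1, 2, 2])
        assert mean_silhouette(pts, labels) == pytest.approx(
            silhouette_oracle(pts, labels), abs=1e-12
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="2 clusters"):
            mean_silhouette(np.zeros((4, 2)), np.zeros(4, dtype=int))


class TestChooseK:
    def test_three_blobs_found(self):
        rng = np.random.default_rng(5)
        pts = np.vstack([rng.normal(c, 0.05, (8, 2)) for c in (0, 10, 20)])
        k, widths = choose_k(pts, 10)
        assert k == 3
        assert widths[3] == max(widths.values())

    def test_single_candidate(self):
        rng = np.random.default_rng(6)
        k, _ = choose_k(rng.standard_normal((10, 2)), 2)
        assert k == 2


def _score_table(rng, n=20):
    return pd.DataFrame(
        {
            "gene": [f"G{i}" for i in range(n)],
            "OR": rng.uniform(1, 100, n),
            "FP": rng.uniform(0, 10, n),
            "dFP": rng.uniform(0, 50, n),
        }
    )


class TestSummarizeClusters:
    def test_sizes_partition_and_or_ordering(self):
        rng = np.random.default_rng(7)
        table = _score_table(rng)
        summary = summarize_clusters(table, k=3)
        assert sum(summary.sizes) == len(table)
        means = summary.characteristics["mean_OR"].to_numpy()
        assert (np.diff(means) <= 0).all()

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(8)
        table = _score_table(rng)
        shuffled = table.sample(frac=1, random_state=1).reset_index(drop=True)
        a = summarize_clusters(table, k=2)
        b = summarize_clusters(shuffled, k=2)
        assert a.sizes == b.sizes
        assert [set(m) for m in a.members] == [set(m) for m in b.members]

    def test_identical_rows_have_zero_spread(self):
        table = pd.DataFrame(
            {"gene": list("abcd"), "OR": [5.0] * 4, "FP": [1.0] * 4, "dFP": [2.0] * 4}
        )
        summary = summarize_clusters(table, k=2)
        assert (summary.characteristics[["sd_OR", "sd_FP", "sd_dFP"]].to_numpy() == 0).all()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            summarize_clusters(pd.DataFrame(columns=["gene", "OR", "FP", "dFP"]))
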