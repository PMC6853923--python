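"""Classical MDS, the distance-group summaries, and the rank-sum test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from repclone.io import SampleId, build_cohort
from repclone.mds import (
    MDSResult,
    classical_mds,
    distance_groups,
    pooled_mds,
    wilcoxon_rank_sum,
)
from repclone.overlap import build_matrix
from repclone.simulate import SyntheticConfig, generate_cohort


def sid(tissue, subset, donor="D1"):
    return SampleId(donor, tissue, "CD4", subset)


class TestClassicalMDS:
    def test_full_rank_reproduces_euclidean_distances(self):
        rng = np.random.default_rng(0)
        points = rng.random((7, 5))
        d = squareform(pdist(points))
        coords, eigval, n_neg = classical_mds(d, n_dims=None)
        np.testing.assert_allclose(squareform(pdist(coords)), d, atol=1e-8)
        assert n_neg == 0

    def test_identical_points_coincide(self):
        d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        coords, _, _ = classical_mds(d, n_dims=None)
        np.testing.assert_allclose(coords[0], coords[1], atol=1e-10)

    def test_3_4_5_triangle_recovered_up_to_rigid_motion(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        coords, _, _ = classical_mds(d, n_dims=2)
        np.testing.assert_allclose(squareform(pdist(coords)), d, atol=1e-10)

    def test_sign_convention_makes_embedding_deterministic(self):
        rng = np.random.default_rng(3)
        d = squareform(pdist(rng.random((6, 4))))
        c1, _, _ = classical_mds(d)
        c2, _, _ = classical_mds(d)
        np.testing.assert_array_equal(c1, c2)
        for axis in c1.T:
            nz = axis[np.abs(axis) > 1e-12]
            assert nz[0] > 0

    def test_degenerate_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            classical_mds(np.zeros((4, 4)))

    def test_matches_scikit_bio_pcoa(self):
        """Independent oracle: embedding distances agree with scikit-bio's PCoA."""
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(1)
        d = squareform(pdist(rng.random((8, 6))))
        coords, _, _ = classical_mds(d, n_dims=None)
        theirs = pcoa(d).samples.to_numpy()
        np.testing.assert_allclose(
            squareform(pdist(coords)), squareform(pdist(theirs)), atol=1e-8
        )


def test_pooled_mds_runs_on_synthetic_cohort():
    cfg = SyntheticConfig(
        n_donors=2, subsets=(("CD4", "CM"), ("CD4", "EM"), ("CD4", "TRM")),
        pool_size_per_tissue=500, sample_depth=1000, seed=2,
    )
    matrix = build_matrix(build_cohort(generate_cohort(cfg)))
    result = pooled_mds(matrix, n_dims=2)
    assert result.coords.shape == (12, 2)
    assert result.eigenvalues[0] > 0


def mds_result_from_coords(coords):
    frame = pd.DataFrame(coords).T
    frame.columns = ["axis_1", "axis_2"]
    frame.index = pd.Index(list(coords.keys()), tupleize_cols=False)
    return MDSResult(frame, np.ones(2), 0)


class TestDistanceGroups:
    def test_coincident_lung_memory_gives_zero_within(self):
        coords = {
            sid("lung", "CM"): [1.0, 1.0],
            sid("lung", "EM"): [1.0, 1.0],
            sid("lung", "TRM"): [1.0, 1.0],
            sid("LDLN", "CM"): [0.0, 0.0],
            sid("LDLN", "EM"): [0.0, 2.0],
        }
        (g,) = distance_groups(mds_result_from_coords(coords))
        assert g.within_lung_memory == pytest.approx(0.0)

    def test_right_triangle_mean_pairwise(self):
        coords = {
            sid("lung", "CM"): [0.0, 0.0],
            sid("lung", "EM"): [0.0, 3.0],
            sid("lung", "TRM"): [4.0, 0.0],
            sid("LDLN", "CM"): [9.0, 9.0],
            sid("LDLN", "EM"): [9.0, 10.0],
        }
        (g,) = distance_groups(mds_result_from_coords(coords))
        assert g.within_lung_memory == pytest.approx((3 + 4 + 5) / 3)

    def test_identical_cross_tissue_subset_contributes_zero(self):
        coords = {
            sid("lung", "TRM"): [2.0, 2.0],
            sid("LDLN", "TRM"): [2.0, 2.0],
        }
        (g,) = distance_groups(mds_result_from_coords(coords))
        assert g.cross_tissue_identical == pytest.approx(0.0)

    def test_naive_vs_memory_mean_and_missing_entries(self):
        coords = {
            sid("lung", "naive"): [0.0, 0.0],
            sid("lung", "CM"): [3.0, 0.0],
            sid("lung", "EM"): [0.0, 5.0],
            sid("LDLN", "CM"): [7.0, 7.0],
        }
        (g,) = distance_groups(mds_result_from_coords(coords))
        assert g.naive_vs_memory_lung == pytest.approx(4.0)
        # the donor has no LDLN naive sample: absent, never imputed
        assert g.naive_vs_memory_ldln is None
        assert "naive_vs_memory_ldln" in g.missing


def rank_sum_permutation_oracle(a, b):
    """Exhaustive two-sided permutation distribution of the Mann-Whitney U."""

    def u_stat(x, y):
        return sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
            1 for xi in x for yi in y if xi == yi
        )

    pooled = list(a) + list(b)
    n_a = len(a)
    observed = u_stat(a, b)
    n_b = len(b)
    mean_u = n_a * n_b / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        x = [pooled[i] for i in idx]
        y = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(x, y) - mean_u) >= abs(observed - mean_u) - 1e-12:
            count += 1
    return count / total


class TestWilcoxonRankSum:
    def test_identical_groups_give_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            _, p = wilcoxon_rank_sum([2.0, 2.0, 2.0], [2.0, 2.0])
        assert p == 1.0

    def test_fully_separated_triples(self):
        # 2 / C(6,3) extreme arrangements
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_two_singletons_cannot_reach_significance(self):
        _, p = wilcoxon_rank_sum([1.0], [2.0])
        assert p == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_matches_exhaustive_permutation_for_small_groups(self):
        """Exact p equals full enumeration for all tie-free splits with n_a+n_b <= 10."""
        rng = np.random.default_rng(7)
        for n_a in range(1, 6):
            for n_b in range(n_a, 11 - n_a):
                values = rng.permutation(np.arange(1, n_a + n_b + 1, dtype=float))
                a, b = values[:n_a], values[n_a:]
                _, p = wilcoxon_rank_sum(a, b)
                assert p == pytest.approx(rank_sum_permutation_oracle(a, b), abs=1e-12)
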