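"""Clone matrices, sharing filters, donor inclusion, and top-overlap ranking."""

import numpy as np
import pytest

from repclone.io import build_cohort
from repclone.overlap import build_matrix, select_donors, top_overlap_clones
from repclone.simulate import SyntheticConfig, generate_cohort

from conftest import make_records, make_sample_rows, PRODUCTIVE_NT


class TestBuildMatrix:
    def test_disjoint_samples_leave_no_shared_columns(self):
        rows = make_sample_rows("D1", "lung", "CM", [(PRODUCTIVE_NT[0], 1)])
        rows += make_sample_rows("D1", "lung", "EM", [(PRODUCTIVE_NT[1], 1)])
        matrix = build_matrix(build_cohort(make_records(rows)))
        assert matrix.frame.shape[1] == 0

    def test_shared_clone_keeps_frequencies(self):
        a, b, c = PRODUCTIVE_NT[:3]
        rows = make_sample_rows("D1", "lung", "CM", [(a, 6), (b, 4)])
        rows += make_sample_rows("D1", "lung", "EM", [(b, 1), (c, 9)])
        matrix = build_matrix(build_cohort(make_records(rows)))
        assert matrix.clone_keys == [b]
        np.testing.assert_allclose(np.sort(matrix.frame[b].to_numpy()), [0.1, 0.4])

    def test_no_filter_keeps_union(self):
        rows = make_sample_rows("D1", "lung", "CM", [(PRODUCTIVE_NT[0], 1)])
        rows += make_sample_rows("D1", "lung", "EM", [(PRODUCTIVE_NT[1], 1)])
        matrix = build_matrix(build_cohort(make_records(rows)), clone_filter="none")
        assert matrix.frame.shape[1] == 2

    def test_fewer_than_two_samples_rejected(self):
        rows = make_sample_rows("D1", "lung", "CM", [(PRODUCTIVE_NT[0], 1)])
        with pytest.raises(ValueError, match="2 samples"):
            build_matrix(build_cohort(make_records(rows)))

    def test_filtered_matrix_has_no_singleton_columns(self):
        cfg = SyntheticConfig(
            n_donors=2, subsets=(("CD4", "CM"), ("CD4", "EM"), ("CD4", "TRM")),
            pool_size_per_tissue=500, sample_depth=1000, seed=4,
        )
        matrix = build_matrix(build_cohort(generate_cohort(cfg)))
        nonzero_rows = (matrix.frame.to_numpy() > 0).sum(axis=0)
        assert matrix.frame.shape[1] > 0
        assert (nonzero_rows >= 2).all()

    def test_row_sums_never_exceed_one(self):
        cfg = SyntheticConfig(
            n_donors=1, subsets=(("CD4", "CM"), ("CD4", "EM")),
            pool_size_per_tissue=400, sample_depth=800, seed=8,
        )
        matrix = build_matrix(build_cohort(generate_cohort(cfg)))
        assert (matrix.frame.sum(axis=1) <= 1 + 1e-9).all()


def _productive_12mers(n):
    """n distinct productive 12-nt CDR3s, generated deterministically."""
    from repclone.io import is_productive

    bases = "ACGT"
    out, i = [], 0
    while len(out) < n:
        tail = "".join(bases[(i >> (2 * k)) & 3] for k in range(5))
        nt = "TGTGCCG" + tail  # 12 nt; only the final codon can hit a stop
        i += 1
        if is_productive(nt):
            out.append(nt)
    return out


def _donor_with_shared(n_shared):
    """A donor with 3 CD4 subsets per tissue sharing exactly n_shared clones.

    The shared clones sit in lung CM and lung EM; every other sample carries
    one unique private clone, so the donor-level shared-clone count is exact.
    """
    pool = _productive_12mers(n_shared + 6)
    shared, privates = pool[:n_shared], pool[n_shared:]
    rows = []
    for t, tissue in enumerate(("lung", "LDLN")):
        for k, subset in enumerate(("CM", "EM", "TRM")):
            if tissue == "lung" and k < 2:
                clones = [(nt, 1) for nt in shared]
            else:
                clones = [(privates[3 * t + k], 1)]
            rows += make_sample_rows("D1", tissue, subset, clones)
    return build_cohort(make_records(rows))


class TestSelectDonors:
    def test_rich_donor_included(self):
        cohort = _donor_with_shared(500)
        (report,) = select_donors(cohort)
        assert report.included and report.n_shared_clones == 500

    def test_too_few_lung_subsets_excluded_with_reason(self):
        cohort = {
            sid: s for sid, s in _donor_with_shared(500).items()
            if not (sid.tissue == "lung" and sid.subset == "TRM")
        }
        (report,) = select_donors(cohort)
        assert not report.included
        assert any("lung subsets < 3" in r for r in report.reasons)

    @pytest.mark.parametrize("n_shared, included", [(150, False), (151, True)])
    def test_shared_clone_boundary_is_strict(self, n_shared, included):
        """Exactly 150 shared clones excludes the donor; 151 includes it."""
        (report,) = select_donors(_donor_with_shared(n_shared))
        assert report.included is included
        assert report.n_shared_clones == n_shared


class TestTopOverlapClones:
    def _matrix(self, columns):
        rows = []
        for subset, clones in columns.items():
            rows += make_sample_rows("D1", "lung", subset, clones)
        rows += make_sample_rows("D1", "LDLN", "CM", [("TGTGCCAGG", 1)])
        return build_matrix(build_cohort(make_records(rows)))

    def test_returns_all_when_fewer_than_n(self):
        a, b, c = PRODUCTIVE_NT[:3]
        matrix = self._matrix({"CM": [(a, 1), (b, 1), (c, 1)], "EM": [(a, 1), (b, 1), (c, 1)]})
        assert len(top_overlap_clones(matrix, n=75)) == 3

    def test_breadth_outranks_frequency(self):
        a, b = PRODUCTIVE_NT[:2]
        matrix = self._matrix(
            {
                "CM": [(a, 1), (b, 99)],
                "EM": [(a, 1), (b, 99)],
                "TRM": [(a, 1)],
            }
        )
        ranked = top_overlap_clones(matrix, n=2)
        assert ranked[0] == a  # in 3 subsets, despite tiny frequency

    def test_equal_breadth_breaks_by_summed_frequency(self):
        a, b = PRODUCTIVE_NT[:2]
        matrix = self._matrix({"CM": [(a, 30), (b, 12), ("TGTGCCAGT", 58)],
                               "EM": [(a, 30), (b, 12), ("TGTGCCAGT", 58)]})
        ranked = top_overlap_clones(matrix, n=3)
        assert ranked.index("TGTGCCAGT") == 0
        assert ranked.index(a) < ranked.index(b)


def test_within_tissue_sharing_beats_cross_tissue_sign_test():
    """share_within >> share_cross: within-tissue memory pairs share more clones
    than cross-tissue pairs of the identical subset, in every one of 10 seeds."""
    wins = 0
    for seed in range(10):
        cfg = SyntheticConfig(
            n_donors=1, subsets=(("CD4", "CM"), ("CD4", "EM"), ("CD4", "TRM")),
            pool_size_per_tissue=500, sample_depth=1200,
            share_within=0.3, share_cross=0.02, seed=seed,
        )
        cohort = build_cohort(generate_cohort(cfg))
        sets = {sid: set(s.clones["cdr3_nt"]) for sid, s in cohort.items()}
        within, cross = [], []
        for a in sets:
            for b in sets:
                if a >= b:
                    continue
                n = len(sets[a] & sets[b])
                if a.tissue == b.tissue:
                    within.append(n)
                elif a.subset == b.subset:
                    cross.append(n)
        if np.mean(within) > np.mean(cross):
            wins += 1
    assert wins == 10
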