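import pandas as pd
import pytest

from repclone.io import annotate_productive, build_cohort

# 9-nt productive CDR3s used to build deterministic toy clones
PRODUCTIVE_NT = [
    "TGTGCCAGC", "TGTGCCTCC", "TGTGCCTGG", "TGTGCCGGC", "TGTGCCCAC",
    "TGTGCCAAC", "TGTGCCGAC", "TGTGCCTAC", "TGTGCCATC", "TGTGCCTTC",
]


def make_records(rows):
    """Build a native clone table from (donor, tissue, lineage, subset, nt, v, j, count) tuples."""
    frame = pd.DataFrame(
        rows,
        columns=["donor_id", "tissue", "lineage", "subset", "cdr3_nt", "v_gene", "j_gene",
                 "read_count"],
    )
    return annotate_productive(frame)


def make_sample_rows(donor, tissue, subset, clones, lineage="CD4"):
    """(nt, count) pairs -> native rows for one sample."""
    return [(donor, tissue, lineage, subset, nt, "V5-1", "J1-1", count) for nt, count in clones]


@pytest.fixture
def toy_cohort():
    """Two donors, two tissues, naive + memory subsets with overlapping clones."""
    rows = []
    rows += make_sample_rows("D1", "lung", "CM", [(PRODUCTIVE_NT[0], 6), (PRODUCTIVE_NT[1], 4)])
    rows += make_sample_rows("D1", "lung", "EM", [(PRODUCTIVE_NT[0], 3), (PRODUCTIVE_NT[2], 7)])
    rows += make_sample_rows("D1", "LDLN", "CM", [(PRODUCTIVE_NT[3], 5), (PRODUCTIVE_NT[4], 5)])
    rows += make_sample_rows("D1", "lung", "naive", [(PRODUCTIVE_NT[i], 1) for i in range(5, 9)])
    rows += make_sample_rows("D2", "lung", "CM", [(PRODUCTIVE_NT[9], 10)])
    return build_cohort(make_records(rows))
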