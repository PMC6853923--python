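"""Sample-by-clonotype frequency matrices, donor inclusion rules, and top-overlap clones.

The sharing filters mirror the study design: the pooled (cohort-level)
analyses keep clonotypes present in two or more samples, and the per-donor
analyses keep clonotypes present in more than one of that donor's CD4
subsets.  Donors enter the clonal analyses only when they have repertoire
data in at least three CD4 subsets from each tissue and more than 150
clonotypes shared between subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import Cohort, SampleId

__all__ = [
    "CloneMatrix",
    "InclusionReport",
    "build_matrix",
    "select_donors",
    "top_overlap_clones",
]

CloneFilter = Literal["ge2_samples", "none"]


@dataclass
class CloneMatrix:
    """Samples x clonotypes matrix of within-sample frequencies.

    Frequencies (not raw counts) make samples of different sequencing depths
    comparable.  Rows are :class:`SampleId`; columns are CDR3 nucleotide
    keys in lexicographic order.  Under the ``ge2_samples`` filter every
    retained column is nonzero in at least two rows.
    """

    frame: pd.DataFrame
    clone_filter: CloneFilter

    @property
    def sample_ids(self) -> list[SampleId]:
        return list(self.frame.index)

    @property
    def clone_keys(self) -> list[str]:
        return list(self.frame.columns)


def build_matrix(samples: Cohort, clone_filter: CloneFilter = "ge2_samples") -> CloneMatrix:
    """Assemble the frequency matrix for a set of samples.

    ``samples`` is whatever scope the caller selected (the whole cohort, or
    one donor's CD4 samples); the sharing filter drops clonotype columns
    nonzero in fewer than two of the given samples.
    """
    if len(samples) < 2:
        raise ValueError(f"need at least 2 samples to build a clone matrix, got {len(samples)}")
    if clone_filter not in ("ge2_samples", "none"):
        raise ValueError(f"unknown clone filter {clone_filter!r}")
    columns: dict[SampleId, pd.Series] = {}
    for sid, sample in samples.items():
        columns[sid] = pd.Series(
            sample.frequencies, index=sample.clones["cdr3_nt"].to_numpy(), dtype=float
        )
    frame = pd.DataFrame(columns).T.fillna(0.0)
    frame = frame.reindex(sorted(frame.columns), axis=1)
    if clone_filter == "ge2_samples":
        shared = (frame.to_numpy() > 0).sum(axis=0) >= 2
        frame = frame.loc[:, shared]
    frame.index = pd.Index([SampleId(*sid) for sid in frame.index], tupleize_cols=False)
    return CloneMatrix(frame, clone_filter)


@dataclass
class InclusionReport:
    """Why one donor passed or failed the clonal-analysis inclusion rule."""

    donor_id: str
    n_subsets_lung: int
    n_subsets_ldln: int
    n_shared_clones: int
    included: bool
    reasons: list[str] = field(default_factory=list)


def shared_clone_count(samples: Cohort) -> int:
    """Number of clonotypes present in more than one of the given samples."""
    tally: dict[str, int] = {}
    for sample in samples.values():
        for nt in sample.clones["cdr3_nt"]:
            tally[nt] = tally.get(nt, 0) + 1
    return sum(1 for n in tally.values() if n >= 2)


def select_donors(
    cohort: Cohort,
    lineage: str = "CD4",
    tissues: Sequence[str] = ("lung", "LDLN"),
    min_subsets_per_tissue: int = 3,
    min_shared_clones: int = 150,
) -> list[InclusionReport]:
    """Apply the donor-inclusion rule for the per-donor clonal analyses.

    A donor is included iff it has data in at least ``min_subsets_per_tissue``
    distinct ``lineage`` subsets in *each* tissue, and strictly more than
    ``min_shared_clones`` clonotypes occur in more than one of its
    ``lineage`` subsets.  (A donor with exactly ``min_shared_clones`` shared
    clonotypes is excluded.)
    """
    reports = []
    donor_ids = sorted({sid.donor_id for sid in cohort})
    t_a, t_b = tissues
    for donor_id in donor_ids:
        donor_samples = {
            sid: s
            for sid, s in cohort.items()
            if sid.donor_id == donor_id and sid.lineage == lineage and s.n_clones > 0
        }
        n_a = len({sid.subset for sid in donor_samples if sid.tissue == t_a})
        n_b = len({sid.subset for sid in donor_samples if sid.tissue == t_b})
        n_shared = shared_clone_count(donor_samples)
        reasons = []
        if n_a < min_subsets_per_tissue:
            reasons.append(f"{t_a} subsets < {min_subsets_per_tissue} (have {n_a})")
        if n_b < min_subsets_per_tissue:
            reasons.append(f"{t_b} subsets < {min_subsets_per_tissue} (have {n_b})")
        if n_shared <= min_shared_clones:
            reasons.append(f"shared clones <= {min_shared_clones} (have {n_shared})")
        reports.append(
            InclusionReport(donor_id, n_a, n_b, n_shared, included=not reasons, reasons=reasons)
        )
    return reports


def top_overlap_clones(
    matrix: CloneMatrix, n: int = 75, rank_by: Literal["breadth", "frequency"] = "breadth"
) -> list[str]:
    """The clonotypes with the most clonal overlap, for heatmap display.

    ``breadth`` ranks by the number of samples carrying the clone (then by
    summed frequency, then lexicographically); ``frequency`` puts summed
    frequency first.  Returns all clones when fewer than ``n`` exist.
    """
    if matrix.clone_filter == "none":
        warnings.warn("top_overlap_clones expects a sharing-filtered matrix")
    values = matrix.frame.to_numpy()
    breadth = (values > 0).sum(axis=0)
    total_freq = values.sum(axis=0)
    keys = np.array(matrix.clone_keys)
    if rank_by == "breadth":
        order = np.lexsort((keys, -total_freq, -breadth))
    elif rank_by == "frequency":
        order = np.lexsort((keys, -breadth, -total_freq))
    else:
        raise ValueError(f"unknown ranking {rank_by!r}")
    return list(keys[order][:n])
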