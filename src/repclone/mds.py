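"""Pooled classical multidimensional scaling and the four distance-group comparisons.

All samples passing the sharing filter are embedded together by classical
(Torgerson) MDS on the Euclidean distances between their shared-clone
frequency vectors, so distances are on one common scale and can be compared
across donors.  Per donor, four groups of embedding distances are averaged:
naive-to-memory within each tissue, among-memory within the lymph node,
among-memory within the lung, and between phenotypically identical memory
subsets across the two tissues.  Groups are compared with two-sided Wilcoxon
rank-sum tests on the per-donor averages.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import mannwhitneyu

from .io import Cohort, SampleId
from .overlap import CloneMatrix

__all__ = [
    "MDSResult",
    "DistanceGroups",
    "pooled_mds",
    "classical_mds",
    "distance_groups",
    "wilcoxon_rank_sum",
]

GROUP_LABELS = (
    "naive_vs_memory_lung",
    "naive_vs_memory_ldln",
    "within_ldln_memory",
    "within_lung_memory",
    "cross_tissue_identical",
)


@dataclass
class MDSResult:
    """Classical MDS embedding of the pooled samples."""

    coords: pd.DataFrame  # rows: SampleId, columns: axis_1..axis_k
    eigenvalues: np.ndarray  # all eigenvalues of the centered Gram matrix, descending
    n_negative_truncated: int


def classical_mds(distances: np.ndarray, n_dims: int | None = 2) -> tuple[np.ndarray, np.ndarray, int]:
    """Torgerson scaling of a symmetric distance matrix.

    Double-centers the squared distances, eigendecomposes, and scales the
    eigenvectors of the positive eigenvalues by their square roots.
    Negative eigenvalues (non-Euclidean input) are truncated and counted.
    ``n_dims=None`` keeps every positive-eigenvalue axis, in which case
    pairwise embedding distances reproduce Euclidean input distances to
    numerical precision.  Axis signs follow the convention that the first
    nonzero loading of each axis is positive.
    """
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    b = (b + b.T) / 2
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(n, 1) * np.finfo(float).eps * max(abs(eigval[0]), 1.0)
    positive = eigval > tol
    n_negative = int((eigval < -tol).sum())
    if not positive.any():
        raise ValueError("degenerate distance matrix: no positive eigenvalues")
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    if n_dims is not None:
        if n_dims < 1:
            raise ValueError("n_dims must be >= 1")
        coords = coords[:, :n_dims]
    # sign convention: first nonzero loading of each axis positive
    for a in range(coords.shape[1]):
        col = coords[:, a]
        nz = np.nonzero(np.abs(col) > tol)[0]
        if len(nz) and col[nz[0]] < 0:
            coords[:, a] = -col
    return coords, eigval, n_negative


def pooled_mds(matrix: CloneMatrix, n_dims: int | None = 2) -> MDSResult:
    """Embed all samples of a sharing-filtered cohort matrix."""
    values = matrix.frame.to_numpy()
    if values.shape[1] == 0 or not np.any(values):
        raise ValueError("clone matrix is all zeros; nothing to embed")
    d = squareform(pdist(values, metric="euclidean"))
    coords, eigval, n_neg = classical_mds(d, n_dims=n_dims)
    frame = pd.DataFrame(
        coords,
        index=matrix.frame.index,
        columns=[f"axis_{a + 1}" for a in range(coords.shape[1])],
    )
    return MDSResult(frame, eigval, n_neg)


@dataclass
class DistanceGroups:
    """One donor's averaged embedding distances in the four comparison groups.

    An entry is ``None`` (never imputed) when the donor lacks the samples
    the group needs; ``missing`` records the reason.
    """

    donor_id: str
    naive_vs_memory_lung: float | None = None
    naive_vs_memory_ldln: float | None = None
    within_ldln_memory: float | None = None
    within_lung_memory: float | None = None
    cross_tissue_identical: float | None = None
    missing: dict = None  # type: ignore[assignment]

    def as_dict(self) -> dict[str, float | None]:
        return {label: getattr(self, label) for label in GROUP_LABELS}


def distance_groups(
    mds: MDSResult,
    lineage: str = "CD4",
    tissues: Sequence[str] = ("lung", "LDLN"),
    memory_subsets: Sequence[str] = ("CM", "EM", "TRM"),
) -> list[DistanceGroups]:
    """Per-donor group averages of pairwise embedding distances.

    Averages are arithmetic means of pairwise distances; the naive-vs-memory
    entry of a tissue is the mean distance from the naive sample to each of
    that tissue's memory samples.
    """
    coords = mds.coords
    xy = {sid: row for sid, row in zip(coords.index, coords.to_numpy())}

    def _dist(a: SampleId, b: SampleId) -> float:
        return float(np.linalg.norm(xy[a] - xy[b]))

    ids = [sid for sid in coords.index if sid.lineage == lineage]
    t_lung, t_ldln = tissues
    results = []
    for donor_id in sorted({sid.donor_id for sid in ids}):
        d_ids = [sid for sid in ids if sid.donor_id == donor_id]
        groups = DistanceGroups(donor_id, missing={})
        mem = {t: [sid for sid in d_ids if sid.tissue == t and sid.subset in memory_subsets]
               for t in (t_lung, t_ldln)}
        naive = {t: [sid for sid in d_ids if sid.tissue == t and sid.subset == "naive"]
                 for t in (t_lung, t_ldln)}
        for tissue, label in ((t_lung, "naive_vs_memory_lung"), (t_ldln, "naive_vs_memory_ldln")):
            if not naive[tissue]:
                groups.missing[label] = f"no {tissue} naive sample"
            elif not mem[tissue]:
                groups.missing[label] = f"no {tissue} memory samples"
            else:
                nv = naive[tissue][0]
                setattr(groups, label,
                        float(np.mean([_dist(nv, m) for m in mem[tissue]])))
        for tissue, label in ((t_ldln, "within_ldln_memory"), (t_lung, "within_lung_memory")):
            if len(mem[tissue]) < 2:
                groups.missing[label] = f"fewer than 2 {tissue} memory samples"
            else:
                pairs = list(itertools.combinations(mem[tissue], 2))
                setattr(groups, label,
                        float(np.mean([_dist(a, b) for a, b in pairs])))
        matched = []
        for subset in memory_subsets:
            lung_s = [sid for sid in mem[t_lung] if sid.subset == subset]
            ldln_s = [sid for sid in mem[t_ldln] if sid.subset == subset]
            if lung_s and ldln_s:
                matched.append(_dist(lung_s[0], ldln_s[0]))
        if matched:
            groups.cross_tissue_identical = float(np.mean(matched))
        else:
            groups.missing["cross_tissue_identical"] = "no memory subset present in both tissues"
        results.append(groups)
    return results


def wilcoxon_rank_sum(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Uses the exact null distribution when the smaller group has at most 8
    values and there are no ties; otherwise the normal approximation with
    tie correction.  Two identical groups return p = 1 with a warning.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1")
        return float(len(a) * len(b) / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    method: Literal["exact", "asymptotic"] = (
        "exact" if (min(len(a), len(b)) <= 8 and not has_ties) else "asymptotic"
    )
    res = mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))
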