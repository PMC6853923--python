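"""Per-donor hierarchical clustering of subsets and the tissue-concordance binomial test.

For each included donor, CD4 subsets are clustered on the Euclidean
distances between their shared-clone frequency vectors.  The dendrogram is
cut at its top split into two clusters; a memory subset is *tissue
concordant* when its tissue of origin matches the majority tissue of its
cluster.  Naive subsets take part in the clustering but are not tallied.
Concordant/total tallies pooled over donors feed an exact two-sided binomial
test against chance assignment (null success probability 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage, to_tree
from scipy.spatial.distance import pdist
from scipy.stats import binomtest

from .io import SampleId
from .overlap import CloneMatrix

__all__ = [
    "Dendrogram",
    "ConcordanceResult",
    "ConcordanceTest",
    "donor_hclust",
    "tissue_concordance",
    "binomial_concordance_test",
    "to_newick",
]

Linkage = Literal["single", "complete", "average", "ward"]


@dataclass
class Dendrogram:
    """An agglomerative merge tree over one donor's subset samples."""

    merges: np.ndarray  # scipy linkage matrix
    leaves: list[SampleId]
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)


@dataclass
class ConcordanceResult:
    donor_id: str
    dendrogram: Dendrogram
    concordant: int
    total: int


@dataclass
class ConcordanceTest:
    k: int  # concordant memory subsets, pooled over donors
    n: int
    p_value: float


def donor_hclust(matrix: CloneMatrix, method: Linkage = "complete") -> Dendrogram:
    """Agglomerative clustering of subset frequency vectors (Euclidean).

    Ties in merge distance resolve deterministically (lowest-index pair
    first, the scipy convention).
    """
    if len(matrix.frame) < 2:
        raise ValueError("need at least 2 subsets to cluster")
    dists = pdist(matrix.frame.to_numpy(), metric="euclidean")
    merges = linkage(dists, method=method)
    return Dendrogram(merges, matrix.sample_ids, method)


def tissue_concordance(
    dendro: Dendrogram, memory_subsets: Iterable[str] = ("CM", "EM", "TRM")
) -> tuple[int, int]:
    """Tally memory subsets falling in the cluster dominated by their own tissue.

    The tree is cut into exactly two clusters at the top split.  Majority
    tissue is taken over *all* leaves of a cluster; a tied cluster has no
    majority, so none of its members count as concordant.  Only memory
    subsets are tallied (naive leaves influence the tree and the majority
    but are never counted).
    """
    memory_subsets = set(memory_subsets)
    tissues = {sid.tissue for sid in dendro.leaves}
    if len(tissues) < 2:
        raise ValueError("tissue concordance needs leaves from at least two tissues")
    assignments = fcluster(dendro.merges, t=2, criterion="maxclust")
    majority: dict[int, str | None] = {}
    for cluster in np.unique(assignments):
        members = [sid for sid, c in zip(dendro.leaves, assignments) if c == cluster]
        counts: dict[str, int] = {}
        for sid in members:
            counts[sid.tissue] = counts.get(sid.tissue, 0) + 1
        best = max(counts.values())
        winners = [t for t, c in counts.items() if c == best]
        majority[int(cluster)] = winners[0] if len(winners) == 1 else None
    concordant = total = 0
    for sid, cluster in zip(dendro.leaves, assignments):
        if sid.subset not in memory_subsets:
            continue
        total += 1
        if majority[int(cluster)] == sid.tissue:
            concordant += 1
    return concordant, total


def binomial_concordance_test(pairs: Iterable[tuple[int, int]]) -> ConcordanceTest:
    """Exact two-sided binomial test of pooled concordance against 1/2.

    ``pairs`` holds per-donor (concordant, total) tallies.  The two-sided
    p-value sums the probabilities of all outcomes no more likely than the
    observed one; under the symmetric null this equals twice the smaller
    tail, capped at 1.
    """
    k = n = 0
    for ki, ni in pairs:
        if ki > ni or ki < 0:
            raise ValueError(f"invalid tally ({ki}, {ni})")
        k += ki
        n += ni
    if n < 1:
        raise ValueError("no memory subsets tallied")
    p = binomtest(k, n, 0.5, alternative="two-sided").pvalue
    return ConcordanceTest(k, n, float(p))


def _newick_escape(label: str) -> str:
    return label.replace(" ", "_").replace("(", "").replace(")", "").replace(",", "").replace(
        ":", "-"
    )


def to_newick(dendro: Dendrogram) -> str:
    """Serialize the merge tree as a Newick string with branch lengths.

    A child's branch length is its parent's merge height minus its own.
    """
    tree = to_tree(dendro.merges)

    def walk(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{_newick_escape(str(dendro.leaves[node.id]))}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = walk(tree.left, tree.dist)
    right = walk(tree.right, tree.dist)
    return f"({left},{right});"
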