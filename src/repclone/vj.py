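"""Frequency-independent V / V-J gene-segment usage and enrichment scoring.

Every clonotype contributes a single count to its (V, J) cell regardless of
its read frequency, so clonal expansion cannot masquerade as recombination
bias.  When pooling across donors, a CDR3 sequence seen in two donors counts
once per donor — identical rearrangements in different people are
independent recombination events — while within one donor a clonotype
appearing in several subsets of the pooling scope counts once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .io import Cohort
from .simulate import SegmentCatalog

__all__ = ["UsageTable", "usage_counts", "representation_scores"]

UNASSIGNED = "unassigned"


@dataclass
class UsageTable:
    """V x J matrix of unique-clone counts for one pooling scope."""

    counts: pd.DataFrame  # index: v_gene, columns: j_gene
    scope: Mapping[str, str]

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def v_margin(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def j_margin(self) -> pd.Series:
        return self.counts.sum(axis=0)


def usage_counts(
    cohort: Cohort,
    scope: Mapping[str, str] | None = None,
    pooled: bool = True,
    catalog: SegmentCatalog | None = None,
) -> UsageTable:
    """Tally unique clonotypes into V x J cells within a scope.

    ``scope`` filters on SampleId fields (e.g. ``{"lineage": "CD4",
    "subset": "TRM"}``); ``pooled=True`` deduplicates clonotypes per donor
    before tallying so each donor contributes each of its clonotypes once.
    With a ``catalog``, labels outside it are tallied under ``unassigned``
    with a warning.
    """
    scope = scope or {}
    selected = [
        s for sid, s in cohort.items() if all(getattr(sid, k) == v for k, v in scope.items())
    ]
    if not selected and not cohort:
        raise ValueError("empty cohort")
    per_donor: dict[str, dict[str, tuple[str, str]]] = {}
    for sid, sample in cohort.items():
        if any(getattr(sid, k) != v for k, v in scope.items()):
            continue
        donor_key = sid.donor_id if pooled else str(sid)
        clones = per_donor.setdefault(donor_key, {})
        for nt, v, j in zip(
            sample.clones["cdr3_nt"], sample.clones["v_gene"], sample.clones["j_gene"]
        ):
            clones.setdefault(nt, (v, j))  # first annotation wins within a donor
    tally: dict[tuple[str, str], int] = {}
    n_unknown = 0
    for clones in per_donor.values():
        for v, j in clones.values():
            if catalog is not None:
                if v not in catalog.v_names:
                    v, n_unknown = UNASSIGNED, n_unknown + 1
                if j not in catalog.j_names:
                    j, n_unknown = UNASSIGNED, n_unknown + 1
            tally[(v, j)] = tally.get((v, j), 0) + 1
    if n_unknown:
        warnings.warn(f"{n_unknown} segment labels outside the catalog counted as {UNASSIGNED!r}")
    if catalog is not None:
        v_names: Sequence[str] = list(catalog.v_names)
        j_names: Sequence[str] = list(catalog.j_names)
        if any(v == UNASSIGNED for v, _ in tally):
            v_names = list(v_names) + [UNASSIGNED]
        if any(j == UNASSIGNED for _, j in tally):
            j_names = list(j_names) + [UNASSIGNED]
    else:
        v_names = sorted({v for v, _ in tally})
        j_names = sorted({j for _, j in tally})
    counts = pd.DataFrame(0, index=pd.Index(v_names, name="v_gene"),
                          columns=pd.Index(j_names, name="j_gene"), dtype=int)
    for (v, j), n in tally.items():
        counts.loc[v, j] += n
    return UsageTable(counts, dict(scope))


def representation_scores(
    table: UsageTable,
    null_model: Literal["uniform", "margin-product"] = "uniform",
    threshold: float = 3.0,
) -> pd.DataFrame:
    """Score segments (or V-J cells) for over/under-representation.

    Under ``uniform`` the expected per-V count is ``total / |V|`` and each V
    also gets an exact binomial p-value against that proportion; under
    ``margin-product`` the expected count of cell (v, j) is
    ``row_total * col_total / total``.  The score is the Pearson residual
    ``(obs - exp) / sqrt(exp)``; residuals beyond ``+/- threshold`` are
    flagged ``over`` / ``under``.  Cells with zero expectation are skipped
    with a warning.
    """
    total = table.total
    if total == 0:
        raise ValueError("usage table is empty")
    rows = []
    if null_model == "uniform":
        v_margin = table.v_margin
        n_v = len(v_margin)
        expected = total / n_v
        for v, obs in v_margin.items():
            residual = (obs - expected) / np.sqrt(expected)
            p = binomtest(int(obs), total, 1.0 / n_v, alternative="two-sided").pvalue
            rows.append(
                {
                    "v_gene": v,
                    "observed": int(obs),
                    "expected": expected,
                    "residual": residual,
                    "p_value": float(p),
                    "flag": "over" if residual > threshold
                    else "under" if residual < -threshold else "none",
                }
            )
    elif null_model == "margin-product":
        v_margin, j_margin = table.v_margin, table.j_margin
        skipped = 0
        for v, rv in v_margin.items():
            for j, cj in j_margin.items():
                expected = rv * cj / total
                if expected == 0:
                    skipped += 1
                    continue
                obs = int(table.counts.loc[v, j])
                residual = (obs - expected) / np.sqrt(expected)
                rows.append(
                    {
                        "v_gene": v,
                        "j_gene": j,
                        "observed": obs,
                        "expected": expected,
                        "residual": residual,
                        "flag": "over" if residual > threshold
                        else "under" if residual < -threshold else "none",
                    }
                )
        if skipped:
            warnings.warn(f"{skipped} cells with zero expected count skipped")
    else:
        raise ValueError(f"unknown null model {null_model!r}")
    return pd.DataFrame(rows)
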