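"""Clone-table input/output, the productive-rearrangement filter, and clonotype collapsing.

A *clone table* is a tidy :class:`pandas.DataFrame` with one row per clonotype
observation in one sample.  The native dialect is a UTF-8, tab-separated file
with a header row and the columns

    donor_id  tissue  lineage  subset  cdr3_nt  v_gene  j_gene  read_count

Two foreign dialects are accepted and mapped onto the same columns:

``airr-like``
    AIRR Rearrangement naming: ``junction`` -> ``cdr3_nt``,
    ``junction_aa`` -> ``cdr3_aa``, ``v_call`` -> ``v_gene``,
    ``j_call`` -> ``j_gene``, ``duplicate_count`` -> ``read_count``.
``mixcr-like``
    MiXCR clone-export naming: ``nSeqCDR3`` -> ``cdr3_nt``,
    ``aaSeqCDR3`` -> ``cdr3_aa``, ``allVHitsWithScore`` -> ``v_gene``,
    ``allJHitsWithScore`` -> ``j_gene``, ``cloneCount`` -> ``read_count``.

Sample metadata columns (``donor_id``, ``tissue``, ``lineage``, ``subset``)
keep their native names in every dialect.

A clonotype is defined by its CDR3 nucleotide sequence alone: reads carrying
identical CDR3 nucleotide sequences are assumed to descend from one
clonally-expanded progenitor, so rows are merged on ``cdr3_nt`` regardless of
their V/J annotation.  A rearrangement is *productive* when the CDR3
nucleotide sequence is in frame (length divisible by three) and its
translation in frame 0 under the standard genetic code contains no stop
codon; only productive rearrangements enter the analyses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, NamedTuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "SampleId",
    "RepertoireSample",
    "Cohort",
    "ParseReport",
    "FormatError",
    "NATIVE_COLUMNS",
    "DIALECTS",
    "read_clone_table",
    "write_clone_table",
    "annotate_productive",
    "filter_productive",
    "collapse_clones",
    "build_cohort",
    "translate_cdr3",
    "is_productive",
]

Dialect = Literal["native", "airr-like", "mixcr-like"]

#: metadata columns shared by every dialect
META_COLUMNS = ["donor_id", "tissue", "lineage", "subset"]
#: mandatory native columns
NATIVE_COLUMNS = META_COLUMNS + ["cdr3_nt", "v_gene", "j_gene", "read_count"]

#: per-dialect map of foreign column name -> native column name
DIALECTS: Mapping[str, Mapping[str, str]] = {
    "native": {},
    "airr-like": {
        "junction": "cdr3_nt",
        "junction_aa": "cdr3_aa",
        "v_call": "v_gene",
        "j_call": "j_gene",
        "duplicate_count": "read_count",
    },
    "mixcr-like": {
        "nSeqCDR3": "cdr3_nt",
        "aaSeqCDR3": "cdr3_aa",
        "allVHitsWithScore": "v_gene",
        "allJHitsWithScore": "j_gene",
        "cloneCount": "read_count",
    },
}

MEMORY_SUBSETS = ("CM", "EM", "TRM")


class FormatError(ValueError):
    """A clone table is missing a mandatory column or is otherwise unreadable."""


class SampleId(NamedTuple):
    """Identifies one sorted T-cell population of one donor."""

    donor_id: str
    tissue: str
    lineage: str
    subset: str

    def __str__(self) -> str:  # compact label for matrices / trees
        return f"{self.donor_id}|{self.tissue}|{self.lineage}|{self.subset}"

    @property
    def is_memory(self) -> bool:
        return self.subset in MEMORY_SUBSETS


@dataclass
class ParseReport:
    """Row-level outcome of parsing one clone table."""

    path: str
    dialect: str
    n_parsed: int
    malformed: list[tuple[int, str]] = field(default_factory=list)  # (line number, reason)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "path": self.path,
                    "dialect": self.dialect,
                    "n_parsed": self.n_parsed,
                    "malformed": [{"line": ln, "reason": r} for ln, r in self.malformed],
                },
                indent=2,
            )
        )


@dataclass
class RepertoireSample:
    """All clonotypes of one (donor, tissue, lineage, subset) after collapsing.

    ``clones`` carries one row per unique CDR3 nucleotide sequence with
    summed ``read_count`` and a normalized ``frequency`` column.
    """

    sample_id: SampleId
    clones: pd.DataFrame
    total_reads: int

    @property
    def n_clones(self) -> int:
        return len(self.clones)

    @property
    def frequencies(self) -> np.ndarray:
        return self.clones["frequency"].to_numpy()

    @property
    def counts(self) -> np.ndarray:
        return self.clones["read_count"].to_numpy()


#: a cohort maps each sample id to its collapsed repertoire
Cohort = dict[SampleId, RepertoireSample]


def translate_cdr3(nt: str) -> str:
    """Translate a CDR3 nucleotide sequence in frame 0 (standard code).

    A trailing partial codon is dropped; stop codons appear as ``*``.
    """
    nt = nt.upper()
    usable = len(nt) - len(nt) % 3
    if usable == 0:
        return ""
    return str(Seq(nt[:usable]).translate())


def is_productive(nt: str) -> bool:
    """In frame and free of stop codons in frame 0."""
    return len(nt) % 3 == 0 and len(nt) > 0 and "*" not in translate_cdr3(nt)


def annotate_productive(records: pd.DataFrame) -> pd.DataFrame:
    """Add/overwrite derived ``cdr3_aa`` and ``productive`` columns."""
    out = records.copy()
    out["cdr3_aa"] = [translate_cdr3(s) for s in out["cdr3_nt"]]
    out["productive"] = [is_productive(s) for s in out["cdr3_nt"]]
    return out


def read_clone_table(
    path: str | Path, dialect: Dialect = "native"
) -> tuple[pd.DataFrame, ParseReport]:
    """Read a clone table, validating every row.

    Returns the well-formed records (with derived ``cdr3_aa`` and
    ``productive`` columns) and a :class:`ParseReport` listing malformed rows
    with their 1-based line numbers.  A missing mandatory column raises
    :class:`FormatError` naming the column; an empty file yields an empty
    frame with a warning.
    """
    path = Path(path)
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {sorted(DIALECTS)}")
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty clone table")
        empty = pd.DataFrame(columns=NATIVE_COLUMNS + ["cdr3_aa", "productive"])
        return empty, ParseReport(str(path), dialect, 0)

    raw = raw.rename(columns=dict(DIALECTS[dialect]))
    missing = [c for c in NATIVE_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    report = ParseReport(str(path), dialect, 0)
    keep = np.ones(len(raw), dtype=bool)
    counts = np.zeros(len(raw), dtype=np.int64)
    for i, row in enumerate(raw.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        nt = getattr(row, "cdr3_nt").upper()
        try:
            count = int(getattr(row, "read_count"))
        except ValueError:
            report.malformed.append((line_no, f"read_count not an integer: {row.read_count!r}"))
            keep[i] = False
            continue
        if count < 1:
            report.malformed.append((line_no, f"read_count must be >= 1, got {count}"))
            keep[i] = False
        elif not nt or set(nt) - set("ACGT"):
            report.malformed.append((line_no, f"cdr3_nt not a nonempty ACGT string: {nt!r}"))
            keep[i] = False
        else:
            counts[i] = count
    records = raw.loc[keep, NATIVE_COLUMNS].copy()
    records["cdr3_nt"] = records["cdr3_nt"].str.upper()
    records["read_count"] = counts[keep]
    records = annotate_productive(records).reset_index(drop=True)
    report.n_parsed = len(records)
    return records, report


def write_clone_table(records: pd.DataFrame, path: str | Path, dialect: Dialect = "native") -> None:
    """Write records as a tab-separated clone table in the given dialect."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    out = records.loc[:, [c for c in NATIVE_COLUMNS if c in records.columns]].copy()
    inverse = {native: foreign for foreign, native in DIALECTS[dialect].items()}
    out = out.rename(columns=inverse)
    out.to_csv(path, sep="\t", index=False)


def filter_productive(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (productive, nonproductive) per the frame/stop rule."""
    if "productive" not in records.columns:
        records = annotate_productive(records)
    mask = records["productive"].to_numpy(dtype=bool)
    return records[mask].reset_index(drop=True), records[~mask].reset_index(drop=True)


def collapse_clones(records: pd.DataFrame) -> RepertoireSample:
    """Merge rows with identical CDR3 nucleotide sequence into clonotypes.

    Read counts are summed.  The merged clone inherits the V/J annotation of
    its highest-count constituent row; count ties resolve to the
    lexicographically smallest (v_gene, j_gene) label pair.  All rows must
    belong to a single sample.
    """
    ids = records[META_COLUMNS].drop_duplicates() if len(records) else pd.DataFrame()
    if len(ids) > 1:
        raise ValueError(f"records span {len(ids)} samples; collapse one sample at a time")
    if len(records) == 0:
        empty = pd.DataFrame(
            columns=["cdr3_nt", "cdr3_aa", "v_gene", "j_gene", "read_count", "frequency"]
        )
        return RepertoireSample(SampleId("", "", "", ""), empty, 0)
    sample_id = SampleId(*ids.iloc[0])

    # winner-takes-all V/J: sort so the first row per clone is the
    # highest-count constituent, ties broken lexicographically
    ordered = records.sort_values(
        ["cdr3_nt", "read_count", "v_gene", "j_gene"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    grouped = ordered.groupby("cdr3_nt", sort=True)
    clones = grouped.agg(
        cdr3_aa=("cdr3_aa", "first") if "cdr3_aa" in records.columns else ("cdr3_nt", "first"),
        v_gene=("v_gene", "first"),
        j_gene=("j_gene", "first"),
        read_count=("read_count", "sum"),
    ).reset_index()
    if "cdr3_aa" not in records.columns:
        clones["cdr3_aa"] = [translate_cdr3(s) for s in clones["cdr3_nt"]]
    total = int(clones["read_count"].sum())
    clones["frequency"] = clones["read_count"] / total
    return RepertoireSample(sample_id, clones, total)


def build_cohort(records: pd.DataFrame, productive_only: bool = True) -> Cohort:
    """Filter (optionally) and collapse a long clone table into a cohort.

    Samples whose records are all nonproductive are dropped.
    """
    if productive_only:
        records, _ = filter_productive(records)
    cohort: Cohort = {}
    for _, group in records.groupby(META_COLUMNS, sort=True):
        sample = collapse_clones(group)
        cohort[sample.sample_id] = sample
    return cohort


def iter_samples(cohort: Cohort, **match: str) -> Iterable[tuple[SampleId, RepertoireSample]]:
    """Yield cohort samples whose id fields equal every given keyword value."""
    for sid, sample in cohort.items():
        if all(getattr(sid, k) == v for k, v in match.items()):
            yield sid, sample
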