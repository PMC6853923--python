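"""End-to-end pipeline: generation/ingest -> filters -> analyses -> report bundle.

Stage order is fixed: input, productive filter, clonotype collapse, donor
inclusion, then the independent analyses (diversity, overlap, clustering,
MDS, V-J usage), then the report.  Later stages consume only the artifacts
of earlier ones.  All randomness flows from the single top-level seed.  A
rerun with the same resolved config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .concordance import ConcordanceResult, binomial_concordance_test, donor_hclust, \
    tissue_concordance, to_newick
from .diversity import clonality, rarefy, unique_clone_census
from .io import Cohort, SampleId, build_cohort, filter_productive, read_clone_table, \
    write_clone_table
from .mds import GROUP_LABELS, distance_groups, pooled_mds, wilcoxon_rank_sum
from .overlap import build_matrix, select_donors, top_overlap_clones
from .simulate import SyntheticConfig, generate_cohort
from .vj import representation_scores, usage_counts

__all__ = ["RunConfig", "ReportBundle", "run_pipeline", "summarize"]

ALL_ANALYSES = ("diversity", "overlap", "clustering", "mds", "vj")


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run."""

    mode: str = "synthetic"  # "synthetic" or "manifest"
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides
    manifest: str | None = None  # sample -> path map (YAML) for mode="manifest"
    dialect: str = "native"
    lineage: str = "CD4"
    min_subsets_per_tissue: int = 3
    min_shared_clones: int = 150
    linkage: str = "complete"
    mds_dims: int = 2
    top_n_overlap: int = 75
    vj_threshold: float = 3.0
    analyses: tuple = ALL_ANALYSES
    seed: int = 0
    outdir: str = "repclone_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "analyses" in data:
            data["analyses"] = tuple(data["analyses"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["analyses"] = list(data["analyses"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def resolve_synthetic(self) -> SyntheticConfig:
        params = dict(self.synthetic)
        params.setdefault("seed", self.seed)
        if "subsets" in params:
            params["subsets"] = tuple(tuple(p) for p in params["subsets"])
        return SyntheticConfig(**params)


@dataclass
class ReportBundle:
    outdir: Path
    config: RunConfig
    manifest: dict  # relative path -> sha256
    report: dict  # stage counts and key results

    @property
    def report_path(self) -> Path:
        return self.outdir / "report.json"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sid_frame(sids: list[SampleId]) -> pd.DataFrame:
    return pd.DataFrame(sids, columns=["donor_id", "tissue", "lineage", "subset"])


def _load_input(config: RunConfig, outdir: Path, report: dict) -> pd.DataFrame:
    if config.mode == "synthetic":
        table = generate_cohort(config.resolve_synthetic())
        write_clone_table(table, outdir / "cohort.tsv")
        report["n_input_rows"] = int(len(table))
        return table
    if config.mode != "manifest":
        raise ValueError(f"unknown mode {config.mode!r}")
    if config.manifest is None:
        raise ValueError("manifest mode requires a manifest path")
    entries = yaml.safe_load(Path(config.manifest).read_text()) or {}
    frames, reports = [], []
    for name, path in sorted(entries.items()):
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"manifest entry {name!r}: missing file {p}")
        records, parse_report = read_clone_table(p, dialect=config.dialect)
        frames.append(records)
        reports.append(
            {"sample": name, "path": str(p), "n_parsed": parse_report.n_parsed,
             "malformed": [{"line": ln, "reason": r} for ln, r in parse_report.malformed]}
        )
    (outdir / "parse_report.json").write_text(json.dumps(reports, indent=2, sort_keys=True))
    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    report["n_input_rows"] = int(len(table))
    return table


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the configured stages and write a self-describing bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": dataclasses.asdict(config)}
    report["config"]["analyses"] = list(config.analyses)

    table = _load_input(config, outdir, report)
    kept, removed = filter_productive(table)
    report["n_productive"] = int(len(kept))
    report["n_nonproductive_removed"] = int(len(removed))

    cohort: Cohort = build_cohort(table, productive_only=True)
    report["n_samples"] = len(cohort)
    total_unique, multi_fraction = unique_clone_census(cohort)
    report["n_unique_clones"] = total_unique
    report["fraction_clones_in_multiple_samples"] = multi_fraction

    inclusion = select_donors(
        cohort,
        lineage=config.lineage,
        min_subsets_per_tissue=config.min_subsets_per_tissue,
        min_shared_clones=config.min_shared_clones,
    )
    pd.DataFrame(
        [
            {
                "donor_id": r.donor_id,
                "n_subsets_lung": r.n_subsets_lung,
                "n_subsets_ldln": r.n_subsets_ldln,
                "n_shared_clones": r.n_shared_clones,
                "included": r.included,
                "reasons": "; ".join(r.reasons),
            }
            for r in inclusion
        ]
    ).to_csv(outdir / "inclusion.tsv", sep="\t", index=False)
    included = [r.donor_id for r in inclusion if r.included]
    report["donors_included"] = included
    report["donors_excluded"] = {
        r.donor_id: r.reasons for r in inclusion if not r.included
    }

    if "diversity" in config.analyses:
        _run_diversity(cohort, outdir, report)
    if "overlap" in config.analyses:
        _run_overlap(cohort, included, config, outdir, report)
    if "clustering" in config.analyses and included:
        _run_clustering(cohort, included, config, outdir, report)
    if "mds" in config.analyses:
        _run_mds(cohort, config, outdir, report)
    if "vj" in config.analyses:
        _run_vj(cohort, config, outdir, report)

    report_path = outdir / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    manifest = {
        str(p.relative_to(outdir)): _sha256(p)
        for p in sorted(outdir.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return ReportBundle(outdir, config, manifest, report)


def _run_diversity(cohort: Cohort, outdir: Path, report: dict) -> None:
    rows, curve_rows = [], []
    for sid, sample in sorted(cohort.items()):
        rows.append(
            {
                "donor_id": sid.donor_id, "tissue": sid.tissue, "lineage": sid.lineage,
                "subset": sid.subset, "n_clones": sample.n_clones,
                "total_reads": sample.total_reads, "clonality": clonality(sample),
            }
        )
        curve = rarefy(sample)
        for depth, expected in zip(curve.depths, curve.expected_unique):
            curve_rows.append(
                {"donor_id": sid.donor_id, "tissue": sid.tissue, "lineage": sid.lineage,
                 "subset": sid.subset, "depth": int(depth), "expected_unique": expected}
            )
    pd.DataFrame(rows).to_csv(outdir / "clonality.tsv", sep="\t", index=False)
    pd.DataFrame(curve_rows).to_csv(outdir / "rarefaction.tsv", sep="\t", index=False)
    report["mean_clonality"] = float(pd.DataFrame(rows)["clonality"].mean())


def _run_overlap(cohort, included, config, outdir, report) -> None:
    matrix = build_matrix(cohort, clone_filter="ge2_samples")
    frame = matrix.frame.copy()
    frame.index = [str(sid) for sid in frame.index]
    frame.to_csv(outdir / "cohort_matrix.tsv", sep="\t")
    report["n_shared_clone_columns"] = int(matrix.frame.shape[1])
    top_rows = []
    for donor_id in included:
        donor_samples = {
            sid: s for sid, s in cohort.items()
            if sid.donor_id == donor_id and sid.lineage == config.lineage
        }
        donor_matrix = build_matrix(donor_samples, clone_filter="ge2_samples")
        for rank, clone in enumerate(
            top_overlap_clones(donor_matrix, n=config.top_n_overlap), start=1
        ):
            top_rows.append({"donor_id": donor_id, "rank": rank, "cdr3_nt": clone})
    if top_rows:
        pd.DataFrame(top_rows).to_csv(outdir / "top_overlap_clones.tsv", sep="\t", index=False)


def _run_clustering(cohort, included, config, outdir, report) -> None:
    results: list[ConcordanceResult] = []
    for donor_id in included:
        donor_samples = {
            sid: s for sid, s in cohort.items()
            if sid.donor_id == donor_id and sid.lineage == config.lineage
        }
        donor_matrix = build_matrix(donor_samples, clone_filter="ge2_samples")
        dendro = donor_hclust(donor_matrix, method=config.linkage)
        (outdir / f"dendrogram_{donor_id}.nwk").write_text(to_newick(dendro) + "\n")
        k, n = tissue_concordance(dendro)
        results.append(ConcordanceResult(donor_id, dendro, k, n))
    test = binomial_concordance_test([(r.concordant, r.total) for r in results])
    payload = {
        "linkage": config.linkage,
        "per_donor": {r.donor_id: {"concordant": r.concordant, "total": r.total}
                      for r in results},
        "concordant": test.k, "total": test.n, "p_value": test.p_value,
    }
    (outdir / "concordance.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
    report["concordance"] = {"k": test.k, "n": test.n, "p_value": test.p_value}


def _run_mds(cohort, config, outdir, report) -> None:
    matrix = build_matrix(cohort, clone_filter="ge2_samples")
    result = pooled_mds(matrix, n_dims=config.mds_dims)
    coords = result.coords.copy()
    coords.insert(0, "sample_id", [str(sid) for sid in coords.index])
    coords.to_csv(outdir / "mds_coords.tsv", sep="\t", index=False)
    groups = distance_groups(result, lineage=config.lineage)
    frame = pd.DataFrame(
        [{"donor_id": g.donor_id, **g.as_dict()} for g in groups]
    )
    frame.to_csv(outdir / "distance_groups.tsv", sep="\t", index=False)

    def col(label):
        return [v for v in frame[label] if v is not None and pd.notna(v)]

    naive_mem = col("naive_vs_memory_lung") + col("naive_vs_memory_ldln")
    comparisons = {
        "naive_mem_vs_within_ldln": (naive_mem, col("within_ldln_memory")),
        "naive_mem_vs_within_lung": (naive_mem, col("within_lung_memory")),
        "cross_identical_vs_naive_mem": (col("cross_tissue_identical"), naive_mem),
        "cross_identical_vs_within_ldln": (col("cross_tissue_identical"),
                                           col("within_ldln_memory")),
        "cross_identical_vs_within_lung": (col("cross_tissue_identical"),
                                           col("within_lung_memory")),
    }
    tests = {}
    for name, (a, b) in comparisons.items():
        if a and b:
            u, p = wilcoxon_rank_sum(a, b)
            tests[name] = {"U": u, "p_value": p, "n_a": len(a), "n_b": len(b)}
    (outdir / "mds_tests.json").write_text(json.dumps(tests, indent=2, sort_keys=True))
    report["mds"] = {
        "n_samples": int(result.coords.shape[0]),
        "n_negative_eigenvalues_truncated": result.n_negative_truncated,
        "group_medians": {
            label: (float(pd.Series(col(label)).median()) if col(label) else None)
            for label in GROUP_LABELS
        },
        "tests": tests,
    }


def _run_vj(cohort, config, outdir, report) -> None:
    scopes = [{}] + [
        {"lineage": lineage, "tissue": tissue, "subset": subset}
        for lineage in sorted({sid.lineage for sid in cohort})
        for tissue in sorted({sid.tissue for sid in cohort})
        for subset in sorted({sid.subset for sid in cohort})
    ]
    long_rows = []
    flagged_over: dict[str, list[str]] = {}
    for scope in scopes:
        table = usage_counts(cohort, scope=scope or None, pooled=True)
        if table.total == 0:
            continue
        scores = representation_scores(table, null_model="uniform",
                                       threshold=config.vj_threshold)
        name = "pooled" if not scope else "{lineage}_{tissue}_{subset}".format(**scope)
        for _, row in scores.iterrows():
            long_rows.append({"scope": name, **row.to_dict()})
        flagged_over[name] = sorted(scores.loc[scores["flag"] == "over", "v_gene"])
    pd.DataFrame(long_rows).to_csv(outdir / "vj_scores.tsv", sep="\t", index=False)
    pooled_table = usage_counts(cohort, scope=None, pooled=True)
    pooled_table.counts.to_csv(outdir / "vj_usage_pooled.tsv", sep="\t")
    report["vj_flagged_over"] = flagged_over


def summarize(outdir: str | Path) -> str:
    """One-page human-readable summary of a report bundle."""
    outdir = Path(outdir)
    report_path = outdir / "report.json"
    if not report_path.exists():
        raise FileNotFoundError(f"no report.json in {outdir}")
    try:
        report = json.loads(report_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt report artifact {report_path}: {exc}") from exc
    lines = [
        f"repclone {report.get('version', '?')} run summary",
        f"  input rows: {report.get('n_input_rows', 'n/a')}; "
        f"productive: {report.get('n_productive', 'n/a')} "
        f"(removed {report.get('n_nonproductive_removed', 'n/a')})",
        f"  samples: {report.get('n_samples', 'n/a')}; "
        f"unique clones: {report.get('n_unique_clones', 'n/a')} "
        f"({100 * report.get('fraction_clones_in_multiple_samples', 0):.1f}% in >1 sample)",
    ]
    included = report.get("donors_included", [])
    lines.append(f"  donors included: {len(included)} ({', '.join(included) or 'none'})")
    for donor, reasons in sorted(report.get("donors_excluded", {}).items()):
        lines.append(f"    excluded {donor}: {'; '.join(reasons)}")
    if not included:
        lines.append("  no donors passed inclusion; clonal analyses skipped")
    conc = report.get("concordance")
    if conc:
        lines.append(
            f"  tissue concordance: {conc['k']}/{conc['n']} memory subsets "
            f"(binomial P = {conc['p_value']:.3g})"
        )
    mds = report.get("mds")
    if mds:
        medians = ", ".join(
            f"{k}={v:.3g}" for k, v in mds["group_medians"].items() if v is not None
        )
        lines.append(f"  MDS group distance medians: {medians}")
    vj = report.get("vj_flagged_over")
    if vj:
        pooled = vj.get("pooled", [])
        lines.append(f"  V segments over-represented (pooled): {', '.join(pooled) or 'none'}")
    return "\n".join(lines)
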