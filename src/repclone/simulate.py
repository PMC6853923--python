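"""Synthetic multi-donor, two-tissue TCR-beta clone tables with controllable sharing.

The generator emulates the structure of paired lung / lung-draining-lymph-node
(LDLN) repertoires sorted into CD4/CD8 naive, central-memory (CM),
effector-memory (EM) and tissue-resident-memory (TRM) populations:

* Each donor carries one progenitor clonotype pool per tissue.  A memory
  sample draws each read from its own tissue's pool with probability
  ``share_within``, from the opposite tissue's pool with probability
  ``share_cross`` (those clones are thereby shared across the donor's two
  tissues), and otherwise from a sample-private pool.  Sharing between memory
  subsets of one tissue therefore rises with ``share_within``; cross-tissue
  sharing rises with ``share_cross``; and when the two probabilities are
  equal the two tissues are statistically exchangeable, so no method should
  be able to separate them.
* Naive samples ignore the tissue pools apart from a symmetric trickle at
  ``share_cross`` and otherwise draw from a private space
  ``naive_diversity_factor`` times larger with a rank exponent flattened by
  the same factor — near-private, highly diverse, low-clonality repertoires.
* Clone sizes follow a discrete power law on rank: the r-th clone of a pool
  has sampling weight proportional to ``r ** -clone_size_alpha``.
* V and J segments are assigned per clonotype with weights from ``vj_bias``
  (default weights over-represent TRBV5-1/7-2/20-1 and suppress
  TRBV5-2/22-2/26, mimicking the usage bias typical of human TRB
  repertoires); CDR3 nucleotide sequences are random in-frame strings of
  9-18 non-stop codons, so chance identity between independently generated
  clonotypes is negligible and sequence identity marks true sharing.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import NATIVE_COLUMNS, annotate_productive

__all__ = [
    "SegmentCatalog",
    "SyntheticConfig",
    "DEFAULT_CATALOG",
    "DEFAULT_VJ_BIAS",
    "generate_cohort",
    "inject_nonproductive",
]

TISSUES = ("lung", "LDLN")
ALL_SUBSETS = tuple(
    (lineage, subset) for lineage in ("CD4", "CD8") for subset in ("naive", "CM", "EM", "TRM")
)

# the 61 sense codons of the standard genetic code
_STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = np.array(
    [c for c in ("".join(p) for p in itertools.product("ACGT", repeat=3)) if c not in _STOPS]
)


@dataclass(frozen=True)
class SegmentCatalog:
    """Germline TRBV / TRBJ segment labels available to the generator."""

    v_names: tuple[str, ...]
    j_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.v_names)) != len(self.v_names) or len(set(self.j_names)) != len(
            self.j_names
        ):
            raise ValueError("segment labels must be unique")


DEFAULT_CATALOG = SegmentCatalog(
    v_names=(
        "V2", "V3-1", "V4-1", "V5-1", "V5-2", "V6-1", "V6-5", "V7-2", "V9",
        "V10-3", "V11-2", "V12-3", "V15", "V18", "V19", "V20-1", "V22-2",
        "V24-1", "V26", "V27", "V28", "V29-1", "V30",
    ),
    j_names=(
        "J1-1", "J1-2", "J1-3", "J1-4", "J1-5", "J1-6",
        "J2-1", "J2-2", "J2-3", "J2-4", "J2-5", "J2-6", "J2-7",
    ),
)

#: default segment sampling weights (unlisted segments weigh 1.0); mirrors the
#: over-use of TRBV5-1/7-2/20-1 and scarcity of TRBV5-2/22-2/26 seen in human
#: TRB repertoires
DEFAULT_VJ_BIAS: Mapping[str, float] = {
    "V5-1": 3.0,
    "V7-2": 2.5,
    "V20-1": 2.0,
    "V5-2": 0.25,
    "V22-2": 0.25,
    "V26": 0.2,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design knobs for one synthetic cohort.

    Defaults mirror the structure of the motivating study: 11 donors, two
    tissues, eight sorted populations per tissue, and strong within-tissue /
    weak cross-tissue clonal sharing among memory subsets.
    """

    n_donors: int = 11
    subsets: tuple[tuple[str, str], ...] = ALL_SUBSETS
    tissues: tuple[str, str] = TISSUES
    pool_size_per_tissue: int = 2000
    sample_depth: int = 5000
    share_within: float = 0.3
    share_cross: float = 0.02
    clone_size_alpha: float = 1.0
    vj_bias: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_VJ_BIAS))
    naive_diversity_factor: float = 5.0
    catalog: SegmentCatalog = DEFAULT_CATALOG
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("share_within", "share_cross"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.share_within + self.share_cross > 1.0:
            raise ValueError(
                "share_within + share_cross must be <= 1 "
                f"(got {self.share_within} + {self.share_cross})"
            )
        for name in ("n_donors", "pool_size_per_tissue", "sample_depth"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.naive_diversity_factor < 1.0:
            raise ValueError("naive_diversity_factor must be >= 1")
        if self.clone_size_alpha < 0:
            raise ValueError("clone_size_alpha must be >= 0")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


def _zipf_probs(n: int, alpha: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** -alpha
    return w / w.sum()


def _random_cdr3_nt(rng: np.random.Generator, n: int) -> list[str]:
    """Random in-frame CDR3s of 9-18 sense codons (27-54 nt, no stop in frame)."""
    n_codons = rng.integers(9, 19, size=n)
    flat = SENSE_CODONS[rng.integers(0, len(SENSE_CODONS), size=int(n_codons.sum()))]
    seqs, pos = [], 0
    for k in n_codons:
        seqs.append("".join(flat[pos : pos + k]))
        pos += k
    return seqs


def _segment_weights(names: Sequence[str], bias: Mapping[str, float]) -> np.ndarray:
    w = np.array([float(bias.get(name, 1.0)) for name in names])
    if (w < 0).any():
        raise ValueError("vj_bias weights must be nonnegative")
    return w / w.sum()


def _make_pool(rng: np.random.Generator, size: int, config: SyntheticConfig) -> pd.DataFrame:
    """A pool of clonotypes with biased V/J assignment, ordered by rank."""
    cat = config.catalog
    return pd.DataFrame(
        {
            "cdr3_nt": _random_cdr3_nt(rng, size),
            "v_gene": rng.choice(
                cat.v_names, size=size, p=_segment_weights(cat.v_names, config.vj_bias)
            ),
            "j_gene": rng.choice(
                cat.j_names, size=size, p=_segment_weights(cat.j_names, config.vj_bias)
            ),
        }
    )


def _draw_counts(rng: np.random.Generator, n_reads: int, probs: np.ndarray) -> np.ndarray:
    return rng.multinomial(n_reads, probs) if n_reads > 0 else np.zeros(len(probs), dtype=int)


def generate_cohort(config: SyntheticConfig) -> pd.DataFrame:
    """Generate one cohort as a long clone table (native columns + derived).

    One row per (sample, clonotype) with its sampled ``read_count``; the
    table concatenates every (donor, tissue, lineage, subset) sample of the
    config.  Deterministic given ``config.seed``.
    """
    root = np.random.SeedSequence(config.seed)
    donor_seeds = root.spawn(config.n_donors)
    depth = config.sample_depth
    p_within, p_cross = config.share_within, config.share_cross
    p_private = 1.0 - p_within - p_cross
    pool_probs = _zipf_probs(config.pool_size_per_tissue, config.clone_size_alpha)
    naive_pool_size = int(round(config.pool_size_per_tissue * config.naive_diversity_factor))
    naive_probs = _zipf_probs(
        naive_pool_size, config.clone_size_alpha / config.naive_diversity_factor
    )

    frames: list[pd.DataFrame] = []
    for d, dseed in enumerate(donor_seeds):
        donor_id = f"D{d + 1:02d}"
        pool_stream, sample_stream = dseed.spawn(2)
        pool_rng = np.random.default_rng(pool_stream)
        pools = {
            tissue: _make_pool(pool_rng, config.pool_size_per_tissue, config)
            for tissue in config.tissues
        }
        sample_seeds = iter(
            sample_stream.spawn(len(config.tissues) * len(config.subsets))
        )
        for tissue in config.tissues:
            other = config.tissues[1] if tissue == config.tissues[0] else config.tissues[0]
            for lineage, subset in config.subsets:
                rng = np.random.default_rng(next(sample_seeds))
                parts: list[pd.DataFrame] = []
                if subset == "naive":
                    # near-private: symmetric trickle from both tissue pools
                    n_pool, n_priv = rng.multinomial(depth, [p_cross, 1.0 - p_cross])
                    n_a, n_b = rng.multinomial(n_pool, [0.5, 0.5]) if n_pool else (0, 0)
                    for t, n_t in ((tissue, n_a), (other, n_b)):
                        counts = _draw_counts(rng, int(n_t), pool_probs)
                        hit = counts > 0
                        part = pools[t].loc[hit].copy()
                        part["read_count"] = counts[hit]
                        parts.append(part)
                    priv_counts = _draw_counts(rng, int(n_priv), naive_probs)
                    hit = priv_counts > 0
                    priv = pd.DataFrame(
                        {
                            "cdr3_nt": _random_cdr3_nt(rng, int(hit.sum())),
                            "v_gene": rng.choice(
                                config.catalog.v_names,
                                size=int(hit.sum()),
                                p=_segment_weights(config.catalog.v_names, config.vj_bias),
                            ),
                            "j_gene": rng.choice(
                                config.catalog.j_names,
                                size=int(hit.sum()),
                                p=_segment_weights(config.catalog.j_names, config.vj_bias),
                            ),
                            "read_count": priv_counts[hit],
                        }
                    )
                    parts.append(priv)
                else:
                    n_own, n_opp, n_priv = rng.multinomial(
                        depth, [p_within, p_cross, p_private]
                    )
                    for t, n_t in ((tissue, n_own), (other, n_opp)):
                        counts = _draw_counts(rng, int(n_t), pool_probs)
                        hit = counts > 0
                        part = pools[t].loc[hit].copy()
                        part["read_count"] = counts[hit]
                        parts.append(part)
                    priv_counts = _draw_counts(rng, int(n_priv), pool_probs)
                    hit = priv_counts > 0
                    priv = pd.DataFrame(
                        {
                            "cdr3_nt": _random_cdr3_nt(rng, int(hit.sum())),
                            "v_gene": rng.choice(
                                config.catalog.v_names,
                                size=int(hit.sum()),
                                p=_segment_weights(config.catalog.v_names, config.vj_bias),
                            ),
                            "j_gene": rng.choice(
                                config.catalog.j_names,
                                size=int(hit.sum()),
                                p=_segment_weights(config.catalog.j_names, config.vj_bias),
                            ),
                            "read_count": priv_counts[hit],
                        }
                    )
                    parts.append(priv)
                sample = pd.concat(parts, ignore_index=True)
                # a clone drawn from two pools of the same sample merges here
                sample = (
                    sample.groupby(["cdr3_nt", "v_gene", "j_gene"], sort=False, as_index=False)[
                        "read_count"
                    ]
                    .sum()
                )
                sample.insert(0, "donor_id", donor_id)
                sample.insert(1, "tissue", tissue)
                sample.insert(2, "lineage", lineage)
                sample.insert(3, "subset", subset)
                frames.append(sample)
    table = pd.concat(frames, ignore_index=True)[NATIVE_COLUMNS]
    return annotate_productive(table)


def inject_nonproductive(
    table: pd.DataFrame, fraction: float, seed: int
) -> tuple[pd.DataFrame, int]:
    """Corrupt ``floor(fraction * n)`` rows into nonproductive rearrangements.

    Rows are chosen by a seeded shuffle; alternate rows get an in-frame stop
    codon or a single-base frameshift.  Returns the new table and the number
    of rows altered.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    n_alter = math.floor(fraction * len(table))
    out = table.copy()
    if n_alter == 0:
        return out, 0
    rng = np.random.default_rng(seed)
    rows = rng.permutation(len(out))[:n_alter]
    nts = out["cdr3_nt"].to_list()
    for i, row in enumerate(rows):
        nt = nts[row]
        if i % 2 == 0:  # in-frame stop codon
            nts[row] = nt[:3] + "TAG" + nt[6:] if len(nt) >= 6 else "TAG"
        else:  # frameshift
            nts[row] = nt + "A"
    out["cdr3_nt"] = nts
    return annotate_productive(out), n_alter
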