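"""Frequency-independent V-segment usage bias, recovered from a planted truth.

Each clonotype counts once regardless of its expansion, so recombination
bias is measured independently of clonality.  The generator plants a 5x
sampling weight on TRBV9; the Pearson-residual score against a uniform null
should flag exactly that segment as over-represented in naive and memory
subsets alike (the bias acts before antigen encounter).
"""

from repclone import SyntheticConfig, build_cohort, generate_cohort
from repclone.vj import representation_scores, usage_counts

config = SyntheticConfig(
    n_donors=3, subsets=(("CD4", "naive"), ("CD4", "TRM")),
    sample_depth=3000, vj_bias={"V9": 5.0}, seed=8,
)
cohort = build_cohort(generate_cohort(config))

for subset in ("naive", "TRM"):
    table = usage_counts(cohort, scope={"subset": subset}, pooled=True)
    scores = representation_scores(table, null_model="uniform", threshold=3.0)
    over = scores[scores["flag"] == "over"]
    print(f"{subset}: {table.total} unique clones pooled over donors")
    for _, row in over.iterrows():
        print(f"  over-represented: {row['v_gene']} "
              f"(observed {row['observed']}, expected {row['expected']:.0f}, "
              f"residual {row['residual']:.1f}, binomial P={row['p_value']:.2g})")

# The same segment is flagged in both subsets: a usage bias that precedes
# antigen selection shows up identically in naive and memory repertoires.
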