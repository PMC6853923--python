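# Methods

## Clonotype definition and the productive filter

A clonotype is keyed by the CDR3 nucleotide sequence alone. Identical CDR3
nucleotide sequences within a cohort are taken to mark descent from one
clonally expanded progenitor, so rows are merged on that key with read
counts summed; the merged clone inherits the V/J annotation of its
highest-count constituent (count ties resolve to the lexicographically
smallest label pair — any deterministic rule would do, and annotation
disagreement within a clone is rare and usually an upstream alignment
artifact). Deduplicating additionally on V/J would only split clones whose
annotations disagree; the package deliberately does not.

A rearrangement is productive when its CDR3 nucleotide length is divisible
by three and the frame-0 translation under the standard genetic code
contains no stop codon. Only productive rearrangements enter any analysis.
Frequencies are per-sample read counts over total reads, so samples of
different sequencing depth are comparable everywhere downstream.

## Diversity

Clonality is `1 − H/ln S` (one minus Pielou evenness), the immunology
convention: 0 for a perfectly even repertoire, 1 for a monoclonal one. A
single-clone sample has `ln S = 0`; it is defined as clonality 1.0, the
monoclonal limit. Rarefaction is computed analytically from the
hypergeometric identity `E[S_m] = Σ_i [1 − C(N−n_i, m)/C(N, m)]`, with the
binomial ratios evaluated as log-gamma differences; this is exact, fast,
and is checked in the tests against Monte-Carlo subsampling without
replacement. The default depth grid is 20 log-spaced integers from 1 to N.
No richness extrapolation beyond observed depth (Chao1/ACE) is attempted.

## Sharing filters, donor inclusion, top-overlap ranking

Cohort-level analyses use clonotypes present in at least two samples;
per-donor analyses use clonotypes present in more than one of that donor's
CD4 subsets. A donor enters the clonal analyses only with data in at least
three CD4 subsets from each tissue and strictly more than 150 clonotypes
shared between subsets; a donor with exactly 150 is excluded, and the
threshold is configurable. "Most overlapping" clones for heatmap display
are ranked primarily by breadth (number of subsets carrying the clone),
then by summed frequency, then lexicographically; a pure-frequency ranking
is available as an alternative since either reading of "highest frequency
of clonal overlap" is defensible.

## Tissue concordance

Each included donor's CD4 subsets are clustered agglomeratively (default
complete linkage; single/average/ward are configurable and recorded in
output metadata) on Euclidean distances between shared-clone frequency
vectors. The tree is cut into exactly two clusters at its top split. A
memory subset is concordant when its tissue equals the majority tissue over
all leaves of its cluster; a tied cluster has no majority and none of its
members count. Naive subsets are clustered and contribute to majorities but
are never tallied. Pooled (concordant, total) tallies over donors feed an
exact two-sided binomial test against success probability 1/2, summing the
probability of every outcome no more likely than the observed one (for a
symmetric null this is twice the smaller tail, capped at 1); the
implementation is scipy's exact test, verified in the tests against
brute-force enumeration of the pmf for every n ≤ 40.

The majority-tie rule makes the statistic conservative: on a complete
two-tissue design with equal subset counts per tissue, a cluster containing
all memory subsets ties and scores zero concordant. Under a tissue-
exchangeable generator (equal within- and cross-tissue sharing) the two
naive samples, which differ systematically from memory samples, form their
own cluster at the top split, leaving exactly that balanced memory cluster
— so the null concordance fraction sits near 0 rather than 1/2. The test
therefore never overstates tissue structure under the null, but the null
distribution of the concordance fraction is not centered at chance; see
Limitations.

## Pooled MDS and distance groups

Classical (Torgerson) scaling: square the pairwise Euclidean distances
between shared-clone frequency vectors, double-center, eigendecompose, and
scale eigenvectors by the square roots of the positive eigenvalues.
Negative eigenvalues (impossible here, since the input distances are
Euclidean, but possible for alternative metrics) are truncated and their
count reported. Axis signs follow the convention that the first nonzero
loading of each axis is positive, making embeddings reproducible. Default
output is 2-D, matching the plotted space in which distance groups are
usually read; a full-rank mode reproduces the input distances to numerical
precision and is used by the test oracle (cross-checked against
scikit-bio's PCoA).

Per donor, four averaged distance groups are computed in the embedding:
mean distance from the naive sample to each memory sample, per tissue; mean
pairwise distance among a tissue's memory samples; and mean distance
between lung and LDLN instances of the same memory subset. Entries whose
samples are missing stay absent with a recorded reason — never imputed.
Group comparisons use the two-sided Wilcoxon rank-sum test on the
per-donor averages: exact null distribution when the smaller group has at
most 8 values and there are no ties, otherwise the normal approximation
with tie correction.

On this package's Euclidean frequency-vector construction, *larger* clonal
overlap produces *smaller* embedding distances. Analyses in the field
sometimes describe the opposite sign convention without specifying the
construction that produces it; the package documents its own direction and
asserts the sharing structure on clone sets (shared-clone counts, Jaccard)
rather than on embedding orientation.

## V-J usage

Each clonotype contributes one count to its (V, J) cell regardless of read
frequency, so expansion cannot imitate recombination bias. Pooling across
donors counts a sequence once per donor (identical rearrangements in
different individuals are independent recombination events) and once per
donor within a scope even if it recurs in several subsets. Enrichment is
scored by Pearson residuals `(obs − exp)/√exp` with exact per-V binomial
p-values; the null is uniform over segments by default, or the
margin-product (independence) model for V-J cells. The flag threshold is
±3 residuals, configurable. No claim is made about which human TRBV
segments are enriched in real cohorts — that requires real data.

## Synthetic cohorts

The generator emulates the study design the analyses target: ~11 donors,
two tissues, eight sorted populations per tissue, heavy-tailed clone sizes,
strong within-tissue and weak cross-tissue memory sharing, near-private
naive repertoires, and subset-independent V/J usage bias.

Each donor has one progenitor clonotype pool per tissue
(`pool_size_per_tissue`, default 2000 clonotypes — large enough that
included donors comfortably clear the 150-shared-clone rule at the default
depth). A memory sample draws each of its `sample_depth` reads (default
5000, a realistic bulk-TCR-seq scale for sorted subsets) from its own
tissue's pool with probability `share_within` (default 0.3), from the
opposite tissue's pool with probability `share_cross` (default 0.02), and
otherwise from a sample-private pool. Clones drawn from the opposite pool
are exactly the donor-level component shared across tissues, and when
`share_within = share_cross` the two tissues are statistically
exchangeable — the property that makes a proper null condition possible.
Within-pool sampling weights follow a rank power law
`w_r ∝ r^−clone_size_alpha` (default exponent 1, a Zipf-like heavy tail
typical of memory repertoires). Naive samples draw only a symmetric
`share_cross` trickle from the two pools and otherwise sample a private
space `naive_diversity_factor` (default 5) times larger with the rank
exponent flattened by the same factor, yielding diverse, near-private,
low-clonality naive repertoires.

CDR3s are random in-frame strings of 9–18 sense codons (27–54 nt, no stop
in frame 0), so all generated rearrangements are productive by
construction and chance identity between independently generated
clonotypes (~61⁻⁹) is negligible: sequence identity marks true sharing.
V and J labels are drawn per clonotype with weights from `vj_bias`; the
default weights over-represent TRBV5-1/7-2/20-1 and suppress
TRBV5-2/22-2/26, mimicking the biased usage reported for human TRB
repertoires. A nonproductive-injection helper corrupts
`floor(fraction·n)` rows (seeded shuffle; alternating in-frame stop and
single-base frameshift) to exercise the productive filter.

What the generator does *not* emulate: V(D)J recombination biophysics
(insertion/deletion profiles, generation probabilities), sequencing error,
missing subsets (every configured sample is produced, whereas real cohorts
lose samples to quality control), convergent recombination, and any
antigen-driven covariance between subsets beyond pool membership. Passing
tests on synthetic cohorts therefore demonstrate that the statistics
recover planted structure of this kind at realistic sizes, not that real
lung/LDLN repertoires have that structure.

## Problem sizes and determinism

Parameter-recovery checks run 20 cohorts of 6 donors × 8 CD4 samples ×
5000 reads per condition; V-bias recovery runs 20 cohorts of 5 donors with
≥10⁴ unique clones per scope — sizes at which the planted effects are
comfortably identifiable and a full run completes in minutes on one CPU.
All randomness descends from one seed through named substreams
(`numpy.random.SeedSequence.spawn`), so cohorts, pipeline bundles and the
acceptance outputs are bit-reproducible; pipeline reruns with an identical
resolved config are byte-identical, verified by manifest checksums.

## Limitations

- The null distribution of the tissue-concordance *fraction* is not
  centered at 1/2 under tissue exchangeability (the tie rule is
  conservative; measured ≈0 on complete designs, as analyzed above). The
  binomial test's significance claims are valid a fortiori, but the
  fraction itself should not be read as a calibrated effect size near the
  null.
- The diversity statistic is one convention (normalized Shannon clonality);
  results that depend on the precise diversity index are qualitative.
- Clonal identity by CDR3 nucleotide sequence ignores convergent
  recombination, which can inflate apparent sharing in real data (not in
  the synthetic cohorts, where sequences are effectively unique).
- MDS distance-group comparisons default to the 2-D embedding; with many
  samples the 2-D projection can distort individual distances (a full-rank
  option exists).
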