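# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate,
and the numerical conventions that make results reproducible.

## EST clustering

Reads are joined when they share an exact seed word of 36 nt and the
implied ungapped dovetail/containment overlap spans ≥ 40 nt at ≥ 80%
identity; clusters are the connected components (single linkage) of the
accepted-overlap graph. These thresholds are the standard
blastn-word/CAP3-overlap settings used by EST assembly pipelines of this
kind. Single-linkage clustering is the minimal reconstruction that
reproduces cluster/singleton statistics; it does not attempt full
overlap-layout-consensus assembly, and overlaps are ungapped (a gapped
80% criterion is future work). Only forward-strand overlaps are
considered by default because the libraries are directional;
`both_strands` adds reverse-complement seeding.

Identity over an overlap is computed on non-N columns (N is missing
data, not mismatch). Consensus: offsets are propagated from the smallest
read id over accepted overlaps; per column the majority base wins, ties
broken A < C < G < T; an edge whose implied offset conflicts with the
established layout is dropped with a warning, splitting the layout if
necessary (with substitution-only errors this is vanishingly rare).
Raising either threshold can only remove edges, so the number of
clusters is monotone in both — a property the suite checks.

## ORF calling and classification

Directional libraries are translated in the three forward frames under
the standard genetic code (stops as `*`, N-containing codons as X,
trailing partial codons dropped). Per frame the ORF candidate runs from
the first Met within the first 300 predicted residues to the first stop;
the longest candidate wins, ties to the lower frame — the universal
EST-annotation convention for resolving the silent multi-frame case.

Signal peptides cannot be predicted faithfully without the original
neural-network predictors, so the secretion call is a documented,
pluggable heuristic: within the first 30 residues, an uninterrupted run
of ≥ 8 hydrophobic residues (A,I,L,F,V,M,W,C — the h-region) followed
within 10 residues by a small residue (A,G,S,C,T — a cleavage-like
site). Proteins shorter than 25 aa return "unknown". When the evidence
table carries an external predictor's yes/no call, that call overrides
the heuristic, so pipelines built on real predictor output keep their
semantics. The window/threshold values are configurable arguments.

Classification is a first-match cascade over a closed vocabulary (19
housekeeping subgroups, 24 secreted families plus an "Unknown secreted
family" bucket) shipped as an editable TSV of lowercase substring
keywords: a curator hint wins outright; a secretion-positive record with
a secreted-family hit (or no informative hit) is S; an informative hit
matching a housekeeping subgroup is H; otherwise U. Keyword matching is
an explicit approximation of manual curation — it is deterministic and
order-independent, but it cannot reproduce judgment calls. Abundance
tables weight by cluster EST counts and report percentages to 1 decimal
with half-up rounding, matching published table formatting; within-group
percentages therefore sum to 100 ± 0.3.

## Divergence pipeline

Alignment is local (Smith-Waterman style) affine-gap dynamic programming
under BLOSUM62 with gap open −11 and extend −1 (a gap of length k costs
11 + (k−1)), i.e. blastp's defaults; the engine is
`Bio.Align.PairwiseAligner` and the wrapper is verified against an
exhaustive alignment-path enumeration oracle on tiny sequences. X scores
0 against everything and never counts as an identity. "Similarity" means
blast-style positives (pairs scoring > 0).

Best hit = highest raw alignment score (mirroring blastp ranking), ties
to the smaller reference id. Queries whose best alignment spans fewer
than 100 columns are excluded from class means. The allele/duplicate
filter visits records in descending length and drops a record whose
positives against a longer retained record reach 80% — normalized by the
shorter sequence's length rather than by aligned columns, because the
per-column similarity of an arbitrarily short local alignment saturates
(a 5-column spurious hit between unrelated proteins can exceed 80%),
which would collapse unrelated records; coverage normalization preserves
the intended behavior (identical pair → one survivor; a contained allele
at 90% → dropped; unrelated sequences → kept) and keeps the result
independent of input order. Class means are plain arithmetic averages of
per-protein percent identity.

The class comparison is a two-sided Mann-Whitney rank-sum test: exact by
enumeration when n1+n2 ≤ 12 with no ties, otherwise the normal
approximation with tie and continuity corrections. The two branches
agree closely (|ΔP| ≤ 0.01) away from the null center at the handover
size; at the center the exact two-sided P clips at 1 while the
approximation gives ~0.94 — irrelevant in practice since the test is
only interpreted in its tail. If every value in both samples is
identical the result is flagged degenerate with P = 1.

## Codon volatility

v(c) is the fraction of a sense codon's single-nucleotide neighbors that
encode a different amino acid. Stop-codon neighbors are excluded from
the denominator by default (the convention of the original index);
`count_stop_neighbors=True` includes them (counting as non-synonymous)
for sensitivity analysis. Denominators are therefore 7, 8 or 9, values
are kept as exact rationals, and under the standard code v = 1 exactly
for ATG and TGG only. Gene volatility is the unweighted mean over sense
codons (stop and ambiguous codons skipped and reported as QC counts;
trailing partial codons trimmed), and genes enter the class mean
unweighted by length. The class comparison uses Welch's unequal-variance
t-test (safer than the pooled variant when class sizes and variances
differ) with the SE denominator floored at 1e-12 so zero-variance
degenerate classes stay finite; per-class SE is the sample SD over genes
divided by √n (over genes, not codons).

## Cross-library frequency analysis

For k libraries with observed focal-class counts O_i out of totals N_i,
the pooled rate p = ΣO/ΣN gives expected counts E_i = pN_i (which
conserve ΣO exactly). Chi-square is reported in two cell conventions
side by side — the full 2 × k contingency table and the class-cells-only
sum — both with df = k−1, no Yates correction by default (flag
available), and upper-tail P from the chi-square distribution. For the
apyrase counts used in the worked analysis (1/503, 99/4066, 66/4232,
0/1753) the pooled rate is 166/10554, the expected Culex counts are 27.6
and 7.9, and the statistic is 52.8 (class cells) or 53.7 (contingency):
the two conventions bracket, but do not exactly reproduce, the
historically printed 54.6, whose cell set/rounding is not recoverable;
the implementation reports all intermediate values rather than tuning to
match. Any expected cell below 1 sets a validity warning flag.

## Phylogenies

Distances from aligned proteins use pairwise deletion of gap/X columns
(complete deletion would discard most columns in gappy family
alignments): p = mismatches/compared columns, or the Poisson correction
d = −ln(1−p). Neighbor joining is the classic Saitou-Nei algorithm; Q
ties are broken by the lexicographically smallest pair of minimal leaf
labels, so results are invariant to input order; negative branch-length
estimates are clamped to 0 with a flag (the convention of standard tree
software). NJ is exact on additive matrices — verified against random
additive matrices up to 12 taxa and an all-topology least-squares oracle
at 6 taxa — and the topology agrees with scikit-bio's independent NJ on
noisy matrices. Bootstrap resamples alignment columns with replacement;
an internal edge's support is the percent of replicate trees containing
its bipartition. The default is 1,000 replicates — published phylograms
of this kind use 10,000, and the semantics are identical, but 1,000
keeps desk-scale runs interactive; renderers may hide supports ≤ 50
while the Newick always carries all of them.

## Synthetic data: what it does and does not show

The generators are pure functions of (parameters, seed) and always emit
ground truth beside the data. Defaults mirror the library conditions of
a typical sialome study: 1,753 reads from ~900 transcripts under a
power-law abundance p_i ∝ i^(−α) with α = 1 (few dominant families, many
singletons), Sanger-like read lengths (mean 550 nt, sd 100), and a
substitution error rate of 0.002/nt (trimmed high-quality Sanger
sequence); indels default to 0 so the clustering oracle stays exact.
Ortholog pairs substitute sites independently and uniformly over the 19
alternative residues — sufficient for identity recovery, not a
substitution-matrix model of evolution. Coding genes are i.i.d. draws
from a codon-usage vector; `codon_usage_for_mean_volatility` tilts the
uniform usage exponentially in v(c) and solves the tilt by bisection, so
any target mean in (0.5, 1.0) is achievable with a smooth usage. The
generated gene bodies exclude the fixed initiator ATG by default
(`include_start=False`): a mandatory ATG (v = 1) would shift every
gene's expected volatility off the usage-weighted mean that the
generator promises. Protein families evolve by per-branch Poisson
substitutions down a random topology with branch lengths divergence ×
U(0.5, 1.5).

Passing tests on these inputs show that the pipeline recovers the
parameters its statistics estimate, under the model it assumes. They do
not show robustness to real-data features the generators omit: indels
and chimeric reads, base-composition bias, paralog interference in
best-hit assignment, codon usage correlated with expression, or
alignment error in family trees.

## Problem sizes

The test suite and acceptance script run at the study's own sample sizes
where those are the point (205/80 genes × 400 codons for volatility;
50/169 ortholog pairs × 300 aa for identity, searched against the pooled
219-protein reference) and at small sizes for exactness properties
(alignment oracle ≤ 6 aa; all-topology oracle at 6 taxa; tiled
error-free libraries of ~20 transcripts). The full suite runs in about a
minute on one CPU.
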