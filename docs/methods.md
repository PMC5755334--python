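# Methods

## Event model

A transcript is an ordered set of exon intervals on one strand (internally
0-based half-open; GTF I/O converts from/to 1-based inclusive). Its splice
chain is the sequence of introns — (donor, acceptor) boundary pairs in
transcription direction; on the minus strand the donor is the higher
genomic coordinate.

Events are defined pairwise on the **common span** of two transcripts (the
intersection of their genomic extents). Within the span we compute the set
of positions exonic in *both* transcripts; each maximal interval not in
that set, where the two intron sub-chains differ, is one variable region
and one event. Classification of the region's sub-chains:

| pattern (sub-chain a vs b) | type |
| --- | --- |
| single intron vs empty (other transcript exonic across it) | IR |
| two introns vs one sharing outer donor and acceptor | ES |
| single vs single, same acceptor, different donor | AD |
| single vs single, same donor, different acceptor | AA |
| anything else | COMPLEX |

Consequences of this convention:

- Differences at transcript termini are not events. Concretely, a region
  whose intron is not fully inside the common span (an alternative
  first/last exon) is skipped. Regions *touching* the span boundary but
  with all introns inside it are kept.
- A single-exon isoform against a multi-exon isoform yields one IR event
  per intron inside the common span (each its own variable region).
- Event identity is the content key (gene, strand, region, unordered chain
  pair); detection over all transcript pairs pools identical events and
  merges their supporting pairs, so counts are non-redundant. A group-wise
  scheme (events defined over all isoforms simultaneously) could merge or
  split differently; we use pairwise-with-pooling throughout.
- Types are invariant under coordinate reflection plus strand flip, because
  donor/acceptor are defined in transcription direction (property-tested).

Expression semantics: a transcript is expressed in tissue *t* iff its FPKM
is ≥ 0.1 there (the cutoff itself survives; values below are filtered).
The cutoff is applied per tissue-specific FPKM value. An event is
within-tissue observable in *t* iff some supporting pair has both members
expressed in *t*; events with both variants expressed somewhere but no
co-expression anywhere are among-tissue events. A gene has tissue-specific
AS if at least one of its events is observable in exactly one tissue (no
requirement that the gene be expressed elsewhere).

## Profiles, patterns, clustering

The per-tissue profile is P = (N_IR, N_AA, N_AD, N_ES) over within-tissue
events; an event observable in k tissues contributes to all k. Complex
events are counted separately and excluded from P (the four basic classes
define the vector); they can be included as a fifth component if desired by
working with the reported `n_complex` column. Homogeneity across tissues is
tested with a Pearson chi-square on the tissue × type table (event types
absent from every tissue are dropped from the table; identical rows return
statistic 0, p = 1 exactly).

"Relative distance" for profile clustering is implemented as Euclidean
distance on row-normalized proportions P / ΣP, which removes depth
differences between tissues — hence clustering is invariant to scaling any
tissue's counts (tested). Agglomeration is complete linkage; input rows are
sorted by tissue name first so ties resolve deterministically. The original
description does not define its relative distance; this normalization is
our documented reading, and chi-square distance would be a drop-in
alternative on the same normalized matrix.

IR patterns are binary vectors over the fixed ten-tissue order, one per
gene with ≥ 1 within-tissue IR event. The binary metric is the asymmetric
Jaccard-style distance — discordant positions over positions set in either
pattern, 0/0 positions ignored (the standard "binary" distance of common
statistical environments); simple-matching (Hamming) distance is available
as an option. Complete linkage, cut at height 0.95 by default; the number
of groups is data-dependent, never hard-coded. Group labels are numbered in
dendrogram leaf order, and genes are sorted lexicographically before
clustering so results are input-order independent.

IR-gene features: retained-intron length and GC are means over the gene's
retained introns (variant regions of its IR events) — genes with several
retained introns use the mean, a choice we make explicitly since single
values would also be defensible. The major transcript is the one with the
highest FPKM over all tissue values, ties broken by lexicographically
smallest transcript id; exon number and major FPKM come from it.

## Randomization test for excess AS

For each AS gene the observed event count is compared with n_reps = 1000
genes drawn uniformly with replacement from the other AS genes; the
empirical p is the fraction of draws reaching the observed value, and genes
with p < 0.05 are flagged. No multiplicity correction is applied to these
p-values (BH adjustment is available separately). Per-gene random
substreams are derived from one seed in sorted-gene order, so results do
not depend on input iteration order.

Tie rule: the literal definition counts draws *strictly greater* than the
observed value, which makes every member of a fully tied population
significant (p = 0). The default here is therefore ≥ ("ge"), which is
conservative under ties; the strict rule remains available as
`tie_rule="gt"`. The two rules differ materially under contamination: if
10% of genes carry a large upward shift, a shifted gene's ≥-rule p includes
the cohort mass at its own value (~0.1), capping sensitivity near 50%
regardless of shift size; the strict rule ignores ties and recovers a
concentrated shifted cohort completely. The planted-excess recovery
analysis accordingly uses the strict rule — the original definition — while
null calibration is reported under the conservative default.
`exact_excess_p` (the fraction of other genes reaching the observed count)
is the analytic limit used to check convergence.

Standard tests are delegated to scipy/statsmodels behind validated fronts:
Fisher's one-tailed exact test; Mann–Whitney U (exact enumeration for
tie-free samples with n ≤ 20 per group, tie-corrected normal approximation
otherwise; fully tied data returns p = 1 by convention since the
tie-corrected variance vanishes); Kruskal–Wallis (H = 0, p = 1 when all
values are identical); Benjamini–Hochberg step-up. The test suite checks
each against independent enumeration or hand-computed oracles.

## Synthetic data: what it emulates, and what it does not

`generate_annotation` builds, per gene, a reference transcript (2–12 exons,
exon lengths uniform 80–300 bp) plus one alternative transcript per planted
event. Events occupy disjoint slots separated by constitutive exons, so
pairwise detection provably recovers exactly the planted set — alternative
× alternative comparisons reproduce the same event signatures and pool away.
Complex events are an exon skip combined with a shifted donor in one
variable region. Event counts per gene follow a zero-truncated Poisson
(mean 2, capped at 4 by geometry); both strands occur with equal
probability.

Defaults are the study conditions: ten tissues with the real tissue names;
event mix proportional to the observed genome-wide shares
(IR 37.55 / AA 17.83 / AD 9.02 / ES 5.01 / complex 30.58%); retained
introns gamma-distributed with mean 90 bp against a 450 bp background
(shape 4, minimum 60 bp); among-tissue fraction 0.327 (the observed share
of among-tissue events); 30% of events single-tissue. GC is a per-intron
simulated label (retained mean 0.40 vs background 0.34, sd 0.05) — no
nucleotide sequences are emitted, since downstream analysis consumes only
the GC fraction. FPKM is log-normal (meanlog 1.5, sdlog 1), clipped up to
the 0.1 cutoff where a transcript is defined as expressed, with sub-cutoff
noise values sprinkled at rate 0.1 to exercise the filter.

Tissue structure: the reference transcript is expressed in a reference set
R (each tissue kept with probability 0.8, at least two); within-event
alternatives are expressed inside R (a single tissue, or each R-tissue with
probability 0.6, minimum two), among-event alternatives entirely outside R
with mutually disjoint sets within a gene. These constraints make the truth
table exact: re-deriving observability from the emitted FPKM and the cutoff
reproduces it verbatim (tested). Making every event observable in every
tissue requires both the reference-set and restriction probabilities set
to 1 with the single-/among-fractions at 0.

`generate_ir_cohort` plants IR-pattern archetypes: groups of genes sharing
a tissue-set archetype (near-disjoint blocks of the ten tissues) with mild
bit noise (extra tissue with probability 0.02 per zero bit, dropout 0.01
per set bit, never emptying a pattern), group-specific GC levels
(0.30/0.36/0.42/0.48), exon counts (3/5/8/11 ± 1) and major-FPKM levels
(meanlog 0.5/1.5/2.5/3.5), while retained-intron length is drawn from one
shared distribution. This is the condition under which the Kruskal–Wallis
feature comparison should flag GC, exon number and FPKM but not length.
`profile_group_config` plants two tissue groups with distinct event-type
mixes (IR-rich vs ES-rich, all events single-tissue) for profile-clustering
recovery.

What the generator does **not** emulate: read-level noise, assembly
artifacts (fragmented or chimeric transcripts), shared exon boundaries
between genes, overlapping genes, correlated event co-occurrence within a
gene, and biological coupling between expression level and splicing.
Passing tests therefore demonstrate correctness of the event algebra,
bookkeeping and statistics on clean transcript models — not robustness to
assembler noise, which in real data is upstream of this package's inputs.

## Numerical and design choices

- Internal coordinates 0-based half-open; conversion happens only in GTF
  I/O and is involutive (tested).
- Event ids are content hashes (SHA-1, 16 hex chars) over the identity
  tuple with chains in canonical sorted order, making ids symmetric in the
  transcript pair.
- Dendrograms come from scipy complete-linkage on condensed distance
  matrices; leaf order and merge heights are deterministic given the sorted
  inputs. Newick branch lengths are parent–child merge-height differences.
- The chi-square helper refuses all-zero tissue rows (instructing their
  exclusion) rather than silently dropping tissues.
- Problem sizes in tests and drivers (hundreds of genes, 1000–2000 genes
  for calibration, 1000 resamples) were chosen to give stable statistics on
  a single CPU in seconds; all are configurable.

## Known limitations

- Pairwise-with-pooling event counts can differ from group-wise event
  nesting schemes on genes with many interacting isoforms; on the
  generator's slot-separated geometry the two coincide.
- The ≥ tie rule makes the randomization test conservative for heavily
  tied count distributions; see the tie-rule discussion above.
- The Mann–Whitney front falls back to the normal approximation whenever
  ties are present, including small samples.
- `read_gtf` accepts only the Cufflinks GTF dialect (exon features with
  gene_id/transcript_id); GFF3 is out of scope.
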