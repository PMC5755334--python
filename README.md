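# splicescape

Multi-tissue alternative-splicing (AS) analysis from assembled transcript
models. Given per-tissue transcript structures (Cufflinks-dialect GTF) and a
transcript × tissue FPKM table, the package

- classifies non-redundant AS events per gene — intron retention (IR), exon
  skipping (ES), alternative donor (AD), alternative acceptor (AA), and
  complex events — by pairwise splice-chain comparison;
- assigns each event its tissue occurrence and partitions events into
  *within-tissue* (both splice variants co-expressed in at least one tissue)
  and *among-tissue* (variants never co-expressed in the same tissue);
- identifies genes with tissue-specific AS (an event observed in exactly one
  tissue);
- builds per-tissue event profiles **P** = (N_IR, N_AA, N_AD, N_ES), tests
  their homogeneity (chi-square), and clusters tissues by complete linkage on
  row-normalized profiles;
- builds per-gene binary IR patterns over the tissue list, clusters them on
  the asymmetric binary (Jaccard-style) distance with a 0.95 cut, and
  compares gene features (retained-intron length and GC, exon number,
  major-transcript FPKM) across groups by Kruskal–Wallis;
- runs a per-gene randomization test for excess AS events: the observed
  event count is compared against 1000 genes resampled from the other AS
  genes, flagging genes with empirical p < 0.05.

Because real multi-tissue RNA-seq inputs are large and external, the package
ships a synthetic-data generator (`splicescape.synthetic_data`) that plants
events of known type, geometry and tissue occurrence — including retained
introns drawn shorter than background introns, per-intron GC labels,
sub-cutoff FPKM values, and tissue-restricted isoforms — together with a
machine-readable truth table. Every stage of the pipeline is validated
against this planted truth.

Intended users: computational biologists studying isoform-level
transcriptome variation across tissues or conditions, and anyone needing a
tested, self-contained reference implementation of splice-chain event
classification.

## The model in brief

Two transcripts of a gene are compared on the intersection of their genomic
spans. A maximal region where their splice chains disagree, flanked by
positions exonic in both transcripts, is one *variable region*; the two
intron sub-chains inside it determine the event type (donor/acceptor read in
transcription direction — on the minus strand the donor is the higher
genomic coordinate). Events identical in (gene, strand, region, chain pair)
are pooled across transcript pairs, so an intron retained in many pairs
counts once. A transcript enters the comparison if it passes the expression
filter FPKM ≥ 0.1 in at least one tissue; an event is observable in tissue
*t* if some supporting pair has both transcripts expressed in *t*.

## Worked example

The numbered drivers under `analysis/` run the whole study on the synthetic
dataset and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_detect_events.py
python analysis/03_profiles_and_patterns.py
python analysis/04_randomization.py
```

`02_detect_events.py` prints, for the default 400-gene dataset:

```
Detected 783 non-redundant AS events in 400 genes
  within-tissue: 523, among-tissue: 260
  by type:
    IR        309 (39.5%)
    COMPLEX   226 (28.9%)
    AA        144 (18.4%)
    AD         65 (8.3%)
    ES         39 (5.0%)
  truth recovery: exact
  genes with a tissue-specific event: 184
```

i.e. the detected (gene, type, region) multiset equals the planted truth
table, and the realized type shares track the configured event mix.
`03_profiles_and_patterns.py` then reports, on a condition with two planted
tissue groups (IR-rich vs ES-rich), a profile-homogeneity chi-square of
p = 4.2e-26, a 2-cluster cut recovering the tissue groups exactly
(ARI = 1.00), four IR-pattern groups recovered at the 0.95 cut, and the
feature contrast across groups:

```
retained_intron_length   H=   2.01 p=0.57  (n.s.)
retained_intron_gc       H= 102.28 p=5.01e-22  (significant)
exon_count               H= 111.41 p=5.45e-24  (significant)
major_fpkm               H= 111.52 p=5.16e-24  (significant)
```

— lengths are drawn identically across groups (so the test correctly finds
nothing), while GC, exon number and major-transcript FPKM differ by
construction.

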