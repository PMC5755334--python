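"""Synthetic multi-tissue gene models with planted splicing events.

Every gene gets a reference transcript plus one alternative transcript per
planted event; each alternative differs from the reference by exactly one
elementary difference (IR, ES, AD, AA) or one complex difference (two
elementary changes inside a single variable region).  Planted retained
introns are drawn from a shorter length distribution than background
introns, and each intron carries a simulated GC-fraction label (no
nucleotide sequences are emitted; downstream analysis only consumes the GC
percentage).

Tissue structure: each gene's reference transcript is expressed (FPKM at or
above the 0.1 cutoff) in a reference tissue set R; each within-tissue event's
alternative transcript is expressed in its observable tissue set (a subset
of R, a single tissue for tissue-specific events), and among-tissue events
place the alternative entirely outside R so the two variants are never
co-expressed in one tissue.  Sub-threshold FPKM values are sprinkled in to
exercise the expression filter.  The emitted truth table records, for every
event, the planted type, variable region and observable tissues, so every
downstream stage can be checked against known ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .as_events import event_identity
from .io_models import (
    DEFAULT_FPKM_CUTOFF,
    ExpressionRecord,
    GeneModel,
    TranscriptModel,
    ValidationError,
)

__all__ = [
    "TEN_TISSUES",
    "SimulationConfig",
    "TruthRecord",
    "Simulation",
    "generate_annotation",
    "generate_expression",
    "simulate",
    "IRCohortConfig",
    "IRCohort",
    "generate_ir_cohort",
    "profile_group_config",
    "truth_to_frame",
    "intron_table",
    "zero_truncated_poisson",
]

#: The ten tissues of the cucumber multi-tissue RNA-seq design.
TEN_TISSUES: tuple[str, ...] = (
    "ovary",
    "expanded_ovary_fertilized",
    "expanded_ovary_not_fertilized",
    "root",
    "stem",
    "leaf",
    "male_flower",
    "female_flower",
    "tendril",
    "tendril_base",
)

#: Observed event-type shares used as the default planting mix.
DEFAULT_EVENT_MIX: dict[str, float] = {
    "IR": 37.55,
    "AA": 17.83,
    "AD": 9.02,
    "ES": 5.01,
    "COMPLEX": 30.58,
}

Interval = tuple[int, int]


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic annotation + expression.

    Lengths are in base pairs, FPKM on the natural scale.  The event mix
    defaults to the observed genome-wide type shares; retained introns are
    drawn with mean 90 bp against a 450 bp background; roughly a third of
    events are among-tissue (detectable only across tissues) and 30% of
    within-tissue events are restricted to a single tissue.
    """

    n_genes: int = 200
    n_tissues: int = 10
    tissue_names: tuple[str, ...] = TEN_TISSUES
    event_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_EVENT_MIX))
    events_per_gene_mean: float = 2.0
    max_events_per_gene: int = 4
    retained_intron_length_mean: float = 90.0
    background_intron_length_mean: float = 450.0
    intron_length_shape: float = 4.0
    min_intron_length: int = 60
    exon_length_range: tuple[int, int] = (80, 300)
    gc_retained: float = 0.40
    gc_background: float = 0.34
    gc_sd: float = 0.05
    fpkm_meanlog: float = 1.5
    fpkm_sdlog: float = 1.0
    expression_cutoff: float = DEFAULT_FPKM_CUTOFF
    ref_tissue_probability: float = 0.8
    tissue_restriction_probability: float = 0.6
    fraction_single_tissue_events: float = 0.3
    fraction_among_tissue_events: float = 0.327
    subthreshold_noise_rate: float = 0.1
    event_mix_by_tissue: Optional[Mapping[str, Mapping[str, float]]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_tissues < 1:
            raise ValidationError("n_genes and n_tissues must be positive")
        if sum(self.event_mix.values()) <= 0:
            raise ValidationError("event_mix weights must sum to > 0")
        for p in (
            self.ref_tissue_probability,
            self.tissue_restriction_probability,
            self.fraction_single_tissue_events,
            self.fraction_among_tissue_events,
            self.subthreshold_noise_rate,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability {p} outside [0, 1]")
        if len(self.tissue_names) < self.n_tissues:
            raise ValidationError("not enough tissue names for n_tissues")
        self.tissue_names = tuple(self.tissue_names[: self.n_tissues])


@dataclass
class TruthRecord:
    """Ground truth for one planted event."""

    gene_id: str
    event_id: str
    planted_type: str
    variant_region: Interval
    tissues_observable: frozenset[str]
    is_tissue_specific: bool
    category: str  # 'within-single' | 'within-multi' | 'among'
    ref_transcript_id: str
    alt_transcript_id: str
    alt_tissues: frozenset[str]  # tissues where the alternative is expressed


@dataclass
class Simulation:
    config: SimulationConfig
    genes: list[GeneModel]
    truth: list[TruthRecord]
    records: set[ExpressionRecord]


# ---------------------------------------------------------------------------
# sampling utilities

_ZT_LAMBDA_CACHE: dict[float, float] = {}


def _zt_lambda(mean: float) -> float:
    """Poisson rate whose zero-truncated mean equals `mean` (mean > 1)."""
    if mean <= 1.0:
        raise ValidationError("zero-truncated Poisson mean must exceed 1")
    lam = _ZT_LAMBDA_CACHE.get(mean)
    if lam is None:
        lam = brentq(lambda l: l / (1.0 - math.exp(-l)) - mean, 1e-9, mean)
        _ZT_LAMBDA_CACHE[mean] = lam
    return lam


def zero_truncated_poisson(
    rng: np.random.Generator,
    size: int = 1,
    lam: Optional[float] = None,
    mean: Optional[float] = None,
) -> np.ndarray:
    """Draw from a zero-truncated Poisson, given either the rate or the mean."""
    if (lam is None) == (mean is None):
        raise ValidationError("give exactly one of lam or mean")
    if lam is None:
        lam = _zt_lambda(float(mean))
    out = np.empty(size, dtype=int)
    for i in range(size):
        x = 0
        while x == 0:
            x = int(rng.poisson(lam))
        out[i] = x
    return out


def _intron_length(rng: np.random.Generator, mean: float, shape: float, minimum: int) -> int:
    L = int(round(rng.gamma(shape, mean / shape)))
    return max(L, minimum)


def _gc(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(np.clip(rng.normal(mean, sd), 0.15, 0.85))


def _fpkm_expressed(rng: np.random.Generator, cfg_meanlog: float, cfg_sdlog: float, cutoff: float) -> float:
    return max(float(rng.lognormal(cfg_meanlog, cfg_sdlog)), cutoff)


# ---------------------------------------------------------------------------
# gene geometry

@dataclass
class _Slot:
    etype: str
    region: Interval
    chain_ref: tuple[Interval, ...]
    chain_alt: tuple[Interval, ...]
    alt_exons: tuple[Interval, ...]
    retained_intron: Optional[Interval]


def _build_gene_geometry(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    types: Sequence[str],
    strand: str,
    origin: int,
) -> tuple[list[Interval], list[tuple[Interval, bool]], list[_Slot]]:
    """Reference exons, introns (with retained flags) and per-event slots."""
    lo, hi = cfg.exon_length_range
    exons: list[Interval] = []
    introns: list[tuple[Interval, bool]] = []
    pos = origin

    def push_exon() -> int:
        nonlocal pos
        L = int(rng.integers(lo, hi + 1))
        exons.append((pos, pos + L))
        pos += L
        return len(exons) - 1

    def push_intron(retained: bool) -> Interval:
        nonlocal pos
        mean = cfg.retained_intron_length_mean if retained else cfg.background_intron_length_mean
        L = _intron_length(rng, mean, cfg.intron_length_shape, cfg.min_intron_length)
        iv = (pos, pos + L)
        introns.append((iv, retained))
        pos += L
        return iv

    def shift_delta(intron_len: int) -> int:
        return int(rng.integers(15, min(60, intron_len - 30) + 1))

    push_exon()
    pending: list[tuple] = []  # (etype, data) to finalize after ref is complete
    for etype in types:
        left = len(exons) - 1
        if etype == "IR":
            iv = push_intron(retained=True)
            push_exon()
            pending.append(("IR", left, iv, None))
        elif etype in ("AD", "AA"):
            iv = push_intron(retained=False)
            push_exon()
            delta = shift_delta(iv[1] - iv[0])
            pending.append((etype, left, iv, delta))
        elif etype == "ES":
            iv1 = push_intron(retained=False)
            push_exon()
            iv2 = push_intron(retained=False)
            push_exon()
            pending.append(("ES", left, (iv1, iv2), None))
        elif etype == "COMPLEX":
            iv1 = push_intron(retained=False)
            push_exon()
            iv2 = push_intron(retained=False)
            push_exon()
            d_iv = iv1 if strand == "+" else iv2
            delta = shift_delta(d_iv[1] - d_iv[0])
            pending.append(("COMPLEX", left, (iv1, iv2), delta))
        else:
            raise ValidationError(f"unknown event type {etype!r}")
    # trailing constitutive exons for variety
    for _ in range(int(rng.integers(0, 3))):
        if len(exons) >= 12:
            break
        push_intron(retained=False)
        push_exon()

    ref = list(exons)
    slots: list[_Slot] = []
    for item in pending:
        etype, left, data, delta = item
        alt = list(ref)
        if etype == "IR":
            iv = data
            alt[left] = (alt[left][0], alt[left + 1][1])
            del alt[left + 1]
            slots.append(_Slot("IR", iv, (iv,), (), tuple(alt), iv))
        elif etype in ("AD", "AA"):
            iv = data
            s, e = iv
            # donor boundary in transcription direction: lower genomic coord on '+'
            modify_left = (strand == "+") == (etype == "AD")
            if modify_left:
                alt[left] = (alt[left][0], s + delta)
                chain_alt = ((s + delta, e),)
            else:
                alt[left + 1] = (e - delta, alt[left + 1][1])
                chain_alt = ((s, e - delta),)
            slots.append(_Slot(etype, iv, (iv,), chain_alt, tuple(alt), None))
        elif etype == "ES":
            iv1, iv2 = data
            region = (iv1[0], iv2[1])
            del alt[left + 1]
            slots.append(_Slot("ES", region, (iv1, iv2), ((iv1[0], iv2[1]),), tuple(alt), None))
        else:  # COMPLEX: exon skip plus a shifted donor, one variable region
            iv1, iv2 = data
            region = (iv1[0], iv2[1])
            if strand == "+":
                alt[left] = (alt[left][0], iv1[0] + delta)
                chain_alt = ((iv1[0] + delta, iv2[1]),)
            else:
                alt[left + 2] = (iv2[1] - delta, alt[left + 2][1])
                chain_alt = ((iv1[0], iv2[1] - delta),)
            del alt[left + 1]
            slots.append(_Slot("COMPLEX", region, (iv1, iv2), chain_alt, tuple(alt), None))
    return ref, introns, slots


# ---------------------------------------------------------------------------
# tissue assignment

def _assign_tissues(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    categories: list[str],
    homes: list[Optional[str]],
) -> tuple[frozenset[str], list[frozenset[str]]]:
    """Reference tissue set R and per-event alternative tissue sets."""
    tissues = list(cfg.tissue_names)
    n = len(tissues)
    n_among = sum(1 for c in categories if c == "among")
    if n_among > n - 2:  # not enough exclusive tissues; demote extras
        excess = n_among - (n - 2)
        for i in range(len(categories) - 1, -1, -1):
            if excess == 0:
                break
            if categories[i] == "among":
                categories[i] = "within-multi"
                excess -= 1
        n_among = n - 2
    r_size = int(np.clip(rng.binomial(n, cfg.ref_tissue_probability), 2, n - n_among))
    forced = sorted({h for h in homes if h is not None})
    r_size = max(r_size, len(forced), 2)
    pool = [t for t in tissues if t not in forced]
    extra = list(rng.choice(pool, size=max(r_size - len(forced), 0), replace=False))
    R = frozenset(forced) | frozenset(extra)
    outside = [t for t in tissues if t not in R]
    rng.shuffle(outside)
    R_list = sorted(R)
    alt_sets: list[frozenset[str]] = []
    for cat, home in zip(categories, homes):
        if cat == "among":
            alt_sets.append(frozenset([outside.pop()]))
        elif cat == "within-single":
            u = home if home is not None else str(rng.choice(R_list))
            alt_sets.append(frozenset([u]))
        else:
            keep = [t for t in R_list if rng.random() < cfg.tissue_restriction_probability]
            missing = [t for t in R_list if t not in keep]
            rng.shuffle(missing)
            while len(keep) < min(2, len(R_list)):
                keep.append(missing.pop())
            alt_sets.append(frozenset(keep))
    return R, alt_sets


def _draw_categories(
    rng: np.random.Generator, cfg: SimulationConfig, n_events: int
) -> list[str]:
    cats = []
    for _ in range(n_events):
        u = rng.random()
        if u < cfg.fraction_among_tissue_events:
            cats.append("among")
        elif u < cfg.fraction_among_tissue_events + cfg.fraction_single_tissue_events:
            cats.append("within-single")
        else:
            cats.append("within-multi")
    return cats


# ---------------------------------------------------------------------------
# public generators

def generate_annotation(
    config: SimulationConfig,
) -> tuple[list[GeneModel], list[TruthRecord]]:
    """Generate gene models with planted events and their truth table.

    Deterministic given ``config.seed``.  Geometry is constructed so every
    planted event occupies its own variable region separated from the next
    by at least one constitutive exon, hence pairwise detection recovers
    exactly the planted events.  Tissue-observability (part of the truth) is
    decided here; :func:`generate_expression` realizes FPKM values
    consistent with it.
    """
    rng = np.random.default_rng([config.seed, 0])
    mix_types = sorted(config.event_mix)
    mix_w = np.array([config.event_mix[t] for t in mix_types], dtype=float)
    mix_p = mix_w / mix_w.sum()

    genes: list[GeneModel] = []
    truth: list[TruthRecord] = []
    cursors: dict[str, int] = {}
    width = len(str(max(config.n_genes - 1, 1)))
    for gi in range(config.n_genes):
        gene_id = f"G{gi:0{width}d}"
        chrom = f"chr{1 + gi % 7}"
        origin = cursors.get(chrom, 1000)
        strand = "+" if rng.random() < 0.5 else "-"
        n_ev = min(
            int(zero_truncated_poisson(rng, mean=config.events_per_gene_mean)[0]),
            config.max_events_per_gene,
        )
        if config.event_mix_by_tissue is not None:
            homes = [str(rng.choice(list(config.tissue_names))) for _ in range(n_ev)]
            types = []
            for h in homes:
                m = config.event_mix_by_tissue[h]
                ts = sorted(m)
                w = np.array([m[t] for t in ts], dtype=float)
                types.append(str(rng.choice(ts, p=w / w.sum())))
            categories = ["within-single"] * n_ev
        else:
            homes = [None] * n_ev
            types = [str(t) for t in rng.choice(mix_types, size=n_ev, p=mix_p)]
            categories = _draw_categories(rng, config, n_ev)

        ref_exons, introns, slots = _build_gene_geometry(rng, config, types, strand, origin)
        cursors[chrom] = ref_exons[-1][1] + 5000

        R, alt_sets = _assign_tissues(rng, config, categories, homes)
        ref_id = f"{gene_id}.t1"
        txs = [
            TranscriptModel(ref_id, gene_id, chrom, strand, tuple(ref_exons))
        ]
        intron_gc = {
            iv: _gc(rng, config.gc_retained if ret else config.gc_background, config.gc_sd)
            for iv, ret in introns
        }
        retained = {iv for iv, ret in introns if ret}
        for k, slot in enumerate(slots):
            alt_id = f"{gene_id}.t{k + 2}"
            txs.append(TranscriptModel(alt_id, gene_id, chrom, strand, slot.alt_exons))
            cat = categories[k]
            observable = alt_sets[k] if cat != "among" else frozenset()
            truth.append(
                TruthRecord(
                    gene_id=gene_id,
                    event_id=event_identity(
                        gene_id, strand, slot.region, slot.chain_ref, slot.chain_alt
                    ),
                    planted_type=slot.etype,
                    variant_region=slot.region,
                    tissues_observable=observable,
                    is_tissue_specific=len(observable) == 1,
                    category=cat,
                    ref_transcript_id=ref_id,
                    alt_transcript_id=alt_id,
                    alt_tissues=alt_sets[k],
                )
            )
        gene = GeneModel(gene_id, chrom, strand, txs)
        gene.meta["ref_tissues"] = R
        gene.meta["intron_gc"] = intron_gc
        gene.meta["retained_introns"] = retained
        gene.meta["ref_transcript_id"] = ref_id
        genes.append(gene)
    return genes, truth


def generate_expression(
    genes: Sequence[GeneModel],
    truth: Sequence[TruthRecord],
    config: SimulationConfig,
) -> set[ExpressionRecord]:
    """Per-tissue FPKM values realizing the truth table's observability.

    The reference transcript gets an above-cutoff FPKM in every tissue of
    its reference set R; each alternative transcript gets above-cutoff FPKM
    exactly in its planted tissue set.  Sub-cutoff noise values (which the
    expression filter must remove) are added at ``subthreshold_noise_rate``.
    """
    by_gene: dict[str, GeneModel] = {g.gene_id: g for g in genes}
    for rec in truth:
        g = by_gene.get(rec.gene_id)
        if g is None:
            raise ValidationError(f"truth record for unknown gene {rec.gene_id}")
        ids = {t.transcript_id for t in g.transcripts}
        if rec.alt_transcript_id not in ids or rec.ref_transcript_id not in ids:
            raise ValidationError(
                f"truth record for {rec.gene_id} names transcripts not in the gene model"
            )
    rng = np.random.default_rng([config.seed, 1])
    cutoff = config.expression_cutoff
    records: set[ExpressionRecord] = set()
    truth_by_gene: dict[str, list[TruthRecord]] = {}
    for rec in truth:
        truth_by_gene.setdefault(rec.gene_id, []).append(rec)
    for g in sorted(genes, key=lambda x: x.gene_id):
        R = g.meta["ref_tissues"]
        ref_id = g.meta["ref_transcript_id"]
        for t in config.tissue_names:
            if t in R:
                records.add(
                    ExpressionRecord(
                        ref_id, t,
                        _fpkm_expressed(rng, config.fpkm_meanlog, config.fpkm_sdlog, cutoff),
                    )
                )
            elif rng.random() < config.subthreshold_noise_rate:
                records.add(ExpressionRecord(ref_id, t, float(rng.uniform(0.01, 0.9 * cutoff))))
        for rec in truth_by_gene.get(g.gene_id, []):
            for t in config.tissue_names:
                if t in rec.alt_tissues:
                    records.add(
                        ExpressionRecord(
                            rec.alt_transcript_id, t,
                            _fpkm_expressed(rng, config.fpkm_meanlog, config.fpkm_sdlog, cutoff),
                        )
                    )
                elif rng.random() < config.subthreshold_noise_rate:
                    records.add(
                        ExpressionRecord(
                            rec.alt_transcript_id, t, float(rng.uniform(0.01, 0.9 * cutoff))
                        )
                    )
    return records


def simulate(config: SimulationConfig) -> Simulation:
    """Annotation + truth + expression in one deterministic bundle."""
    genes, truth = generate_annotation(config)
    records = generate_expression(genes, truth, config)
    return Simulation(config, genes, truth, records)


# ---------------------------------------------------------------------------
# planted IR-pattern cohort (grouped genes with group-level features)

@dataclass
class IRCohortConfig:
    """A cohort of IR genes with planted IR-pattern archetypes.

    Each group has a tissue-set archetype (near-disjoint across groups) and
    group-specific GC, exon-number and major-transcript FPKM levels, while
    retained-intron length is drawn from one shared distribution — the
    configuration used to probe which gene features separate IR-pattern
    groups.
    """

    n_groups: int = 4
    genes_per_group: int = 30
    tissue_names: tuple[str, ...] = TEN_TISSUES
    archetypes: Optional[tuple[frozenset[str], ...]] = None
    add_bit_probability: float = 0.02
    drop_bit_probability: float = 0.01
    gc_by_group: tuple[float, ...] = (0.30, 0.36, 0.42, 0.48)
    gc_sd: float = 0.03
    exons_by_group: tuple[int, ...] = (3, 5, 8, 11)
    fpkm_meanlog_by_group: tuple[float, ...] = (0.5, 1.5, 2.5, 3.5)
    fpkm_sdlog: float = 0.4
    retained_intron_length_mean: float = 90.0
    background_intron_length_mean: float = 450.0
    intron_length_shape: float = 4.0
    min_intron_length: int = 60
    exon_length_range: tuple[int, int] = (80, 300)
    expression_cutoff: float = DEFAULT_FPKM_CUTOFF
    seed: int = 0

    def default_archetypes(self) -> tuple[frozenset[str], ...]:
        if self.archetypes is not None:
            return self.archetypes
        n, g = len(self.tissue_names), self.n_groups
        base, rem = divmod(n, g)
        sizes = [base + (1 if i < rem else 0) for i in range(g)]
        out, start = [], 0
        for s in sizes:
            out.append(frozenset(self.tissue_names[start : start + s]))
            start += s
        return tuple(out)


@dataclass
class IRCohort:
    config: IRCohortConfig
    genes: list[GeneModel]
    truth: list[TruthRecord]
    records: set[ExpressionRecord]
    groups: dict[str, int]  # gene_id -> planted group (0-based)


def generate_ir_cohort(config: IRCohortConfig) -> IRCohort:
    """Grouped IR genes: archetype IR patterns with mild bit noise.

    Every gene carries exactly one IR event observable in its (noisy)
    archetype tissue set; the reference transcript is expressed in all
    tissues and is always the gene's major (highest-FPKM) transcript.
    """
    cfg = config
    rng = np.random.default_rng([cfg.seed, 2])
    archetypes = cfg.default_archetypes()
    if len(archetypes) != cfg.n_groups:
        raise ValidationError("need one archetype per group")
    lo, hi = cfg.exon_length_range
    genes: list[GeneModel] = []
    truth: list[TruthRecord] = []
    records: set[ExpressionRecord] = set()
    groups: dict[str, int] = {}
    cursors: dict[str, int] = {}
    gid = 0
    for g in range(cfg.n_groups):
        support = archetypes[g]
        for _ in range(cfg.genes_per_group):
            gene_id = f"IRG{gid:04d}"
            gid += 1
            chrom = f"chr{1 + gid % 7}"
            origin = cursors.get(chrom, 1000)
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(np.clip(cfg.exons_by_group[g] + rng.integers(-1, 2), 3, 12))
            retained_idx = int(rng.integers(0, n_exons - 1))
            pos = origin
            exons: list[Interval] = []
            introns: list[Interval] = []
            for i in range(n_exons):
                L = int(rng.integers(lo, hi + 1))
                exons.append((pos, pos + L))
                pos += L
                if i < n_exons - 1:
                    mean = (
                        cfg.retained_intron_length_mean
                        if i == retained_idx
                        else cfg.background_intron_length_mean
                    )
                    Li = _intron_length(rng, mean, cfg.intron_length_shape, cfg.min_intron_length)
                    introns.append((pos, pos + Li))
                    pos += Li
            cursors[chrom] = pos + 5000
            retained_iv = introns[retained_idx]
            alt = list(exons)
            alt[retained_idx] = (alt[retained_idx][0], alt[retained_idx + 1][1])
            del alt[retained_idx + 1]
            ref_id, alt_id = f"{gene_id}.t1", f"{gene_id}.t2"
            txs = [
                TranscriptModel(ref_id, gene_id, chrom, strand, tuple(exons)),
                TranscriptModel(alt_id, gene_id, chrom, strand, tuple(alt)),
            ]
            # noisy archetype pattern: sporadic extra tissues, rare dropouts
            bits = set(support)
            for t in cfg.tissue_names:
                if t not in support and rng.random() < cfg.add_bit_probability:
                    bits.add(t)
            for t in sorted(support):
                if len(bits) > 1 and rng.random() < cfg.drop_bit_probability:
                    bits.discard(t)
            observable = frozenset(bits)
            intron_gc = {
                iv: _gc(
                    rng,
                    cfg.gc_by_group[g] if iv == retained_iv else 0.34,
                    cfg.gc_sd if iv == retained_iv else 0.05,
                )
                for iv in introns
            }
            gene = GeneModel(gene_id, chrom, strand, txs)
            gene.meta["ref_tissues"] = frozenset(cfg.tissue_names)
            gene.meta["intron_gc"] = intron_gc
            gene.meta["retained_introns"] = {retained_iv}
            gene.meta["ref_transcript_id"] = ref_id
            genes.append(gene)
            groups[gene_id] = g
            truth.append(
                TruthRecord(
                    gene_id=gene_id,
                    event_id=event_identity(
                        gene_id, strand, retained_iv, (retained_iv,), ()
                    ),
                    planted_type="IR",
                    variant_region=retained_iv,
                    tissues_observable=observable,
                    is_tissue_specific=len(observable) == 1,
                    category="within-single" if len(observable) == 1 else "within-multi",
                    ref_transcript_id=ref_id,
                    alt_transcript_id=alt_id,
                    alt_tissues=observable,
                )
            )
            for t in cfg.tissue_names:
                ref_fpkm = _fpkm_expressed(
                    rng, cfg.fpkm_meanlog_by_group[g], cfg.fpkm_sdlog, cfg.expression_cutoff
                )
                records.add(ExpressionRecord(ref_id, t, ref_fpkm))
                if t in observable:
                    alt_fpkm = max(ref_fpkm * float(rng.uniform(0.2, 0.7)), cfg.expression_cutoff)
                    records.add(ExpressionRecord(alt_id, t, min(alt_fpkm, ref_fpkm)))
    return IRCohort(cfg, genes, truth, records, groups)


def profile_group_config(
    seed: int,
    n_genes: int = 300,
    tissue_names: tuple[str, ...] = TEN_TISSUES,
    split: int = 5,
) -> tuple[SimulationConfig, dict[str, int]]:
    """Config planting two tissue groups with distinct event-type mixes.

    The first ``split`` tissues favour intron retention, the rest favour
    exon skipping, so the per-tissue event profiles separate into two
    clusters.  All events are single-tissue so profiles are independent
    tallies.
    """
    group_a = tissue_names[:split]
    mix_a = {"IR": 0.55, "AA": 0.20, "AD": 0.10, "ES": 0.05, "COMPLEX": 0.10}
    mix_b = {"IR": 0.10, "AA": 0.15, "AD": 0.20, "ES": 0.45, "COMPLEX": 0.10}
    by_tissue = {t: (mix_a if t in group_a else mix_b) for t in tissue_names}
    cfg = SimulationConfig(
        n_genes=n_genes,
        tissue_names=tissue_names,
        n_tissues=len(tissue_names),
        event_mix_by_tissue=by_tissue,
        ref_tissue_probability=1.0,
        seed=seed,
    )
    groups = {t: (0 if t in group_a else 1) for t in tissue_names}
    return cfg, groups


# ---------------------------------------------------------------------------
# tabular exports

def truth_to_frame(truth: Iterable[TruthRecord]) -> pd.DataFrame:
    rows = []
    for r in truth:
        rows.append(
            {
                "gene_id": r.gene_id,
                "event_id": r.event_id,
                "planted_type": r.planted_type,
                "variant_start": r.variant_region[0],
                "variant_end": r.variant_region[1],
                "category": r.category,
                "tissues_observable": ";".join(sorted(r.tissues_observable)),
                "is_tissue_specific": r.is_tissue_specific,
                "ref_transcript_id": r.ref_transcript_id,
                "alt_transcript_id": r.alt_transcript_id,
            }
        )
    return pd.DataFrame(rows)


def intron_table(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Per-intron table (reference chain): length, retained flag, GC label."""
    rows = []
    for g in genes:
        gc = g.meta.get("intron_gc", {})
        retained = g.meta.get("retained_introns", set())
        for iv, val in sorted(gc.items()):
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "start": iv[0],
                    "end": iv[1],
                    "length": iv[1] - iv[0],
                    "retained": iv in retained,
                    "gc": val,
                }
            )
    return pd.DataFrame(rows)
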