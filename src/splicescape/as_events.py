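"""Detection and classification of alternative-splicing events.

Events are found by pairwise splice-chain comparison restricted to the
common genomic span of the two transcripts.  A maximal region where the
chains disagree, flanked on both sides by positions exonic in *both*
transcripts (or by the common-span boundary), is one variable region and
yields one event.  The two intron sub-chains inside the region determine
the type, with donor/acceptor read in transcription direction:

* IR  -- one sub-chain is a single intron, the other is empty (the other
  transcript runs exonically across the intron);
* ES  -- two introns versus one intron sharing the outer donor and
  acceptor (the exon between is absent from the other transcript);
* AD  -- single intron each, shared acceptor, different donor;
* AA  -- single intron each, shared donor, different acceptor;
* COMPLEX -- any other disagreement (mutually exclusive exons, combined
  differences, ...).

Differences at transcript termini (outside the common span, e.g.
alternative first/last exons) produce no event.  Events are pooled
non-redundantly per gene: the identity key is (gene, strand, variable
region, unordered chain pair), so the same intron retained in many
transcript pairs counts once.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_models import (
    ExpressionRecord,
    GeneModel,
    TranscriptModel,
    ValidationError,
    expressed_by_tissue,
    DEFAULT_FPKM_CUTOFF,
)

__all__ = [
    "EVENT_TYPES",
    "SpliceChain",
    "ASEvent",
    "splice_chain",
    "classify_pairwise",
    "detect_gene_events",
    "detect_events",
    "partition_within_among",
    "tissue_specific_genes",
    "event_identity",
    "events_to_frame",
]

EVENT_TYPES = ("IR", "ES", "AD", "AA", "COMPLEX")

Interval = tuple[int, int]


@dataclass(frozen=True)
class SpliceChain:
    """A transcript's introns as (donor, acceptor) pairs in transcription order.

    The donor is the exon-to-intron boundary in transcription direction; on
    the minus strand it is the higher genomic coordinate.
    """

    transcript_id: str
    introns: tuple[tuple[int, int], ...]


def splice_chain(t: TranscriptModel) -> SpliceChain:
    """Derive the splice chain from a transcript's exons.

    Single-exon transcripts yield an empty chain.
    """
    genomic = t.introns  # (start, end) gaps, genomic order
    if t.strand == "+":
        ordered = tuple((s, e) for s, e in genomic)
    else:
        ordered = tuple((e, s) for s, e in reversed(genomic))
    return SpliceChain(t.transcript_id, ordered)


@dataclass
class ASEvent:
    """One non-redundant alternative-splicing difference within a gene.

    ``chain_a``/``chain_b`` are the two alternative intron sub-chains inside
    the variant region, stored genomically (start, end) and in canonical
    (order-free) order; one may be empty.  ``tissues`` is the set of tissues
    where the event is within-tissue observable (some supporting transcript
    pair has both members expressed there).
    """

    gene_id: str
    chrom: str
    strand: str
    event_type: str
    variant_region: Interval
    chain_a: tuple[Interval, ...]
    chain_b: tuple[Interval, ...]
    supporting_pairs: set[tuple[str, str]] = field(default_factory=set)
    tissues: frozenset[str] = frozenset()

    @property
    def event_id(self) -> str:
        return event_identity(
            self.gene_id, self.strand, self.variant_region, self.chain_a, self.chain_b
        )


def event_identity(
    gene_id: str,
    strand: str,
    region: Interval,
    chain_a: Sequence[Interval],
    chain_b: Sequence[Interval],
) -> str:
    """Content hash identifying an event; symmetric in the two chains."""
    a, b = sorted((tuple(chain_a), tuple(chain_b)))
    payload = f"{gene_id}|{strand}|{region[0]}-{region[1]}|{a}|{b}"
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def _canonical_chains(
    ca: Sequence[Interval], cb: Sequence[Interval]
) -> tuple[tuple[Interval, ...], tuple[Interval, ...]]:
    a, b = sorted((tuple(ca), tuple(cb)))
    return a, b


# ---------------------------------------------------------------------------
# interval helpers (sorted, disjoint interval lists)

def _clip(intervals: Sequence[Interval], span: Interval) -> list[Interval]:
    lo, hi = span
    out = []
    for s, e in intervals:
        s2, e2 = max(s, lo), min(e, hi)
        if e2 > s2:
            out.append((s2, e2))
    return out


def _intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if e > s:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _gaps(cover: Sequence[Interval], span: Interval) -> list[Interval]:
    """Maximal sub-intervals of span not covered by `cover` (sorted, disjoint)."""
    out = []
    pos = span[0]
    for s, e in cover:
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if span[1] > pos:
        out.append((pos, span[1]))
    return out


# ---------------------------------------------------------------------------
# classification

def _transcription_order(introns: Sequence[Interval], strand: str) -> list[Interval]:
    return list(introns) if strand == "+" else list(reversed(introns))


def _donor_acceptor(intron: Interval, strand: str) -> tuple[int, int]:
    s, e = intron
    return (s, e) if strand == "+" else (e, s)


def _classify_region(
    ia: Sequence[Interval], ib: Sequence[Interval], strand: str
) -> str:
    """Type of a variable region from its two genomic intron sub-chains."""
    na, nb = len(ia), len(ib)
    if {na, nb} == {0, 1}:
        return "IR"
    if na == 1 and nb == 1:
        da, aa = _donor_acceptor(ia[0], strand)
        db, ab = _donor_acceptor(ib[0], strand)
        if aa == ab and da != db:
            return "AD"
        if da == db and aa != ab:
            return "AA"
        return "COMPLEX"
    if {na, nb} == {1, 2}:
        one = ia if na == 1 else ib
        two = _transcription_order(ia if na == 2 else ib, strand)
        d1, _ = _donor_acceptor(two[0], strand)
        _, a2 = _donor_acceptor(two[1], strand)
        d, a = _donor_acceptor(one[0], strand)
        if d == d1 and a == a2:
            return "ES"
        return "COMPLEX"
    return "COMPLEX"


def classify_pairwise(a: TranscriptModel, b: TranscriptModel) -> list[ASEvent]:
    """All AS events between two transcripts of the same gene.

    Symmetric in its arguments: the same events (and event ids) come out of
    ``classify_pairwise(b, a)``.
    """
    if (a.gene_id, a.chrom, a.strand) != (b.gene_id, b.chrom, b.strand):
        raise ValidationError(
            f"transcripts {a.transcript_id}/{b.transcript_id} are not comparable "
            "(different gene, chrom or strand)"
        )
    span = (max(a.start, b.start), min(a.end, b.end))
    if span[1] <= span[0]:
        raise ValidationError(
            f"transcripts {a.transcript_id}/{b.transcript_id} have disjoint spans"
        )
    ex_a = _clip(a.exons, span)
    ex_b = _clip(b.exons, span)
    common = _intersect(ex_a, ex_b)
    pair = tuple(sorted((a.transcript_id, b.transcript_id)))
    events: list[ASEvent] = []
    for gap in _gaps(common, span):
        ia = [iv for iv in a.introns if iv[1] > gap[0] and iv[0] < gap[1]]
        ib = [iv for iv in b.introns if iv[1] > gap[0] and iv[0] < gap[1]]
        if tuple(ia) == tuple(ib):
            continue  # shared intron, chains agree here
        # terminal difference: an involved intron leaves the common span
        if any(iv[0] < span[0] or iv[1] > span[1] for iv in ia + ib):
            continue
        etype = _classify_region(ia, ib, a.strand)
        ca, cb = _canonical_chains(ia, ib)
        events.append(
            ASEvent(
                gene_id=a.gene_id,
                chrom=a.chrom,
                strand=a.strand,
                event_type=etype,
                variant_region=gap,
                chain_a=ca,
                chain_b=cb,
                supporting_pairs={pair},
            )
        )
    return events


def detect_gene_events(
    gene: GeneModel, expressed: Mapping[str, set[str]]
) -> list[ASEvent]:
    """Non-redundant AS events of one gene, with tissue occurrence.

    ``expressed`` maps tissue -> transcript_ids surviving the expression
    filter.  Transcripts expressed in at least one tissue anywhere enter the
    pairwise comparison; events identical by content are pooled and their
    supporting pairs merged.  An event's tissues are those where at least
    one supporting pair has *both* transcripts expressed.
    """
    anywhere = set().union(*expressed.values()) if expressed else set()
    txs = sorted(
        (t for t in gene.transcripts if t.transcript_id in anywhere),
        key=lambda t: t.transcript_id,
    )
    pooled: dict[str, ASEvent] = {}
    for i in range(len(txs)):
        for j in range(i + 1, len(txs)):
            a, b = txs[i], txs[j]
            if min(a.end, b.end) <= max(a.start, b.start):
                continue
            for ev in classify_pairwise(a, b):
                key = ev.event_id
                if key in pooled:
                    pooled[key].supporting_pairs |= ev.supporting_pairs
                else:
                    pooled[key] = ev
    for ev in pooled.values():
        ev.tissues = frozenset(
            t
            for t, present in expressed.items()
            if any(x in present and y in present for x, y in ev.supporting_pairs)
        )
    return sorted(pooled.values(), key=lambda e: (e.variant_region, e.event_id))


def detect_events(
    genes: Iterable[GeneModel],
    records: Iterable[ExpressionRecord],
    threshold: float = DEFAULT_FPKM_CUTOFF,
) -> list[ASEvent]:
    """Run the expression filter and event detection over a gene set."""
    expressed = expressed_by_tissue(records, threshold)
    out: list[ASEvent] = []
    for gene in sorted(genes, key=lambda g: g.gene_id):
        out.extend(detect_gene_events(gene, expressed))
    return out


def partition_within_among(
    events: Iterable[ASEvent],
) -> tuple[list[ASEvent], list[ASEvent]]:
    """Split events into within-tissue (co-expressed somewhere) and among-tissue.

    Among-tissue events have both variants expressed overall but never in
    the same tissue, so their tissues set is empty.  The two parts are
    disjoint and cover the input.
    """
    within = [e for e in events if e.tissues]
    among = [e for e in events if not e.tissues]
    return within, among


def tissue_specific_genes(
    events: Iterable[ASEvent],
) -> dict[str, set[tuple[str, str]]]:
    """Genes with at least one event observed in exactly one tissue.

    Returns gene_id -> set of (event_id, tissue); a gene can appear under
    several tissues via different events.
    """
    out: dict[str, set[tuple[str, str]]] = {}
    for e in events:
        if len(e.tissues) == 1:
            (tissue,) = e.tissues
            out.setdefault(e.gene_id, set()).add((e.event_id, tissue))
    return out


def events_to_frame(events: Iterable[ASEvent]):
    """Tabular view of an event list (one row per event)."""
    import pandas as pd

    rows = []
    for e in events:
        rows.append(
            {
                "event_id": e.event_id,
                "gene_id": e.gene_id,
                "chrom": e.chrom,
                "strand": e.strand,
                "type": e.event_type,
                "variant_start": e.variant_region[0],
                "variant_end": e.variant_region[1],
                "chain_a": ",".join(f"{s}-{t}" for s, t in e.chain_a),
                "chain_b": ",".join(f"{s}-{t}" for s, t in e.chain_b),
                "n_supporting_pairs": len(e.supporting_pairs),
                "tissues": ";".join(sorted(e.tissues)),
                "within_or_among": "within" if e.tissues else "among",
            }
        )
    return pd.DataFrame(rows)
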