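"""Transcript models, expression records and the file formats that carry them.

Input transcript models come as Cufflinks-dialect GTF: ``exon`` feature rows
with ``gene_id``/``transcript_id`` attributes and 1-based inclusive
coordinates.  Internally every interval is 0-based half-open so interval
arithmetic downstream needs no off-by-one bookkeeping; conversion happens
only at the file boundary.

Expression is a transcript x tissue FPKM table, read either in long form
(``transcript_id``, ``tissue``, ``fpkm``) or as a wide matrix whose first
column holds transcript ids.  The expression filter keeps records with
FPKM >= 0.1 by default (values *below* the cutoff are discarded, the cutoff
itself survives).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GTFParseError",
    "ValidationError",
    "TranscriptModel",
    "GeneModel",
    "ExpressionRecord",
    "read_gtf",
    "write_gtf",
    "read_expression_table",
    "write_expression_table",
    "filter_expressed",
    "expressed_by_tissue",
    "DEFAULT_FPKM_CUTOFF",
]

DEFAULT_FPKM_CUTOFF = 0.1


class GTFParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


class ValidationError(ValueError):
    """A domain invariant was violated by the input."""


Interval = tuple[int, int]


@dataclass(frozen=True)
class ExpressionRecord:
    """One transcript's FPKM in one tissue."""

    transcript_id: str
    tissue: str
    fpkm: float

    def __post_init__(self) -> None:
        if self.fpkm < 0:
            raise ValidationError(
                f"negative FPKM {self.fpkm!r} for {self.transcript_id}/{self.tissue}"
            )


@dataclass
class TranscriptModel:
    """A transcript's ordered exon intervals on one strand.

    Exons are 0-based half-open genomic intervals, sorted by start and
    non-overlapping.  The intron (splice) chain derives from the gaps
    between consecutive exons.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[Interval, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        exons = tuple(tuple(e) for e in self.exons)
        self.exons = exons
        if not exons:
            raise ValidationError(f"transcript {self.transcript_id}: no exons")
        prev_end = None
        for s, e in exons:
            if e - s < 1:
                raise ValidationError(
                    f"transcript {self.transcript_id}: empty exon ({s}, {e})"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"transcript {self.transcript_id}: exons overlap or are unsorted at ({s}, {e})"
                )
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) >= 2

    @property
    def introns(self) -> tuple[Interval, ...]:
        """Genomic gaps between consecutive exons, in genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


@dataclass
class GeneModel:
    """A gene: one or more transcript models sharing chrom and strand.

    ``meta`` holds optional generator-provided annotation (per-intron GC
    labels, the retained-intron set, the reference tissue set); it is not
    part of the core contract and absent for models read from plain GTF.
    """

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValidationError(f"gene {self.gene_id}: no transcripts")
        for t in self.transcripts:
            if t.gene_id != self.gene_id or t.chrom != self.chrom or t.strand != self.strand:
                raise ValidationError(
                    f"gene {self.gene_id}: transcript {t.transcript_id} disagrees on "
                    "gene_id/chrom/strand"
                )

    @property
    def is_multi_exon(self) -> bool:
        """A gene is multi-exon iff at least one transcript has >= 2 exons."""
        return any(t.is_multi_exon for t in self.transcripts)


_ATTR_RE = re.compile(r'(\w+)\s+(?:"([^"]*)"|([^;\s]+))')


def _parse_attributes(text: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _ATTR_RE.finditer(text)}


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read Cufflinks-dialect GTF into gene models.

    Only ``exon`` feature rows are used; all other feature types are
    ignored.  Coordinates are converted from 1-based inclusive to 0-based
    half-open.  Genes are returned sorted by gene_id, transcripts by
    transcript_id, exons by start.
    """
    exons_by_tx: dict[str, list[Interval]] = {}
    tx_info: dict[str, tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GTFParseError(
                    f"{path}: line {lineno}: non-integer coordinates {start_s!r}/{end_s!r}"
                ) from None
            if start1 < 1 or end1 < start1:
                raise GTFParseError(
                    f"{path}: line {lineno}: invalid coordinate range {start1}..{end1}"
                )
            attr = _parse_attributes(attrs)
            gene_id, tx_id = attr.get("gene_id"), attr.get("transcript_id")
            if not gene_id or not tx_id:
                raise GTFParseError(
                    f"{path}: line {lineno}: missing gene_id or transcript_id attribute"
                )
            info = (gene_id, chrom, strand)
            if tx_id in tx_info and tx_info[tx_id] != info:
                raise ValidationError(
                    f"{path}: line {lineno}: transcript {tx_id} spans multiple "
                    "gene_id/chrom/strand combinations"
                )
            tx_info.setdefault(tx_id, info)
            exons_by_tx.setdefault(tx_id, []).append((start1 - 1, end1))

    genes: dict[str, GeneModel] = {}
    for tx_id in sorted(exons_by_tx):
        gene_id, chrom, strand = tx_info[tx_id]
        tx = TranscriptModel(
            transcript_id=tx_id,
            gene_id=gene_id,
            chrom=chrom,
            strand=strand,
            exons=tuple(sorted(exons_by_tx[tx_id])),
        )
        if gene_id in genes:
            g = genes[gene_id]
            if g.chrom != chrom or g.strand != strand:
                raise ValidationError(
                    f"gene {gene_id}: transcripts on multiple chroms/strands"
                )
            g.transcripts.append(tx)
        else:
            genes[gene_id] = GeneModel(gene_id, chrom, strand, [tx])
    return [genes[g] for g in sorted(genes)]


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "splicescape") -> None:
    """Write gene models as exon rows, 1-based inclusive, deterministically ordered."""
    with open(path, "w") as fh:
        for gene in sorted(genes, key=lambda g: g.gene_id):
            for tx in sorted(gene.transcripts, key=lambda t: t.transcript_id):
                for s, e in tx.exons:
                    attrs = f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";'
                    fh.write(
                        f"{gene.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t{attrs}\n"
                    )


_LONG_COLUMNS = {"transcript_id", "tissue", "fpkm"}


def read_expression_table(path: str | Path) -> set[ExpressionRecord]:
    """Read a transcript-by-tissue FPKM table, long or wide form (auto-detected).

    Missing cells in the wide form are treated as FPKM 0.  Negative values
    or duplicate (transcript, tissue) pairs raise :class:`ValidationError`.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if _LONG_COLUMNS.issubset(df.columns):
        long = df[["transcript_id", "tissue", "fpkm"]].copy()
    else:
        id_col = df.columns[0]
        long = df.melt(id_vars=[id_col], var_name="tissue", value_name="fpkm")
        long = long.rename(columns={id_col: "transcript_id"})
    long["fpkm"] = long["fpkm"].fillna(0.0).astype(float)
    dup = long.duplicated(subset=["transcript_id", "tissue"])
    if dup.any():
        t = long[dup].iloc[0]
        raise ValidationError(
            f"duplicate expression record for ({t['transcript_id']}, {t['tissue']})"
        )
    return {
        ExpressionRecord(str(r.transcript_id), str(r.tissue), float(r.fpkm))
        for r in long.itertuples(index=False)
    }


def write_expression_table(
    records: Iterable[ExpressionRecord], path: str | Path, wide: bool = False
) -> None:
    rows = sorted(records, key=lambda r: (r.transcript_id, r.tissue))
    df = pd.DataFrame(
        {"transcript_id": [r.transcript_id for r in rows],
         "tissue": [r.tissue for r in rows],
         "fpkm": [r.fpkm for r in rows]}
    )
    if wide:
        df = df.pivot(index="transcript_id", columns="tissue", values="fpkm").reset_index()
        df.columns.name = None
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def filter_expressed(
    records: Iterable[ExpressionRecord], threshold: float = DEFAULT_FPKM_CUTOFF
) -> set[ExpressionRecord]:
    """Keep records with FPKM >= threshold.

    A transcript is "expressed in tissue t" iff it survives for t; a gene is
    expressed in t iff at least one of its transcripts is.
    """
    if threshold < 0:
        raise ValidationError(f"threshold must be >= 0, got {threshold}")
    return {r for r in records if r.fpkm >= threshold}


def expressed_by_tissue(
    records: Iterable[ExpressionRecord], threshold: float = DEFAULT_FPKM_CUTOFF
) -> dict[str, set[str]]:
    """Map tissue -> set of transcript_ids expressed there (FPKM >= threshold)."""
    out: dict[str, set[str]] = {}
    for r in filter_expressed(records, threshold):
        out.setdefault(r.tissue, set()).add(r.transcript_id)
    return out
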