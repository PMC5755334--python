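"""Per-tissue AS-event profiles, per-gene IR patterns, and their clustering.

The AS event profile of a tissue is the vector P = (N_IR, N_AA, N_AD, N_ES)
of within-tissue counts of the four basic event classes; complex events are
tallied alongside but excluded from P by default.  Profiles are compared on
row-normalized proportions ("relative distance"): tissues with different
overall event loads but the same type composition are distance zero, which
makes libraries of different depth comparable.

The IR pattern of a gene is a binary vector over the tissue list, bit i set
iff the gene has a within-tissue IR event in tissue i.  Patterns are
compared with the asymmetric binary (Jaccard-style) distance ignoring
shared-zero positions and clustered with complete linkage; the tree is cut
at height 0.95 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage, to_tree
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2_contingency

from .as_events import ASEvent
from .io_models import ExpressionRecord, GeneModel, ValidationError

__all__ = [
    "BASIC_TYPES",
    "ASProfile",
    "IRPattern",
    "IRGeneFeatures",
    "build_profiles",
    "profile_chi_square",
    "Dendrogram",
    "cluster_profiles",
    "build_ir_patterns",
    "binary_distance",
    "cluster_ir_patterns",
    "ir_pattern_dendrogram",
    "ir_gene_features",
    "ir_features_table",
    "profiles_to_frame",
]

BASIC_TYPES = ("IR", "AA", "AD", "ES")


@dataclass
class ASProfile:
    """Within-tissue basic-event counts of one tissue (complex kept aside)."""

    tissue: str
    n_ir: int
    n_aa: int
    n_ad: int
    n_es: int
    n_complex: int = 0

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.n_ir, self.n_aa, self.n_ad, self.n_es], dtype=float)

    def vector_with_complex(self) -> np.ndarray:
        return np.append(self.vector, float(self.n_complex))


@dataclass(frozen=True)
class IRPattern:
    """Gene's binary IR occurrence vector over an ordered tissue list."""

    gene_id: str
    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if not any(self.bits):
            raise ValidationError(f"IR pattern of {self.gene_id} has no set bit")

    @property
    def support(self) -> frozenset[int]:
        return frozenset(i for i, b in enumerate(self.bits) if b)


@dataclass
class IRGeneFeatures:
    """The four gene-level features compared across IR-pattern groups."""

    gene_id: str
    retained_intron_length: float  # mean bp over the gene's retained introns
    retained_intron_gc: float  # mean GC fraction of the same introns
    exon_count: int  # exons of the major transcript
    major_fpkm: float  # highest FPKM of the major transcript


def build_profiles(
    within_events: Iterable[ASEvent], tissues: Sequence[str]
) -> list[ASProfile]:
    """One profile per tissue; an event in k tissues contributes to all k."""
    idx = {t: i for i, t in enumerate(tissues)}
    counts = np.zeros((len(tissues), 4), dtype=int)
    complexes = np.zeros(len(tissues), dtype=int)
    col = {t: i for i, t in enumerate(BASIC_TYPES)}
    for e in within_events:
        for t in e.tissues:
            if t not in idx:
                raise ValidationError(f"event {e.event_id} names unknown tissue {t!r}")
            if e.event_type in col:
                counts[idx[t], col[e.event_type]] += 1
            else:
                complexes[idx[t]] += 1
    return [
        ASProfile(t, *counts[i].tolist(), n_complex=int(complexes[i]))
        for i, t in enumerate(tissues)
    ]


def profile_chi_square(profiles: Sequence[ASProfile]) -> tuple[float, int, float]:
    """Pearson chi-square of homogeneity on the tissue x 4 count table."""
    if len(profiles) < 2:
        raise ValidationError("need at least two profiles")
    table = np.stack([p.vector for p in profiles])
    zero = [p.tissue for p, row in zip(profiles, table) if row.sum() == 0]
    if zero:
        raise ValidationError(
            f"tissues with zero events must be excluded first: {', '.join(zero)}"
        )
    if np.allclose(table, table[0]):
        # identical rows: homogeneity statistic is exactly zero
        return 0.0, 3 * (len(profiles) - 1), 1.0
    table = table[:, table.sum(axis=0) > 0]  # event types absent everywhere carry no information
    stat, p, df, _ = chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)


class Dendrogram:
    """Complete-linkage merge tree with deterministic leaf labels.

    Thin wrapper over a scipy linkage matrix adding labelled cutting and
    Newick export (branch lengths are merge-height differences).
    """

    def __init__(self, linkage_matrix: np.ndarray, labels: Sequence[str]):
        self.linkage = linkage_matrix
        self.labels = list(labels)

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in leaves_list(self.linkage)]

    def cut(self, height: Optional[float] = None, k: Optional[int] = None) -> dict[str, int]:
        """Group labels 1..k, numbered in dendrogram leaf order."""
        if (height is None) == (k is None):
            raise ValidationError("give exactly one of height or k")
        if height is not None:
            raw = fcluster(self.linkage, t=height, criterion="distance")
        else:
            raw = fcluster(self.linkage, t=k, criterion="maxclust")
        relabel: dict[int, int] = {}
        for leaf in leaves_list(self.linkage):
            relabel.setdefault(int(raw[leaf]), len(relabel) + 1)
        return {lab: relabel[int(raw[i])] for i, lab in enumerate(self.labels)}

    def to_newick(self) -> str:
        tree = to_tree(self.linkage)

        def fmt(node, parent_dist: float) -> str:
            length = max(parent_dist - node.dist, 0.0)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return fmt(tree, tree.dist) + ";"


def cluster_profiles(profiles: Sequence[ASProfile]) -> Dendrogram:
    """Complete-linkage tree on Euclidean distances of profile proportions.

    Each P is normalized to P / sum(P), so the tree is invariant to uniform
    scaling of any tissue's counts.  Input rows are sorted by tissue name
    first, making ties deterministic.
    """
    if len(profiles) < 2:
        raise ValidationError("need at least two profiles")
    ordered = sorted(profiles, key=lambda p: p.tissue)
    mat = np.stack([p.vector for p in ordered])
    sums = mat.sum(axis=1)
    if (sums == 0).any():
        bad = [p.tissue for p, s in zip(ordered, sums) if s == 0]
        raise ValidationError(f"zero-sum profile for: {', '.join(bad)}")
    props = mat / sums[:, None]
    Z = linkage(pdist(props, metric="euclidean"), method="complete")
    return Dendrogram(Z, [p.tissue for p in ordered])


def build_ir_patterns(
    within_events: Iterable[ASEvent], tissues: Sequence[str]
) -> list[IRPattern]:
    """One pattern per gene having at least one within-tissue IR event."""
    idx = {t: i for i, t in enumerate(tissues)}
    bits_by_gene: dict[str, list[int]] = {}
    for e in within_events:
        if e.event_type != "IR" or not e.tissues:
            continue
        row = bits_by_gene.setdefault(e.gene_id, [0] * len(tissues))
        for t in e.tissues:
            if t not in idx:
                raise ValidationError(f"event {e.event_id} names unknown tissue {t!r}")
            row[idx[t]] = 1
    return [IRPattern(g, tuple(bits)) for g, bits in sorted(bits_by_gene.items())]


def binary_distance(p: IRPattern, q: IRPattern) -> float:
    """Asymmetric binary distance: discordant bits over bits set in either.

    Positions where both patterns are 0 are ignored; identical patterns are
    at distance 0, disjoint supports at distance 1.
    """
    if len(p.bits) != len(q.bits):
        raise ValidationError("patterns have different lengths")
    a, b = np.asarray(p.bits, bool), np.asarray(q.bits, bool)
    union = int((a | b).sum())
    if union == 0:
        raise ValidationError("binary distance undefined for two all-zero patterns")
    return float((a ^ b).sum() / union)


def _pattern_linkage(
    patterns: Sequence[IRPattern], metric: str
) -> tuple[np.ndarray, list[str]]:
    if len(patterns) < 2:
        raise ValidationError("need at least two patterns")
    n = len({len(p.bits) for p in patterns})
    if n != 1:
        raise ValidationError("patterns have different lengths")
    ordered = sorted(patterns, key=lambda p: p.gene_id)
    X = np.stack([np.asarray(p.bits, dtype=bool) for p in ordered])
    if metric == "binary":
        D = pdist(X, metric="jaccard")
    elif metric == "matching":
        D = pdist(X, metric="hamming")
    else:
        raise ValidationError(f"unknown pattern metric {metric!r}")
    return linkage(D, method="complete"), [p.gene_id for p in ordered]


def ir_pattern_dendrogram(
    patterns: Sequence[IRPattern], metric: str = "binary"
) -> Dendrogram:
    Z, labels = _pattern_linkage(patterns, metric)
    return Dendrogram(Z, labels)


def cluster_ir_patterns(
    patterns: Sequence[IRPattern],
    cut_height: float = 0.95,
    metric: str = "binary",
) -> dict[str, int]:
    """Complete-linkage groups of IR patterns, tree cut at ``cut_height``.

    Returns gene_id -> group label, labels 1..k in dendrogram leaf order.
    Genes are sorted lexicographically before clustering so the result does
    not depend on input order.
    """
    return ir_pattern_dendrogram(patterns, metric).cut(height=cut_height)


def ir_gene_features(
    gene: GeneModel,
    events: Iterable[ASEvent],
    expr: Iterable[ExpressionRecord],
    intron_gc: Optional[Mapping[tuple[int, int], float]] = None,
) -> IRGeneFeatures:
    """Features of one IR gene.

    Retained introns are the variant regions of the gene's IR events;
    length and GC are means over them (GC from ``intron_gc`` or the gene's
    generator-provided labels).  The major transcript is the one with the
    highest FPKM over all tissue values, ties broken by lexicographically
    smallest transcript id.
    """
    regions = sorted(
        {e.variant_region for e in events if e.gene_id == gene.gene_id and e.event_type == "IR"}
    )
    if not regions:
        raise ValidationError(f"gene {gene.gene_id} has no IR event")
    gc_map = intron_gc if intron_gc is not None else gene.meta.get("intron_gc")
    if gc_map is None:
        raise ValidationError(f"no GC source available for gene {gene.gene_id}")
    try:
        gc = float(np.mean([gc_map[r] for r in regions]))
    except KeyError as err:
        raise ValidationError(
            f"gene {gene.gene_id}: no GC label for retained intron {err.args[0]}"
        ) from None
    length = float(np.mean([e - s for s, e in regions]))
    own_ids = {t.transcript_id for t in gene.transcripts}
    best: tuple[float, str] | None = None
    for rec in expr:
        if rec.transcript_id in own_ids:
            key = (-rec.fpkm, rec.transcript_id)
            if best is None or key < best:
                best = key
    if best is None:
        raise ValidationError(f"gene {gene.gene_id} has no expression records")
    major_id = best[1]
    major = next(t for t in gene.transcripts if t.transcript_id == major_id)
    return IRGeneFeatures(
        gene_id=gene.gene_id,
        retained_intron_length=length,
        retained_intron_gc=gc,
        exon_count=len(major.exons),
        major_fpkm=-best[0],
    )


def ir_features_table(
    genes: Iterable[GeneModel],
    events: Iterable[ASEvent],
    expr: Iterable[ExpressionRecord],
) -> pd.DataFrame:
    """Feature rows for every gene with at least one IR event."""
    events = list(events)
    expr = list(expr)
    ir_genes = {e.gene_id for e in events if e.event_type == "IR"}
    rows = []
    for g in sorted(genes, key=lambda x: x.gene_id):
        if g.gene_id not in ir_genes:
            continue
        f = ir_gene_features(g, events, expr)
        rows.append(
            {
                "gene_id": f.gene_id,
                "retained_intron_length": f.retained_intron_length,
                "retained_intron_gc": f.retained_intron_gc,
                "exon_count": f.exon_count,
                "major_fpkm": f.major_fpkm,
            }
        )
    return pd.DataFrame(rows)


def profiles_to_frame(profiles: Sequence[ASProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tissue": [p.tissue for p in profiles],
            "N_IR": [p.n_ir for p in profiles],
            "N_AA": [p.n_aa for p in profiles],
            "N_AD": [p.n_ad for p in profiles],
            "N_ES": [p.n_es for p in profiles],
            "n_complex": [p.n_complex for p in profiles],
        }
    )
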