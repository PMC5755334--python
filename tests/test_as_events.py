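from collections import Counter

import pytest

from splicescape import (
    GeneModel,
    SimulationConfig,
    ValidationError,
    classify_pairwise,
    detect_events,
    detect_gene_events,
    generate_annotation,
    partition_within_among,
    splice_chain,
    tissue_specific_genes,
)

from _oracles import brute_force_pair_events
from conftest import make_tx


class TestSpliceChain:
    def test_plus_strand_single_intron(self):
        t = make_tx([(0, 100), (200, 300)])
        assert splice_chain(t).introns == ((100, 200),)

    def test_single_exon_empty_chain(self):
        assert splice_chain(make_tx([(0, 100)])).introns == ()

    def test_minus_strand_transcription_order_and_donor(self):
        """On '-' introns run right-to-left and the donor is the higher coordinate."""
        t = make_tx([(0, 100), (200, 300), (400, 500)], strand="-")
        assert splice_chain(t).introns == ((400, 300), (200, 100))


class TestClassifyPairwise:
    def test_identical_transcripts_no_events(self):
        a = make_tx([(0, 100), (200, 300)])
        assert classify_pairwise(a, a) == []

    def test_intron_retention(self):
        a = make_tx([(0, 100), (200, 300)], tid="a")
        b = make_tx([(0, 300)], tid="b")
        (ev,) = classify_pairwise(a, b)
        assert (ev.event_type, ev.variant_region) == ("IR", (100, 200))

    def test_exon_skipping(self):
        a = make_tx([(0, 100), (200, 250), (400, 500)], tid="a")
        b = make_tx([(0, 100), (400, 500)], tid="b")
        (ev,) = classify_pairwise(a, b)
        assert (ev.event_type, ev.variant_region) == ("ES", (100, 400))

    def test_alternative_donor_plus_strand(self):
        a = make_tx([(0, 100), (200, 300)], tid="a")
        b = make_tx([(0, 120), (200, 300)], tid="b")
        (ev,) = classify_pairwise(a, b)
        assert (ev.event_type, ev.variant_region) == ("AD", (100, 200))

    def test_alternative_acceptor_plus_strand(self):
        a = make_tx([(0, 100), (200, 300)], tid="a")
        b = make_tx([(0, 100), (180, 300)], tid="b")
        (ev,) = classify_pairwise(a, b)
        assert ev.event_type == "AA"

    def test_donor_acceptor_follow_transcription_direction(self):
        """The same genomic boundary shift is AD on '-' where it was AA on '+'."""
        a = make_tx([(0, 100), (200, 300)], strand="-", tid="a")
        b = make_tx([(0, 100), (180, 300)], strand="-", tid="b")
        (ev,) = classify_pairwise(a, b)
        assert ev.event_type == "AD"

    def test_single_exon_isoform_gives_one_ir_per_intron(self):
        a = make_tx([(0, 100), (200, 300), (400, 500)], tid="a")
        b = make_tx([(0, 500)], tid="b")
        events = classify_pairwise(a, b)
        assert [e.event_type for e in events] == ["IR", "IR"]
        assert [e.variant_region for e in events] == [(100, 200), (300, 400)]

    def test_terminal_difference_is_not_an_event(self):
        """Alternative last exons (difference outside the common span) yield nothing."""
        a = make_tx([(0, 100), (200, 300)], tid="a")
        b = make_tx([(0, 150)], tid="b")
        assert classify_pairwise(a, b) == []

    def test_event_identity_is_order_free(self):
        a = make_tx([(0, 100), (200, 300)], tid="a")
        b = make_tx([(0, 300)], tid="b")
        ids_ab = {e.event_id for e in classify_pairwise(a, b)}
        ids_ba = {e.event_id for e in classify_pairwise(b, a)}
        assert ids_ab == ids_ba

    def test_different_genes_rejected(self):
        a = make_tx([(0, 100), (200, 300)], gid="g1")
        b = make_tx([(0, 300)], gid="g2", tid="t2")
        with pytest.raises(ValidationError):
            classify_pairwise(a, b)

    def test_matches_brute_force_oracle_on_generated_pairs(self):
        """Interval-arithmetic detection equals position-array brute force."""
        genes, _ = generate_annotation(SimulationConfig(n_genes=60, seed=13))
        n_pairs = 0
        for g in genes:
            txs = g.transcripts
            for i in range(len(txs)):
                for j in range(i + 1, len(txs)):
                    got = sorted(
                        (e.event_type, e.variant_region)
                        for e in classify_pairwise(txs[i], txs[j])
                    )
                    exp = sorted(brute_force_pair_events(txs[i], txs[j]))
                    assert got == exp, (g.gene_id, txs[i].transcript_id, txs[j].transcript_id)
                    n_pairs += 1
        assert n_pairs >= 100

    def test_strand_reflection_preserves_types(self):
        """Reflecting coordinates and flipping strand leaves event types unchanged."""
        genes, _ = generate_annotation(SimulationConfig(n_genes=30, seed=21))
        C = 10_000_000

        def reflect(t):
            exons = tuple(sorted((C - e, C - s) for s, e in t.exons))
            return make_tx(
                exons,
                strand="-" if t.strand == "+" else "+",
                tid=t.transcript_id,
                gid=t.gene_id,
                chrom=t.chrom,
            )

        for g in genes:
            txs = g.transcripts
            for i in range(len(txs)):
                for j in range(i + 1, len(txs)):
                    orig = Counter(e.event_type for e in classify_pairwise(txs[i], txs[j]))
                    refl = Counter(
                        e.event_type
                        for e in classify_pairwise(reflect(txs[i]), reflect(txs[j]))
                    )
                    assert orig == refl


class TestDetectGeneEvents:
    def test_single_transcript_gene_has_no_events(self):
        g = GeneModel("g1", "chr1", "+", [make_tx([(0, 100), (200, 300)])])
        assert detect_gene_events(g, {"leaf": {"t1"}}) == []

    def test_same_difference_in_two_pairs_pools_to_one_event(self):
        t1 = make_tx([(0, 100), (200, 300)], tid="t1")
        t2 = make_tx([(0, 300)], tid="t2")
        t3 = make_tx([(0, 300), (400, 450)], tid="t3")  # same retention, extra exon
        g = GeneModel("g1", "chr1", "+", [t1, t2, t3])
        events = detect_gene_events(g, {"leaf": {"t1", "t2", "t3"}})
        ir = [e for e in events if e.variant_region == (100, 200)]
        assert len(ir) == 1
        assert ir[0].supporting_pairs == {("t1", "t2"), ("t1", "t3")}

    def test_event_tissues_require_coexpression_of_a_supporting_pair(self):
        t1 = make_tx([(0, 100), (200, 300)], tid="t1")
        t2 = make_tx([(0, 300)], tid="t2")
        g = GeneModel("g1", "chr1", "+", [t1, t2])
        expressed = {"leaf": {"t1", "t2"}, "root": {"t1"}, "stem": {"t2"}}
        (ev,) = detect_gene_events(g, expressed)
        assert ev.tissues == frozenset({"leaf"})


class TestPartitionAndTissueSpecific:
    def test_partition_is_exhaustive_and_disjoint(self, small_sim):
        events = detect_events(small_sim.genes, small_sim.records)
        within, among = partition_within_among(events)
        assert len(within) + len(among) == len(events)
        assert all(e.tissues for e in within)
        assert all(not e.tissues for e in among)

    def test_single_tissue_event_flags_its_gene(self):
        t1 = make_tx([(0, 100), (200, 300)], tid="t1")
        t2 = make_tx([(0, 300)], tid="t2")
        g = GeneModel("g1", "chr1", "+", [t1, t2])
        events = detect_gene_events(g, {"root": {"t1", "t2"}, "leaf": {"t1"}})
        specific = tissue_specific_genes(events)
        assert set(specific) == {"g1"}
        ((_, tissue),) = specific["g1"]
        assert tissue == "root"

    def test_multi_tissue_event_contributes_nothing(self):
        t1 = make_tx([(0, 100), (200, 300)], tid="t1")
        t2 = make_tx([(0, 300)], tid="t2")
        g = GeneModel("g1", "chr1", "+", [t1, t2])
        events = detect_gene_events(g, {"root": {"t1", "t2"}, "stem": {"t1", "t2"}})
        assert tissue_specific_genes(events) == {}
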