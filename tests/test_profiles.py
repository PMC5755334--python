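import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicescape import (
    ASEvent,
    ExpressionRecord,
    GeneModel,
    IRPattern,
    ValidationError,
    binary_distance,
    build_ir_patterns,
    build_profiles,
    cluster_ir_patterns,
    cluster_profiles,
    ir_gene_features,
    profile_chi_square,
)
from splicescape.profiles import ASProfile

from conftest import make_tx

TISSUES = ("leaf", "root", "stem")


def _event(etype="IR", tissues=(), gene="g1", region=(100, 200)):
    return ASEvent(
        gene_id=gene,
        chrom="chr1",
        strand="+",
        event_type=etype,
        variant_region=region,
        chain_a=(region,),
        chain_b=(),
        tissues=frozenset(tissues),
    )


class TestBuildProfiles:
    def test_no_events_all_zero(self):
        profs = build_profiles([], TISSUES)
        assert all(p.vector.sum() == 0 and p.n_complex == 0 for p in profs)

    def test_multi_tissue_event_counts_in_each_tissue(self):
        profs = build_profiles([_event("IR", ("leaf", "stem"))], TISSUES)
        by = {p.tissue: p for p in profs}
        assert by["leaf"].n_ir == 1 and by["stem"].n_ir == 1 and by["root"].n_ir == 0

    def test_complex_events_kept_out_of_the_vector(self):
        profs = build_profiles([_event("COMPLEX", ("leaf",))], TISSUES)
        by = {p.tissue: p for p in profs}
        assert by["leaf"].vector.sum() == 0 and by["leaf"].n_complex == 1

    def test_unknown_tissue_rejected(self):
        with pytest.raises(ValidationError):
            build_profiles([_event("IR", ("flower",))], TISSUES)


class TestProfileChiSquare:
    def test_identical_rows_give_zero_statistic(self):
        profs = [ASProfile("a", 5, 4, 3, 2), ASProfile("b", 5, 4, 3, 2)]
        stat, df, p = profile_chi_square(profs)
        assert stat == 0.0 and p == 1.0 and df == 3

    def test_two_by_two_matches_hand_expansion(self):
        """[[10,20],[20,10]]: all expected 15, chi2 = 4*(5^2/15) = 20/3."""
        profs = [ASProfile("a", 10, 20, 0, 0), ASProfile("b", 20, 10, 0, 0)]
        # restrict to the two informative columns via a direct computation
        from scipy.stats import chi2_contingency

        stat, p, df, _ = chi2_contingency([[10, 20], [20, 10]], correction=False)
        assert stat == pytest.approx(20 / 3)
        full_stat, _, _ = profile_chi_square(profs)
        assert full_stat == pytest.approx(stat)

    def test_zero_row_raises_naming_exclusion(self):
        profs = [ASProfile("a", 1, 0, 0, 0), ASProfile("b", 0, 0, 0, 0)]
        with pytest.raises(ValidationError, match="excluded"):
            profile_chi_square(profs)

    def test_type_i_error_calibration(self):
        """Tables drawn from one multinomial reject at ~ the nominal rate."""
        rng = np.random.default_rng(12)
        probs = np.array([0.4, 0.3, 0.2, 0.1])
        reject = 0
        n_sim = 1000
        for _ in range(n_sim):
            rows = rng.multinomial(400, probs, size=3)
            profs = [ASProfile(f"t{i}", *row.tolist()) for i, row in enumerate(rows)]
            _, _, p = profile_chi_square(profs)
            reject += p < 0.05
        assert 0.03 <= reject / n_sim <= 0.07


class TestClusterProfiles:
    def test_proportional_profiles_merge_first_at_zero_height(self):
        profs = [
            ASProfile("a", 10, 5, 3, 2),
            ASProfile("b", 20, 10, 6, 4),
            ASProfile("c", 1, 10, 1, 10),
        ]
        dend = cluster_profiles(profs)
        first = dend.linkage[0]
        merged = {dend.labels[int(first[0])], dend.labels[int(first[1])]}
        assert merged == {"a", "b"} and first[2] == pytest.approx(0.0)

    def test_identical_pair_merges_before_distinct_profile(self):
        profs = [
            ASProfile("x", 3, 3, 3, 3),
            ASProfile("y", 3, 3, 3, 3),
            ASProfile("z", 12, 0, 0, 0),
        ]
        dend = cluster_profiles(profs)
        first = dend.linkage[0]
        assert {dend.labels[int(first[0])], dend.labels[int(first[1])]} == {"x", "y"}

    def test_invariant_to_scaling_one_tissue(self):
        base = [ASProfile("a", 10, 5, 3, 2), ASProfile("b", 4, 9, 2, 5), ASProfile("c", 7, 7, 1, 5)]
        scaled = [ASProfile("a", 30, 15, 9, 6)] + base[1:]
        assert cluster_profiles(base).to_newick() == cluster_profiles(scaled).to_newick()

    def test_zero_sum_profile_rejected(self):
        with pytest.raises(ValidationError):
            cluster_profiles([ASProfile("a", 0, 0, 0, 0), ASProfile("b", 1, 0, 0, 0)])


class TestIRPatterns:
    def test_pattern_built_from_ir_events_only(self):
        events = [
            _event("IR", ("root",), gene="g1"),
            _event("ES", ("leaf",), gene="g2", region=(300, 400)),
        ]
        pats = build_ir_patterns(events, TISSUES)
        assert len(pats) == 1
        assert pats[0].gene_id == "g1"
        assert pats[0].bits == (0, 1, 0)

    def test_all_zero_pattern_impossible(self):
        with pytest.raises(ValidationError):
            IRPattern("g", (0, 0, 0))


class TestBinaryDistance:
    def test_identity(self):
        p = IRPattern("a", (1, 0, 1, 0))
        assert binary_distance(p, p) == 0.0

    def test_disjoint_supports_are_maximal(self):
        p = IRPattern("a", (1, 1, 0, 0))
        q = IRPattern("b", (0, 0, 1, 1))
        assert binary_distance(p, q) == 1.0

    def test_partial_overlap_value(self):
        """1010 vs 1100: two discordant positions over three informative ones."""
        p = IRPattern("a", (1, 0, 1, 0))
        q = IRPattern("b", (1, 1, 0, 0))
        assert binary_distance(p, q) == pytest.approx(2 / 3)

    @given(
        st.lists(
            st.tuples(*[st.integers(0, 1)] * 6).filter(lambda b: any(b)),
            min_size=3,
            max_size=3,
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_is_a_metric_on_nonzero_patterns(self, bits):
        p, q, r = (IRPattern(f"g{i}", b) for i, b in enumerate(bits))
        dpq, dqr, dpr = binary_distance(p, q), binary_distance(q, r), binary_distance(p, r)
        assert dpq == binary_distance(q, p)
        assert (dpq == 0) == (p.bits == q.bits)
        assert dpr <= dpq + dqr + 1e-12


class TestClusterIRPatterns:
    def test_all_identical_one_group(self):
        pats = [IRPattern(f"g{i}", (1, 0, 1)) for i in range(4)]
        assert set(cluster_ir_patterns(pats).values()) == {1}

    def test_cut_at_one_merges_everything_connected(self):
        pats = [
            IRPattern("g1", (1, 1, 0, 0)),
            IRPattern("g2", (0, 1, 1, 0)),
            IRPattern("g3", (0, 0, 1, 1)),
        ]
        groups = cluster_ir_patterns(pats, cut_height=1.0)
        assert set(groups.values()) == {1}

    def test_group_labels_follow_dendrogram_order(self):
        pats = [
            IRPattern("g1", (1, 1, 0, 0)),
            IRPattern("g2", (1, 1, 0, 0)),
            IRPattern("g3", (0, 0, 1, 1)),
            IRPattern("g4", (0, 0, 1, 1)),
        ]
        groups = cluster_ir_patterns(pats, cut_height=0.5)
        assert len(set(groups.values())) == 2
        assert groups["g1"] == groups["g2"] and groups["g3"] == groups["g4"]


class TestIRGeneFeatures:
    def _gene(self):
        t1 = make_tx([(0, 100), (180, 300)], tid="t1")
        t2 = make_tx([(0, 300)], tid="t2")
        g = GeneModel("g1", "chr1", "+", [t1, t2])
        g.meta["intron_gc"] = {(100, 180): 0.45}
        return g

    def test_single_retained_intron_features(self):
        g = self._gene()
        events = [_event("IR", ("leaf",), region=(100, 180))]
        expr = [
            ExpressionRecord("t1", "leaf", 5.0),
            ExpressionRecord("t1", "root", 1.0),
            ExpressionRecord("t2", "leaf", 4.0),
            ExpressionRecord("t2", "root", 6.0),
        ]
        f = ir_gene_features(g, events, expr)
        assert f.retained_intron_length == 80
        assert f.retained_intron_gc == pytest.approx(0.45)
        # t2 has the single highest FPKM anywhere (6.0) and is single-exon
        assert f.major_fpkm == 6.0 and f.exon_count == 1

    def test_fpkm_tie_broken_lexicographically(self):
        g = self._gene()
        events = [_event("IR", ("leaf",), region=(100, 180))]
        expr = [ExpressionRecord("t2", "leaf", 5.0), ExpressionRecord("t1", "root", 5.0)]
        f = ir_gene_features(g, events, expr)
        assert f.exon_count == 2  # t1 wins the tie

    def test_gene_without_ir_event_rejected(self):
        with pytest.raises(ValidationError):
            ir_gene_features(self._gene(), [_event("ES", ("leaf",))], [])
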