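import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cageatlas import (
    BreadthClass,
    BreadthThresholds,
    ConsensusCluster,
    GeneModel,
    PositionClass,
    TranscriptModel,
    assign_to_genes,
    classify_breadth,
    classify_position,
    name_promoters,
    width_summaries,
)
from oracles import brute_breadth


def cc(start, end, strand="+", chrom="chr1", cid="c1"):
    return ConsensusCluster(consensus_id=cid, chrom=chrom, strand=strand, start=start, end=end)


def gene(gene_id="G", strand="+", span=(1000, 5000), chrom="chr1"):
    return GeneModel(gene_id=gene_id, chrom=chrom, strand=strand, span=span)


class TestAssign:
    def test_cluster_inside_gene(self):
        [rec] = assign_to_genes([cc(2000, 2100)], [gene()])
        assert rec.gene_id == "G"

    def test_opposite_strand_unassigned(self):
        [rec] = assign_to_genes([cc(2000, 2100, strand="-")], [gene()])
        assert rec.gene_id is None

    def test_largest_overlap_wins(self):
        a = gene("A", span=(1000, 2030))  # overlaps 30 bp
        b = gene("B", span=(2020, 5000))  # overlaps 10 bp
        [rec] = assign_to_genes([cc(2000, 2030)], [a, b])
        assert rec.gene_id == "A"
        assert rec.overlap_bp == 30

    def test_upstream_flank_catches_5prime_cluster(self):
        [plus] = assign_to_genes([cc(700, 750)], [gene()], upstream_flank=500)
        assert plus.gene_id == "G"
        # flank extends 5' of the gene only: same interval on '-' means downstream
        [minus] = assign_to_genes(
            [cc(700, 750, strand="-")], [gene(strand="-")], upstream_flank=500
        )
        assert minus.gene_id is None


class TestNaming:
    def test_single_promoter(self):
        recs = assign_to_genes([cc(2000, 2100)], [gene()])
        name_promoters(recs, [gene()])
        assert recs[0].name == "p1.G"

    def test_plus_strand_order(self):
        recs = assign_to_genes([cc(2500, 2600, cid="x"), cc(1200, 1300, cid="y")], [gene()])
        name_promoters(recs, [gene()])
        names = {r.consensus.consensus_id: r.name for r in recs}
        assert names == {"y": "p1.G", "x": "p2.G"}

    def test_minus_strand_order_reversed(self):
        g = gene(strand="-")
        recs = assign_to_genes(
            [cc(1200, 1300, strand="-", cid="y"), cc(2500, 2600, strand="-", cid="x")], [g]
        )
        name_promoters(recs, [g])
        names = {r.consensus.consensus_id: r.name for r in recs}
        assert names == {"x": "p1.G", "y": "p2.G"}

    def test_numbering_is_bijective_and_order_invariant(self, rng):
        g = gene(span=(0, 100_000))
        starts = rng.choice(90_000, size=12, replace=False)
        clusters = [cc(int(s), int(s) + 10, cid=f"c{i}") for i, s in enumerate(starts)]
        recs1 = name_promoters(assign_to_genes(clusters, [g]), [g])
        perm = list(rng.permutation(len(clusters)))
        recs2 = name_promoters(assign_to_genes([clusters[i] for i in perm], [g]), [g])
        n1 = {r.consensus.consensus_id: r.name for r in recs1}
        n2 = {r.consensus.consensus_id: r.name for r in recs2}
        assert n1 == n2
        assert sorted(n1.values()) == sorted(f"p{k}.G" for k in range(1, 13))


class TestPosition:
    TX = TranscriptModel(
        "G", "G.t1", "chr1", "+",
        exons=[(1000, 1400), (2000, 2400), (3000, 3400)], cds_start=200,
    )

    def rec(self, start, end):
        recs = assign_to_genes([cc(start, end)], [gene(span=(1000, 3400))])
        return recs[0]

    def test_five_prime_utr(self):
        assert classify_position(self.rec(1050, 1100), self.TX) == PositionClass.FIVE_PRIME_UTR

    def test_coding_exon(self):
        assert classify_position(self.rec(2100, 2160), self.TX) == PositionClass.CODING_EXON

    def test_intron(self):
        assert classify_position(self.rec(1500, 1700), self.TX) == PositionClass.INTRON

    def test_past_last_exon_is_flank(self):
        assert classify_position(self.rec(3400, 3402), self.TX) == PositionClass.FLANK

    def test_noncoding_transcript_reports_plain_exon(self):
        tx = TranscriptModel("G", "t", "chr1", "+", exons=[(1000, 1400)], cds_start=None)
        assert classify_position(self.rec(1100, 1120), tx) == PositionClass.EXON


class TestBreadth:
    def test_all_zero_is_non_ubiquitous(self):
        prof = {f"t{i}": 0.0 for i in range(8)}
        assert classify_breadth(prof) == BreadthClass.NON_UBIQUITOUS

    def test_spike_above_tenfold_is_nonuniform(self):
        prof = dict({f"t{i}": 1.0 for i in range(7)}, t7=12.0)
        assert classify_breadth(prof) == BreadthClass.UBIQUITOUS_NONUNIFORM

    def test_flat_profile_is_uniform(self):
        prof = {f"t{i}": 1.0 for i in range(8)}
        assert classify_breadth(prof) == BreadthClass.UBIQUITOUS_UNIFORM

    def test_single_tissue_selective_is_non_ubiquitous(self):
        prof = dict({f"t{i}": 0.0 for i in range(7)}, bone_marrow=8.0)
        assert classify_breadth(prof) == BreadthClass.NON_UBIQUITOUS

    def test_boundary_tie_at_fold_is_uniform(self):
        prof = dict({f"t{i}": 1.0 for i in range(7)}, t7=10.0)  # max == 10 x median
        assert classify_breadth(prof) == BreadthClass.UBIQUITOUS_UNIFORM

    def test_boundary_at_median_floor(self):
        prof = {f"t{i}": 0.2 for i in range(8)}  # median == floor, not < floor
        assert classify_breadth(prof) == BreadthClass.UBIQUITOUS_UNIFORM

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            classify_breadth({})

    def test_agrees_with_direct_rule_on_random_profiles(self, rng):
        for _ in range(2000):
            n = int(rng.integers(2, 10))
            vals = np.round(rng.exponential(1.0, size=n) * (rng.random(n) > 0.3), 3)
            prof = {f"t{i}": float(v) for i, v in enumerate(vals)}
            assert classify_breadth(prof).value == brute_breadth(list(vals))

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_fold_rule_is_scale_free(self, scale):
        rng = np.random.default_rng(4)
        base = rng.exponential(5.0, size=8) + 0.5
        a = classify_breadth({f"t{i}": float(v) for i, v in enumerate(base)})
        b = classify_breadth({f"t{i}": float(v * scale) for i, v in enumerate(base)})
        # scaling can only move profiles across the absolute median floor
        if a != BreadthClass.NON_UBIQUITOUS and b != BreadthClass.NON_UBIQUITOUS:
            assert a == b


class TestWidths:
    def test_single_interval(self):
        out = width_summaries({"domains": [(0, 225)]})
        assert out["domains"]["median"] == 225

    def test_two_groups(self):
        out = width_summaries({"long": [(0, 1029)], "short": [(0, 320)]})
        assert out["long"]["median"] == 1029
        assert out["short"]["median"] == 320

    def test_median_of_three(self):
        out = width_summaries({"g": [(0, 1), (0, 2), (0, 3)]})
        assert out["g"]["median"] == 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            width_summaries({"g": []})
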