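import numpy as np
import pytest

from glrscope.core import GeneIndex, GeneModel, GenomicInterval, Peak, PeakSet
from glrscope.enhancers import (
    annotate_location,
    annotate_locations,
    call_active_enhancers,
    call_active_enhancers as call,
    link_to_genes,
    promoter_bound_genes,
)


def peak(chrom, start, end, apex, pid, pileup=1.0):
    return Peak(GenomicInterval(chrom, start, end), apex=apex, pileup=pileup,
                peak_id=pid)


def gene(gene_id, chrom, start, end, strand="+", exons=None):
    exons = exons or [(start, end)]
    return GeneModel(
        gene_id=gene_id, gene_name=gene_id, chrom=chrom, strand=strand,
        locus=GenomicInterval(chrom, start, end, strand),
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
    )


@pytest.fixture
def far_gene():
    return GeneIndex([gene("g1", "chr1", 12_000, 15_000)])


class TestEnhancerCalling:
    def test_overlapping_marks_far_from_gene(self, far_gene):
        k9 = PeakSet([peak("chr1", 1000, 1400, 1200, "k9")])
        k4 = PeakSet([peak("chr1", 1100, 1600, 1300, "k4")])
        (e,) = call(k9, k4, far_gene)
        assert (e.interval.start, e.interval.end, e.center) == (1000, 1600, 1200)
        assert e.h3k9ac_ids == ("k9",) and e.h3k4me2_ids == ("k4",)
        assert e.distance_to_gene >= 5_000

    def test_gene_too_close_blocks_enhancer(self):
        genes = GeneIndex([gene("g1", "chr1", 3_600, 6_000)])  # 2 kb away
        k9 = PeakSet([peak("chr1", 1000, 1400, 1200, "k9")])
        k4 = PeakSet([peak("chr1", 1100, 1600, 1300, "k4")])
        assert call(k9, k4, genes) == []

    def test_no_mark_overlap_no_enhancers(self, far_gene):
        k9 = PeakSet([peak("chr1", 1000, 1400, 1200, "k9")])
        k4 = PeakSet([peak("chr1", 2000, 2400, 2200, "k4")])
        assert call(k9, k4, far_gene) == []

    def test_apex_mode_uses_summit_distance(self, far_gene):
        # intervals overlap but apexes 350 bp apart: rejected at apex:300
        k9 = PeakSet([peak("chr1", 1000, 1500, 1050, "k9")])
        k4 = PeakSet([peak("chr1", 1100, 1600, 1400, "k4")])
        assert call(k9, k4, far_gene, mark_coincidence="apex:300") == []
        assert len(call(k9, k4, far_gene, mark_coincidence="apex:400")) == 1

    def test_overlapping_candidates_merge_with_strongest_center(self, far_gene):
        k9 = PeakSet([
            peak("chr1", 1000, 1500, 1200, "k9a", pileup=5),
            peak("chr1", 1400, 1900, 1700, "k9b", pileup=9),
        ])
        k4 = PeakSet([peak("chr1", 900, 2000, 1500, "k4")])
        (e,) = call(k9, k4, far_gene)
        assert e.center == 1700  # strongest H3K9Ac apex
        assert set(e.h3k9ac_ids) == {"k9a", "k9b"}

    def test_every_enhancer_respects_min_distance(self, small_sim):
        regions = call_active_enhancers(
            small_sim.peak_sets["H3K9Ac"], small_sim.peak_sets["H3K4Me2"],
            small_sim.genes,
        )
        assert regions
        for e in regions:
            gaps = [
                max(0, max(g.locus.start - e.interval.end,
                           e.interval.start - g.locus.end))
                for g in small_sim.genes if g.chrom == e.chrom
            ]
            assert min(gaps) >= 5_000


class TestLocationAnnotation:
    genes = GeneIndex([
        gene("g1", "chr1", 10_000, 20_000,
             exons=[(10_000, 11_000), (15_000, 16_000), (19_000, 20_000)]),
    ])

    def test_apex_at_tss_is_promoter(self):
        p = peak("chr1", 9_900, 10_100, 10_000, "p")
        assert annotate_location(p, self.genes).location == "promoter"

    def test_intronic_between_exons(self):
        p = peak("chr1", 12_900, 13_100, 13_000, "p")
        ann = annotate_location(p, self.genes)
        assert ann.location == "intronic" and ann.gene_id == "g1"

    def test_exonic_outside_promoter_window(self):
        p = peak("chr1", 15_400, 15_600, 15_500, "p")
        assert annotate_location(p, self.genes).location == "exonic"

    def test_gene_free_chromosome_is_intergenic(self):
        p = peak("chr9", 1_000, 1_200, 1_100, "p")
        assert annotate_location(p, self.genes).location == "intergenic"

    def test_classes_partition_peak_set(self, small_sim):
        anns = annotate_locations(small_sim.peak_sets["LSD1"], small_sim.genes)
        assert len(anns) == len(small_sim.peak_sets["LSD1"])
        assert all(
            a.location in ("promoter", "exonic", "intronic", "intergenic")
            for a in anns
        )


class TestPromoterBinding:
    def test_boundary_inclusive(self):
        genes = GeneIndex([gene("g1", "chr1", 10_000, 20_000)])
        at_edge = PeakSet([peak("chr1", 10_900, 11_100, 11_000, "p")])
        beyond = PeakSet([peak("chr1", 10_901, 11_101, 11_001, "p")])
        assert promoter_bound_genes(genes, at_edge) == {"g1": True}
        assert promoter_bound_genes(genes, beyond) == {"g1": False}

    def test_no_peaks_all_unbound(self):
        genes = GeneIndex([gene("g1", "chr1", 10_000, 20_000)])
        assert promoter_bound_genes(genes, PeakSet([])) == {"g1": False}

    def test_matches_brute_force(self, small_sim):
        peaks = small_sim.peak_sets["LSD1"]
        flags = promoter_bound_genes(small_sim.genes, peaks, 1_000)
        for g in small_sim.genes:
            expected = any(
                p.chrom == g.chrom and abs(p.apex - g.tss) <= 1_000 for p in peaks
            )
            assert flags[g.gene_id] == expected


class _Site:
    def __init__(self, sid, chrom, center):
        self.site_id = sid
        self.chrom = chrom
        self.center = center


class TestLinkToGenes:
    genes = GeneIndex([
        gene("a", "chr1", 1_000, 2_000),
        gene("b", "chr1", 9_000, 10_000),
    ])

    def test_many_to_one(self):
        sites = [_Site("s1", "chr1", 1_100), _Site("s2", "chr1", 1_500)]
        s2g, g2s = link_to_genes(sites, self.genes)
        assert s2g == {"s1": "a", "s2": "a"}
        assert g2s == {"a": ["s1", "s2"]}

    def test_equidistant_tie_takes_smaller_gene_id(self):
        sites = [_Site("s", "chr1", 5_000)]  # 4000 bp from both TSSs
        s2g, _ = link_to_genes(sites, self.genes)
        assert s2g["s"] == "a"

    def test_chromosome_without_genes_flagged_unassigned(self):
        s2g, _ = link_to_genes([_Site("s", "chrZ", 100)], self.genes)
        assert s2g["s"] is None

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(9)
        genes = GeneIndex([
            gene(f"g{i:02d}", "chr1", int(p), int(p) + 500)
            for i, p in enumerate(rng.choice(2_000, size=15, replace=False) * 100)
        ])
        sites = [_Site(f"s{i}", "chr1", int(rng.integers(0, 220_000)))
                 for i in range(20)]
        s2g, _ = link_to_genes(sites, genes)
        for s in sites:
            expected = min(genes, key=lambda g: (abs(g.tss - s.center), g.gene_id))
            assert s2g[s.site_id] == expected.gene_id
        assert len(set(s2g.values())) <= len(sites)
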