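import numpy as np
import pytest

from glrscope.coincidence import (
    CATEGORIES,
    coincidence_summary,
    is_coincident,
    partition_categories,
    partition_report,
    percent,
    round_half_up,
    stratified_coincidence,
    top_fraction,
)
from glrscope.core import GenomicInterval, Peak, PeakSet, ValidationError


def peak(chrom, apex, pileup=1.0, pid=None, width=400):
    start = max(0, apex - width // 2)
    return Peak(GenomicInterval(chrom, start, apex + width // 2),
                apex=apex, pileup=pileup, peak_id=pid or f"{chrom}:{apex}")


def random_peakset(rng, n, prefix, chroms=("chr1", "chr2"), span=50_000):
    peaks = []
    for i in range(n):
        apex = int(rng.integers(500, span))
        peaks.append(peak(str(rng.choice(chroms)), apex,
                          pileup=float(rng.uniform(0, 50)),
                          pid=f"{prefix}{i}"))
    return PeakSet(peaks)


class TestIsCoincident:
    def test_equal_apexes(self):
        q = peak("chr1", 1000, pid="q")
        assert is_coincident(q, PeakSet([peak("chr1", 1000, pid="t")])).peak_id == "t"

    @pytest.mark.parametrize("delta,hit", [(500, True), (501, False)])
    def test_boundary_inclusive(self, delta, hit):
        q = peak("chr1", 1000, pid="q")
        found = is_coincident(q, PeakSet([peak("chr1", 1000 + delta, pid="t")]))
        assert (found is not None) == hit

    def test_different_chromosomes(self):
        q = peak("chr1", 1000, pid="q")
        assert is_coincident(q, PeakSet([peak("chr2", 1000, pid="t")])) is None

    def test_tie_breaks_toward_smaller_coordinate(self):
        q = peak("chr1", 1000, pid="q")
        targets = PeakSet([peak("chr1", 900, pid="lo"), peak("chr1", 1100, pid="hi")])
        assert is_coincident(q, targets).peak_id == "lo"

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            queries = random_peakset(rng, int(rng.integers(1, 60)), "q")
            targets = random_peakset(rng, int(rng.integers(1, 60)), "t")
            for q in queries:
                got = is_coincident(q, targets, 500)
                hits = [t for t in targets
                        if t.chrom == q.chrom and abs(t.apex - q.apex) <= 500]
                if not hits:
                    assert got is None
                else:
                    best = min(hits, key=lambda t: (abs(t.apex - q.apex), t.apex))
                    assert got.peak_id == best.peak_id


class TestCoincidenceSummary:
    def test_identical_sets_are_100pct(self):
        ps = PeakSet([peak("chr1", 1000, pid="a"), peak("chr1", 5000, pid="b")])
        s = coincidence_summary(ps, ps)
        assert s.percent == 100.0

    def test_empty_query_set_rejected(self):
        with pytest.raises(ValidationError):
            coincidence_summary(PeakSet([]), PeakSet([peak("chr1", 1000)]))

    def test_equals_all_pairs_brute_force(self):
        rng = np.random.default_rng(3)
        q = random_peakset(rng, 50, "q")
        t = random_peakset(rng, 50, "t")
        s = coincidence_summary(q, t, 500)
        brute = sum(
            any(tp.chrom == qp.chrom and abs(tp.apex - qp.apex) <= 500 for tp in t)
            for qp in q
        )
        assert s.n_coincident == brute

    def test_invariant_under_translation_and_relabeling(self):
        rng = np.random.default_rng(4)
        q = random_peakset(rng, 40, "q")
        t = random_peakset(rng, 40, "t")
        base = coincidence_summary(q, t).percent

        def shift(ps, delta, rename):
            return PeakSet([
                Peak(GenomicInterval(rename(p.chrom), p.start + delta,
                                     p.end + delta),
                     apex=p.apex + delta, pileup=p.pileup, peak_id=p.peak_id)
                for p in ps
            ])

        moved = coincidence_summary(
            shift(q, 10_000, lambda c: "X" + c), shift(t, 10_000, lambda c: "X" + c)
        ).percent
        assert moved == base


class TestTopFraction:
    def test_count_is_ceiling(self):
        rng = np.random.default_rng(5)
        ps = random_peakset(rng, 100, "p")
        assert len(top_fraction(ps, 0.05)) == 5
        assert len(top_fraction(ps, 0.041)) == 5  # ceil(4.1)

    def test_tied_pileups_use_coordinate_order(self):
        peaks = [peak("chr1", 10_000, pileup=5, pid="b"),
                 peak("chr1", 2_000, pileup=5, pid="a"),
                 peak("chr2", 500, pileup=5, pid="c")]
        top = top_fraction(PeakSet(peaks), 2 / 3)
        assert sorted(p.peak_id for p in top) == ["a", "b"]

    def test_equals_sort_oracle(self):
        rng = np.random.default_rng(6)
        ps = random_peakset(rng, 73, "p")
        top = top_fraction(ps, 0.1)
        expected = sorted(ps, key=lambda p: (-p.pileup, p.chrom, p.start))[:8]
        assert {p.peak_id for p in top} == {p.peak_id for p in expected}

    def test_fraction_one_equals_unstratified(self):
        rng = np.random.default_rng(7)
        q = random_peakset(rng, 40, "q")
        t = random_peakset(rng, 40, "t")
        assert (
            stratified_coincidence(q, t, fraction=1.0).percent
            == coincidence_summary(q, t).percent
        )


def brute_force_partition(gfi1, lsd1, rcor1, window=500):
    """Independent O(n*m) greedy matcher mirroring the documented tie rules."""

    def claim(anchors, cands):
        pairs = sorted(
            (abs(c.apex - a.apex), a.chrom, a.apex, c.apex, a.peak_id, c.peak_id)
            for a in anchors for c in cands
            if a.chrom == c.chrom and abs(c.apex - a.apex) <= window
        )
        taken_a, taken_c, out = set(), set(), {}
        for _, _, _, _, aid, cid in pairs:
            if aid not in taken_a and cid not in taken_c:
                out[aid] = cid
                taken_a.add(aid)
                taken_c.add(cid)
        return out

    lc, rc = claim(gfi1, lsd1), claim(gfi1, rcor1)
    counts = dict.fromkeys(CATEGORIES, 0)
    for g in gfi1:
        has_l, has_r = g.peak_id in lc, g.peak_id in rc
        counts[{(1, 1): "GLR", (1, 0): "GL", (0, 1): "GR", (0, 0): "G"}[
            (has_l, has_r)]] += 1
    free_l = [p for p in lsd1 if p.peak_id not in set(lc.values())]
    free_r = [p for p in rcor1 if p.peak_id not in set(rc.values())]
    lr = claim(free_l, free_r)
    counts["LR"] = len(lr)
    counts["L"] = len(free_l) - len(lr)
    counts["R"] = len(free_r) - len(lr)
    return counts


class TestPartition:
    def test_three_equal_apexes_make_one_glr_site(self):
        g = PeakSet([peak("chr1", 1000, pid="g")])
        l = PeakSet([peak("chr1", 1000, pid="l")])
        r = PeakSet([peak("chr1", 1000, pid="r")])
        (a,) = partition_categories(g, l, r)
        assert a.category == "GLR"
        assert a.partners == {"GFI1": "g", "LSD1": "l", "RCOR1": "r"}

    def test_pairwise_window_example(self):
        # G at 1000, L at 1400 (|d|=400 <= 500), R at 2100 (1100 > 500 from G)
        g = PeakSet([peak("chr1", 1000, pid="g")])
        l = PeakSet([peak("chr1", 1400, pid="l")])
        r = PeakSet([peak("chr1", 2100, pid="r")])
        cats = sorted(a.category for a in partition_categories(g, l, r))
        assert cats == ["GL", "R"]

    def test_duplicate_ids_across_sets_rejected(self):
        g = PeakSet([peak("chr1", 1000, pid="x")])
        l = PeakSet([peak("chr1", 1400, pid="x")])
        with pytest.raises(ValidationError):
            partition_categories(g, l, PeakSet([]))

    def test_random_instances_match_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(25):
            g = random_peakset(rng, int(rng.integers(1, 30)), "g", span=20_000)
            l = random_peakset(rng, int(rng.integers(1, 30)), "l", span=20_000)
            r = random_peakset(rng, int(rng.integers(1, 30)), "r", span=20_000)
            got = partition_categories(g, l, r)
            got_counts = {c: sum(a.category == c for a in got) for c in CATEGORIES}
            assert got_counts == brute_force_partition(g, l, r)

    def test_partition_exhaustive_and_exclusive(self, small_sim):
        g, l, r = (small_sim.peak_sets[f] for f in ("GFI1", "LSD1", "RCOR1"))
        assignments = partition_categories(g, l, r)
        claimed = [pid for a in assignments for pid in a.partners.values()]
        assert len(claimed) == len(set(claimed))  # no peak in two sites
        assert len(claimed) == len(g) + len(l) + len(r)  # every peak placed
        assert len({a.site_id for a in assignments}) == len(assignments)


class TestReporting:
    def test_round_half_up(self):
        assert round_half_up(22.95, 1) == 23.0
        assert round_half_up(0.25, 1) == 0.3
        assert percent(1, 3, 1) == 33.3

    def test_zero_count_is_zero_percent(self):
        assert percent(0, 50, 0) == 0.0

    def test_report_counts_sum_to_sites(self, small_sim):
        g, l, r = (small_sim.peak_sets[f] for f in ("GFI1", "LSD1", "RCOR1"))
        assignments = partition_categories(g, l, r)
        rep = partition_report(assignments)
        assert rep["count"].sum() == len(assignments)
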