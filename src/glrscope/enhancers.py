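"""Active-enhancer calling and genomic-location annotation.

An active intergenic enhancer is a region at least ``min_gene_distance``
(default 5 kb) from any annotated gene locus carrying coincident H3K9Ac and
H3K4Me2 peaks. Coincidence between the broad histone-mark peaks is interval
overlap by default (summits of broad marks are unstable); an apex-distance
mode is available. The enhancer center is the H3K9Ac apex.

Peak locations are classified promoter > exonic > intronic > intergenic by
apex position, with the promoter defined as TSS +/- 1 kb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from intervaltree import IntervalTree

from .core import GeneIndex, GenomicInterval, Peak, PeakSet

logger = logging.getLogger(__name__)

DEFAULT_MIN_GENE_DISTANCE = 5_000
DEFAULT_PROMOTER_HALFWIDTH = 1_000

LOCATION_CLASSES = ("promoter", "exonic", "intronic", "intergenic")


@dataclass(frozen=True)
class EnhancerRegion:
    """A called active intergenic enhancer."""

    interval: GenomicInterval
    center: int
    h3k9ac_ids: tuple[str, ...]
    h3k4me2_ids: tuple[str, ...]
    pileup: float  # strongest contributing H3K9Ac pileup
    nearest_gene_id: str | None = None
    distance_to_gene: float = float("inf")
    lsd1_bound: bool | None = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def region_id(self) -> str:
        return f"{self.chrom}:{self.interval.start}-{self.interval.end}"


@dataclass(frozen=True)
class LocationAnnotation:
    peak_id: str
    location: str
    gene_id: str | None = None


def _gene_distance(
    genes: GeneIndex, chrom: str, start: int, end: int
) -> tuple[float, str | None]:
    """Min gap between [start, end) and any gene locus on the chromosome."""
    gs = genes.by_chrom.get(chrom)
    if not gs:
        return float("inf"), None
    starts = np.array([g.locus.start for g in gs])
    ends = np.array([g.locus.end for g in gs])
    gaps = np.maximum(0, np.maximum(starts - end, start - ends))
    i = int(np.argmin(gaps))
    return float(gaps[i]), gs[i].gene_id


def call_active_enhancers(
    h3k9ac: PeakSet,
    h3k4me2: PeakSet,
    genes: GeneIndex,
    min_gene_distance: int = DEFAULT_MIN_GENE_DISTANCE,
    mark_coincidence: str = "overlap",
) -> list[EnhancerRegion]:
    """Call active intergenic enhancers from coincident mark peaks.

    A candidate is any H3K9Ac peak coincident with >=1 H3K4Me2 peak
    (``mark_coincidence``: "overlap" for single-base interval overlap, or
    "apex:<bp>" for apex distance). The candidate interval is the union of
    the coincident peak intervals and its center is the H3K9Ac apex.
    Candidates closer than ``min_gene_distance`` to a gene locus are
    dropped; overlapping survivors are merged, the merged center taken from
    the strongest H3K9Ac peak.
    """
    apex_window: int | None = None
    if mark_coincidence.startswith("apex:"):
        apex_window = int(mark_coincidence.split(":", 1)[1])
    elif mark_coincidence != "overlap":
        raise ValueError("mark_coincidence must be 'overlap' or 'apex:<bp>'")

    k4_trees: dict[str, IntervalTree] = {}
    for p in h3k4me2:
        k4_trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)

    candidates: list[EnhancerRegion] = []
    for k9 in h3k9ac:
        tree = k4_trees.get(k9.chrom)
        if tree is None:
            continue
        if apex_window is None:
            hits = [iv.data for iv in tree.overlap(k9.start, k9.end)]
        else:
            hits = [
                iv.data
                for iv in tree.overlap(k9.apex - apex_window, k9.apex + apex_window + 1)
                if abs(iv.data.apex - k9.apex) <= apex_window
            ]
        if not hits:
            continue
        start = min([k9.start] + [h.start for h in hits])
        end = max([k9.end] + [h.end for h in hits])
        dist, gene_id = _gene_distance(genes, k9.chrom, start, end)
        if dist < min_gene_distance:
            continue
        candidates.append(
            EnhancerRegion(
                interval=GenomicInterval(k9.chrom, start, end),
                center=k9.apex,
                h3k9ac_ids=(k9.peak_id,),
                h3k4me2_ids=tuple(sorted(h.peak_id for h in hits)),
                pileup=k9.pileup,
                nearest_gene_id=gene_id,
                distance_to_gene=dist,
            )
        )

    # merge overlapping retained regions; center follows the strongest H3K9Ac
    candidates.sort(key=lambda r: (r.chrom, r.interval.start))
    merged: list[EnhancerRegion] = []
    for r in candidates:
        if merged and r.chrom == merged[-1].chrom and r.interval.start < merged[-1].interval.end:
            prev = merged[-1]
            strongest = prev if prev.pileup >= r.pileup else r
            dist, gene_id = _gene_distance(
                genes, r.chrom, prev.interval.start, max(prev.interval.end, r.interval.end)
            )
            merged[-1] = EnhancerRegion(
                interval=GenomicInterval(
                    r.chrom, prev.interval.start, max(prev.interval.end, r.interval.end)
                ),
                center=strongest.center,
                h3k9ac_ids=tuple(sorted(set(prev.h3k9ac_ids) | set(r.h3k9ac_ids))),
                h3k4me2_ids=tuple(sorted(set(prev.h3k4me2_ids) | set(r.h3k4me2_ids))),
                pileup=strongest.pileup,
                nearest_gene_id=gene_id,
                distance_to_gene=dist,
            )
        else:
            merged.append(r)
    return merged


class _LocusIndex:
    """Interval trees over gene loci and exons plus sorted TSS arrays."""

    def __init__(self, genes: GeneIndex) -> None:
        self.locus_trees: dict[str, IntervalTree] = {}
        self.exon_trees: dict[str, IntervalTree] = {}
        self.tss: dict[str, np.ndarray] = {}
        for chrom, gs in genes.by_chrom.items():
            lt, et = IntervalTree(), IntervalTree()
            for g in gs:
                lt.addi(g.locus.start, g.locus.end, g.gene_id)
                for e in g.exons:
                    et.addi(e.start, e.end, g.gene_id)
            self.locus_trees[chrom] = lt
            self.exon_trees[chrom] = et
            self.tss[chrom] = np.sort(np.array([g.tss for g in gs]))


def annotate_location(
    peak: Peak,
    genes: GeneIndex,
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
    _index: _LocusIndex | None = None,
) -> LocationAnnotation:
    """Classify one peak by apex: promoter > exonic > intronic > intergenic."""
    idx = _index if _index is not None else _LocusIndex(genes)
    chrom, apex = peak.chrom, peak.apex
    tss = idx.tss.get(chrom)
    if tss is not None and len(tss):
        i = int(np.searchsorted(tss, apex))
        for j in (i - 1, i):
            if 0 <= j < len(tss) and abs(int(tss[j]) - apex) <= promoter_halfwidth:
                gene, _ = genes.nearest_tss(chrom, apex)
                return LocationAnnotation(peak.peak_id, "promoter", gene.gene_id)
    exon_hits = idx.exon_trees.get(chrom, IntervalTree()).at(apex)
    if exon_hits:
        gene_id = sorted(iv.data for iv in exon_hits)[0]
        return LocationAnnotation(peak.peak_id, "exonic", gene_id)
    locus_hits = idx.locus_trees.get(chrom, IntervalTree()).at(apex)
    if locus_hits:
        gene_id = sorted(iv.data for iv in locus_hits)[0]
        return LocationAnnotation(peak.peak_id, "intronic", gene_id)
    return LocationAnnotation(peak.peak_id, "intergenic", None)


def annotate_locations(
    peaks: PeakSet,
    genes: GeneIndex,
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
) -> list[LocationAnnotation]:
    idx = _LocusIndex(genes)
    return [
        annotate_location(p, genes, promoter_halfwidth, _index=idx) for p in peaks
    ]


def promoter_bound_genes(
    genes: GeneIndex,
    peaks: PeakSet,
    halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
) -> dict[str, bool]:
    """Flag each gene whose TSS +/- halfwidth contains a peak apex (inclusive)."""
    apex_by_chrom = {
        chrom: arr for chrom, (arr, _) in peaks.apex_index().items()
    }
    out = {}
    for g in genes:
        arr = apex_by_chrom.get(g.chrom)
        if arr is None or len(arr) == 0:
            out[g.gene_id] = False
            continue
        lo = np.searchsorted(arr, g.tss - halfwidth, side="left")
        hi = np.searchsorted(arr, g.tss + halfwidth, side="right")
        out[g.gene_id] = bool(hi > lo)
    return out


def link_to_genes(
    sites: list, genes: GeneIndex
) -> tuple[dict[str, str | None], dict[str, list[str]]]:
    """Assign each site (object with .chrom, .center, .region_id or .site_id)
    to the gene with the nearest TSS to its center.

    Many sites may share one gene. Sites on chromosomes without genes are
    flagged unassigned (None) with a warning. Returns (site -> gene_id,
    gene_id -> [site ids]).
    """
    site_to_gene: dict[str, str | None] = {}
    gene_sites: dict[str, list[str]] = {}
    for s in sites:
        sid = getattr(s, "region_id", None) or getattr(s, "site_id")
        try:
            gene, _ = genes.nearest_tss(s.chrom, s.center)
        except LookupError:
            logger.warning("site %s: no gene on chromosome %s", sid, s.chrom)
            site_to_gene[sid] = None
            continue
        site_to_gene[sid] = gene.gene_id
        gene_sites.setdefault(gene.gene_id, []).append(sid)
    return site_to_gene, gene_sites
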