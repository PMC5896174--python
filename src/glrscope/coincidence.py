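"""Peak co-occupancy by apex distance.

Two peaks are coincident when their apexes lie within a fixed window
(default +/-500 bp, boundary inclusive) on the same chromosome. Sites are
partitioned into Venn categories over the three factors (GFI1 = G,
LSD1 = L, RCOR1 = R): GLR, GL, GR, G anchored on GFI1 peaks, then LR, L, R
from the peaks no GFI1 site claimed. Partner claiming is greedy one-to-one
by ascending apex distance so a single partner peak is never counted at
two adjacent anchor sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .core import Peak, PeakSet, ValidationError

DEFAULT_WINDOW = 500

CATEGORIES = ("GLR", "GL", "GR", "LR", "G", "L", "R")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero to the printed precision (reporting rule)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int, decimals: int = 1) -> float:
    """100*count/total rounded half-up to `decimals` places."""
    if total <= 0:
        raise ValidationError("percent undefined for empty denominator")
    return round_half_up(100.0 * count / total, decimals)


def is_coincident(
    query: Peak, targets: PeakSet, window: int = DEFAULT_WINDOW
) -> Peak | None:
    """Nearest target whose apex is within +/-window bp of the query apex.

    Boundary inclusive (|delta| == window counts); ties on distance break
    toward the smaller coordinate. Returns None when no target qualifies.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    index = targets.apex_index().get(query.chrom)
    if index is None:
        return None
    apexes, peaks = index
    lo = int(np.searchsorted(apexes, query.apex - window, side="left"))
    hi = int(np.searchsorted(apexes, query.apex + window, side="right"))
    best: Peak | None = None
    best_key: tuple[int, int] | None = None
    for j in range(lo, hi):
        p = peaks[j]
        key = (abs(p.apex - query.apex), p.apex)
        if best_key is None or key < best_key:
            best, best_key = p, key
    return best


@dataclass(frozen=True)
class CoincidenceSummary:
    """Fraction of query peaks with >=1 coincident target peak."""

    query_factor: str
    target_factor: str
    n_query: int
    n_coincident: int
    window: int = DEFAULT_WINDOW

    @property
    def percent(self) -> float:
        return percent(self.n_coincident, self.n_query, decimals=1)

    @property
    def fraction(self) -> float:
        return self.n_coincident / self.n_query


def coincidence_summary(
    queries: PeakSet, targets: PeakSet, window: int = DEFAULT_WINDOW
) -> CoincidenceSummary:
    """Count queries with any target apex within the window."""
    if len(queries) == 0:
        raise ValidationError("coincidence fraction undefined for empty query set")
    n_hit = sum(1 for q in queries if is_coincident(q, targets, window) is not None)
    return CoincidenceSummary(
        query_factor=queries.factor,
        target_factor=targets.factor,
        n_query=len(queries),
        n_coincident=n_hit,
        window=window,
    )


def top_fraction(peaks: PeakSet, fraction: float) -> PeakSet:
    """The strongest ceil(fraction*n) peaks by pileup.

    Ties broken by (chrom, start) so the selection is deterministic.
    """
    if len(peaks) == 0:
        raise ValidationError("top_fraction of an empty PeakSet")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    k = math.ceil(fraction * len(peaks))
    ranked = sorted(peaks, key=lambda p: (-p.pileup, p.chrom, p.start))
    return PeakSet(ranked[:k], factor=peaks.factor, condition=peaks.condition)


def stratified_coincidence(
    queries: PeakSet,
    targets: PeakSet,
    window: int = DEFAULT_WINDOW,
    fraction: float = 0.05,
) -> CoincidenceSummary:
    """Coincidence restricted to the strongest `fraction` of query peaks."""
    return coincidence_summary(top_fraction(queries, fraction), targets, window)


@dataclass(frozen=True)
class CategoryAssignment:
    """One site's Venn label with the partner peaks backing each letter."""

    site_id: str
    category: str
    anchor: Peak
    partners: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"unknown category {self.category}")


def _greedy_claim(
    anchors: PeakSet, candidates: PeakSet, window: int
) -> dict[str, str]:
    """One-to-one anchor->candidate matching, ascending |apex distance|.

    Deterministic: ties on distance break by anchor coordinate then
    candidate coordinate.
    """
    pairs: list[tuple[int, str, int, int, str, str]] = []
    cand_index = candidates.apex_index()
    for a in anchors:
        index = cand_index.get(a.chrom)
        if index is None:
            continue
        apexes, peaks = index
        lo = int(np.searchsorted(apexes, a.apex - window, side="left"))
        hi = int(np.searchsorted(apexes, a.apex + window, side="right"))
        for j in range(lo, hi):
            c = peaks[j]
            pairs.append(
                (abs(c.apex - a.apex), a.chrom, a.apex, c.apex, a.peak_id, c.peak_id)
            )
    pairs.sort()
    claimed_a: set[str] = set()
    claimed_c: set[str] = set()
    out: dict[str, str] = {}
    for _, _, _, _, a_id, c_id in pairs:
        if a_id in claimed_a or c_id in claimed_c:
            continue
        out[a_id] = c_id
        claimed_a.add(a_id)
        claimed_c.add(c_id)
    return out


def partition_categories(
    gfi1: PeakSet,
    lsd1: PeakSet,
    rcor1: PeakSet,
    window: int = DEFAULT_WINDOW,
) -> list[CategoryAssignment]:
    """Partition all peaks into GLR/GL/GR/LR/G/L/R sites.

    GFI1 peaks anchor the G-containing categories: each claims at most one
    LSD1 and one RCOR1 partner within the window (greedy by distance, no
    L-R mutual constraint). Unclaimed LSD1/RCOR1 peaks are then mutually
    matched into LR sites (anchored on the LSD1 peak) and the rest become
    singleton L or R sites. Every input peak lands in exactly one site.
    """
    all_ids = [p.peak_id for s in (gfi1, lsd1, rcor1) for p in s]
    if len(set(all_ids)) != len(all_ids):
        raise ValidationError("duplicate peak ids across the three peak sets")

    l_claim = _greedy_claim(gfi1, lsd1, window)
    r_claim = _greedy_claim(gfi1, rcor1, window)

    assignments: list[CategoryAssignment] = []
    for g in gfi1:
        partners = {}
        label = "G"
        if g.peak_id in l_claim:
            partners["LSD1"] = l_claim[g.peak_id]
        if g.peak_id in r_claim:
            partners["RCOR1"] = r_claim[g.peak_id]
        if "LSD1" in partners and "RCOR1" in partners:
            label = "GLR"
        elif "LSD1" in partners:
            label = "GL"
        elif "RCOR1" in partners:
            label = "GR"
        partners["GFI1"] = g.peak_id
        assignments.append(
            CategoryAssignment(site_id=g.peak_id, category=label, anchor=g,
                               partners=partners)
        )

    used_l = set(l_claim.values())
    used_r = set(r_claim.values())
    free_l = PeakSet([p for p in lsd1 if p.peak_id not in used_l],
                     factor=lsd1.factor)
    free_r = PeakSet([p for p in rcor1 if p.peak_id not in used_r],
                     factor=rcor1.factor)

    lr_claim = _greedy_claim(free_l, free_r, window)
    paired_r = set(lr_claim.values())
    for p in free_l:
        if p.peak_id in lr_claim:
            assignments.append(
                CategoryAssignment(
                    site_id=p.peak_id,
                    category="LR",
                    anchor=p,
                    partners={"LSD1": p.peak_id, "RCOR1": lr_claim[p.peak_id]},
                )
            )
        else:
            assignments.append(
                CategoryAssignment(p.peak_id, "L", p, {"LSD1": p.peak_id})
            )
    for p in free_r:
        if p.peak_id not in paired_r:
            assignments.append(
                CategoryAssignment(p.peak_id, "R", p, {"RCOR1": p.peak_id})
            )
    return assignments


def partition_report(
    assignments: list[CategoryAssignment], decimals: int = 1
) -> pd.DataFrame:
    """Category counts with percents of sites and of each factor's peaks.

    `pct_of_<factor>` is the share of that factor's peaks sitting in the
    category (denominator = number of peaks of the factor over all sites).
    """
    n_sites = len(assignments)
    factor_totals = {"GFI1": 0, "LSD1": 0, "RCOR1": 0}
    cat_counts: dict[str, int] = {c: 0 for c in CATEGORIES}
    cat_factor: dict[str, dict[str, int]] = {
        c: {f: 0 for f in factor_totals} for c in CATEGORIES
    }
    for a in assignments:
        cat_counts[a.category] += 1
        for f in factor_totals:
            if f in a.partners:
                factor_totals[f] += 1
                cat_factor[a.category][f] += 1
    rows = []
    for cat in CATEGORIES:
        if cat_counts[cat] == 0 and n_sites > 0:
            continue
        row = {"category": cat, "count": cat_counts[cat]}
        row["pct_of_sites"] = (
            percent(cat_counts[cat], n_sites, decimals) if n_sites else 0.0
        )
        for f, tot in factor_totals.items():
            row[f"pct_of_{f}"] = (
                percent(cat_factor[cat][f], tot, decimals) if tot else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)


def assignments_to_bed(assignments: list[CategoryAssignment]) -> pd.DataFrame:
    """Site table in BED-like columns (anchor interval, category as name)."""
    rows = [
        {
            "chrom": a.anchor.chrom,
            "start": a.anchor.start,
            "end": a.anchor.end,
            "name": a.category,
            "score": a.anchor.pileup,
            "site_id": a.site_id,
            "apex": a.anchor.apex,
        }
        for a in assignments
    ]
    return pd.DataFrame(rows).sort_values(["chrom", "start"]).reset_index(drop=True)
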