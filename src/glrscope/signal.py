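"""Windowed RPKM signal, condition fold changes, meta-profiles, heatmaps.

Read counts are estimated from the depth integral: count = (sum of
per-base depth over the window) / read_length, and
rpkm = count * 1e9 / (window_bp * total_mapped_reads). Windows clipped at
chromosome ends use the clipped length in the denominator; a window lying
entirely off-chromosome scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CoverageTrack, GenomicInterval, PeakSet, ValidationError


def _clip_window(
    track: CoverageTrack, chrom: str, start: int, end: int
) -> tuple[int, int]:
    size = track.chrom_sizes.get(chrom)
    lo = max(0, start)
    hi = end if size is None else min(end, size)
    return lo, hi


def window_rpkm(track: CoverageTrack, window: GenomicInterval) -> float:
    """RPKM of one window (clipped at chromosome ends)."""
    lo, hi = _clip_window(track, window.chrom, window.start, window.end)
    if hi <= lo:
        return 0.0
    count = track.depth_sum(window.chrom, lo, hi) / track.read_length
    return count * 1e9 / ((hi - lo) * track.total_mapped_reads)


def category_signal(
    track: CoverageTrack, sites: list, flank: int
) -> pd.DataFrame:
    """One RPKM value per site over center +/- flank.

    `sites` are objects with .chrom, .center and a .region_id or .site_id.
    """
    rows = []
    for s in sites:
        sid = getattr(s, "region_id", None) or getattr(s, "site_id")
        lo, hi = _clip_window(track, s.chrom, s.center - flank, s.center + flank)
        if hi <= lo:
            rpkm = 0.0
        else:
            count = track.depth_sum(s.chrom, lo, hi) / track.read_length
            rpkm = count * 1e9 / ((hi - lo) * track.total_mapped_reads)
        rows.append(
            {"region_id": sid, "mark": track.mark, "condition": track.condition,
             "rpkm": rpkm}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FoldChangeSummary:
    """Per-site log2 fold changes plus the percent change of group means."""

    per_site: pd.DataFrame
    mean_ctrl: float
    mean_trt: float

    @property
    def percent_change(self) -> float:
        return 100.0 * (self.mean_trt / self.mean_ctrl - 1.0)


def fold_change_summary(
    track_ctrl: CoverageTrack,
    track_trt: CoverageTrack,
    sites: list,
    flank: int,
    pseudocount: float = 0.5,
) -> FoldChangeSummary:
    """Treated-vs-control signal change over site windows.

    Per-site log2fc uses a pseudocount; the summary percent change is the
    ratio of unshifted group means, 100*(mean_trt/mean_ctrl - 1).
    """
    ctrl = category_signal(track_ctrl, sites, flank)
    trt = category_signal(track_trt, sites, flank)
    df = pd.DataFrame(
        {
            "region_id": ctrl["region_id"],
            "rpkm_ctrl": ctrl["rpkm"],
            "rpkm_trt": trt["rpkm"].to_numpy(),
        }
    )
    df["log2fc"] = np.log2(
        (df["rpkm_trt"] + pseudocount) / (df["rpkm_ctrl"] + pseudocount)
    )
    mean_ctrl = float(df["rpkm_ctrl"].mean())
    mean_trt = float(df["rpkm_trt"].mean())
    if mean_ctrl == 0:
        raise ValidationError("percent change undefined: control mean is 0")
    return FoldChangeSummary(per_site=df, mean_ctrl=mean_ctrl, mean_trt=mean_trt)


def _binned_rpkm_matrix(
    track: CoverageTrack,
    anchors: list[tuple[str, int]],
    flank: int,
    bin_width: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-anchor per-offset-bin RPKM matrix and the bin start offsets.

    This single code path backs both meta-profiles and heatmap matrices so
    their consistency (column mean == profile) is exact by construction.
    """
    if flank <= 0 or bin_width <= 0 or (2 * flank) % bin_width != 0:
        raise ValueError("bin_width must evenly divide 2*flank")
    n_bins = 2 * flank // bin_width
    offsets = -flank + bin_width * np.arange(n_bins)
    mat = np.zeros((len(anchors), n_bins))
    scale = 1e9 / (track.read_length * track.total_mapped_reads)
    for i, (chrom, pos) in enumerate(anchors):
        starts = pos + offsets
        ends = starts + bin_width
        size = track.chrom_sizes.get(chrom)
        lo = np.maximum(starts, 0)
        hi = ends if size is None else np.minimum(ends, size)
        lengths = np.maximum(hi - lo, 0)
        sums = track.depth_sums(chrom, lo.astype(float), np.maximum(hi, lo).astype(float))
        with np.errstate(divide="ignore", invalid="ignore"):
            row = np.where(lengths > 0, sums * scale / np.maximum(lengths, 1), 0.0)
        mat[i] = row
    return mat, offsets


@dataclass(frozen=True)
class MetaProfile:
    """Mean RPKM per offset bin around a set of anchors."""

    anchor_description: str
    flank: int
    bin_width: int
    offsets: np.ndarray
    values: np.ndarray
    n_anchors: int


def meta_profile(
    track: CoverageTrack,
    anchors: list[tuple[str, int]],
    flank: int,
    bin_width: int,
    anchor_description: str = "",
) -> MetaProfile:
    """Mean signal profile over anchors; bins clipped at chromosome edges."""
    if not anchors:
        raise ValidationError("meta_profile needs at least one anchor")
    mat, offsets = _binned_rpkm_matrix(track, anchors, flank, bin_width)
    return MetaProfile(
        anchor_description=anchor_description,
        flank=flank,
        bin_width=bin_width,
        offsets=offsets,
        values=mat.mean(axis=0),
        n_anchors=len(anchors),
    )


@dataclass(frozen=True)
class HeatmapMatrix:
    """Sites x position-bins RPKM matrix, rows ranked by pileup descending."""

    row_ids: list[str]
    pileups: np.ndarray
    offsets: np.ndarray
    matrix: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=[int(o) for o in self.offsets])
        df.insert(0, "peak_id", self.row_ids)
        df.insert(1, "pileup", self.pileups)
        return df


def heatmap_matrix(
    track: CoverageTrack,
    peaks: PeakSet,
    flank: int = 1_000,
    bin_width: int = 25,
) -> HeatmapMatrix:
    """Signal heatmap around peak apexes, strongest peak first.

    Ties on pileup break by (chrom, start). Column means of the matrix
    equal the meta-profile over the same peaks.
    """
    ranked = sorted(peaks, key=lambda p: (-p.pileup, p.chrom, p.start))
    anchors = [(p.chrom, p.apex) for p in ranked]
    if not anchors:
        raise ValidationError("heatmap_matrix needs at least one peak")
    mat, offsets = _binned_rpkm_matrix(track, anchors, flank, bin_width)
    return HeatmapMatrix(
        row_ids=[p.peak_id for p in ranked],
        pileups=np.array([p.pileup for p in ranked]),
        offsets=offsets,
        matrix=mat,
    )
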