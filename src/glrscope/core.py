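"""Core genomic domain types and coordinate arithmetic.

All coordinates are 0-based half-open (BED convention). 1-based formats
(GTF, MACS2 peak tables) are converted at the I/O boundary, never inside
the analysis code. Strand is carried on intervals and genes but is ignored
by all distance and coincidence computations, which operate on unstranded
peak apexes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when an object violates a structural invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"strand must be one of {STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap in bp between two intervals: 0 if they overlap, inf across chromosomes."""
    if a.chrom != b.chrom:
        return math.inf
    return float(max(0, max(b.start - a.end, a.start - b.end)))


@dataclass(frozen=True)
class Peak:
    """A called binding interval with its summit (apex) and strength (pileup).

    The apex is the absolute 0-based position of maximal read depth; pileup
    is the MACS2-style strength value used to rank peaks.
    """

    interval: GenomicInterval
    apex: int
    pileup: float
    peak_id: str
    factor: str = ""

    def __post_init__(self) -> None:
        if not self.interval.contains(self.apex):
            raise ValidationError(
                f"peak {self.peak_id}: apex {self.apex} outside "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.pileup < 0:
            raise ValidationError(f"peak {self.peak_id}: negative pileup")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


class PeakSet:
    """Ordered collection of peaks from one factor/condition.

    Kept sorted by (chrom, start); peak ids must be unique. Per-chromosome
    apex arrays are cached for binary-search lookups.
    """

    def __init__(
        self,
        peaks: Iterable[Peak],
        factor: str = "",
        condition: str = "",
    ) -> None:
        self.peaks = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end, p.peak_id))
        self.factor = factor
        self.condition = condition
        ids = [p.peak_id for p in self.peaks]
        if len(set(ids)) != len(ids):
            dup = pd.Series(ids).value_counts()
            raise ValidationError(
                f"duplicate peak ids in PeakSet: {dup[dup > 1].index.tolist()[:5]}"
            )
        self._by_chrom: dict[str, list[Peak]] | None = None
        self._apex_index: dict[str, tuple[np.ndarray, list[Peak]]] | None = None

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakSet):
            return NotImplemented
        return self.peaks == other.peaks

    def by_chrom(self) -> dict[str, list[Peak]]:
        if self._by_chrom is None:
            out: dict[str, list[Peak]] = {}
            for p in self.peaks:
                out.setdefault(p.chrom, []).append(p)
            self._by_chrom = out
        return self._by_chrom

    def apex_index(self) -> dict[str, tuple[np.ndarray, list[Peak]]]:
        """Per-chromosome (sorted apex array, peaks in that order)."""
        if self._apex_index is None:
            out = {}
            for chrom, peaks in self.by_chrom().items():
                ordered = sorted(peaks, key=lambda p: (p.apex, p.start, p.peak_id))
                out[chrom] = (np.array([p.apex for p in ordered]), ordered)
            self._apex_index = out
        return self._apex_index

    def ids(self) -> set[str]:
        return {p.peak_id for p in self.peaks}


@dataclass(frozen=True)
class GeneModel:
    """A gene locus with TSS, strand and exon structure.

    TSS is locus.start for + strand and locus.end - 1 for - strand.
    Exons must lie within the locus and not overlap each other.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    locus: GenomicInterval
    exons: tuple[GenomicInterval, ...]
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand must be + or -")
        if len(self.exons) == 0:
            raise ValidationError(f"gene {self.gene_id}: zero exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        prev_end = self.locus.start - 1
        for e in exons:
            if e.start < self.locus.start or e.end > self.locus.end:
                raise ValidationError(f"gene {self.gene_id}: exon outside locus")
            if e.start < prev_end:
                raise ValidationError(f"gene {self.gene_id}: overlapping exons")
            prev_end = e.end
        expected = self.locus.start if self.strand == "+" else self.locus.end - 1
        if self.tss != expected:
            raise ValidationError(f"gene {self.gene_id}: inconsistent TSS")

    @property
    def tss(self) -> int:
        return self.locus.start if self.strand == "+" else self.locus.end - 1


class GeneIndex:
    """Gene collection with per-chromosome TSS arrays for nearest-TSS queries."""

    def __init__(self, genes: Iterable[GeneModel]) -> None:
        self.genes = list(genes)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate gene_id in gene collection")
        self.by_id = {g.gene_id: g for g in self.genes}
        self._tss: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in self.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        # sort by (tss, gene_id) so the first entry at a tied TSS has the
        # lexicographically smallest id
        for chrom, gs in by_chrom.items():
            gs = sorted(gs, key=lambda g: (g.tss, g.gene_id))
            self._tss[chrom] = (np.array([g.tss for g in gs]), gs)
        self.by_chrom = by_chrom

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes)

    def chroms(self) -> set[str]:
        return set(self._tss)

    def nearest_tss(self, chrom: str, pos: int) -> tuple[GeneModel, int]:
        """Gene with minimum |tss - pos|; ties broken by smaller gene_id.

        Returns (gene, signed distance tss - pos). Raises LookupError when
        the chromosome carries no gene.
        """
        if chrom not in self._tss:
            raise LookupError(f"no gene on chromosome {chrom}")
        tss_arr, genes = self._tss[chrom]
        i = int(np.searchsorted(tss_arr, pos))
        best: tuple[int, str, GeneModel] | None = None
        # candidate TSS values flanking the insertion point; at a tied
        # distance the leftmost entry with that TSS has the smallest id
        for j in (i - 1, i):
            if 0 <= j < len(genes):
                t = int(tss_arr[j])
                k = int(np.searchsorted(tss_arr, t))  # first gene at this TSS
                g = genes[k]
                cand = (abs(t - pos), g.gene_id, g)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        assert best is not None
        g = best[2]
        return g, g.tss - pos


class CoverageTrack:
    """Per-chromosome step function of read depth with a normalization basis.

    Stores, per chromosome, breakpoint and value arrays describing a
    piecewise-constant depth; queries outside the covered range return 0.
    `total_mapped_reads` and `read_length` convert depth integrals into
    estimated read counts for RPKM computation.
    """

    def __init__(
        self,
        chrom_data: dict[str, tuple[np.ndarray, np.ndarray]],
        total_mapped_reads: int,
        read_length: int,
        mark: str = "",
        condition: str = "",
        chrom_sizes: dict[str, int] | None = None,
    ) -> None:
        if total_mapped_reads <= 0:
            raise ValidationError("total_mapped_reads must be positive")
        if read_length <= 0:
            raise ValidationError("read_length must be positive")
        self.total_mapped_reads = int(total_mapped_reads)
        self.read_length = int(read_length)
        self.mark = mark
        self.condition = condition
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (bounds, values) in chrom_data.items():
            bounds = np.asarray(bounds, dtype=np.int64)
            values = np.asarray(values, dtype=np.float64)
            if len(bounds) != len(values) + 1:
                raise ValidationError(f"{chrom}: need len(bounds) == len(values)+1")
            if np.any(np.diff(bounds) <= 0):
                raise ValidationError(f"{chrom}: breakpoints not increasing")
            if np.any(values < 0):
                raise ValidationError(f"{chrom}: negative depth")
            # cumulative integral at each breakpoint for O(log n) window sums
            cum = np.concatenate([[0.0], np.cumsum(values * np.diff(bounds))])
            self._data[chrom] = (bounds, values, cum)
        if chrom_sizes is None:
            chrom_sizes = {c: int(b[-1]) for c, (b, _, _) in self._data.items()}
        self.chrom_sizes = chrom_sizes

    @classmethod
    def from_intervals(
        cls,
        intervals: Sequence[tuple[str, int, int, float]],
        total_mapped_reads: int,
        read_length: int,
        **kwargs,
    ) -> "CoverageTrack":
        """Build from (chrom, start, end, value) records; overlap is an error."""
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in intervals:
            if value < 0:
                raise ValidationError(f"negative coverage value at {chrom}:{start}")
            if end <= start:
                raise ValidationError(f"empty coverage interval at {chrom}:{start}")
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        chrom_data = {}
        for chrom, ivs in per_chrom.items():
            ivs.sort()
            bounds = [ivs[0][0]]
            values: list[float] = []
            for start, end, value in ivs:
                if start < bounds[-1]:
                    raise ValidationError(
                        f"overlapping coverage intervals at {chrom}:{start}"
                    )
                if start > bounds[-1]:
                    values.append(0.0)
                    bounds.append(start)
                values.append(value)
                bounds.append(end)
            chrom_data[chrom] = (np.array(bounds), np.array(values))
        return cls(chrom_data, total_mapped_reads, read_length, **kwargs)

    def chroms(self) -> set[str]:
        return set(self._data)

    def _cum_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Cumulative depth integral from -inf to each position."""
        bounds, values, cum = self._data[chrom]
        pos = np.clip(pos, bounds[0], bounds[-1])
        idx = np.searchsorted(bounds, pos, side="right") - 1
        idx = np.clip(idx, 0, len(values) - 1)
        return cum[idx] + values[idx] * (pos - bounds[idx])

    def depth_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base depth over [start, end); 0 beyond coverage."""
        if end <= start:
            return 0.0
        if chrom not in self._data:
            return 0.0
        lo, hi = self._cum_at(chrom, np.array([start, end], dtype=np.float64))
        return float(hi - lo)

    def depth_sums(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Vectorized depth_sum over parallel start/end arrays."""
        starts = np.asarray(starts, dtype=np.float64)
        ends = np.asarray(ends, dtype=np.float64)
        if chrom not in self._data:
            return np.zeros(len(starts))
        out = self._cum_at(chrom, ends) - self._cum_at(chrom, starts)
        return np.where(ends > starts, out, 0.0)

    def mean_depth(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            return 0.0
        return self.depth_sum(chrom, start, end) / (end - start)

    def to_intervals(self) -> list[tuple[str, int, int, float]]:
        """Non-zero runs as (chrom, start, end, value), bedGraph-ready."""
        out = []
        for chrom in sorted(self._data):
            bounds, values, _ = self._data[chrom]
            for i, v in enumerate(values):
                if v != 0.0:
                    out.append((chrom, int(bounds[i]), int(bounds[i + 1]), float(v)))
        return out


@dataclass
class ExpressionTable:
    """Per-gene expression in two conditions with log2 fold change.

    Columns: gene_id, expr_ctrl, expr_trt, log2fc, expressed. log2fc must be
    finite for every expressed gene; gene ids are unique.
    """

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("gene_id", "expr_ctrl", "expr_trt", "log2fc")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"expression table missing columns {missing}")
        if "expressed" not in self.df.columns:
            self.df = self.df.assign(expressed=True)
        if self.df["gene_id"].duplicated().any():
            raise ValidationError("duplicate gene_id in expression table")
        expressed = self.df[self.df["expressed"]]
        if not np.isfinite(expressed["log2fc"].to_numpy()).all():
            raise ValidationError("non-finite log2fc for an expressed gene")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def expressed(self) -> pd.DataFrame:
        return self.df[self.df["expressed"]]

    def log2fc_of(self, gene_ids: Iterable[str]) -> pd.Series:
        sub = self.df.set_index("gene_id")["log2fc"]
        return sub.reindex([g for g in gene_ids if g in sub.index])
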