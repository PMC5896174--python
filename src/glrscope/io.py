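"""Readers and writers for the standard formats the pipeline consumes.

narrowPeak and MACS2 peak tables become :class:`~glrscope.core.PeakSet`;
bedGraph becomes :class:`~glrscope.core.CoverageTrack`; GTF/BED12 become
:class:`~glrscope.core.GeneModel` collections. 1-based inputs (GTF, MACS2
tables) are converted to 0-based half-open on read and back on write.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    CoverageTrack,
    ExpressionTable,
    GeneIndex,
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    ValidationError,
)


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------- peaks

NARROWPEAK_COLS = (
    "chrom start end name score strand signalValue pValue qValue summit".split()
)


def read_peaks(
    path: str | Path,
    format: str = "narrowPeak",
    factor: str = "",
    condition: str = "",
    min_pileup: float | None = None,
) -> PeakSet:
    """Read a peak file into a sorted PeakSet.

    narrowPeak: 10 whitespace-separated columns; apex = start + summit
    offset (column 10), falling back to the interval midpoint when the
    offset is -1; pileup taken from signalValue (column 7).

    macs2_xls: MACS2's tab-separated peak table with a header line;
    1-based inclusive coordinates and an ``abs_summit`` column, both
    converted to the 0-based convention; pileup from the ``pileup`` column.

    ``min_pileup`` optionally drops peaks below a strength floor (no
    filter by default: the upstream caller's threshold is taken as given).
    """
    path = Path(path)
    if format == "narrowPeak":
        peaks = _read_narrowpeak(path, factor)
    elif format == "macs2_xls":
        peaks = _read_macs2_xls(path, factor)
    else:
        raise ValueError(f"unknown peak format {format!r}")
    if min_pileup is not None:
        peaks = [p for p in peaks if p.pileup >= min_pileup]
    return PeakSet(peaks, factor=factor, condition=condition)


def _read_narrowpeak(path: Path, factor: str) -> list[Peak]:
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) != 10:
                raise ParseError(
                    f"{path}:{lineno}: expected 10 narrowPeak columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                name = fields[3]
                signal = float(fields[6])
                summit = int(fields[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            interval = GenomicInterval(chrom, start, end)
            apex = interval.midpoint if summit == -1 else start + summit
            try:
                peaks.append(
                    Peak(interval, apex=apex, pileup=signal, peak_id=name, factor=factor)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def _read_macs2_xls(path: Path, factor: str) -> list[Peak]:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return []
    required = {"chr", "start", "end", "abs_summit", "pileup", "name"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing MACS2 columns {sorted(missing)}")
    peaks = []
    for row in df.itertuples(index=False):
        interval = GenomicInterval(str(row.chr), int(row.start) - 1, int(row.end))
        peaks.append(
            Peak(
                interval,
                apex=int(row.abs_summit) - 1,
                pileup=float(row.pileup),
                peak_id=str(row.name),
                factor=factor,
            )
        )
    return peaks


def write_peaks(peaks: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as narrowPeak (summit stored as offset from start)."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t0\t.\t"
                f"{p.pileup!r}\t-1\t-1\t{p.apex - p.start}\n"
            )


# ---------------------------------------------------------------- coverage


def read_coverage(
    path: str | Path,
    total_mapped_reads: int,
    read_length: int,
    mark: str = "",
    condition: str = "",
    chrom_sizes: dict[str, int] | None = None,
) -> CoverageTrack:
    """Read a bedGraph (0-based half-open) into a CoverageTrack.

    Overlapping intervals and negative values are validation errors; gaps
    between intervals read back as depth 0.
    """
    records: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(
                    f"{path}:{lineno}: expected 4 bedGraph columns, got {len(fields)}"
                )
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return CoverageTrack.from_intervals(
        records,
        total_mapped_reads=total_mapped_reads,
        read_length=read_length,
        mark=mark,
        condition=condition,
        chrom_sizes=chrom_sizes,
    )


def write_coverage(track: CoverageTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.to_intervals():
            fh.write(f"{chrom}\t{start}\t{end}\t{value!r}\n")


# ---------------------------------------------------------------- genes


def read_genes(path: str | Path, format: str = "gtf") -> GeneIndex:
    """Read gene models from GTF (1-based, via gffutils) or BED12."""
    if format == "gtf":
        return _read_gtf(Path(path))
    if format == "bed12":
        return _read_bed12(Path(path))
    raise ValueError(f"unknown gene format {format!r}")


def _read_gtf(path: Path) -> GeneIndex:
    import gffutils

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        db = gffutils.create_db(
            os.fspath(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    genes = []
    for g in db.features_of_type("gene"):
        exons = tuple(
            GenomicInterval(e.seqid, e.start - 1, e.end, e.strand)
            for e in db.children(g, featuretype="exon")
        )
        if not exons:
            raise ValidationError(f"{path}: gene {g.id} has zero exons")
        biotype = (g.attributes.get("gene_biotype") or ["protein_coding"])[0]
        name = (g.attributes.get("gene_name") or [g.id])[0]
        genes.append(
            GeneModel(
                gene_id=g.id,
                gene_name=name,
                chrom=g.seqid,
                strand=g.strand,
                locus=GenomicInterval(g.seqid, g.start - 1, g.end, g.strand),
                exons=exons,
                biotype=biotype,
            )
        )
    return GeneIndex(genes)


def _read_bed12(path: Path) -> GeneIndex:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 BED12 columns")
            chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offsets, sizes)
            )
            genes.append(
                GeneModel(
                    gene_id=name,
                    gene_name=name,
                    chrom=chrom,
                    strand=strand,
                    locus=GenomicInterval(chrom, start, end, strand),
                    exons=exons,
                )
            )
    return GeneIndex(genes)


def write_genes_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene + exon GTF lines (1-based inclusive)."""
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.locus.start)):
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.gene_name}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\tglrscope\tgene\t{g.locus.start + 1}\t{g.locus.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{g.chrom}\tglrscope\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f'{g.strand}\t.\tgene_id "{g.gene_id}";\n'
                )


# ---------------------------------------------------------------- tables


def read_expression(
    path: str | Path, min_mean_expr: float | None = None
) -> ExpressionTable:
    """Read a TSV of (gene_id, expr_ctrl, expr_trt, log2fc[, expressed]).

    When the ``expressed`` column is absent every gene is flagged expressed
    unless ``min_mean_expr`` imposes a mean-expression floor.
    """
    df = pd.read_csv(path, sep="\t")
    if "expressed" in df.columns:
        df["expressed"] = df["expressed"].astype(bool)
    elif min_mean_expr is not None:
        mean = (df["expr_ctrl"] + df["expr_trt"]) / 2
        df["expressed"] = mean >= min_mean_expr
    return ExpressionTable(df)


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (set_name, gene_id) -> {set_name: genes}."""
    df = pd.read_csv(path, sep="\t", header=None, names=["set_name", "gene_id"])
    return {
        name: set(sub["gene_id"].astype(str))
        for name, sub in df.groupby("set_name", sort=True)
    }


def write_gene_sets(sets: dict[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(sets):
            for gene in sorted(sets[name]):
                fh.write(f"{name}\t{gene}\n")
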