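"""Synthetic multi-factor ChIP-seq data with planted ground truth.

The generator emits everything the pipeline consumes: a gene annotation,
GFI1/LSD1/RCOR1 peak sets with strength-coupled co-binding, H3K9Ac/H3K4Me2
mark peaks, two-condition coverage tracks with a multiplicative treated
effect planted only at triple-occupied (GLR) sites, and an expression table
in which genes nearest strong GLR sites are upregulated.

Planted structure (all configurable): each GFI1 peak receives an LSD1
(RCOR1) partner with probability increasing in its pileup rank, so overall
coincidence matches ``coincidence_*`` while the strongest peaks are almost
always co-bound; partner apexes are jittered by a truncated normal whose
truncation (+/-400 bp) keeps every planted partner recoverable by the
+/-500 bp coincidence rule. Coverage is Poisson background plus a
triangular (tent) kernel of height equal to the peak pileup at each apex,
giving closed-form window integrals for oracle tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

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
from . import io as gio


@dataclass
class SimulationConfig:
    """All knobs of the generator; a fixed seed fixes every output."""

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 10_000_000
    n_genes: int = 800
    gene_length_range: tuple[int, int] = (4_000, 12_000)
    gene_gap: int = 3_000
    n_gfi1_peaks: int = 2_000
    coincidence_lsd1: float = 0.713
    coincidence_rcor1: float = 0.334
    strength_coupling_lsd1: float = 0.951
    strength_coupling_rcor1: float = 0.826
    apex_jitter_sd: float = 100.0
    jitter_truncation: int = 400
    n_extra_lsd1: int = 5_000
    n_extra_rcor1: int = 1_350
    n_lr_pairs: int = 150
    n_extra_enhancers: int = 600
    n_genic_marks: int = 150
    enhancer_fc_acetyl: float = 1.5
    enhancer_fc_k4me2: float = 1.09
    de_effect: float = 0.8
    de_effect_weak: float = 0.3
    de_noise_sd: float = 0.2
    pileup_threshold: float = 35.0
    pileup_log_mean: float = math.log(18.0)
    pileup_log_sd: float = 0.7
    mark_pileup_log_mean: float = math.log(15.0)
    mark_pileup_log_sd: float = 0.5
    peak_halfwidth: int = 200
    kernel_halfwidth: int = 300
    background_depth: float = 0.05
    background_bin: int = 200
    read_length: int = 50
    min_apex_separation: int = 1_100
    enhancer_gene_margin: int = 6_000

    def validate(self) -> None:
        for name in ("coincidence_lsd1", "coincidence_rcor1",
                     "strength_coupling_lsd1", "strength_coupling_rcor1"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        for name in ("enhancer_fc_acetyl", "enhancer_fc_k4me2"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.n_chroms < 1 or self.chrom_length < 10_000:
            raise ValidationError("genome too small")
        if self.jitter_truncation >= 500:
            raise ValidationError(
                "jitter_truncation must stay below the 500 bp coincidence window"
            )
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValidationError("bad gene_length_range")
        # feasibility of non-overlapping gene placement
        per_chrom = math.ceil(self.n_genes / self.n_chroms)
        need = per_chrom * (hi + self.gene_gap)
        if need > self.chrom_length:
            raise ValidationError(
                f"cannot fit {per_chrom} genes of up to {hi} bp plus gaps "
                f"into {self.chrom_length} bp chromosomes"
            )


@dataclass
class SimSite:
    """One mark-bearing candidate enhancer site of the simulation."""

    site_id: str
    chrom: str
    apex: int
    is_glr: bool
    gfi1_pileup: float | None
    k9_pileup: float
    acetyl_multiplier: float
    k4me2_multiplier: float
    k9_peak_id: str = ""
    k4me2_peak_id: str = ""


@dataclass
class GroundTruthManifest:
    """Planted assignments against which pipeline estimates are checked."""

    config: dict
    gfi1_partners: dict[str, dict[str, str | None]]
    true_category: dict[str, str]
    enhancer_sites: list[SimSite]
    target_genes_strong: list[str]
    target_genes_weak: list[str]
    chrom_sizes: dict[str, int]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": self.config,
            "gfi1_partners": self.gfi1_partners,
            "true_category": self.true_category,
            "enhancer_sites": [asdict(s) for s in self.enhancer_sites],
            "target_genes_strong": self.target_genes_strong,
            "target_genes_weak": self.target_genes_weak,
            "chrom_sizes": self.chrom_sizes,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthManifest":
        d = json.loads(Path(path).read_text())
        d["enhancer_sites"] = [SimSite(**s) for s in d["enhancer_sites"]]
        return cls(**d)


@dataclass
class SimulationResult:
    config: SimulationConfig
    genes: GeneIndex
    chrom_sizes: dict[str, int]
    peak_sets: dict[str, PeakSet]
    tracks: dict[tuple[str, str], CoverageTrack]
    expression: ExpressionTable
    manifest: GroundTruthManifest

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        gio.write_genes_gtf(self.genes, outdir / "genes.gtf")
        paths["genes"] = outdir / "genes.gtf"
        for factor, ps in self.peak_sets.items():
            p = outdir / f"{factor}.narrowPeak"
            gio.write_peaks(ps, p)
            paths[factor] = p
        for (mark, cond), track in self.tracks.items():
            p = outdir / f"{mark}_{cond}.bedGraph"
            gio.write_coverage(track, p)
            paths[f"{mark}_{cond}"] = p
        gio.write_expression(self.expression, outdir / "expression.tsv")
        paths["expression"] = outdir / "expression.tsv"
        self.manifest.to_json(outdir / "manifest.json")
        paths["manifest"] = outdir / "manifest.json"
        sizes = pd.DataFrame(
            sorted(self.chrom_sizes.items()), columns=["chrom", "size"]
        )
        sizes.to_csv(outdir / "chrom.sizes", sep="\t", header=False, index=False)
        paths["chrom_sizes"] = outdir / "chrom.sizes"
        return paths


# ---------------------------------------------------------------- genome


def generate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[GeneIndex, dict[str, int]]:
    """Place non-overlapping genes on both strands, deterministically."""
    config.validate()
    chrom_sizes = {
        f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)
    }
    genes: list[GeneModel] = []
    counts = [
        config.n_genes // config.n_chroms
        + (1 if i < config.n_genes % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    gid = 0
    lo, hi = config.gene_length_range
    for ci, chrom in enumerate(sorted(chrom_sizes)):
        n = counts[ci]
        if n == 0:
            continue
        lengths = rng.integers(lo, hi + 1, size=n)
        used = int(lengths.sum()) + n * config.gene_gap
        slack = config.chrom_length - used - 2 * config.gene_gap
        if slack < 0:
            raise ValidationError("genes cannot fit on chromosome")
        # distribute the slack as random inter-gene spacing
        cuts = np.sort(rng.uniform(0, slack, size=n)).astype(int)
        pos = config.gene_gap
        prev_cut = 0
        for i in range(n):
            pos += int(cuts[i] - prev_cut)
            prev_cut = int(cuts[i])
            start = pos
            end = start + int(lengths[i])
            strand = "+" if rng.random() < 0.5 else "-"
            exons = _make_exons(chrom, start, end, strand, rng)
            biotype = "protein_coding" if rng.random() < 0.9 else "lincRNA"
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"g{gid:04d}",
                    gene_name=f"GENE{gid:04d}",
                    chrom=chrom,
                    strand=strand,
                    locus=GenomicInterval(chrom, start, end, strand),
                    exons=exons,
                    biotype=biotype,
                )
            )
            pos = end + config.gene_gap
    return GeneIndex(genes), chrom_sizes


def _make_exons(
    chrom: str, start: int, end: int, strand: str, rng: np.random.Generator
) -> tuple[GenomicInterval, ...]:
    length = end - start
    n_exons = int(rng.integers(2, 6))
    # pick 2*n_exons ordered internal breakpoints; odd segments are exons
    inner = np.sort(rng.choice(np.arange(1, length), size=2 * n_exons - 2,
                               replace=False))
    bounds = np.concatenate([[0], inner, [length]])
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        exons.append(
            GenomicInterval(chrom, start + int(bounds[i]),
                            start + int(bounds[i + 1]), strand)
        )
    return tuple(exons)


# ---------------------------------------------------------------- peaks


def _truncated_normal_jitter(
    rng: np.random.Generator, n: int, sd: float, bound: int
) -> np.ndarray:
    """Normal(0, sd) truncated to [-bound, bound], by rejection."""
    if sd == 0:
        return np.zeros(n, dtype=int)
    out = rng.normal(0, sd, size=n)
    bad = np.abs(out) > bound
    while bad.any():
        out[bad] = rng.normal(0, sd, size=int(bad.sum()))
        bad = np.abs(out) > bound
    return np.rint(out).astype(int)


def _partner_probability(
    rank_quantile: np.ndarray, overall: float, coupling: float
) -> np.ndarray:
    """Monotone-in-strength partner probability with exact mean `overall`.

    A mixture of an i.i.d. Bernoulli(overall) component and a deterministic
    top-fraction component: p(q) = (1-s)*c + s*1[q > 1-c]. The expected
    overall coincidence is c for any coupling s, while the strongest peaks
    approach probability s + (1-s)*c.
    """
    return (1 - coupling) * overall + coupling * (rank_quantile > 1 - overall)


def _spaced_positions(
    rng: np.random.Generator, n: int, length: int, margin: int, min_sep: int
) -> np.ndarray:
    """n positions in [margin, length-margin) with pairwise gaps >= min_sep."""
    span = length - 2 * margin
    if n * min_sep >= span:
        raise ValidationError("cannot place peaks with the requested separation")
    slack = span - n * min_sep
    cuts = np.sort(rng.uniform(0, slack, size=n))
    return (margin + cuts + min_sep * np.arange(n)).astype(int)


def generate_peak_sets(
    config: SimulationConfig,
    genes: GeneIndex,
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
) -> tuple[dict[str, PeakSet], GroundTruthManifest]:
    """GFI1/LSD1/RCOR1 peak sets with coupled co-binding plus mark peaks."""
    hw = config.peak_halfwidth
    chroms = sorted(chrom_sizes)

    # -- GFI1 anchors, well separated so partner claiming is unambiguous
    counts = [
        config.n_gfi1_peaks // len(chroms)
        + (1 if i < config.n_gfi1_peaks % len(chroms) else 0)
        for i in range(len(chroms))
    ]
    gfi1_peaks: list[Peak] = []
    apexes_by_chrom: dict[str, list[int]] = {c: [] for c in chroms}
    pid = 0
    for ci, chrom in enumerate(chroms):
        pos = _spaced_positions(
            rng, counts[ci], chrom_sizes[chrom], margin=5_000,
            min_sep=4 * config.min_apex_separation,
        )
        for apex in pos:
            pid += 1
            pileup = float(
                np.exp(rng.normal(config.pileup_log_mean, config.pileup_log_sd))
            )
            gfi1_peaks.append(_peak(chrom, int(apex), hw, pileup,
                                    f"GFI1_{pid:05d}", "GFI1", chrom_sizes))
            apexes_by_chrom[chrom].append(int(apex))

    # -- strength-coupled partner assignment
    pileups = np.array([p.pileup for p in gfi1_peaks])
    order = np.argsort(np.argsort(pileups, kind="stable"), kind="stable")
    rank_q = (order + 1) / len(pileups)  # 1.0 = strongest
    p_l = _partner_probability(rank_q, config.coincidence_lsd1,
                               config.strength_coupling_lsd1)
    p_r = _partner_probability(rank_q, config.coincidence_rcor1,
                               config.strength_coupling_rcor1)
    has_l = rng.random(len(gfi1_peaks)) < p_l
    has_r = rng.random(len(gfi1_peaks)) < p_r
    jit_l = _truncated_normal_jitter(rng, len(gfi1_peaks),
                                     config.apex_jitter_sd,
                                     config.jitter_truncation)
    jit_r = _truncated_normal_jitter(rng, len(gfi1_peaks),
                                     config.apex_jitter_sd,
                                     config.jitter_truncation)

    lsd1_peaks: list[Peak] = []
    rcor1_peaks: list[Peak] = []
    partners: dict[str, dict[str, str | None]] = {}
    true_category: dict[str, str] = {}
    for i, g in enumerate(gfi1_peaks):
        entry: dict[str, str | None] = {"LSD1": None, "RCOR1": None}
        if has_l[i]:
            pid_l = f"LSD1_p{i + 1:05d}"
            apex = int(np.clip(g.apex + jit_l[i], hw, chrom_sizes[g.chrom] - hw - 1))
            pu = g.pileup * float(np.exp(rng.normal(0, 0.3)))
            lsd1_peaks.append(_peak(g.chrom, apex, hw, pu, pid_l, "LSD1",
                                    chrom_sizes))
            apexes_by_chrom[g.chrom].append(apex)
            entry["LSD1"] = pid_l
        if has_r[i]:
            pid_r = f"RCOR1_p{i + 1:05d}"
            apex = int(np.clip(g.apex + jit_r[i], hw, chrom_sizes[g.chrom] - hw - 1))
            pu = g.pileup * float(np.exp(rng.normal(0, 0.3)))
            rcor1_peaks.append(_peak(g.chrom, apex, hw, pu, pid_r, "RCOR1",
                                     chrom_sizes))
            apexes_by_chrom[g.chrom].append(apex)
            entry["RCOR1"] = pid_r
        partners[g.peak_id] = entry
        true_category[g.peak_id] = {
            (True, True): "GLR", (True, False): "GL",
            (False, True): "GR", (False, False): "G",
        }[(bool(has_l[i]), bool(has_r[i]))]

    # -- factor-only peaks, kept > min_apex_separation from everything
    def place_extras(n: int, prefix: str, factor: str, out: list[Peak]) -> list[int]:
        placed = []
        per_chrom = [
            n // len(chroms) + (1 if i < n % len(chroms) else 0)
            for i in range(len(chroms))
        ]
        for ci, chrom in enumerate(chroms):
            occupied = np.sort(np.array(apexes_by_chrom[chrom]))
            need = per_chrom[ci]
            accepted: list[int] = []
            attempts = 0
            while len(accepted) < need:
                attempts += 1
                if attempts > 200 * need + 1_000:
                    raise ValidationError("cannot place factor-only peaks")
                cand = int(rng.integers(5_000, chrom_sizes[chrom] - 5_000))
                j = int(np.searchsorted(occupied, cand))
                near = [
                    occupied[k] for k in (j - 1, j) if 0 <= k < len(occupied)
                ]
                if any(abs(cand - x) < config.min_apex_separation for x in near):
                    continue
                occupied = np.insert(occupied, j, cand)
                accepted.append(cand)
            for apex in accepted:
                pu = float(
                    np.exp(rng.normal(config.pileup_log_mean - 0.3,
                                      config.pileup_log_sd))
                )
                out.append(_peak(chrom, apex, hw, pu,
                                 f"{prefix}_{len(out):05d}", factor, chrom_sizes))
                placed.append(apex)
            apexes_by_chrom[chrom] = list(occupied)
        return placed

    place_extras(config.n_extra_lsd1, "LSD1_x", "LSD1", lsd1_peaks)
    place_extras(config.n_extra_rcor1, "RCOR1_x", "RCOR1", rcor1_peaks)

    # -- planted LR pairs (LSD1+RCOR1 without GFI1)
    lr_anchors = place_extras(config.n_lr_pairs, "LSD1_lr", "LSD1", lsd1_peaks)
    lr_jit = _truncated_normal_jitter(rng, len(lr_anchors),
                                      config.apex_jitter_sd,
                                      config.jitter_truncation)
    for i, apex in enumerate(lr_anchors):
        chrom = lsd1_peaks[-len(lr_anchors) + i].chrom
        pu = float(np.exp(rng.normal(config.pileup_log_mean - 0.3,
                                     config.pileup_log_sd)))
        a = int(np.clip(apex + lr_jit[i], hw, chrom_sizes[chrom] - hw - 1))
        rcor1_peaks.append(_peak(chrom, a, hw, pu,
                                 f"RCOR1_lr{i:04d}", "RCOR1", chrom_sizes))

    # -- histone-mark peaks: at every GLR site far enough from genes, at
    #    extra gene-distal positions, and (as decoys) inside gene loci
    sites: list[SimSite] = []
    k9_peaks: list[Peak] = []
    k4_peaks: list[Peak] = []
    k9_hw, k4_hw = 300, 350
    from .enhancers import _gene_distance

    def add_mark_site(chrom: str, apex: int, is_glr: bool,
                      gfi1_pileup: float | None, site_id: str) -> None:
        k9_pu = float(np.exp(rng.normal(config.mark_pileup_log_mean,
                                        config.mark_pileup_log_sd)))
        k4_pu = float(np.exp(rng.normal(config.mark_pileup_log_mean,
                                        config.mark_pileup_log_sd)))
        k9_id = f"H3K9Ac_{len(k9_peaks):05d}"
        k4_id = f"H3K4Me2_{len(k4_peaks):05d}"
        k9_peaks.append(_peak(chrom, apex, k9_hw, k9_pu, k9_id, "H3K9Ac",
                              chrom_sizes))
        k4_apex = int(np.clip(apex + int(rng.integers(-100, 101)),
                              k4_hw, chrom_sizes[chrom] - k4_hw - 1))
        k4_peaks.append(_peak(chrom, k4_apex, k4_hw, k4_pu, k4_id, "H3K4Me2",
                              chrom_sizes))
        sites.append(
            SimSite(
                site_id=site_id,
                chrom=chrom,
                apex=apex,
                is_glr=is_glr,
                gfi1_pileup=gfi1_pileup,
                k9_pileup=k9_pu,
                acetyl_multiplier=config.enhancer_fc_acetyl if is_glr else 1.0,
                k4me2_multiplier=config.enhancer_fc_k4me2 if is_glr else 1.0,
                k9_peak_id=k9_id,
                k4me2_peak_id=k4_id,
            )
        )

    for g in gfi1_peaks:
        if true_category[g.peak_id] != "GLR":
            continue
        dist, _ = _gene_distance(genes, g.chrom, g.apex - k4_hw, g.apex + k4_hw)
        if dist < config.enhancer_gene_margin:
            continue
        add_mark_site(g.chrom, g.apex, True, g.pileup, g.peak_id)

    # gene-distal non-GLR enhancer sites
    n_placed = 0
    attempts = 0
    while n_placed < config.n_extra_enhancers:
        attempts += 1
        if attempts > 200 * config.n_extra_enhancers + 1_000:
            raise ValidationError("cannot place extra enhancer sites")
        chrom = chroms[int(rng.integers(len(chroms)))]
        cand = int(rng.integers(5_000, chrom_sizes[chrom] - 5_000))
        occupied = np.sort(np.array(apexes_by_chrom[chrom]))
        j = int(np.searchsorted(occupied, cand))
        near = [occupied[k] for k in (j - 1, j) if 0 <= k < len(occupied)]
        if any(abs(cand - x) < 2_500 for x in near):
            continue
        dist, _ = _gene_distance(genes, chrom, cand - k4_hw, cand + k4_hw)
        if dist < config.enhancer_gene_margin:
            continue
        apexes_by_chrom[chrom] = list(np.insert(occupied, j, cand))
        add_mark_site(chrom, cand, False, None, f"ENH_{n_placed:04d}")
        n_placed += 1

    # genic decoy mark peaks: coincident marks that the >=5 kb rule rejects
    genic = [g for g in genes if len(g.locus) > 2 * k4_hw + 10]
    for i in range(min(config.n_genic_marks, len(genic))):
        g = genic[int(rng.integers(len(genic)))]
        apex = int(rng.integers(g.locus.start + k4_hw, g.locus.end - k4_hw))
        k9_peaks.append(_peak(g.chrom, apex, k9_hw,
                              float(np.exp(rng.normal(
                                  config.mark_pileup_log_mean,
                                  config.mark_pileup_log_sd))),
                              f"H3K9Ac_g{i:04d}", "H3K9Ac", chrom_sizes))
        k4_peaks.append(_peak(g.chrom, apex, k4_hw,
                              float(np.exp(rng.normal(
                                  config.mark_pileup_log_mean,
                                  config.mark_pileup_log_sd))),
                              f"H3K4Me2_g{i:04d}", "H3K4Me2", chrom_sizes))

    peak_sets = {
        "GFI1": PeakSet(gfi1_peaks, factor="GFI1", condition="vehicle"),
        "LSD1": PeakSet(lsd1_peaks, factor="LSD1", condition="vehicle"),
        "RCOR1": PeakSet(rcor1_peaks, factor="RCOR1", condition="vehicle"),
        "H3K9Ac": PeakSet(k9_peaks, factor="H3K9Ac", condition="vehicle"),
        "H3K4Me2": PeakSet(k4_peaks, factor="H3K4Me2", condition="vehicle"),
    }
    manifest = GroundTruthManifest(
        config=asdict(config) | {"gene_length_range": list(config.gene_length_range)},
        gfi1_partners=partners,
        true_category=true_category,
        enhancer_sites=sites,
        target_genes_strong=[],
        target_genes_weak=[],
        chrom_sizes=dict(chrom_sizes),
    )
    return peak_sets, manifest


def _peak(
    chrom: str, apex: int, halfwidth: int, pileup: float, peak_id: str,
    factor: str, chrom_sizes: dict[str, int],
) -> Peak:
    start = max(0, apex - halfwidth)
    end = min(chrom_sizes[chrom], apex + halfwidth)
    return Peak(GenomicInterval(chrom, start, end), apex=apex, pileup=pileup,
                peak_id=peak_id, factor=factor)


# ---------------------------------------------------------------- coverage


def generate_coverage(
    config: SimulationConfig,
    peak_sets: dict[str, PeakSet],
    manifest: GroundTruthManifest,
    chrom_sizes: dict[str, int],
    rng: np.random.Generator,
    marks: tuple[str, ...] = ("H3K9Ac", "H3K4Me2"),
    conditions: tuple[str, ...] = ("vehicle", "og86"),
    factor_tracks: tuple[str, ...] = ("GFI1",),
) -> dict[tuple[str, str], CoverageTrack]:
    """Tent-kernel coverage per mark and condition.

    depth = Poisson background (piecewise constant per ``background_bin``)
    plus, at every mark peak apex, a triangular kernel of height equal to
    the peak pileup. In the treated condition kernels at GLR sites are
    scaled by the planted multiplier; everything else is untouched. Both
    conditions share the control library size as their RPKM basis.
    """
    mult_by_peak: dict[str, float] = {}
    for s in manifest.enhancer_sites:
        mult_by_peak[s.k9_peak_id] = s.acetyl_multiplier
        mult_by_peak[s.k4me2_peak_id] = s.k4me2_multiplier
    tracks: dict[tuple[str, str], CoverageTrack] = {}
    for mark in marks + tuple(factor_tracks):
        conds = conditions if mark in marks else ("vehicle",)
        control_total: int | None = None
        for cond in conds:
            chrom_data = {}
            for chrom in sorted(chrom_sizes):
                arr = _chrom_coverage(
                    config, peak_sets[mark], cond, chrom,
                    chrom_sizes[chrom], mult_by_peak, rng,
                )
                chrom_data[chrom] = _run_length_encode(arr)
            integral = sum(
                float(np.sum(v * np.diff(b))) for b, v in chrom_data.values()
            )
            total = max(1, round(integral / config.read_length))
            if control_total is None:
                control_total = total
            tracks[(mark, cond)] = CoverageTrack(
                chrom_data,
                total_mapped_reads=control_total,
                read_length=config.read_length,
                mark=mark,
                condition=cond,
                chrom_sizes=dict(chrom_sizes),
            )
    return tracks


def _chrom_coverage(
    config: SimulationConfig,
    peaks: PeakSet,
    cond: str,
    chrom: str,
    length: int,
    mult_by_peak: dict[str, float],
    rng: np.random.Generator,
) -> np.ndarray:
    n_bins = math.ceil(length / config.background_bin)
    if config.background_depth > 0:
        bg = rng.poisson(
            config.background_depth * config.background_bin, size=n_bins
        ) / config.background_bin
    else:
        bg = np.zeros(n_bins)
    arr = np.repeat(bg, config.background_bin)[:length].astype(np.float64)
    khw = config.kernel_halfwidth
    kernel = 1.0 - np.abs(np.arange(-khw, khw + 1)) / khw
    for p in peaks.by_chrom().get(chrom, []):
        height = p.pileup
        if cond != "vehicle":
            height *= mult_by_peak.get(p.peak_id, 1.0)
        lo = max(0, p.apex - khw)
        hi = min(length, p.apex + khw + 1)
        arr[lo:hi] += height * kernel[lo - (p.apex - khw): hi - (p.apex - khw)]
    return arr


def _run_length_encode(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    change = np.flatnonzero(np.diff(arr)) + 1
    bounds = np.concatenate([[0], change, [len(arr)]])
    values = arr[bounds[:-1]]
    return bounds, values


def tent_kernel_integral(
    apex: int, height: float, halfwidth: int, start: int, end: int
) -> float:
    """Exact sum of the discrete tent kernel over bases in [start, end).

    The kernel places height*(1 - |x - apex|/halfwidth) at each integer x
    with |x - apex| < halfwidth; this closed form is the oracle for window
    signal on noise-free synthetic tracks.
    """
    lo = max(start, apex - halfwidth + 1)
    hi = min(end - 1, apex + halfwidth - 1)
    if hi < lo:
        return 0.0
    xs = np.arange(lo, hi + 1)
    return float(np.sum(height * (1.0 - np.abs(xs - apex) / halfwidth)))


# ---------------------------------------------------------------- expression


def generate_expression(
    config: SimulationConfig,
    genes: GeneIndex,
    manifest: GroundTruthManifest,
    rng: np.random.Generator,
) -> ExpressionTable:
    """Log-normal baseline expression with planted upregulation.

    Genes nearest a GLR site whose GFI1 pileup is >= the strength threshold
    get +de_effect log2fc (plus noise); genes nearest only weaker GLR sites
    get +de_effect_weak; everything else is centred on 0.
    """
    strong: set[str] = set()
    weak: set[str] = set()
    for s in manifest.enhancer_sites:
        if not s.is_glr or s.gfi1_pileup is None:
            continue
        try:
            gene, _ = genes.nearest_tss(s.chrom, s.apex)
        except LookupError:
            continue
        if s.gfi1_pileup >= config.pileup_threshold:
            strong.add(gene.gene_id)
        else:
            weak.add(gene.gene_id)
    weak -= strong
    manifest.target_genes_strong = sorted(strong)
    manifest.target_genes_weak = sorted(weak)

    rows = []
    for g in genes:
        base = float(np.exp(rng.normal(3.0, 1.0)))
        if g.gene_id in strong:
            lfc = config.de_effect + rng.normal(0, config.de_noise_sd)
        elif g.gene_id in weak:
            lfc = config.de_effect_weak + rng.normal(0, config.de_noise_sd)
        else:
            lfc = rng.normal(0, config.de_noise_sd)
        expressed = bool(rng.random() < 0.95)
        rows.append(
            {
                "gene_id": g.gene_id,
                "expr_ctrl": base,
                "expr_trt": base * 2.0 ** lfc,
                "log2fc": float(lfc),
                "expressed": expressed,
            }
        )
    return ExpressionTable(pd.DataFrame(rows))


# ---------------------------------------------------------------- driver


def simulate(config: SimulationConfig) -> SimulationResult:
    """Run all generator stages off one seed with per-stage substreams."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_genome, rng_peaks, rng_cov, rng_expr = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )
    genes, chrom_sizes = generate_genome(config, rng_genome)
    peak_sets, manifest = generate_peak_sets(config, genes, chrom_sizes, rng_peaks)
    tracks = generate_coverage(config, peak_sets, manifest, chrom_sizes, rng_cov)
    expression = generate_expression(config, genes, manifest, rng_expr)
    return SimulationResult(
        config=config,
        genes=genes,
        chrom_sizes=chrom_sizes,
        peak_sets=peak_sets,
        tracks=tracks,
        expression=expression,
        manifest=manifest,
    )
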