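"""End-to-end orchestration: simulate -> coincide -> enhancers -> signal ->
integrate, as one reproducible seeded run with a consolidated report.

Stages communicate only through the files and in-memory objects declared
here; the report echoes the full configuration so a run can be repeated
exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .coincidence import (
    assignments_to_bed,
    coincidence_summary,
    partition_categories,
    partition_report,
    stratified_coincidence,
)
from .core import ValidationError
from .enhancers import call_active_enhancers, link_to_genes, promoter_bound_genes
from .integrate import (
    normalized_enrichment,
    peak_gene_set,
    rank_by_log2fc,
    select_de_genes,
    strength_stratified_expression,
)
from .signal import fold_change_summary
from .simulate import SimulationConfig, simulate

logger = logging.getLogger("glrscope")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "glrscope_run"
    coincidence_window: int = 500
    promoter_halfwidth: int = 1_000
    enhancer_min_distance: int = 5_000
    pileup_threshold: float = 35.0
    de_threshold: float = 0.5
    top_fraction: float = 0.05
    signal_flank: int = 1_000
    n_permutations: int = 1_000
    write_files: bool = True
    log_level: str = "INFO"
    simulation: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("coincidence_window", "promoter_halfwidth",
                     "enhancer_min_distance", "signal_flank",
                     "n_permutations"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 < self.top_fraction <= 1):
            raise ValidationError("top_fraction must be in (0, 1]")
        if self.de_threshold <= 0:
            raise ValidationError("de_threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def simulation_config(self) -> SimulationConfig:
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(self.simulation) - known
        if unknown:
            raise ValidationError(f"unknown simulation keys: {sorted(unknown)}")
        kwargs = dict(self.simulation)
        kwargs.setdefault("seed", self.seed)
        if "gene_length_range" in kwargs:
            kwargs["gene_length_range"] = tuple(kwargs["gene_length_range"])
        return SimulationConfig(**kwargs)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage on freshly simulated data; return the report dict."""
    logging.basicConfig(
        level=config.log_level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
    t0 = time.time()
    outdir = Path(config.outdir)
    report: dict[str, Any] = {
        "version": __version__,
        "config": dataclasses.asdict(config),
    }

    logger.info("[simulate] generating synthetic dataset (seed=%d)", config.seed)
    sim = simulate(config.simulation_config())
    if config.write_files:
        outdir.mkdir(parents=True, exist_ok=True)
        sim.write(outdir / "simulated")
    report["simulate"] = {
        "n_genes": len(sim.genes),
        "peak_counts": {k: len(v) for k, v in sim.peak_sets.items()},
    }

    logger.info("[coincide] classifying peak co-occupancy")
    gfi1, lsd1, rcor1 = (sim.peak_sets[f] for f in ("GFI1", "LSD1", "RCOR1"))
    w = config.coincidence_window
    overall_l = coincidence_summary(gfi1, lsd1, w)
    overall_r = coincidence_summary(gfi1, rcor1, w)
    top_l = stratified_coincidence(gfi1, lsd1, w, config.top_fraction)
    top_r = stratified_coincidence(gfi1, rcor1, w, config.top_fraction)
    assignments = partition_categories(gfi1, lsd1, rcor1, w)
    part = partition_report(assignments)
    if config.write_files:
        assignments_to_bed(assignments).to_csv(
            outdir / "sites.bed", sep="\t", header=False, index=False
        )
        part.to_csv(outdir / "partition.tsv", sep="\t", index=False)
    cat_counts = {
        row["category"]: int(row["count"]) for _, row in part.iterrows()
    }
    report["coincide"] = {
        "gfi1_lsd1_pct": overall_l.percent,
        "gfi1_rcor1_pct": overall_r.percent,
        "top_gfi1_lsd1_pct": top_l.percent,
        "top_gfi1_rcor1_pct": top_r.percent,
        "category_counts": cat_counts,
    }

    logger.info("[enhancers] calling active intergenic enhancers")
    enhancer_regions = call_active_enhancers(
        sim.peak_sets["H3K9Ac"], sim.peak_sets["H3K4Me2"], sim.genes,
        min_gene_distance=config.enhancer_min_distance,
    )
    lsd1_bound = {
        e.region_id: any(
            abs(a - e.center) <= w
            for a in _chrom_apexes(lsd1, e.chrom, e.center, w)
        )
        for e in enhancer_regions
    }
    promoter_flags = promoter_bound_genes(
        sim.genes, lsd1, config.promoter_halfwidth
    )
    report["enhancers"] = {
        "n_enhancers": len(enhancer_regions),
        "n_lsd1_bound": int(sum(lsd1_bound.values())),
        "n_promoter_bound_genes": int(sum(promoter_flags.values())),
    }

    logger.info("[signal] quantifying condition fold changes")
    glr_ids = {a.site_id for a in assignments if a.category == "GLR"}
    glr_sites = [s for s in sim.manifest.enhancer_sites if s.site_id in glr_ids]
    other_sites = [s for s in sim.manifest.enhancer_sites if not s.is_glr]
    site_views_glr = [_SiteView(s.site_id, s.chrom, s.apex, s.gfi1_pileup or 0.0)
                      for s in glr_sites]
    site_views_other = [_SiteView(s.site_id, s.chrom, s.apex, 0.0)
                        for s in other_sites]
    signal_report = {}
    for mark in ("H3K9Ac", "H3K4Me2"):
        ctrl = sim.tracks[(mark, "vehicle")]
        trt = sim.tracks[(mark, "og86")]
        fc_glr = fold_change_summary(ctrl, trt, site_views_glr,
                                     config.signal_flank)
        fc_other = fold_change_summary(ctrl, trt, site_views_other,
                                       config.signal_flank)
        signal_report[mark] = {
            "pct_change_glr": fc_glr.percent_change,
            "pct_change_other": fc_other.percent_change,
        }
    report["signal"] = signal_report

    logger.info("[integrate] expression and gene-set enrichment")
    up, down = select_de_genes(sim.expression, config.de_threshold)
    all_glr_views = [
        _SiteView(s.site_id, s.chrom, s.apex, s.gfi1_pileup or 0.0)
        for s in sim.manifest.enhancer_sites if s.is_glr
    ]
    site_to_gene, _ = link_to_genes(all_glr_views, sim.genes)
    glr_genes = peak_gene_set(site_to_gene, sim.genes)
    ranked = rank_by_log2fc(sim.expression)
    enr = normalized_enrichment(
        ranked, glr_genes, n_perm=config.n_permutations,
        seed=config.seed + 10_000, gene_set_name="GLR_linked",
    )
    strata = strength_stratified_expression(
        all_glr_views, site_to_gene, sim.expression,
        pileup_threshold=config.pileup_threshold,
    )
    report["integrate"] = {
        "n_up": len(up),
        "n_down": len(down),
        "n_glr_linked_genes": len(glr_genes),
        "enrichment": {
            "es": enr.es, "nes": enr.nes, "p_value": enr.p_value,
            "n_hits": enr.n_hits,
        },
        "strata_means": {k: float(v.mean()) for k, v in strata.values.items()},
        "anova_p": strata.anova_p,
    }
    report["elapsed_s"] = round(time.time() - t0, 2)

    if config.write_files:
        (outdir / "report.json").write_text(json.dumps(report, indent=1))
        logger.info("report written to %s", outdir / "report.json")
    return report


@dataclass(frozen=True)
class _SiteView:
    """Minimal site adapter (chrom/center/pileup) for signal and linking."""

    site_id: str
    chrom: str
    center: int
    pileup: float


def _chrom_apexes(peaks, chrom: str, center: int, window: int):
    index = peaks.apex_index().get(chrom)
    if index is None:
        return []
    import numpy as np

    arr, _ = index
    lo = np.searchsorted(arr, center - window, side="left")
    hi = np.searchsorted(arr, center + window, side="right")
    return [int(a) for a in arr[lo:hi]]
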