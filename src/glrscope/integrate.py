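"""Expression integration: DE thresholding, ranked gene-set enrichment,
strength-stratified expression, and group comparison statistics.

Enrichment uses the weighted Kolmogorov-Smirnov running-sum statistic on a
list of genes ranked by descending log2 fold change: hits increment the sum
in proportion to |metric|^p (normalized over hits), misses decrement by
1/(N - N_hits); the enrichment score (ES) is the extremum of the running
sum. Significance comes from gene-set permutation: random same-size sets
drawn without replacement from the ranked list, with the NES defined as
ES divided by the mean |null ES| of matching sign and FDR by
Benjamini-Hochberg across the gene sets tested together.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionTable, ValidationError


# ---------------------------------------------------------------- DE genes


def select_de_genes(
    expr: ExpressionTable, threshold: float = 0.5
) -> tuple[list[str], list[str]]:
    """Up/down gene lists among expressed genes at |log2fc| >= threshold.

    Boundary inclusive: a gene at exactly +threshold is upregulated.
    """
    if threshold <= 0:
        raise ValidationError("DE threshold must be positive")
    df = expr.expressed
    up = df.loc[df["log2fc"] >= threshold, "gene_id"].tolist()
    down = df.loc[df["log2fc"] <= -threshold, "gene_id"].tolist()
    return up, down


# ---------------------------------------------------------------- ranking


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by descending ranking metric (log2 fold change)."""

    genes: list[str]
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValidationError("genes and metric length mismatch")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in ranked list")
        if not np.all(np.isfinite(self.metric)):
            raise ValidationError("non-finite ranking metric")
        if np.any(np.diff(self.metric) > 0):
            raise ValidationError("metric not sorted descending")

    def __len__(self) -> int:
        return len(self.genes)


def rank_by_log2fc(expr: ExpressionTable) -> RankedList:
    """Expressed genes ranked by descending log2fc (ties by gene_id)."""
    df = expr.expressed.sort_values(
        ["log2fc", "gene_id"], ascending=[False, True]
    )
    return RankedList(df["gene_id"].tolist(), df["log2fc"].to_numpy(dtype=float))


# ---------------------------------------------------------------- enrichment


def enrichment_score(
    ranked: RankedList,
    gene_set: Iterable[str],
    weight_exponent: float = 1.0,
) -> tuple[float, np.ndarray, list[str]]:
    """Weighted-KS enrichment score, running sum, and leading edge.

    With weight_exponent 0 the ES reduces to the classical two-sample KS
    statistic between hit and miss rank positions (up to sign).
    """
    members = set(gene_set)
    hit = np.array([g in members for g in ranked.genes])
    n_hit = int(hit.sum())
    n = len(ranked)
    if n_hit == 0 or n_hit == n:
        raise ValidationError("gene set intersection with ranked list is empty or full")
    weights = np.abs(ranked.metric) ** weight_exponent
    hit_w = np.where(hit, weights, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit metrics are exactly zero: fall back to equal weights
        hit_w = hit.astype(float)
        denom = hit_w.sum()
    step_hit = hit_w / denom
    step_miss = np.where(hit, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(step_hit - step_miss)
    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    es = float(running[i_max]) if running[i_max] >= -running[i_min] else float(running[i_min])
    if es >= 0:
        leading = [g for g, h in zip(ranked.genes[: i_max + 1], hit[: i_max + 1]) if h]
    else:
        leading = [g for g, h in zip(ranked.genes[i_min:], hit[i_min:]) if h]
    return es, running, leading


@dataclass(frozen=True)
class EnrichmentResult:
    gene_set_name: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    leading_edge: list[str]
    n_genes: int
    n_hits: int
    n_permutations: int
    seed: int


def normalized_enrichment(
    ranked: RankedList,
    gene_set: Iterable[str],
    n_perm: int = 1_000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    gene_set_name: str = "",
) -> EnrichmentResult:
    """ES with permutation NES and nominal p for one gene set.

    The null draws random gene sets of matching size without replacement
    from the ranked genes. NES = es / mean(|null es| of the same sign);
    nominal p is the same-sign tail fraction with one pseudo-observation.
    A seed is required so results are reproducible.
    """
    if seed is None:
        raise ValidationError("a seed is required for permutation enrichment")
    if n_perm < 100:
        import warnings

        warnings.warn("n_perm < 100 gives a coarse null", stacklevel=2)
    members = set(gene_set) & set(ranked.genes)
    es, _, leading = enrichment_score(ranked, members, weight_exponent)
    rng = np.random.default_rng(seed)
    n = len(ranked)
    k = len(members)
    weights = np.abs(ranked.metric) ** weight_exponent
    null = np.empty(n_perm)
    inv_miss = 1.0 / (n - k)
    for b in range(n_perm):
        idx = rng.choice(n, size=k, replace=False)
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        hw = np.where(hit, weights, 0.0)
        denom = hw.sum()
        if denom == 0:
            hw = hit.astype(float)
            denom = float(k)
        running = np.cumsum(hw / denom - np.where(hit, 0.0, inv_miss))
        mx, mn = running.max(), running.min()
        null[b] = mx if mx >= -mn else mn
    same_sign = null >= 0 if es >= 0 else null < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        nes = np.sign(es) * np.inf
        p = 1.0 / (n_perm + 1)
    else:
        nes = es / float(np.mean(np.abs(null[same_sign])))
        p = (1 + int(np.sum(np.abs(null[same_sign]) >= abs(es)))) / (1 + n_same)
    return EnrichmentResult(
        gene_set_name=gene_set_name,
        es=es,
        nes=float(nes),
        p_value=float(p),
        fdr_q=float(p),  # single set: BH leaves p unchanged
        leading_edge=leading,
        n_genes=n,
        n_hits=k,
        n_permutations=n_perm,
        seed=seed,
    )


def enrich_gene_sets(
    ranked: RankedList,
    gene_sets: dict[str, Iterable[str]],
    n_perm: int = 1_000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
) -> list[EnrichmentResult]:
    """Permutation enrichment for several sets with BH FDR across them."""
    if seed is None:
        raise ValidationError("a seed is required for permutation enrichment")
    results = []
    for i, (name, members) in enumerate(sorted(gene_sets.items())):
        results.append(
            normalized_enrichment(
                ranked,
                members,
                n_perm=n_perm,
                seed=seed + i,
                weight_exponent=weight_exponent,
                gene_set_name=name,
            )
        )
    from statsmodels.stats.multitest import multipletests

    pvals = [r.p_value for r in results]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return [
        EnrichmentResult(
            r.gene_set_name, r.es, r.nes, r.p_value, float(q), r.leading_edge,
            r.n_genes, r.n_hits, r.n_permutations, r.seed,
        )
        for r, q in zip(results, qvals)
    ]


# ---------------------------------------------------------------- gene sets


def peak_gene_set(
    site_to_gene: dict[str, str | None],
    genes=None,
    protein_coding_only: bool = False,
) -> set[str]:
    """Unique nearest genes of a site->gene mapping (dedup; many-to-one)."""
    out = {g for g in site_to_gene.values() if g is not None}
    if protein_coding_only and genes is not None:
        out = {g for g in out if genes.by_id[g].biotype == "protein_coding"}
    return out


# ---------------------------------------------------------------- strata


@dataclass(frozen=True)
class StrataComparison:
    """Expression fold-change comparison between site-strength strata."""

    strata: dict[str, list[str]]  # label -> gene ids
    values: dict[str, np.ndarray]  # label -> log2fc values
    anova_f: float
    anova_p: float
    posthoc: pd.DataFrame


def strength_stratified_expression(
    sites: list,
    site_to_gene: dict[str, str | None],
    expr: ExpressionTable,
    pileup_threshold: float = 35.0,
) -> StrataComparison:
    """Compare log2fc of genes near stronger vs weaker sites vs background.

    Stronger: genes nearest a site with pileup >= threshold (inclusive);
    weaker: genes nearest only sub-threshold sites; background: all other
    expressed genes. A gene near both a stronger and a weaker site counts
    as stronger, keeping the strata disjoint.
    """
    strong_genes: set[str] = set()
    weak_genes: set[str] = set()
    for s in sites:
        sid = getattr(s, "region_id", None) or getattr(s, "site_id")
        gene = site_to_gene.get(sid)
        if gene is None:
            continue
        if s.pileup >= pileup_threshold:
            strong_genes.add(gene)
        else:
            weak_genes.add(gene)
    weak_genes -= strong_genes
    expressed = set(expr.expressed["gene_id"])
    strong_genes &= expressed
    weak_genes &= expressed
    background = expressed - strong_genes - weak_genes
    strata = {
        "stronger": sorted(strong_genes),
        "weaker": sorted(weak_genes),
        "background": sorted(background),
    }
    for label, gs in strata.items():
        if not gs:
            raise ValidationError(f"empty stratum: {label}")
    fc = expr.df.set_index("gene_id")["log2fc"]
    values = {label: fc.loc[gs].to_numpy() for label, gs in strata.items()}
    f, p = stats.f_oneway(*values.values())
    posthoc = _tukey(values)
    return StrataComparison(
        strata=strata, values=values, anova_f=float(f), anova_p=float(p),
        posthoc=posthoc,
    )


def _tukey(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    data = np.concatenate(list(groups.values()))
    labels = np.concatenate(
        [[label] * len(v) for label, v in groups.items()]
    )
    res = pairwise_tukeyhsd(data, labels)
    return pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    ).rename(columns={"p-adj": "p_adj"})


def group_compare(
    groups: dict[str, Sequence[float]],
    method: str = "anova_tukey",
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Pairwise group statistics.

    Methods: ``welch_t`` (unequal-variance t per pair), ``anova_tukey``
    (one-way ANOVA + Tukey HSD), ``anova_fisher_lsd`` (one-way ANOVA +
    Fisher's least significant difference: pairwise t with the pooled
    within-group mean square and N-k degrees of freedom).
    """
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValidationError(f"group {k} has fewer than 2 values")
    rows = []
    if method == "welch_t":
        for a, b in combinations(arrays, 2):
            t, p = stats.ttest_ind(arrays[a], arrays[b], equal_var=False)
            rows.append({"group1": a, "group2": b, "statistic": float(t),
                         "p_value": float(p)})
    elif method == "anova_tukey":
        f, p_anova = stats.f_oneway(*arrays.values())
        tk = _tukey(arrays)
        for r in tk.itertuples(index=False):
            rows.append({"group1": r.group1, "group2": r.group2,
                         "statistic": float(r.meandiff),
                         "p_value": float(r.p_adj),
                         "anova_f": float(f), "anova_p": float(p_anova)})
    elif method == "anova_fisher_lsd":
        f, p_anova = stats.f_oneway(*arrays.values())
        n_total = sum(len(v) for v in arrays.values())
        k = len(arrays)
        mse = sum(
            ((v - v.mean()) ** 2).sum() for v in arrays.values()
        ) / (n_total - k)
        for a, b in combinations(arrays, 2):
            va, vb = arrays[a], arrays[b]
            se = np.sqrt(mse * (1 / len(va) + 1 / len(vb)))
            t = (va.mean() - vb.mean()) / se
            p = 2 * stats.t.sf(abs(t), df=n_total - k)
            rows.append({"group1": a, "group2": b, "statistic": float(t),
                         "p_value": float(p),
                         "anova_f": float(f), "anova_p": float(p_anova)})
    else:
        raise ValueError(f"unknown method {method!r}")
    df = pd.DataFrame(rows)
    if bh_adjust:
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(df["p_value"], method="fdr_bh")
        df["p_bh"] = q
    return df
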