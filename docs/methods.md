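# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open (BED convention). GTF and
MACS2 peak tables are 1-based and converted at the I/O boundary. Strand is
carried on gene models (it determines the TSS: `locus.start` on `+`,
`locus.end − 1` on `−`) but ignored by all distance and coincidence
computations, which operate on unstranded peak apexes. A narrowPeak summit
offset of −1 falls back to the interval midpoint (floor division) so that
every peak has a defined apex.

## Peak co-occupancy

Two peaks are *coincident* when their apexes are within ±500 bp on the
same chromosome. The boundary is inclusive (|Δ| = 500 counts): "within
±500 bp" is read inclusively and the choice is fixed here so results are
reproducible. Coincidence percentages are rounded half-up to the reported
precision.

The Venn partition over the three factors anchors the G-containing
categories (GLR, GL, GR, G) on GFI1 peaks: LSD1 and RCOR1 peaks each need
only be within the window of the GFI1 apex; no mutual L–R constraint is
imposed at triple sites. Partner claiming is greedy one-to-one by
ascending apex distance (ties broken by anchor then partner coordinate),
which prevents a single partner peak from being counted at two adjacent
anchor sites and makes the partition deterministic. LSD1/RCOR1 peaks left
unclaimed are then mutually matched into LR sites with the same rule;
the remainder become singleton L and R sites. Every input peak therefore
belongs to exactly one site — an invariant the tests assert. Anchoring on
GFI1 (rather than on merged coordinates) and one-to-one claiming are
design choices; the underlying co-occupancy definition is pairwise against
the anchor and does not itself dictate either.

Strength stratification takes the strongest ⌈f·n⌉ peaks by pileup
(ties by coordinate) and recomputes coincidence on that subset; f = 0.05
reproduces a "strongest 5 %" analysis.

## Active-enhancer calling

A candidate enhancer is any H3K9Ac peak whose interval overlaps at least
one H3K4Me2 peak interval. Interval overlap (single base suffices) rather
than apex distance is the default coincidence rule for the broad histone
marks, whose summits are unstable; an `apex:<bp>` mode is available. The
candidate interval is the union of the contributing peak intervals and its
center is the H3K9Ac apex (acetylation marks the active center; no other
center definition is imposed by the inputs). Candidates closer than 5 kb
to any annotated gene *locus* (a stricter reading than TSS-only distance)
are dropped; overlapping survivors are merged with the merged center taken
from the strongest H3K9Ac peak.

Location annotation classifies a peak by its apex with the conventional
precedence promoter > exonic > intronic > intergenic, the promoter being
TSS ± 1 kb (boundary inclusive). The same 1 kb rule defines
promoter-bound genes.

## Signal quantification

Coverage tracks are piecewise-constant per-base depth step functions with
a library normalizer (`total_mapped_reads`, `read_length`). Window read
counts are estimated from the depth integral, `count = Σ depth /
read_length`, and RPKM = `count × 10⁹ / (window_bp × total_mapped_reads)`.
Integrating depth (rather than counting read 5′ ends) is the natural
contract when tracks, not reads, are the input, and it makes the
tent-kernel oracle exact. Windows clipped at chromosome ends use the
clipped length; a window entirely off-chromosome scores 0.

Per-site condition fold change is `log2((rpkm_trt + p)/(rpkm_ctrl + p))`
with a 0.5 RPKM pseudocount (avoids infinities at zero-signal sites). The
*summary* percent change for a site category is computed on the ratio of
unshifted group means, `100·(mean_trt/mean_ctrl − 1)`, matching the "mean
signal increased by X %" phrasing; mean-of-ratios is deliberately not used
and the estimator choice is documented here because it is not forced by
the definitions.

Meta-profiles and heatmap matrices share one binning code path (per-anchor
per-offset-bin RPKM), so heatmap column means equal the meta-profile
exactly by construction. Heatmap rows are ranked by pileup descending,
ties by coordinate. Default bins are 25 bp over apex ± 1 kb; promoter and
enhancer fold-change windows default to ± 2.5 kb; all configurable.

## Expression integration

DE selection takes expressed genes with log2FC ≥ +0.5 (up) or ≤ −0.5
(down); the boundary is inclusive. "Expressed" is an input flag (with an
optional mean-expression floor), since expressed-gene definitions are
upstream of this package.

Gene-set enrichment is the weighted Kolmogorov–Smirnov running sum on the
descending-log2FC ranked list: hits add `|metric|^p / Σ_hits |metric|^p`,
misses subtract `1/(N − N_hits)`; the ES is the extremum, and the leading
edge is the hits at or before (after, for negative ES) the extremum. The
default weight exponent is 1 (standard practice); exponent 0 reduces the
ES to the classical two-sample KS statistic between hit and miss ranks,
which the tests exploit as an independent oracle. Significance uses
*gene-set permutation* — random same-size sets drawn without replacement
from the ranked genes — because the input is a precomputed ranked list and
phenotype labels are unavailable. NES = ES / mean(|null ES| of matching
sign); the nominal p is the same-sign tail fraction with one
pseudo-observation; FDR across sets tested together is Benjamini–Hochberg.
A seed is mandatory.

Strength-stratified expression compares log2FC of genes nearest
strong sites (pileup ≥ 35, inclusive), genes nearest only weaker sites,
and all other expressed genes (the background group excludes the linked
genes — the less ambiguous of the two possible readings), with one-way
ANOVA and Tukey HSD. `group_compare` additionally offers Welch t and
Fisher's LSD (pairwise t on the pooled within-group mean square with
N − k df; written in-house since no installed package exposes LSD).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes;
its defaults are the study conditions.

**Genome.** 4 chromosomes × 10 Mb, 800 non-overlapping genes of 4–12 kb
(2–5 exons, both strands, 90 % protein-coding), placed with ≥ 3 kb gaps.
These sizes are desk-scale choices that keep all simulations and tests in
seconds-to-minutes while leaving ~60 % of the genome gene-distal so that
intergenic enhancers exist in numbers.

**Peaks.** 2,000 GFI1 anchor peaks with log-normal pileups
(median 18, σ_log = 0.7, so ~17 % exceed the strength threshold 35). Each
anchor receives an LSD1 (RCOR1) partner with probability
`p(q) = (1 − s)·c + s·1[q > 1 − c]`, where q is the pileup rank quantile,
c the overall coincidence and s the strength coupling. This mixture keeps
the expected overall coincidence exactly c for any s while the strongest
peaks approach `s + (1 − s)·c`. Defaults c = 0.713 / 0.334 and
s = 0.951 / 0.826 for LSD1 / RCOR1 solve the pair of constraints
(overall, top-5 %) = (71.3 %, 98.6 %) and (33.4 %, 88.4 %) — the printed
co-binding structure this generator emulates. Partner apexes are jittered
by Normal(0, 100 bp) truncated at ±400 bp: the truncation margin keeps
every planted partner strictly inside the ±500 bp rule, separating
classifier correctness from generator leakage. 5,000 extra LSD1, 1,350
extra RCOR1 and 150 planted LR pairs (scaled from the genome-wide factor
peak-count ratios) are placed > 1 kb from all other apexes so they can
never create accidental coincidences. Coincident H3K9Ac/H3K4Me2 peaks are
placed at every triple-occupied site ≥ 6 kb from genes, at 600 extra
gene-distal sites, and (as decoys the ≥ 5 kb rule must reject) at 150
genic positions.

**Coverage.** depth = Poisson background (λ = 0.05/bp, piecewise constant
per 200 bp bin) + a triangular (tent) kernel of half-width 300 bp and
height equal to the peak pileup at each apex. The tent kernel has a
closed-form window integral (`tent_kernel_integral`), used as the oracle
for RPKM tests. In the treated condition, kernels at GLR sites are scaled
by 1.5 (H3K9Ac; ~+50 %, between the two reported acetylation increases)
and 1.09 (H3K4Me2; ~+9 %); all other sites are untouched. Both conditions
share the control library size as the RPKM basis, reflecting per-library
normalization; the low background keeps the dilution of the planted
multiplicative effect by background signal below one percentage point.
The Poisson background is a modelling choice — no noise model is given
for the real tracks.

**Expression.** Log-normal baseline; genes nearest a strong GLR site
(GFI1 pileup ≥ 35) get log2FC = 0.8 + Normal(0, 0.2), genes nearest only
weaker GLR sites 0.3 + noise, everything else pure noise. 95 % of genes
are flagged expressed.

**Determinism.** One global seed spawns independent per-stage substreams
(genome, peaks, coverage, expression), so outputs are bit-identical for a
fixed seed and stages are individually reproducible.

**What the generator does not emulate.** Read-level sampling (fragment
lengths, strand cross-correlation, GC bias), input/IgG controls, peak
shape heterogeneity, correlated replicate noise, and any dependence
between expression baseline and chromatin state. Passing the parameter-
recovery tests therefore demonstrates estimator correctness under the
planted model, not robustness to the full messiness of real ChIP-seq.

## Numerical choices

- Percentages round half-up at the reported precision (reporting
  convention, applied uniformly).
- Nearest-TSS ties break toward the lexicographically smaller gene id;
  pileup ties in rankings break by (chrom, start).
- `fold_change_summary` raises when the control mean is 0 rather than
  returning an undefined percent.
- Degenerate inputs (empty query set, empty stratum, empty/full gene-set
  intersection, missing seed) raise typed validation errors naming the
  problem.

## Problem sizes

Default simulations use 2,000 anchor peaks on a 40 Mb genome with 800
genes; the full pipeline runs in ~8 s and the acceptance script in under
a minute. These scales give binomial/normal sampling errors comfortably
inside the recovery bounds asserted by the tests (e.g. coincidence s.e.
≈ 0.003 at n = 2,000 under the coupled model).

## Known limitations

- The enhancer caller requires single-base interval overlap between the
  marks; a minimum-overlap-fraction mode is not implemented.
- Coincidence modes other than apex distance (e.g. reciprocal interval
  overlap) and >3-factor generalizations are out of scope.
- GSEA here supports gene-set permutation only; phenotype permutation
  requires per-sample expression, which the input tables do not carry.
- bedGraph is the only coverage format (no bigWig).
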