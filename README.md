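# glrscope

Integrative ChIP-seq/RNA-seq analysis of transcription-factor/corepressor
co-occupancy and enhancer activation, built around the GFI1–LSD1–RCOR1
(CoREST) axis in myeloid leukemia cells.

When LSD1 is inhibited pharmacologically, the LSD1/RCOR1 corepressor
complex is evicted from enhancers bound by the SNAG-domain repressor GFI1,
local histone acetylation (H3K9Ac, H3K27Ac) rises, and genes near the
strongest co-occupied ("GLR") sites are upregulated. `glrscope` implements
the genomics toolchain needed to make and test that argument from standard
file formats:

- **Peak co-occupancy by summit distance** — two peaks are coincident when
  their apexes lie within ±500 bp (inclusive) on the same chromosome.
  Sites are partitioned into the Venn categories GLR / GL / GR / LR / G /
  L / R with deterministic greedy one-to-one partner claiming, and
  coincidence can be stratified by peak strength (MACS2 pileup), e.g. the
  strongest 5 % of anchor peaks.
- **Active-enhancer calling** — an active intergenic enhancer is a region
  at least 5 kb from any annotated gene carrying coincident H3K9Ac and
  H3K4Me2 peaks; the enhancer center is the H3K9Ac apex.
- **Windowed signal quantification** — RPKM
  (`count × 10⁹ / (window_bp × total_mapped_reads)`, with
  `count = Σ depth / read_length`) in fixed windows, treated/vehicle fold
  changes per site category, meta-profiles and strength-ranked heatmap
  matrices around peak apexes.
- **Peak-to-gene linking and expression integration** — nearest-TSS
  assignment, DE-gene thresholding at |log₂FC| ≥ 0.5, weighted
  Kolmogorov–Smirnov gene-set enrichment with gene-set-permutation NES /
  p / BH-FDR, and strength-stratified expression comparison
  (pileup ≥ 35 vs < 35) with one-way ANOVA + Tukey HSD.
- **A synthetic-data generator** with planted ground truth (co-binding
  coupled to peak strength, a multiplicative treated acetylation effect at
  triple-occupied sites only, an expression effect at genes near strong
  GLR sites) so every estimator can be validated end-to-end against known
  parameters.

Audience: computational biologists working with MACS2-style peak calls
(narrowPeak or MACS2 peak tables), bedGraph coverage, GTF/BED12 gene
models and simple expression TSVs.

## Worked example

Simulate a dataset and run the whole analysis in one call:

```python
from glrscope.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1, write_files=False))
print(report["coincide"])
print(report["signal"]["H3K9Ac"])
```

prints (seed 1):

```
{'gfi1_lsd1_pct': 71.5, 'gfi1_rcor1_pct': 32.9,
 'top_gfi1_lsd1_pct': 99.0, 'top_gfi1_rcor1_pct': 92.0,
 'category_counts': {'GLR': 619, 'GL': 810, 'GR': 38, 'LR': 150,
                     'G': 533, 'L': 5000, 'R': 1350}}
{'pct_change_glr': 49.074883783882186,
 'pct_change_other': -0.0030856142709922985}
```

Reading: 71.5 % of the 2,000 GFI1 peaks have an LSD1 summit within
±500 bp (the generator planted 71.3 %), and 99 % of the strongest 5 % do —
co-binding concentrates in the strongest peaks. 619 sites are occupied by
all three factors. At those GLR sites the treated/vehicle H3K9Ac signal
rises by 49 % (planted effect: ×1.5, i.e. +50 %), while non-GLR enhancer
sites are unchanged within noise.

The same stages are exposed as a CLI:

```bash
glrscope simulate --seed 1 --out sim/
glrscope coincide --gfi1 sim/GFI1.narrowPeak --lsd1 sim/LSD1.narrowPeak \
    --rcor1 sim/RCOR1.narrowPeak --window 500 --top-fraction 0.05 --out report
glrscope enhancers --h3k9ac sim/H3K9Ac.narrowPeak \
    --h3k4me2 sim/H3K4Me2.narrowPeak --genes sim/genes.gtf \
    --min-distance 5000 --out enhancers.bed
glrscope run --seed 1 --out run/
```

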