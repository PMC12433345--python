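# atacspec

Tissue-specificity analysis of bulk ATAC-seq for multi-tissue study designs:
from per-sample MACS2 peak calls to tissue-specific regulatory regions, the
transcription-factor motifs enriched in them, and the genes whose expression
tracks their promoter accessibility.

The package is aimed at regulatory-genomics analysts working with bulk
chromatin-accessibility panels across tissues (the bundled synthetic design
emulates a 6-tissue × 8-replicate panel of brain and endocrine tissues:
amygdala, hippocampus, hypothalamus, thalamus, adrenal and pituitary gland).

## What it computes

**Consensus peaks.** Each sample's narrowPeak summits are extended ±75 bp
into fixed 151-bp windows, clustered across samples by single-linkage
overlap, and clusters supported by ≥ 2 peaksets become consensus regions
re-centered on the median summit. Fragments are counted per region by
midpoint containment; regions are kept only if at least one tissue has
count ≥ 10 in ≥ 75% of its replicates and the total count is ≥ 100; counts
are normalized to reads per million (RPM).

**Entropy-based tissue specificity.** For region accessibility *E*ᵢ (mean
RPM in tissue *i*), relative accessibility is

&nbsp;&nbsp;&nbsp;&nbsp;*R*ᵢ = *E*ᵢ / Σ*E*,&nbsp;&nbsp;&nbsp;
*H* = −Σᵢ *R*ᵢ log₂ *R*ᵢ,

with *H* ∈ [0, log₂ *N*]: 0 means all accessibility in one tissue, log₂ *N*
means uniform. A region is called tissue-specific when *H* < 2 (strict) and
max *R*ᵢ ≥ 0.33, labeled with its argmax tissue.

**Motif enrichment.** Known motifs (HOMER `.motif` format) are scanned as
log₂-odds PWMs over both strands of the tissue-specific sequences and of
GC- and length-matched background windows drawn from the same genome (2:1,
0.05-wide GC bins). Per motif and tissue, the number of motif-positive
sequences is tested with a hypergeometric upper tail (significance at
p < 0.001), and results are reported as a motif × tissue matrix, per-tissue
uniquely-significant sets with UpSet intersection counts, and a
coefficient-of-variation ranking.

**ATAC–RNA integration.** Regions whose midpoint lies within ±3 kb of a
TSS are paired with that transcript; within each tissue the Pearson
correlation between region RPM and gene expression across replicates is
tested (two-sided t, n−2 df), pairs with r > 0 and p < 0.05 qualify, and
each gene keeps its best pair per tissue. Tissue-uniquely enriched motifs
are additionally checked for expression support: the TF gene must be
expressed in that tissue and significantly higher there than in every other
tissue (one-sided Welch tests).

**Synthetic data.** `atacspec.synthio` generates a full input bundle with
known ground truth — random genome and gene models, shared and
tissue-specific loci with negative-binomial counts (target relative
accessibility 0.6), motif consensi planted in specific loci, and expression
with planted promoter correlations (ρ = 0.9) — so every stage can be
validated against planted truth.

## Worked example

```python
from atacspec import SimConfig, generate_bundle, InputData, PipelineConfig, run_all

bundle = generate_bundle(SimConfig(seed=7))          # 6 tissues x 8 replicates
result = run_all(InputData.from_bundle(bundle), PipelineConfig(seed=7))

spec = result.spec_table
print("consensus regions :", len(result.regions))
print("tissue-specific   :", (spec["label"] != "none").sum())
print("AG motif p in AG  :", result.p_matrix.loc["AG-planted", "AG"])
print(result.cis_counts)
```

prints

```
consensus regions : 3600
tissue-specific   : 475
AG motif p in AG  : 1.465e-37
tissue
AG     252
Amy    255
HT     248
Hip    251
PG     247
Tal    256
```

All 3,600 planted loci are recovered as 151-bp consensus regions; 475 are
classified tissue-specific (73–84 per tissue out of 100 planted each — the
planted entropy of 1.90 bits sits close to the strict H < 2 cutoff, so a
fraction of specific loci lands just above it under replicate noise). Each
planted motif is overwhelmingly significant in its own tissue only, and each
tissue recovers ~250 genes with a positive promoter-accessibility/expression
correlation (150 planted correlated genes plus promoter-sharing neighbors).

The same analysis runs from files via the CLI:

```bash
atacspec simulate --out bundle/ --seed 7
atacspec all --samples bundle/samples.tsv --peaks-dir bundle/ \
    --fragments-dir bundle/ --genome bundle/genome.fa --gtf bundle/anno.gtf \
    --motifs bundle/planted.motifs --expr bundle/expr.tsv \
    --tf-map bundle/tf_gene_map.tsv --out run/
```

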