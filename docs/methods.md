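# Methods

This note documents the statistical model, the fixed conventions, and the
design decisions behind `atacspec`, in the order the pipeline runs.

## Coordinate and format conventions

All internal coordinates are 0-based half-open, the native convention of
BED/narrowPeak; GTF input (1-based closed) is converted on read and back on
write. The TSS of a transcript is its span start on the + strand and span
end − 1 on the − strand. FASTA is uppercased on read. Parsers reject
structural errors (wrong column counts, non-integer coordinates, summit
offsets outside the peak, probability rows off unity by more than 1e-3)
with the offending line number rather than repairing them; motif rows off
by at most 1e-3 are renormalized. Peaks without a summit column fall back
to the interval midpoint, so plain BED peaks can be consumed.

## Consensus regions

Every peak is replaced by its summit extended `flank` bp each side
(default 75, width 151) and clipped at chromosome ends. Extended intervals
are clustered by single-linkage ≥ 1 bp overlap across all samples; clusters
with peaks from at least `min_overlap` (default 2) distinct samples yield
one region, re-centered on the median member summit with ties broken toward
the lower coordinate. Median re-centering is deterministic and robust to a
single sample's summit wobble; because the re-extended window is contained
in the cluster's extent, output regions are provably disjoint, which in
turn makes fragment counting a partition.

Fragments are assigned by midpoint containment (`floor((start+end)/2)`), so
each fragment counts at most once. The region filter keeps a region iff
(a) at least one tissue has `ceil(0.75 · n_replicates)` samples with
count ≥ 10, and (b) the total count over all samples is ≥ 100.
"Represented" in (a) reuses the count-≥ 10 rule rather than introducing a
second threshold; the 100-read floor in (b) is interpreted as a per-region
total across samples — a per-sample reading would make the per-sample
minimum of 10 redundant. RPM normalization uses the in-matrix library size
(reads assigned to consensus regions), keeping the pipeline self-contained
in its own inputs; columns sum to 10⁶ exactly.

## Tissue specificity

Per-tissue accessibility E_i is the unweighted mean RPM over that tissue's
replicates (the tissue-level expectation the entropy framework assumes).
Relative accessibility R_i = E_i/ΣE; the specificity index is
H = −Σ R_i log₂ R_i with 0·log₂ 0 = 0, bounded by [0, log₂ N]. Regions
with ΣE = 0 are reported as unclassifiable (H = NaN, no label), never
silently dropped. Classification uses a strict H < 2 and an inclusive
max R_i ≥ 0.33, matching the wording "less than 2" / "at least 0.33";
argmax ties break toward the earlier tissue in the configured order.
Classification is invariant to uniform rescaling of E.

Three different TSS windows are in play and each use site is separately
configurable: −1000/+100 (strand-oriented, inclusive) for the %-TSS-peaks
QC statistic, ±2 kb for TSS enrichment profiles, and ±3 kb for promoter
assignment. Genomic context labels a region by its midpoint with precedence
promoter > exon > intron > other, where promoter is the strand-oriented
3 kb upstream of the TSS; UTR sub-annotation collapses into exon unless the
GTF provides UTR features. Replicate correlation is Pearson on
log₁₀(RPM + 1); the pseudo-count of 1 RPM handles zeros, which the log plot
otherwise cannot. Zero-variance samples yield missing correlations.

## Motif enrichment

PWMs are scored as log₂ odds against a background base distribution
(uniform by default), with probabilities floored at 1e-3 so zero entries
stay finite, and N bases contributing a fixed −10 bits. Both strands are
scanned (reverse strand = reverse complement scored with the same matrix);
reported positions are forward-strand leftmost. A window counts as an
occurrence when its score reaches the motif's threshold, read from the
motif file and interpreted in bits; a non-positive stored threshold falls
back to 80% of the motif's maximal attainable score, a deterministic rule.
A sequence contributes at most once to the per-motif positive count, even
with hits on both strands at one position.

Background windows are drawn uniformly from the genome, excluding the
target regions and each other, matching each target's length exactly and
the targets' GC histogram in 0.05-wide bins (counts apportioned by largest
remainder; a bin that cannot be filled after 1000 draws per window is
topped up from the nearest bin with a warning). The default 2:1
background:target ratio and GC-bin width follow common known-motif
practice. Enrichment per motif and tissue is the hypergeometric upper tail
P(X ≥ k) with population M = n_target + n_background, K motif-positive
overall, n = n_target draws, evaluated in log space; significance is
p < 0.001. The hypergeometric (not binomial) tail is exact at these set
sizes. Fold enrichment is (k_t/n_t)/(k_b/n_b), capped at 10⁶ when the
background has no occurrences. This plain GC-binned matching deliberately
omits HOMER's additional CpG- and auto-normalization steps, which are not
part of the documented model. The "enrichment score" used for the
coefficient-of-variation ranking is −log₁₀(p) (motifs with mean score > 20
ranked by CV = sd/mean); the significance filter itself always uses p.

## ATAC–RNA integration

Promoter pairs are region-midpoint within ±3 kb of a TSS, inclusive at
both ends and strand-agnostic (the window is symmetric). Correlations are
computed within each tissue across its replicates — the per-tissue gene
counts such analyses report imply per-tissue testing — as the sample
Pearson r with a two-sided t test (t = r√(n−2)/√(1−r²), n−2 df); |r| = 1
reports p = 0, zero variance reports a missing result. At n = 8 the
smallest significant |r| at p < 0.05 is ≈ 0.707; the pipeline applies only
positivity and p < 0.05 and reports r, rather than treating 0.70 as an
independent threshold. Each gene keeps its maximum-r qualifying pair per
tissue. A Benjamini–Hochberg column (within tissue, across all tested
pairs) is emitted for reference but is not used for the headline filter,
which follows the raw-p convention.

TF expression support for tissue-uniquely enriched motifs requires
(i) mean expression ≥ 1.0 (matrix units; no threshold is standard, 1.0 is
conservative for RPKM-like units) in the motif's tissue, and (ii) that
tissue having the maximal mean with a one-sided Welch two-sample test
rejecting at α = 0.05 against **every** other tissue. The location test is
a deliberate design choice where only "significantly higher" is specified;
Welch handles the unequal variances typical of expression data. TF names
map to gene IDs through an explicit table with a case-insensitive
gene-symbol fallback; unmapped TFs are listed, not fatal.

## Synthetic data generator

The generator emulates the study design end to end and is itself tested
code. Defaults: 6 tissues × 8 replicates, 2 chromosomes × 1 Mb at GC 0.42,
3,000 shared + 100 per-tissue specific loci, 500 genes, NB mean 50
reads/locus/sample.

* **Genome and genes.** Bases are i.i.d. at the configured GC. Genes are
  placed in per-chromosome slots (spans 1–3 kb, 2–5 exons, random strand),
  so spans never overlap.
* **Loci.** Summits sit on a jittered grid guaranteeing ≥ 320 bp
  separation, so summit-extended windows never chain across loci and the
  consensus stage can recover the truth 1:1. About 30% of shared loci are
  pulled to within 2 kb of a TSS so the promoter-integration stage has
  signal.
* **Counts.** Negative binomial with var = μ + 0.2·μ² — the bulk-count
  convention in which √dispersion ≈ 0.45 is the biological CV, realistic
  for outbred animals. A specific locus allocates expected accessibility
  share f = 0.6 to its target tissue and (1−f)/5 to each other; shared
  loci are uniform, so expected R_i for planted loci is 0.6 and the
  deterministic entropy is 1.90 bits. Samples emit a narrowPeak at a locus
  when its count ≥ 5, with ±10 bp summit wobble; fragments are 150-bp
  intervals centered on the true summit, one per count.
* **Motifs.** One 10-mer consensus per tissue (pairwise distinct, also
  under reverse complement) is written into 80% of that tissue's specific
  loci at a random strand and offset within ±40 bp of the summit (inside
  the 151-bp window), and into shared loci at a 2% background rate. The
  matching PWMs (0.97 per consensus base) with thresholds at 80% of the
  maximum score admit only exact matches.
* **Expression.** 30% of genes owning a promoter locus follow
  a·RPM + Gaussian noise, calibrated per tissue so the within-tissue
  correlation is ρ = 0.9 in expectation (σ_noise = a·sd·√(1/ρ²−1)); one
  gene per tissue is that tissue's planted TF (mean 50 in its tissue, ~1
  elsewhere); all other genes are independent log-normal.
* **Determinism.** Each stage draws from its own stream derived from the
  single seed, so stages are independently reproducible and a bundle is
  byte-identical across runs.

What the generator does **not** emulate — Tn5 sequence bias, nucleosomal
fragment-length periodicity, read-level errors, correlated locus
accessibility, mappability structure — bounds what passing tests show:
they validate the algorithms and their statistical behavior under the
declared noise model, not performance on real libraries.

A known property of the default conditions: with the planted entropy
(1.90 bits) only 0.10 bits below the strict H < 2 cutoff and replicate
noise spreading H by ≈ 0.12 bits, roughly 20% of planted specific loci
land above the cutoff; the classification stage recovers ~79% of planted
labels at zero false discovery. Raising f or lowering the dispersion moves
recovery toward 1, but the defaults are kept as the declared study
conditions.

## Numerical choices and degenerate inputs

Entropy treats 0·log₂ 0 as 0 and rejects R vectors whose sum deviates from
1 by more than 1e-6. The hypergeometric tail is summed in log space
(logsumexp of log-pmfs) and clipped to ≤ 1. Pearson p uses the t
transformation rather than permutations. Largest-remainder rounding makes
GC-bin quotas deterministic. Median ties in consensus re-centering break
low; argmax ties in classification break by tissue order. Empty peak
files, empty region sets, zero-count samples, sequences shorter than a
motif, and genes without expression rows all have defined behavior (empty
results, NaN sentinels, or named errors) exercised by the test suite.

## Problem sizes used in the checks

The bundled validation runs the full declared design (3,600 loci,
48 samples, ≈ 8.6 M fragments, 500 genes) through every stage in well
under a minute on one core; structural and CLI tests use scaled-down
bundles (60–300 shared loci) chosen for speed, since the properties they
check are size-independent.

## Known limitations

Only known-motif enrichment is implemented (no de novo discovery, motif
clustering, or ChIP validation); differential accessibility between tissue
pairs, pathway enrichment, and embedding/heatmap visualization are out of
scope. Distal (enhancer) peak–gene linking is not attempted — only
promoter-window cis pairs. The GTF reader takes a single annotation;
reconciling annotation versions between ATAC and RNA data is the user's
responsibility.
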