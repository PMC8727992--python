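# Methods

## The mixture model and the estimator

Subcellular fractionation RNA-seq yields per-fraction expression vectors
that are each normalized to a fixed total (TPM to 1e6), which discards
the relative amounts of RNA in the compartments. The whole-cell (WC)
library physically pools the compartments, so for every gene *i*

TPM_WC,i = θ·TPM_Cyto,i + (1 − θ)·TPM_Nuc,i

holds exactly when the three libraries measure the same underlying
molecule pools, with θ equal to the cytosolic share of total RNA
molecules. `sfae` estimates θ by minimizing

E(θ) = (1/n) Σᵢ [ ln( (θ·C_i + (1 − θ)·N_i) / W_i ) ]²

over the filtered gene set. The log-ratio form weights relative rather
than absolute deviations, so highly expressed genes do not dominate, and
E(θ) is typically a smooth single-minimum ("bell") curve on [0, 1].

**Gene filtering.** Two rules, applied in order and counted separately:

1. *Positivity* — genes with any of C, N, W ≤ 0 are removed (the
   logarithm requires it; the model itself is silent about zeros).
2. *Between-range* — genes with W outside [min(C, N), max(C, N)] are
   removed: no mixture weight can place the prediction outside the range
   of its two endpoints. The bounds are inclusive: a gene with W exactly
   at a fraction value is perfectly explained by θ ∈ {0, 1}.

No renormalization is applied after filtering; the cost uses the TPM
values as given. FPKM input is handled identically (the cost is
scale-sensitive only through the per-sample normalization, which both
units share).

**Optimization.** The scalar problem is solved with bounded Brent search
on [0, 1] (tolerance 1e-6 on θ, the default); boundary values are
checked explicitly, and an optional dense-grid cross-check
(`verify_with_grid`, step 1e-4) guards against a stalled line search —
correctness is defined by agreement with the grid, not by a particular
optimizer. For k ≥ 2 fractions the weights live on the probability
simplex; SLSQP with a sum-to-one equality constraint and box bounds is
used, with a simplex-lattice fallback at resolution 0.01. If all
fraction vectors are identical the weights are unidentifiable and are
reported uniform with a `non_identifiable` flag. Estimation is
deterministic and single-threaded.

**Subsets.** Estimating θ on a gene subset (e.g. short- vs long-half-life
RNAs) is the same operation with a caller-provided gene list applied
before filtering — no separate code path.

## Per-gene localization quantities

With a global θ, the fraction TPMs are placed on a common absolute
scale: θ·C_i and (1 − θ)·N_i are proportional to molecule numbers.

* **Adjusted log2 ratio** log2(θ·C_i) − log2((1 − θ)·N_i), computed only
  where both C_i and N_i reach a minimum expression of 0.1 TPM
  (configurable) — ratios of near-zero values are noise. θ of exactly 0
  or 1 is rejected.
* **Per-gene CR** θ·C_i / (θ·C_i + (1 − θ)·N_i) ∈ [0, 1]. This formula
  is a design choice of this package (the adjustment is usually stated
  only at the ratio level); it is the unique gene-level cytosolic
  fraction whose abundance-weighted mean — weights θ·C_i + (1 − θ)·N_i —
  equals the global θ exactly for TPM-normalized inputs. That
  conservation identity is enforced by tests to 1e-10. Note it weights
  genes on the TPM scale, not the molecule scale.
* **Variation statistics** per gene across cell lines: range (max − min,
  "CR max diff") and sample variance of the per-gene CR, computed for
  genes with ≥ 3 unmasked cell lines (configurable).
* **Clustering** (k-means, default k = 3, 10 restarts, fixed seed) runs
  on per-gene z-scored adjusted ratios; zero-variance rows z-score to
  all zeros. Cluster labels are re-ordered by ascending mean adjusted
  ratio (label 0 = most nuclear) so labels are stable across runs. A
  chi-square test of biotype × cluster association accompanies the
  composition table. Because the z-score removes each gene's mean level,
  clusters separate cell-line *profiles*, not overall localization
  levels.

## Gene classes and motif enrichment

Genes are classified from the signs of their median adjusted log2
ratios in polyA and non-polyA libraries: (+, +) cytosolic, (−, −)
nuclear, (+, −) bivalent (cytosolic as polyA, nuclear as non-polyA).
Exact zeros and the (−, +) quadrant are left unclassified rather than
guessed — only three quadrants have a defined biological reading. The
same rule applies to log2 molecule-count ratios from single-molecule
data (mouse Cyto-/Nuc-gene sets).

Motif enrichment works on **densities** — occurrences per nucleotide of
each gene's representative isoform (highest summed expression across
cell lines, ties to the lexicographically smallest id) — which removes
the length bias a raw count would carry. Per motif, a two-sided Wilcoxon
rank-sum test compares in-set vs out-of-set densities;
Benjamini–Hochberg FDR is applied across motifs, and "enriched" requires
q < 0.05 (configurable) with the in-set median larger. Occurrence tables
come from an external scanner (FIMO dialect supported) at that scanner's
own thresholds; a deliberately simple IUPAC consensus scanner (counting
overlapping sense-strand matches) is included so the whole path can be
exercised without external tools. Cross-species concordance collapses
bivalent-enriched motifs into cytosol-enriched before comparing
compartment preferences between species.

**Small-sample testing.** When both groups have ≤ 8 observations the
rank-sum p-value is computed by exact enumeration of all C(n_a+n_b, n_a)
rank assignments on midranks (valid under ties; two-sided p = doubled
smaller tail, capped at 1); larger samples use the tie-corrected normal
approximation. Fisher's exact test (scipy) handles 2×2 contingency
tables, cross-checked in tests against hypergeometric enumeration.

## Isoform switching and splicing completeness

The **switch screen** correlates, per gene, the per-gene CR vector
across cell lines with the isoform *ratio* (isoform TPM / summed gene
TPM per cell line) of the two most abundant isoforms. The correlation
target is the ratio rather than raw isoform TPM (the two readings of
the procedure differ; raw-TPM mode is available via `use_ratio=False`).
A gene passes when |r₁| > 0.4 and |r₂| > 0.4, the signs differ, and the
gene's median TPM across cell lines is ≥ 3 (inclusive; the source
descriptions disagree between "greater than" and "≥" and the inclusive
reading is used). Pearson r requires ≥ 4 paired cell lines; constant
vectors are reported missing with a reason. The positively correlated
isoform is "exported", the negative one "retained"; a Fisher test on
the exported/retained × coding/noncoding table quantifies coding-status
enrichment.

**Splice-completeness ratios** count fragments per gene: a fragment
(mate blocks merged) is assigned to a gene when all blocks fall inside
the gene's span (unstranded by default); it is *incomplete* when any
aligned base overlaps the gene's intronic space — the gene span minus
the exon union over all annotated transcripts, since a read inside any
annotated exon is not evidence of incomplete splicing — and *complete*
when every block lies within the exon union. Fragments spanning two
genes or matching neither category are ignored but counted, so
incomplete + complete + ignored equals the assigned total. The reported
statistic is the natural-log incomplete/complete ratio, undefined when
either count is zero.

**Summed intron length** per gene defaults to the exon-union policy
(span length minus exon-union length); a representative-isoform policy
(sum of that isoform's inter-exon gaps) is available because the
transcript set behind published intron-length distributions is usually
unstated. The union policy can only remove intronic bases relative to a
span-covering representative.

## The synthetic-data generator

`sfae.simulate` produces datasets with exact ground truth so every
analysis is testable without downloads.

**Fractionation** (`simulate_fractionation`): nuclear molecule
abundances are lognormal (meanlog 2, sdlog 1.5 — spanning the dynamic
range of RNA-seq TPMs); cytoplasmic abundances come from a target θ
(per-gene log cyto/nuc ratios with spread `ratio_sdlog` = 1.0, rescaled
so the molecule share hits θ exactly) or an explicit per-gene ratio.
The per-gene ratio spread matters: with a single shared ratio the
per-fraction TPM normalization makes the Cyto and Nuc TPM vectors
identical and θ is only identifiable through noise. Multiplicative
lognormal noise (`noise_sdlog`) perturbs the two fraction molecule
vectors; the WC library pools exactly those realized molecules, so WC
remains an exact θ-mixture of the fraction TPMs with θ equal to the
realized molecule share (`SimTruth.theta_true`), and every column is
TPM-normalized to 1e6. An optional independent WC measurement-noise
layer (`wc_noise_sdlog`, default 0) breaks the exact mixture for
robustness studies. What this generator does **not** emulate: gene-gene
correlation, library-size/count noise (no Poisson layer by default),
fraction cross-contamination, and multi-replicate designs — so passing
recovery tests demonstrates correctness of the estimator under the
model's own assumptions, not robustness to every artefact of real
libraries (the `wc_noise_sdlog` tests probe one such violation).

**Isoform panels** (`simulate_isoform_panel`): cell-line CRs evenly
spaced in [0.4, 0.9] (the band observed in real panels) with small
per-gene jitter. Each gene has four isoforms of comparable base
abundance (0.35/0.25/0.22/0.18) with independent lognormal share jitter
(sdlog 0.4) per cell line; with only two isoforms the two ratios are
exactly complementary, making the screen's opposite-sign criterion
vacuous and its null pass rate irreducibly high — several comparably
expressed isoforms are both realistic and necessary for the screen's
error rates to be meaningful. Planted switch genes blend a
deterministic two-isoform trade-off along the CR axis with the null
profile, weighted so the planted |r| tracks `effect` (exactly null at
effect 0, exactly deterministic at effect 1). Planted genes get median
TPM ≥ 3 so the expression gate does not mask the correlation signal;
null gene medians straddle the threshold.

**Motif data** (`simulate_motif_data`): occurrence counts are Poisson
with rate = base density × length × multiplier, the multiplier applied
in-set only; lengths are lognormal around 2 kb. `inset_length_factor`
builds length-confounded nulls (the density normalization must absorb
them), and `emit_sequences` plants literal consensus matches into random
sequences for scanner tests.

**Reads** (`simulate_gene_reads`): single-block fragments placed inside
a random exon (complete) or intron (incomplete) of each gene's
exon-union model, with per-fragment Bernoulli incompleteness at the
requested rate.

All generators are pure functions of their parameters and seed.

## Problem sizes and numerical choices

Tests run the estimator at 2,000 genes (recovery across θ = 0.1…0.9, 20
replicates each), the grid oracles at step 1e-4 (scalar) and lattice
resolution 0.01 (simplex), the switch screen at 500-gene/11-cell-line
panels over 10 seeds, and motif enrichment at 1,000 genes — sizes at
which every statistical bound tested has comfortable margin while the
whole suite stays interactive. Ties in representative-isoform selection
break lexicographically; cluster labels are ordered by mean ratio;
variance is clamped to exactly 0 whenever the range is 0 so the two
zero-sets coincide. Known limitations: no uncertainty interval on θ (a
bootstrap over genes is a straightforward extension), no per-RNA-class
mixture weights (one global θ by design), and the accession-scale
analyses (ENCODE/SRA/GSA datasets) require external downloads and
alignment/quantification upstream of this package.
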