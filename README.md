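# sfae — Subcellular Fraction Abundance Estimator

`sfae` estimates the **global cytosolic RNA abundance ratio** (CR, written
θ) from subcellular-fractionation RNA-seq expression tables, and provides
the downstream analyses that a fractionation study needs once that ratio
is known: absolute Cyto/Nuc ratio adjustment, localization gene classes,
RBP motif-density enrichment, isoform-switch screening, splicing-
completeness read ratios and cross-cell-line CR variation statistics.

## The problem and the model

Cytosol, nucleus and whole-cell (WC) libraries are each normalized
independently (TPM/FPKM), so the two fraction vectors cannot be compared
on an absolute scale: the cytosol typically holds far more RNA than the
nucleus, and a "relative" Cyto/Nuc TPM ratio understates cytosolic
enrichment. The WC library, however, pools the two compartments with
unknown weights, which makes it an internal anchor. Modelling

TPM_WC,i ≈ θ·TPM_Cyto,i + (1 − θ)·TPM_Nuc,i

for every gene *i*, the single mixture weight θ ∈ [0, 1] is the fraction
of total RNA molecules residing in the cytosol. `sfae` estimates θ by
minimizing the mean squared log-ratio cost

E(θ) = (1/n) Σᵢ [ ln( (θ·C_i + (1 − θ)·N_i) / W_i ) ]²

over genes that (a) are strictly positive in all three vectors and
(b) have W_i within the inclusive range [min(C_i, N_i), max(C_i, N_i)]
(a WC value outside that range cannot arise from any mixture). The same
cost with simplex-constrained weights handles k > 2 fractions
(CeFra-seq-style data). With θ in hand, per-gene quantities follow:

* adjusted (absolute) log2 Cyto/Nuc ratio: log2(θ·C_i) − log2((1 − θ)·N_i)
* per-gene cytosolic fraction: θ·C_i / (θ·C_i + (1 − θ)·N_i), whose
  abundance-weighted mean recovers the global θ exactly.

## Worked example

```python
from sfae import simulate, estimator, localization

# synthetic Cyto/Nuc/WC table with a known cytosolic share of 0.75
table, truth = simulate.simulate_fractionation(
    n_genes=2000, theta=0.75, noise_sdlog=0.1, seed=21)

triplet = estimator.filter_triplet(table, "Cyto", "Nuc", "WC")
est = estimator.estimate_cr(triplet)
print(f"theta={est.theta:.4f}  E={est.e_min:.3g}  n={est.n_genes}")
```

prints

```
theta=0.7427  E=1.3e-15  n=2000
```

i.e. the estimator recovers the realized cytosolic molecule share
(`truth.theta_true` is 0.7427 for this seed — the per-gene fraction
noise shifts the realized share slightly off the 0.75 target) using all
2,000 genes. The same estimate from the shell:

```bash
sfae simulate fractionation --n-genes 2000 --theta 0.75 --seed 21 -o sim.tsv
sfae estimate --expr sim.tsv --cyto Cyto --nuc Nuc --wc WC -o cr.tsv
```

Downstream, `sfae adjust` converts a table plus θ into per-gene absolute
ratios, `sfae cluster` / `sfae classify` build the localization gene
groups, `sfae motif-enrich` tests RBP motif densities between a gene set
and the rest (rank-sum + BH-FDR), `sfae isoform-screen` finds genes whose
two most abundant isoforms correlate oppositely with the per-gene CR
across cell lines, and `sfae splice-ratio` counts intron-overlapping vs
exon-only fragments per gene. See `docs/methods.md` for the statistical
details and every tunable parameter.

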