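"""Synthetic fractionation datasets with known ground truth.

The generators emulate the data model the estimator assumes: per-gene
nuclear and cytoplasmic molecule abundances, independent per-fraction
TPM normalization, a whole-cell library whose TPMs are exactly the
theta-weighted mixture of the fraction TPMs (with theta equal to the
cytosolic molecule share), and multiplicative lognormal measurement
noise applied per fraction before renormalization. All generators are
pure functions of their parameters and seed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sfae.types import (
    ExpressionTable, Gene, GeneModels, ReadBlockSketch, SimTruth, Transcript,
)

TPM_SCALE = 1e6
DEFAULT_MEANLOG = 2.0
DEFAULT_SDLOG = 1.5


def _tpm(v: np.ndarray) -> np.ndarray:
    return v / v.sum() * TPM_SCALE


def simulate_fractionation(
    n_genes: int = 2000,
    theta: float | None = 0.8,
    per_gene_ratio: float | np.ndarray | None = None,
    ratio_sdlog: float = 1.0,
    meanlog: float = DEFAULT_MEANLOG,
    sdlog: float = DEFAULT_SDLOG,
    noise_sdlog: float = 0.0,
    wc_noise_sdlog: float = 0.0,
    seed: int = 0,
    weights=None,
) -> tuple[ExpressionTable, SimTruth]:
    """Simulate Cytosol / Nucleus / WC expression with known theta.

    Nuclear molecule abundances are lognormal(meanlog, sdlog). The
    cytoplasmic abundances come either from a global target ``theta`` —
    per-gene log cyto/nuc ratios are drawn with spread ``ratio_sdlog``
    (genes genuinely differ in localization) and rescaled so the
    cytosolic molecule share equals ``theta`` exactly — or from an
    explicit ``per_gene_ratio`` (scalar or array of cyto/nuc molecule
    ratios, e.g. a uniform 3.8).

    Noise model: multiplicative lognormal noise (``noise_sdlog``) is
    applied per gene to the cytosol and nucleus molecule vectors; these
    noised vectors are the realized fraction abundances, and the WC
    library pools exactly those molecules — WC stays an exact
    theta-mixture of the fraction TPM vectors, with theta equal to the
    realized cytosolic molecule share (``SimTruth.theta_true``, always
    sum(cyto)/sum(cyto+nuc)). An additional independent WC measurement
    noise layer (``wc_noise_sdlog``, off by default) breaks that exact
    mixture for robustness studies. Every sample is TPM-normalized to
    1e6 at the end.

    When ``weights`` (a k-simplex vector) is given, a k-fraction dataset
    is generated instead, with fraction samples F1..Fk and WC pooling
    the k noised fractions with those weights.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    rng = np.random.default_rng(seed)

    if weights is not None:
        return _simulate_multifraction(n_genes, np.asarray(weights, float),
                                       meanlog, sdlog, noise_sdlog,
                                       wc_noise_sdlog, seed, rng)

    nuc = rng.lognormal(mean=meanlog, sigma=sdlog, size=n_genes)
    if per_gene_ratio is not None:
        ratio = np.broadcast_to(np.asarray(per_gene_ratio, float), (n_genes,))
        if (ratio < 0).any():
            raise ValueError("per-gene cyto/nuc ratios must be non-negative")
        cyto = ratio * nuc
    else:
        if theta is None or not 0.0 < theta < 1.0:
            raise ValueError("theta must be in (0, 1)")
        log_ratio = rng.normal(np.log(theta / (1.0 - theta)), ratio_sdlog,
                               size=n_genes)
        cyto = np.exp(log_ratio) * nuc
        # rescale so the molecule share hits the target theta exactly
        cyto *= (theta / (1.0 - theta)) * nuc.sum() / cyto.sum()

    if noise_sdlog > 0:
        cyto = cyto * rng.lognormal(0.0, noise_sdlog, size=n_genes)
        nuc = nuc * rng.lognormal(0.0, noise_sdlog, size=n_genes)
    wc_noise = (rng.lognormal(0.0, wc_noise_sdlog, size=n_genes)
                if wc_noise_sdlog > 0 else 1.0)
    theta_true = float(cyto.sum() / (cyto.sum() + nuc.sum()))
    cols = {
        "Cyto": _tpm(cyto),
        "Nuc": _tpm(nuc),
        "WC": _tpm((cyto + nuc) * wc_noise),
    }

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    meta = pd.DataFrame(
        {"fraction": ["cytosol", "nucleus", "whole_cell"],
         "cell_line": "sim", "polya": "polyA"},
        index=["Cyto", "Nuc", "WC"],
    )
    truth = SimTruth(theta_true=theta_true, seed=seed, noise_sdlog=noise_sdlog,
                     cyto_molecules=cyto, nuc_molecules=nuc)
    return ExpressionTable(values=values, sample_meta=meta), truth


def _simulate_multifraction(n_genes, weights, meanlog, sdlog, noise_sdlog,
                            wc_noise_sdlog, seed, rng):
    k = len(weights)
    if k < 2 or (weights < 0).any() or abs(weights.sum() - 1) > 1e-9:
        raise ValueError("weights must be a k>=2 simplex vector")
    # molecules per fraction scaled so fraction j holds weights[j] of the total
    base = rng.lognormal(mean=meanlog, sigma=sdlog, size=(n_genes, k))
    base = base / base.sum(axis=0, keepdims=True)  # per-fraction composition
    molecules = base * weights  # column j sums to weights[j]
    if noise_sdlog > 0:
        molecules = molecules * rng.lognormal(0.0, noise_sdlog,
                                              size=(n_genes, k))
    wc_noise = (rng.lognormal(0.0, wc_noise_sdlog, size=n_genes)
                if wc_noise_sdlog > 0 else 1.0)
    weights_true = molecules.sum(axis=0) / molecules.sum()
    cols = {f"F{j + 1}": _tpm(molecules[:, j]) for j in range(k)}
    cols["WC"] = _tpm(molecules.sum(axis=1) * wc_noise)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    values = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    meta = pd.DataFrame(
        {"fraction": ["other"] * k + ["whole_cell"],
         "cell_line": "sim", "polya": "polyA"},
        index=list(cols.keys()),
    )
    truth = SimTruth(theta_true=weights_true, seed=seed, noise_sdlog=noise_sdlog)
    return ExpressionTable(values=values, sample_meta=meta), truth


def simulate_isoform_panel(
    n_genes: int = 500,
    n_cell_lines: int = 11,
    n_switch: int = 25,
    effect: float = 0.9,
    cr_range: tuple[float, float] = (0.4, 0.9),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series, SimTruth]:
    """Multi-isoform gene panel with planted CR-coupled isoform switches.

    Cell-line CRs are evenly spaced over ``cr_range`` (the band observed
    in real fractionation panels); per-gene CRs add small jitter. Every
    gene carries four isoforms of comparable base abundance (human genes
    typically have several annotated isoforms) whose expression shares
    fluctuate independently across cell lines (multiplicative lognormal
    jitter on Dirichlet-style base shares) — with only two isoforms the
    two ratios would be exactly complementary and the opposite-correlation
    criterion of the switch screen would be vacuous. For the ``n_switch`` planted
    genes the first isoform's share is additionally coupled to the gene's
    CR vector so its planted Pearson correlation is approximately
    ``effect``; null genes get CR-independent shares. Planted genes are
    guaranteed a median gene TPM >= 3 so the expression criterion of the
    screen does not hide them; null gene TPM medians straddle the
    threshold.

    Returns (isoform_expression, gene_expression, per_gene_cr, gene_map,
    truth).
    """
    if n_cell_lines < 5:
        raise ValueError("n_cell_lines must be >= 5")
    if n_switch > n_genes:
        raise ValueError("n_switch cannot exceed n_genes")
    if not 0.0 <= effect <= 1.0:
        raise ValueError("effect must be in [0, 1]")
    rng = np.random.default_rng(seed)
    cell_lines = [f"CL{j + 1:02d}" for j in range(n_cell_lines)]
    gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    switch_genes = set(gene_ids[:n_switch])

    cl_cr = np.linspace(cr_range[0], cr_range[1], n_cell_lines)
    jitter = rng.normal(0.0, 0.01, size=(n_genes, n_cell_lines))
    cr = np.clip(cl_cr[None, :] + jitter, 0.01, 0.99)
    per_gene_cr = pd.DataFrame(cr, index=gene_ids, columns=cell_lines)

    # gene-level TPM: planted genes comfortably expressed, nulls straddle 3
    gene_tpm = np.empty((n_genes, n_cell_lines))
    gene_tpm[:n_switch] = rng.lognormal(np.log(30.0), 0.5,
                                        size=(n_switch, n_cell_lines))
    gene_tpm[n_switch:] = rng.lognormal(np.log(3.0), 1.0,
                                        size=(n_genes - n_switch, n_cell_lines))

    base_shares = np.array([0.35, 0.25, 0.22, 0.18])
    n_iso = len(base_shares)
    share_jitter_sdlog = 0.4  # cell-line variability of each isoform share
    # blend constant matching the spread of the deterministic switch profile
    # to the spread of the null share profile, so planted |r| tracks `effect`
    kappa = 1.6
    iso_rows, iso_ids, gene_of = [], [], []
    for i, g in enumerate(gene_ids):
        z_cr = (cr[i] - cr[i].mean())
        sd = z_cr.std()
        z_cr = z_cr / sd if sd > 0 else z_cr
        jitter = rng.lognormal(0.0, share_jitter_sdlog,
                               size=(n_iso, n_cell_lines))
        null_shares = base_shares[:, None] * jitter
        null_shares /= null_shares.sum(axis=0)
        if g in switch_genes:
            # deterministic switch profile: isoforms 1 and 2 trade off
            # along the CR axis, minor isoforms stay flat
            frac = np.clip(0.55 + 0.25 * z_cr, 0.02, 0.98)
            switch_shares = np.vstack([
                0.7 * frac, 0.7 * (1.0 - frac),
                np.full(n_cell_lines, 0.18), np.full(n_cell_lines, 0.12),
            ])
            switch_shares /= switch_shares.sum(axis=0)
            w_null = kappa * np.sqrt(max(0.0, 1.0 - effect ** 2))
            shares = effect * switch_shares + w_null * null_shares
        else:
            shares = null_shares
        shares = shares / shares.sum(axis=0)
        for j in range(n_iso):
            iso_ids.append(f"{g}.T{j + 1}")
            gene_of.append(g)
            iso_rows.append(shares[j] * gene_tpm[i])
    isoform_expression = pd.DataFrame(iso_rows, index=iso_ids, columns=cell_lines)
    gene_expression = pd.DataFrame(gene_tpm, index=gene_ids, columns=cell_lines)
    gene_map = pd.Series(gene_of, index=iso_ids, name="gene_id")
    truth = SimTruth(theta_true=float("nan"), seed=seed,
                     planted_switch_genes=switch_genes)
    return isoform_expression, gene_expression, per_gene_cr, gene_map, truth


BASES = np.array(list("ACGT"))


def simulate_motif_data(
    n_genes: int = 1000,
    geneset_fraction: float = 0.2,
    motif_multipliers: dict[str, float] | None = None,
    base_density: float = 0.002,
    length_meanlog: float = np.log(2000.0),
    length_sdlog: float = 0.3,
    seed: int = 0,
    inset_length_factor: float = 1.0,
    emit_sequences: bool = False,
    motif_consensus: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.Series, pd.Index, SimTruth]:
    """Motif occurrence counts with planted in-set density shifts.

    Counts are Poisson with rate ``base_density * length * multiplier``,
    the multiplier applied only to in-set genes. ``inset_length_factor``
    scales in-set lengths to build length-confounded null datasets (the
    density normalization should absorb it). With ``emit_sequences`` the
    generator instead writes random sequences carrying the requested
    number of planted consensus matches, for scanner tests.

    Returns (occurrences, lengths, geneset_index, truth); occurrences is
    a (motif_id, sequence_id, count) table. When sequences are emitted the
    first element is a dict {gene: sequence} instead.
    """
    if motif_multipliers is None:
        motif_multipliers = {"M1": 1.0}
    if any(m <= 0 for m in motif_multipliers.values()):
        raise ValueError("motif multipliers must be > 0")
    rng = np.random.default_rng(seed)
    gene_ids = pd.Index([f"G{i:04d}" for i in range(n_genes)])
    n_in = int(round(geneset_fraction * n_genes))
    geneset = gene_ids[:n_in]
    lengths = rng.lognormal(length_meanlog, length_sdlog, size=n_genes)
    lengths[:n_in] *= inset_length_factor
    lengths = pd.Series(np.maximum(lengths, 50).round().astype(int),
                        index=gene_ids, name="length")

    rows = []
    in_mask = gene_ids.isin(geneset)
    for motif, mult in motif_multipliers.items():
        rate = base_density * lengths.to_numpy(float)
        rate = np.where(in_mask, rate * mult, rate)
        counts = rng.poisson(rate)
        for g, c in zip(gene_ids, counts):
            if c > 0:
                rows.append((motif, g, int(c)))
    occurrences = pd.DataFrame(rows, columns=["motif_id", "sequence_id", "count"])
    truth = SimTruth(theta_true=float("nan"), seed=seed,
                     planted_motif_effects=dict(motif_multipliers))

    if emit_sequences:
        if motif_consensus is None:
            raise ValueError("emit_sequences requires motif_consensus strings")
        seqs = {}
        counts_by_gene = occurrences.pivot_table(
            index="sequence_id", columns="motif_id", values="count",
            aggfunc="sum", fill_value=0).reindex(gene_ids, fill_value=0)
        for g in gene_ids:
            length = int(lengths[g])
            seq = rng.choice(BASES, size=length)
            # planted matches overwrite the random background; the random
            # background itself may add chance matches on top
            for motif, cons in motif_consensus.items():
                k = int(counts_by_gene.loc[g, motif]) if motif in counts_by_gene else 0
                if k == 0:
                    continue
                pos = rng.choice(max(1, length - len(cons)), size=k, replace=False) \
                    if length - len(cons) >= k else np.arange(k)
                for p in pos:
                    seq[p : p + len(cons)] = list(cons)
            seqs[g] = "".join(seq)
        return seqs, lengths, geneset, truth
    return occurrences, lengths, geneset, truth


def two_exon_gene(gene_id: str, chrom: str, start: int,
                  exon_len: int = 200, intron_len: int = 300,
                  n_exons: int = 2, biotype: str = "protein_coding") -> Gene:
    """Convenience constructor for a simple multi-exon gene model."""
    exons = []
    pos = start
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len))
        pos += exon_len + intron_len
    tx = Transcript(transcript_id=f"{gene_id}.T1", exons=exons, biotype=biotype)
    return Gene(gene_id=gene_id, chrom=chrom, strand="+",
                transcripts={tx.transcript_id: tx}, biotype=biotype)


def simulate_gene_reads(
    models: GeneModels,
    incomplete_fraction: float | dict[str, float],
    n_fragments: int | dict[str, int],
    read_length: int = 50,
    seed: int = 0,
) -> list[ReadBlockSketch]:
    """Emit exon-only and intron-overlapping fragments per gene.

    Each fragment is a single aligned block: complete fragments fall
    inside a random exon, incomplete fragments inside a random intron of
    the gene's exon-union model. Whether a fragment is incomplete is an
    independent Bernoulli draw at the requested per-gene fraction.
    """
    rng = np.random.default_rng(seed)
    out: list[ReadBlockSketch] = []
    for gene in models:
        f = (incomplete_fraction.get(gene.gene_id, 0.0)
             if isinstance(incomplete_fraction, dict) else incomplete_fraction)
        n = (n_fragments.get(gene.gene_id, 0)
             if isinstance(n_fragments, dict) else n_fragments)
        introns = gene.intronic_space()
        exons = gene.exon_union()
        if f > 0 and not introns:
            raise ValueError(
                f"incomplete fraction requested for intronless gene {gene.gene_id}"
            )
        for i in range(n):
            incomplete = rng.random() < f
            pool = introns if incomplete else exons
            lo, hi = pool[rng.integers(len(pool))]
            span = hi - lo
            rl = min(read_length, span)
            start = lo + int(rng.integers(0, span - rl + 1))
            out.append(ReadBlockSketch(
                read_id=f"{gene.gene_id}_r{i}",
                blocks=[(gene.chrom, start, start + rl)],
            ))
    return out
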