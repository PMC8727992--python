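"""Localization gene classes and RBP motif-density enrichment.

Genes are classified from the signs of their median adjusted log2
Cyto/Nuc ratios in polyA and non-polyA libraries: cytosolic (both
positive), nuclear (both negative) or bivalent (cytosolic as polyA,
nuclear as non-polyA). Motif enrichment asks, per RBP motif, whether
motif density on each gene's representative isoform differs between a
gene class and the rest of the genes (rank-sum test, BH-FDR across
motifs). Densities (occurrences per nucleotide of isoform length) remove
the length bias a raw occurrence count would carry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from sfae._stats import bh_fdr, rank_sum_test

CLASS_CYTO = "cyto"
CLASS_NUC = "nuc"
CLASS_BIVALENT = "bivalent"
CLASS_UNCLASSIFIED = "unclassified"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def classify_genes(
    polya_medians: pd.Series | dict,
    nonpolya_medians: pd.Series | dict,
) -> pd.DataFrame:
    """Assign each gene to cyto / nuc / bivalent / unclassified.

    Rule on (polyA median, non-polyA median) signs: (+,+) cyto, (-,-) nuc,
    (+,-) bivalent; exact zeros, the (-,+) quadrant and genes with a
    missing median are unclassified. The same rule applies to
    log2(Number_Cyto/Number_Nuc) pairs from molecule-count data.
    """
    pa = pd.Series(polya_medians, dtype=float)
    npa = pd.Series(nonpolya_medians, dtype=float)
    genes = pa.index.union(npa.index)
    pa = pa.reindex(genes)
    npa = npa.reindex(genes)
    cls = pd.Series(CLASS_UNCLASSIFIED, index=genes, dtype=object)
    both = pa.notna() & npa.notna()
    cls[both & (pa > 0) & (npa > 0)] = CLASS_CYTO
    cls[both & (pa < 0) & (npa < 0)] = CLASS_NUC
    cls[both & (pa > 0) & (npa < 0)] = CLASS_BIVALENT
    return pd.DataFrame({
        "polyA_median_log2": pa,
        "nonpolyA_median_log2": npa,
        "gene_class": cls,
    })


def representative_isoform(
    isoform_expression: pd.DataFrame, gene_map: pd.Series | dict,
) -> pd.Series:
    """Per gene, the isoform with the highest total expression across cell
    lines; ties broken by lexicographically smallest isoform id."""
    gene_map = pd.Series(gene_map)
    missing = isoform_expression.index.difference(gene_map.index)
    if len(missing):
        raise ValueError(f"isoforms without a gene mapping: {list(missing[:5])}")
    totals = isoform_expression.sum(axis=1)
    df = pd.DataFrame({"gene": gene_map.reindex(isoform_expression.index),
                       "total": totals})
    # tie-break on isoform id: ids ascending within equal totals
    df = (df.reset_index(names="isoform")
            .sort_values(["gene", "total", "isoform"],
                         ascending=[True, False, True]))
    rep = df.groupby("gene", sort=True).first()["isoform"]
    rep.name = "representative_isoform"
    return rep


def motif_density(
    occurrences: pd.DataFrame, lengths: pd.Series | dict,
    sequences: list | None = None,
) -> pd.DataFrame:
    """Per (motif, sequence) density = occurrence count / sequence length.

    ``lengths`` maps every scored sequence to its length in nucleotides;
    sequences absent from the occurrence table get count 0 for every
    motif. Returns a sequences x motifs density matrix.
    """
    lengths = pd.Series(lengths, dtype=float)
    if sequences is None:
        sequences = lengths.index
    sequences = pd.Index(sequences)
    bad = lengths.reindex(sequences)
    missing = sequences[bad.isna() | (bad <= 0)]
    if len(missing):
        raise ValueError(
            f"missing or non-positive length for sequences: {list(missing[:5])}"
        )
    counts = occurrences.pivot_table(
        index="sequence_id", columns="motif_id", values="count",
        aggfunc="sum", fill_value=0,
    ).reindex(sequences, fill_value=0)
    return counts.div(lengths.reindex(sequences), axis=0)


@dataclass
class EnrichmentRow:
    motif_id: str
    geneset_id: str
    p_value: float
    q_value: float
    direction: str  # "enriched" | "depleted"
    median_in: float
    median_out: float


def motif_enrichment(
    densities: pd.DataFrame,
    geneset,
    geneset_id: str = "geneset",
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum enrichment of motif densities in a gene set vs the rest.

    ``densities`` is sequences(genes) x motifs; BH-FDR is applied across
    the motifs. A motif is called enriched when q < ``q_threshold`` and
    the in-set median density exceeds the out-set median.
    """
    geneset = pd.Index(sorted(set(geneset)))
    in_mask = densities.index.isin(geneset)
    if in_mask.sum() == 0 or (~in_mask).sum() == 0:
        raise ValueError("geneset and its complement must both be non-empty")
    rows = []
    for motif in densities.columns:
        col = densities[motif].to_numpy(float)
        a, b = col[in_mask], col[~in_mask]
        if np.all(col == col[0]):
            p = 1.0
        else:
            p = rank_sum_test(a, b).p_value
        med_in, med_out = float(np.median(a)), float(np.median(b))
        rows.append((motif, geneset_id, p,
                     "enriched" if med_in > med_out else "depleted",
                     med_in, med_out))
    out = pd.DataFrame(
        rows, columns=["motif_id", "geneset_id", "p_value", "direction",
                       "median_in", "median_out"],
    )
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = (out["q_value"] < q_threshold) & (out["direction"] == "enriched")
    return out[["motif_id", "geneset_id", "p_value", "q_value", "direction",
                "median_in", "median_out", "significant"]]


def _collapse(pref: str) -> str:
    return CLASS_CYTO if pref == CLASS_BIVALENT else pref


def species_concordance(
    human_results: pd.Series | dict,
    mouse_results: pd.Series | dict,
) -> pd.DataFrame:
    """Cross-species agreement of enriched-motif localization preferences.

    Inputs map motif id -> compartment preference (cyto/nuc/bivalent) for
    motifs called enriched in each species; bivalent collapses into cyto
    before comparison. Returns counts of shared motifs with same vs
    different preference plus motifs enriched in only one species.
    """
    h = {m: _collapse(v) for m, v in pd.Series(human_results).items()}
    m = {k: _collapse(v) for k, v in pd.Series(mouse_results).items()}
    shared = sorted(set(h) & set(m))
    same = sum(h[x] == m[x] for x in shared)
    different = len(shared) - same
    return pd.DataFrame({
        "category": ["same", "different", "human_only", "mouse_only"],
        "count": [same, different,
                  len(set(h) - set(m)), len(set(m) - set(h))],
    })


def scan_consensus(
    sequences: dict[str, str], motifs: dict[str, str],
) -> pd.DataFrame:
    """Count overlapping sense-strand matches of IUPAC consensus motifs.

    A deliberately simple consensus scanner for testing the enrichment
    path end-to-end without an external PWM scanner; cDNA inputs are
    sense-strand so only the given strand is scanned. Returns the
    (motif_id, sequence_id, count) occurrence table.
    """
    patterns = {}
    for mid, cons in motifs.items():
        bad = set(cons.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC character(s) {sorted(bad)} in motif {mid}")
        patterns[mid] = re.compile(
            "(?=" + "".join(IUPAC[ch] for ch in cons.upper()) + ")"
        )
    rows = []
    for sid, seq in sequences.items():
        seq = seq.upper().replace("U", "T")
        bad = set(seq) - {"A", "C", "G", "T", "N"}
        if bad:
            raise ValueError(f"invalid character(s) {sorted(bad)} in sequence {sid}")
        for mid, pat in patterns.items():
            count = sum(1 for _ in pat.finditer(seq))
            if count:
                rows.append((mid, sid, count))
    return pd.DataFrame(rows, columns=["motif_id", "sequence_id", "count"])
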