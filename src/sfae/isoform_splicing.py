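"""Isoform-level localization switching and splicing-completeness analyses.

Three analyses live here:

* a screen for genes whose two most abundant isoforms correlate in
  opposite directions with the per-gene CR across cell lines — candidate
  localization-switching isoforms;
* per-gene ratios of incompletely spliced (intron-overlapping) to fully
  spliced (exon-only) fragments, a proxy for unspliced transcript load in
  a fraction;
* summed intron length per gene, computed against the exon union of all
  annotated transcripts (default) or a representative isoform's gaps.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from sfae.types import GeneModels, ReadBlockSketch

logger = logging.getLogger(__name__)

MIN_PAIRED_CELL_LINES = 4
DEFAULT_MIN_ABS_R = 0.4
DEFAULT_MIN_MEDIAN_TPM = 3.0


def isoform_cr_correlation(
    per_gene_cr_matrix: pd.DataFrame,
    isoform_expression: pd.DataFrame,
    gene_map: pd.Series | dict,
    use_ratio: bool = True,
) -> pd.DataFrame:
    """Pearson correlation of each isoform with its gene's CR vector.

    The correlation target is the isoform *ratio* (isoform expression
    divided by summed gene expression per cell line) by default;
    ``use_ratio=False`` correlates raw isoform expression instead. At
    least 4 paired cell lines (both values defined) are required;
    constant vectors yield a missing r with a reason.
    """
    gene_map = pd.Series(gene_map)
    cell_lines = [c for c in isoform_expression.columns
                  if c in per_gene_cr_matrix.columns]
    iso = isoform_expression[cell_lines]
    genes = gene_map.reindex(iso.index)
    if genes.isna().any():
        raise ValueError("isoform without a gene mapping")
    gene_totals = iso.groupby(genes).transform("sum")
    rows = []
    for tx in iso.index:
        g = genes[tx]
        if g not in per_gene_cr_matrix.index:
            rows.append((tx, g, np.nan, 0, "gene has no CR vector"))
            continue
        cr = per_gene_cr_matrix.loc[g, cell_lines].to_numpy(float)
        if use_ratio:
            tot = gene_totals.loc[tx].to_numpy(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                target = np.where(tot > 0, iso.loc[tx].to_numpy(float) / tot, np.nan)
        else:
            target = iso.loc[tx].to_numpy(float)
        ok = np.isfinite(cr) & np.isfinite(target)
        if ok.sum() < MIN_PAIRED_CELL_LINES:
            rows.append((tx, g, np.nan, int(ok.sum()), "fewer than 4 paired cell lines"))
            continue
        x, y = cr[ok], target[ok]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append((tx, g, np.nan, int(ok.sum()), "constant vector"))
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", stats.NearConstantInputWarning)
            r = float(stats.pearsonr(x, y).statistic)
        rows.append((tx, g, r, int(ok.sum()), ""))
    return pd.DataFrame(
        rows, columns=["isoform_id", "gene_id", "r", "n_cell_lines", "reason"]
    ).set_index("isoform_id")


def screen_switch_genes(
    per_gene_cr_matrix: pd.DataFrame,
    isoform_expression: pd.DataFrame,
    gene_expression: pd.DataFrame,
    gene_map: pd.Series | dict,
    min_abs_r: float = DEFAULT_MIN_ABS_R,
    min_median_tpm: float = DEFAULT_MIN_MEDIAN_TPM,
    use_ratio: bool = True,
) -> pd.DataFrame:
    """Screen for localization-switching isoform pairs.

    For each gene with >= 2 isoforms, the two most abundant isoforms (by
    summed expression across cell lines, ties broken by isoform id) are
    correlated with the gene's CR vector. A gene passes when |r1| and
    |r2| both exceed ``min_abs_r``, the correlations have opposite signs
    and the gene's median expression across cell lines is at least
    ``min_median_tpm``. The positively correlated isoform is reported as
    exported (cytosolic), the negative one as retained (nuclear).
    """
    gene_map = pd.Series(gene_map)
    corr = isoform_cr_correlation(
        per_gene_cr_matrix, isoform_expression, gene_map, use_ratio=use_ratio,
    )
    totals = isoform_expression.sum(axis=1)
    order = (pd.DataFrame({"gene": gene_map.reindex(totals.index),
                           "total": totals})
             .reset_index(names="isoform")
             .sort_values(["gene", "total", "isoform"],
                          ascending=[True, False, True]))
    rows = []
    for gene, grp in order.groupby("gene", sort=True):
        if len(grp) < 2:
            continue
        iso1, iso2 = grp["isoform"].iloc[0], grp["isoform"].iloc[1]
        r1 = corr.loc[iso1, "r"]
        r2 = corr.loc[iso2, "r"]
        med = (float(np.median(gene_expression.loc[gene].to_numpy(float)))
               if gene in gene_expression.index else np.nan)
        reasons = []
        if not np.isfinite(r1) or not np.isfinite(r2):
            reasons.append("undefined correlation")
        else:
            if abs(r1) <= min_abs_r or abs(r2) <= min_abs_r:
                reasons.append(f"|r| <= {min_abs_r}")
            if np.sign(r1) == np.sign(r2):
                reasons.append("same correlation sign")
        if not np.isfinite(med) or med < min_median_tpm:
            reasons.append(f"median TPM < {min_median_tpm}")
        passes = not reasons
        exported = retained = None
        if passes:
            exported = iso1 if r1 > 0 else iso2
            retained = iso2 if r1 > 0 else iso1
        rows.append((gene, iso1, iso2, r1, r2, med, passes,
                     exported, retained, ";".join(reasons)))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "isoform1", "isoform2", "r1", "r2",
                 "median_gene_tpm", "passes", "exported_isoform",
                 "retained_isoform", "fail_reasons"],
    ).set_index("gene_id")


def biotype_switch_enrichment(
    screen: pd.DataFrame, isoform_biotypes: pd.Series | dict,
    coding_biotype: str = "protein_coding",
) -> tuple[pd.DataFrame, float]:
    """Fisher's exact test of coding status vs export direction.

    Builds the 2x2 table (exported/retained x coding/noncoding) over
    passing screen rows and returns (table, two-sided p). An empty margin
    leaves p as NaN with the table still reported.
    """
    bt = pd.Series(isoform_biotypes)
    passing = screen[screen["passes"]]
    missing = [tx for col in ("exported_isoform", "retained_isoform")
               for tx in passing[col] if tx not in bt.index]
    if missing:
        raise ValueError(f"isoforms without biotype annotation: {missing[:5]}")
    counts = np.zeros((2, 2), dtype=int)  # rows: exported, retained; cols: coding, noncoding
    for i, col in enumerate(("exported_isoform", "retained_isoform")):
        for tx in passing[col]:
            coding = bt[tx] == coding_biotype
            counts[i, 0 if coding else 1] += 1
    table = pd.DataFrame(counts, index=["exported", "retained"],
                         columns=["coding", "noncoding"])
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        return table, float("nan")
    p = float(stats.fisher_exact(counts, alternative="two-sided")[1])
    return table, p


@dataclass
class SpliceRatioRow:
    gene_id: str
    incomplete_count: int
    complete_count: int
    ignored_count: int

    @property
    def ratio(self) -> float:
        return (self.incomplete_count / self.complete_count
                if self.complete_count > 0 else float("nan"))

    @property
    def log_ratio(self) -> float:
        if self.incomplete_count > 0 and self.complete_count > 0:
            return math.log(self.incomplete_count / self.complete_count)
        return float("nan")


def _overlaps(block: tuple[int, int], intervals: list[tuple[int, int]]) -> bool:
    a, b = block
    return any(a < hi and lo < b for lo, hi in intervals)


def _within(block: tuple[int, int], intervals: list[tuple[int, int]]) -> bool:
    a, b = block
    return any(lo <= a and b <= hi for lo, hi in intervals)


def splice_completeness_ratio(
    reads: list[ReadBlockSketch], models: GeneModels,
) -> dict[str, SpliceRatioRow]:
    """Count incompletely vs fully spliced fragments per gene.

    A fragment is assigned to a gene when all its blocks fall within the
    gene's span (unstranded); fragments compatible with more than one
    gene are skipped. An assigned fragment is *incomplete* when any
    aligned base overlaps the gene's intronic space (span minus exon
    union over all transcripts), *complete* when every block lies within
    the exon union, and ignored otherwise. Genes with zero assigned
    fragments are omitted (count logged).
    """
    gene_list = list(models)
    spans = [(g.chrom, *g.span, g) for g in gene_list]
    exon_unions = {g.gene_id: g.exon_union() for g in gene_list}
    intronic = {g.gene_id: g.intronic_space() for g in gene_list}

    counts: dict[str, SpliceRatioRow] = {}
    for frag in reads:
        chroms = {c for c, _, _ in frag.blocks}
        if len(chroms) != 1:
            continue
        chrom = next(iter(chroms))
        blocks = [(s, e) for _, s, e in frag.blocks]
        lo, hi = blocks[0][0], blocks[-1][1]
        hits = [g for (gc, gs, ge, g) in spans
                if gc == chrom and gs <= lo and hi <= ge]
        if len(hits) != 1:
            continue
        gene = hits[0]
        row = counts.setdefault(
            gene.gene_id, SpliceRatioRow(gene.gene_id, 0, 0, 0))
        if any(_overlaps(b, intronic[gene.gene_id]) for b in blocks):
            row.incomplete_count += 1
        elif all(_within(b, exon_unions[gene.gene_id]) for b in blocks):
            row.complete_count += 1
        else:
            row.ignored_count += 1
    n_silent = len(gene_list) - len(counts)
    if n_silent:
        logger.info("splice_completeness_ratio: %d genes with no assigned reads",
                    n_silent)
    return counts


def summed_intron_length(
    models: GeneModels,
    policy: str = "exon_union",
    representative: pd.Series | dict | None = None,
) -> pd.Series:
    """Total intron length per gene in nucleotides.

    ``policy="exon_union"`` (default): gene span length minus exon-union
    length — bases covered by no annotated exon. ``policy="representative"``:
    sum of the representative isoform's inter-exon gaps; requires a
    gene -> isoform mapping (e.g. from
    :func:`sfae.genesets_motifs.representative_isoform`).
    """
    if policy == "exon_union":
        out = {g.gene_id: sum(b - a for a, b in g.intronic_space())
               for g in models}
    elif policy == "representative":
        if representative is None:
            raise ValueError("representative policy needs a gene -> isoform map")
        rep = pd.Series(representative)
        out = {}
        for g in models:
            tx_id = rep.get(g.gene_id)
            if tx_id is None or tx_id not in g.transcripts:
                raise ValueError(f"no representative isoform for gene {g.gene_id}")
            out[g.gene_id] = sum(b - a for a, b in g.transcripts[tx_id].intron_gaps())
    else:
        raise ValueError(f"unknown policy {policy!r}")
    s = pd.Series(out, dtype=int)
    s.name = f"summed_intron_length[{policy}]"
    return s
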