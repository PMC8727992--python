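import numpy as np
import pandas as pd
import pytest

from sfae.types import ExpressionTable, Gene, GeneModels, Transcript


@pytest.fixture
def tiny_table():
    values = pd.DataFrame(
        {
            "Cyto": [10.0, 2.0, 5.0],
            "Nuc": [2.0, 8.0, 5.0],
            "WC": [5.0, 4.0, 5.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    meta = pd.DataFrame(
        {
            "fraction": ["cytosol", "nucleus", "whole_cell"],
            "cell_line": ["K562"] * 3,
            "polya": ["polyA"] * 3,
        },
        index=["Cyto", "Nuc", "WC"],
    )
    return ExpressionTable(values=values, sample_meta=meta)


@pytest.fixture
def two_gene_models():
    """Two genes on chr1: one with an intron, one single-exon."""
    t1 = Transcript("tx1", exons=[(100, 300), (600, 800)], biotype="protein_coding")
    t2 = Transcript("tx2", exons=[(100, 800)], biotype="retained_intron")
    g1 = Gene("geneA", chrom="chr1", strand="+",
              transcripts={"tx1": t1, "tx2": t2}, biotype="protein_coding")
    t3 = Transcript("tx3", exons=[(2000, 2500)], biotype="lincRNA")
    g2 = Gene("geneB", chrom="chr1", strand="-",
              transcripts={"tx3": t3}, biotype="lincRNA")
    return GeneModels(genes={"geneA": g1, "geneB": g2})


@pytest.fixture
def intron_gene_models():
    """A single two-exon gene whose intron is not covered by any transcript."""
    t = Transcript("txI", exons=[(0, 1000), (2000, 3000)], biotype="protein_coding")
    g = Gene("geneI", chrom="chr2", strand="+", transcripts={"txI": t},
             biotype="protein_coding")
    return GeneModels(genes={"geneI": g})


GTF_TEXT = """\
chr1\ttest\tgene\t101\t800\t.\t+\t.\tgene_id "geneA"; gene_biotype "protein_coding";
chr1\ttest\ttranscript\t101\t800\t.\t+\t.\tgene_id "geneA"; transcript_id "tx1"; transcript_biotype "protein_coding";
chr1\ttest\texon\t601\t800\t.\t+\t.\tgene_id "geneA"; transcript_id "tx1";
chr1\ttest\texon\t101\t300\t.\t+\t.\tgene_id "geneA"; transcript_id "tx1";
chr1\ttest\tgene\t1\t300\t.\t-\t.\tgene_id "geneB";
chr1\ttest\ttranscript\t1\t300\t.\t-\t.\tgene_id "geneB"; transcript_id "tx2";
chr1\ttest\texon\t1\t100\t.\t-\t.\tgene_id "geneB"; transcript_id "tx2";
chr1\ttest\texon\t201\t300\t.\t-\t.\tgene_id "geneB"; transcript_id "tx2";
"""


@pytest.fixture
def gtf_file(tmp_path):
    path = tmp_path / "anno.gtf"
    path.write_text(GTF_TEXT)
    return path
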