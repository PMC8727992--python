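"""Readers and writers for the standard formats the toolkit touches.

Supported inputs: tab-separated expression tables (generic genes x samples
TSV or single-sample RSEM ``.genes.results``-style files), Ensembl-dialect
GTF annotation, FIMO motif-occurrence TSV (or a pre-aggregated
(motif, sequence, count) dialect) and plain FASTA. Internal genomic
coordinates are 0-based half-open; GTF's 1-based inclusive convention is
converted exactly at this boundary.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd

from sfae.types import ExpressionTable, Gene, GeneModels, Transcript

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# expression tables

def read_expression_table(
    path: str | Path,
    metadata: dict[str, dict[str, str]],
    unit: str = "TPM",
    gene_id_column: str | int = 0,
) -> ExpressionTable:
    """Read a genes x samples TSV into an :class:`ExpressionTable`.

    ``metadata`` maps every sample column to its labels, e.g.
    ``{"S1": {"fraction": "cytosol", "cell_line": "K562", "polya": "polyA"}}``.
    Non-numeric cells, negative values and duplicate gene ids are rejected.
    """
    df = pd.read_csv(path, sep="\t", index_col=gene_id_column, comment="#")
    unlabeled = [s for s in df.columns if s not in metadata]
    if unlabeled:
        raise ValueError(f"samples without metadata labels: {unlabeled}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric expression value in {path}: {exc}") from exc
    meta = pd.DataFrame.from_dict(metadata, orient="index").loc[list(df.columns)]
    meta["fraction"] = meta.get("fraction", "other")
    if "cell_line" not in meta.columns:
        meta["cell_line"] = "unknown"
    if "polya" not in meta.columns:
        meta["polya"] = "unknown"
    return ExpressionTable(values=df, sample_meta=meta, unit=unit)


def read_rsem_table(
    path: str | Path,
    sample_id: str,
    metadata: dict[str, str],
    value_column: str = "TPM",
    id_column: str = "gene_id",
) -> ExpressionTable:
    """Read one RSEM ``.genes.results``/``.isoforms.results``-style file.

    Selects ``value_column`` (``TPM`` by default, ``FPKM`` supported) as the
    single sample named ``sample_id``.
    """
    df = pd.read_csv(path, sep="\t")
    for col in (id_column, value_column):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in RSEM file {path}")
    values = df.set_index(id_column)[[value_column]].astype(float)
    values.columns = [sample_id]
    meta = pd.DataFrame.from_dict({sample_id: metadata}, orient="index")
    for col, default in (("fraction", "other"), ("cell_line", "unknown"),
                         ("polya", "unknown")):
        if col not in meta.columns:
            meta[col] = default
    return ExpressionTable(values=values, sample_meta=meta,
                           unit="FPKM" if value_column == "FPKM" else "TPM")


def write_expression_table(
    table: ExpressionTable, path: str | Path, float_format: str = "%.6g",
    header_comment: str | None = None,
) -> None:
    """Write the expression matrix as TSV (optionally with a # comment header)."""
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        table.values.to_csv(fh, sep="\t", float_format=float_format)


# ---------------------------------------------------------------------------
# gene annotation

def read_gene_annotation(path: str | Path) -> GeneModels:
    """Parse an Ensembl-dialect GTF into :class:`GeneModels`.

    Coordinates are converted from GTF 1-based inclusive to internal
    0-based half-open (start-1, end). Biotypes come from
    ``gene_biotype``/``transcript_biotype`` attributes when present, else
    ``"unknown"``. Exon lines are grouped under their ``transcript_id``
    parent; an exon without one is an error.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True, disable_infer_transcripts=True,
    )
    tx_meta: dict[str, tuple[str, str, str, str]] = {}  # tx -> (gene, chrom, strand, biotype)
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    gene_meta: dict[str, tuple[str, str, str]] = {}  # gene -> (chrom, strand, biotype)

    def attr1(feat, key, default=None):
        vals = feat.attributes.get(key)
        return vals[0] if vals else default

    for feat in db.all_features():
        if feat.featuretype == "gene":
            gid = attr1(feat, "gene_id")
            if gid is None:
                raise ValueError(f"gene feature without gene_id at {feat.seqid}:{feat.start}")
            gene_meta[gid] = (feat.seqid, feat.strand,
                              attr1(feat, "gene_biotype", "unknown"))
        elif feat.featuretype == "transcript":
            tid = attr1(feat, "transcript_id")
            gid = attr1(feat, "gene_id")
            if tid is None or gid is None:
                raise ValueError("transcript feature lacking transcript_id/gene_id")
            tx_meta[tid] = (gid, feat.seqid, feat.strand,
                            attr1(feat, "transcript_biotype", "unknown"))
            tx_exons.setdefault(tid, [])
        elif feat.featuretype == "exon":
            tid = attr1(feat, "transcript_id")
            if tid is None:
                raise ValueError(
                    f"exon without transcript parent at {feat.seqid}:{feat.start}"
                )
            # GTF 1-based inclusive -> 0-based half-open
            tx_exons.setdefault(tid, []).append((feat.start - 1, feat.end))
            if tid not in tx_meta:
                gid = attr1(feat, "gene_id")
                if gid is None:
                    raise ValueError(f"exon without transcript parent: {tid}")
                tx_meta[tid] = (gid, feat.seqid, feat.strand, "unknown")

    genes: dict[str, Gene] = {}
    for tid, (gid, chrom, strand, biotype) in tx_meta.items():
        exons = tx_exons.get(tid, [])
        if not exons:
            logger.warning("transcript %s has no exon lines; skipped", tid)
            continue
        if gid not in genes:
            g_chrom, g_strand, g_biotype = gene_meta.get(gid, (chrom, strand, "unknown"))
            genes[gid] = Gene(gene_id=gid, chrom=g_chrom, strand=g_strand,
                              transcripts={}, biotype=g_biotype)
        genes[gid].transcripts[tid] = Transcript(
            transcript_id=tid, exons=exons, biotype=biotype,
        )
    return GeneModels(genes=genes)


def write_gene_annotation(models: GeneModels, path: str | Path,
                          source: str = "sfae") -> None:
    """Write GeneModels back to GTF (1-based inclusive), the exact inverse
    of :func:`read_gene_annotation` on round-trip."""
    with open(path, "w") as fh:
        for gene in models:
            lo, hi = gene.span
            attrs = f'gene_id "{gene.gene_id}"; gene_biotype "{gene.biotype}";'
            fh.write("\t".join([gene.chrom, source, "gene", str(lo + 1), str(hi),
                                ".", gene.strand, ".", attrs]) + "\n")
            for tx in gene.transcripts.values():
                tlo, thi = tx.span
                tattrs = (f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                          f'transcript_biotype "{tx.biotype}";')
                fh.write("\t".join([gene.chrom, source, "transcript", str(tlo + 1),
                                    str(thi), ".", gene.strand, ".", tattrs]) + "\n")
                for a, b in tx.exons:
                    fh.write("\t".join([gene.chrom, source, "exon", str(a + 1),
                                        str(b), ".", gene.strand, ".", tattrs]) + "\n")


# ---------------------------------------------------------------------------
# motif occurrences

FIMO_REQUIRED = {"motif_id", "sequence_name"}


def read_motif_occurrences(
    path: str | Path, dialect: str = "fimo",
) -> pd.DataFrame:
    """Read motif occurrences into a (motif_id, sequence_id, count) table.

    ``dialect="fimo"`` expects FIMO's TSV match output (one row per match;
    rows are aggregated into counts). ``dialect="counts"`` expects a
    pre-aggregated TSV with columns motif_id, sequence_id, count.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if dialect == "fimo":
        if not FIMO_REQUIRED.issubset(df.columns):
            raise ValueError(
                f"unrecognized FIMO header in {path}: need columns {sorted(FIMO_REQUIRED)}"
            )
        if df.empty:
            return pd.DataFrame(columns=["motif_id", "sequence_id", "count"])
        if {"start", "stop"}.issubset(df.columns):
            if (df["start"].astype(float) < 0).any() or (df["stop"].astype(float) < 0).any():
                raise ValueError("negative match coordinates in FIMO file")
        counts = (
            df.groupby(["motif_id", "sequence_name"], sort=True)
            .size().rename("count").reset_index()
            .rename(columns={"sequence_name": "sequence_id"})
        )
        return counts
    if dialect == "counts":
        need = {"motif_id", "sequence_id", "count"}
        if not need.issubset(df.columns):
            raise ValueError(f"unrecognized counts header in {path}")
        if (df["count"].astype(float) < 0).any():
            raise ValueError("negative occurrence count")
        out = (
            df.groupby(["motif_id", "sequence_id"], sort=True)["count"]
            .sum().reset_index()
        )
        out["count"] = out["count"].astype(int)
        return out
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# FASTA (for the test-only consensus scanner and simulated sequences)

def read_fasta(path: str | Path) -> dict[str, str]:
    """Plain FASTA reader returning {id: sequence} (id = first token)."""
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            elif line:
                parts.append(line)
    if name is not None:
        seqs[name] = "".join(parts)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# read-block sketches (BAM-derivable fragment block lists)

def read_block_sketches(path: str | Path):
    """Read a (read_id, chrom, start, end) TSV into ReadBlockSketch records.

    Rows sharing a read_id are merged into one fragment. A documented
    one-liner derives this file from a BAM:
    ``bedtools bamtobed -split -i in.bam | awk '{print $4"\\t"$1"\\t"$2"\\t"$3}'``.
    """
    from sfae.types import ReadBlockSketch

    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["read_id", "chrom", "start", "end"])
    out = []
    for rid, grp in df.groupby("read_id", sort=False):
        blocks = [(r.chrom, int(r.start), int(r.end)) for r in grp.itertuples()]
        out.append(ReadBlockSketch(read_id=str(rid), blocks=blocks))
    return out


def write_block_sketches(sketches, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sk in sketches:
            for chrom, start, end in sk.blocks:
                fh.write(f"{sk.read_id}\t{chrom}\t{start}\t{end}\n")
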