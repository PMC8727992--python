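"""Domain containers shared across the toolkit.

Conventions
-----------
* All genomic coordinates are 0-based half-open internally; conversion to
  and from the GTF 1-based inclusive convention happens only in
  :mod:`sfae.io_formats`.
* Expression values are per-sample normalized units (TPM or FPKM); the
  unit is recorded in metadata and the estimator treats both identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FRACTION_LABELS = frozenset({"cytosol", "nucleus", "whole_cell", "other"})
POLYA_LABELS = frozenset({"polyA", "nonpolyA", "unknown"})


@dataclass
class ExpressionTable:
    """Genes x samples non-negative expression matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample; entries
        are non-negative finite reals (TPM or FPKM).
    sample_meta
        DataFrame indexed by sample id with columns ``fraction``
        (one of ``cytosol``/``nucleus``/``whole_cell``/``other``),
        ``cell_line`` and ``polya`` (``polyA``/``nonpolyA``/``unknown``).
    unit
        Expression unit label, ``"TPM"`` or ``"FPKM"``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    unit: str = "TPM"

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dupes = v.index[v.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            bad = v.columns[np.where(~np.isfinite(arr))[1]].unique().tolist()
            raise ValueError(f"non-finite expression values in samples {bad}")
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression value for gene {v.index[g]!r} "
                f"in sample {v.columns[s]!r}"
            )
        missing = set(v.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if "fraction" not in self.sample_meta.columns:
            raise ValueError("sample_meta must have a 'fraction' column")
        bad_frac = set(self.sample_meta["fraction"]) - FRACTION_LABELS
        if bad_frac:
            raise ValueError(f"unknown fraction labels: {sorted(bad_frac)}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_for(self, fraction: str, **meta) -> list[str]:
        """Sample ids matching a fraction label and optional metadata equality filters."""
        sel = self.sample_meta["fraction"] == fraction
        for key, val in meta.items():
            sel &= self.sample_meta[key] == val
        return [s for s in self.sample_meta.index[sel] if s in self.values.columns]


@dataclass
class Transcript:
    transcript_id: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, non-overlapping
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        self.exons = sorted((int(a), int(b)) for a, b in self.exons)
        for (a, b), (c, _) in zip(self.exons, self.exons[1:]):
            if c < b:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        """Spliced (mature) length in nucleotides."""
        return sum(b - a for a, b in self.exons)

    def intron_gaps(self) -> list[tuple[int, int]]:
        return [
            (b, c) for (_, b), (c, _) in zip(self.exons, self.exons[1:]) if c > b
        ]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript]
    biotype: str = "unknown"

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts.values()))
        return min(starts), max(ends)

    def exon_union(self) -> list[tuple[int, int]]:
        """Merged union of all transcripts' exon intervals."""
        ivs = sorted(
            iv for t in self.transcripts.values() for iv in t.exons
        )
        merged: list[tuple[int, int]] = []
        for a, b in ivs:
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        return merged

    def intronic_space(self) -> list[tuple[int, int]]:
        """Gene span minus the exon union: bases covered by no annotated exon."""
        lo, hi = self.span
        out, cur = [], lo
        for a, b in self.exon_union():
            if a > cur:
                out.append((cur, a))
            cur = max(cur, b)
        if cur < hi:
            out.append((cur, hi))
        return out


@dataclass
class GeneModels:
    """Per-gene transcript models keyed by gene id."""

    genes: dict[str, Gene]

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> Gene:
        return self.genes[gene_id]

    def __iter__(self):
        return iter(self.genes.values())

    def transcript_to_gene(self) -> dict[str, str]:
        return {
            t: g.gene_id for g in self.genes.values() for t in g.transcripts
        }


@dataclass
class ReadBlockSketch:
    """Minimal fragment representation: read id plus sorted aligned blocks.

    Mate blocks of a paired fragment are merged into the same record; blocks
    are (chrom, start, end) with 0-based half-open coordinates.
    """

    read_id: str
    blocks: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks)
        for (ca, _, b), (cb, c, _) in zip(self.blocks, self.blocks[1:]):
            if ca == cb and c < b:
                raise ValueError(f"overlapping blocks in fragment {self.read_id}")


@dataclass
class FractionTriplet:
    """Filtered, strictly positive (Cytosol, Nucleus, WC) expression vectors."""

    gene_ids: np.ndarray
    c: np.ndarray
    n_vec: np.ndarray
    w: np.ndarray
    n_removed_nonpositive: int = 0
    n_removed_out_of_range: int = 0

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        self.n_vec = np.asarray(self.n_vec, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.gene_ids = np.asarray(self.gene_ids)
        lens = {len(self.gene_ids), len(self.c), len(self.n_vec), len(self.w)}
        if len(lens) != 1:
            raise ValueError("triplet vectors must be equally long")
        if len(self.c) == 0:
            raise ValueError("empty estimation set: no genes survive filtering")
        for name, v in (("cytosol", self.c), ("nucleus", self.n_vec), ("WC", self.w)):
            if not (v > 0).all():
                raise ValueError(f"non-positive {name} value in FractionTriplet")
        lo = np.minimum(self.c, self.n_vec)
        hi = np.maximum(self.c, self.n_vec)
        if ((self.w < lo) | (self.w > hi)).any():
            raise ValueError("WC value outside the [min(C,N), max(C,N)] range")

    @property
    def n_genes(self) -> int:
        return len(self.c)


@dataclass
class FractionSet:
    """k >= 2 positive fraction vectors plus WC; weights filled by estimation."""

    gene_ids: np.ndarray
    fractions: pd.DataFrame  # genes x k fraction columns, strictly positive
    w: np.ndarray
    weights: np.ndarray | None = None
    non_identifiable: bool = False

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.fractions.shape[1] < 2:
            raise ValueError("FractionSet needs at least two fractions")
        if len(self.w) != self.fractions.shape[0]:
            raise ValueError("WC vector length mismatch")
        if not (self.fractions.to_numpy() > 0).all() or not (self.w > 0).all():
            raise ValueError("FractionSet requires strictly positive values")
        if self.weights is not None:
            wts = np.asarray(self.weights, dtype=float)
            if (wts < -1e-12).any() or abs(wts.sum() - 1) > 1e-9:
                raise ValueError("weights must lie on the simplex")

    @property
    def n_genes(self) -> int:
        return self.fractions.shape[0]

    @property
    def k(self) -> int:
        return self.fractions.shape[1]


@dataclass
class CREstimate:
    """Result of the mixture-weight estimation.

    ``theta`` is the cytosolic ratio CR in [0, 1]; ``e_min`` the minimized
    mean squared log-ratio error; ``profile`` an optional (theta, E) grid
    for error-curve plots.
    """

    theta: float
    e_min: float
    n_genes: int
    converged: bool = True
    profile: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if self.e_min < 0:
            raise ValueError("e_min must be non-negative")


@dataclass
class SimTruth:
    """Ground truth emitted by the synthetic-data generators."""

    theta_true: float | np.ndarray
    seed: int
    noise_sdlog: float = 0.0
    cyto_molecules: np.ndarray | None = None
    nuc_molecules: np.ndarray | None = None
    planted_switch_genes: set[str] = field(default_factory=set)
    planted_motif_effects: dict[str, float] = field(default_factory=dict)
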