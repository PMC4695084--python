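"""Junction and gene expression with cross-tissue library-size normalization.

Raw junction expression is the number of reads spanning the junction in a
tissue.  Raw gene expression is mean exonic read depth: total aligned bases
falling on the gene's exon union, divided by the exon-union length.  Both are
placed on a common scale across tissues by scaling each tissue's raw values
by ``mean(N) / N_t`` where ``N_t`` is the tissue's total aligned read count
(each paired-end mate counted separately).  This resembles RPKM but
normalizes to the mean library size rather than per-million reads, so values
remain on a read-count-like scale and a single presence threshold applies to
junctions and genes alike.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .annotation import GeneModel
from .catalog import JunctionKey, JunctionEvidence

__all__ = [
    "LibrarySizes",
    "ExpressionMatrix",
    "junction_counts",
    "exonic_coverage",
    "gene_expression",
    "normalize",
    "count_aligned_reads",
    "depth_arrays",
    "write_bedgraph",
]


@dataclass(frozen=True)
class LibrarySizes:
    """Total aligned reads per tissue (paired-end mates counted separately)."""

    sizes: Mapping[str, int]

    def __post_init__(self):
        for tissue, n in self.sizes.items():
            if n <= 0:
                raise ValueError(f"library size for {tissue} must be positive, got {n}")

    @property
    def mean(self) -> float:
        return sum(self.sizes.values()) / len(self.sizes)

    def __getitem__(self, tissue: str) -> int:
        return self.sizes[tissue]


@dataclass
class ExpressionMatrix:
    """Entities (junction ids or gene ids) x tissues, values >= 0.

    ``data`` is a pandas DataFrame with entity-string index and tissue
    columns; absent combinations are 0.
    """

    data: pd.DataFrame
    kind: str                 # "junction" | "gene"
    normalized: bool = False

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="entity")

    @classmethod
    def from_tsv(cls, path, kind: str, normalized: bool = False) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="entity")
        return cls(df, kind=kind, normalized=normalized)


def junction_counts(evidence_by_tissue) -> ExpressionMatrix:
    """Raw junction x tissue spanning-read counts.

    ``evidence_by_tissue`` maps tissue -> {JunctionKey: JunctionEvidence or
    int count}; it may also be a sequence of (tissue, mapping) pairs, in
    which case a repeated tissue id is an error.
    """
    if not isinstance(evidence_by_tissue, Mapping):
        seen = {}
        for tissue, mapping in evidence_by_tissue:
            if tissue in seen:
                raise ValueError(f"duplicate tissue id: {tissue}")
            seen[tissue] = mapping
        evidence_by_tissue = seen
    columns = {}
    for tissue, mapping in evidence_by_tissue.items():
        col = {}
        for key, ev in mapping.items():
            count = ev.read_count if isinstance(ev, JunctionEvidence) else int(ev)
            col[str(key)] = count
        columns[tissue] = col
    df = pd.DataFrame(columns).fillna(0.0)
    df = df[list(evidence_by_tissue)]  # preserve tissue order
    df = df.sort_index()
    return ExpressionMatrix(df, kind="junction", normalized=False)


def depth_arrays(source, chrom_lengths: Mapping[str, int],
                 include_secondary: bool = False) -> tuple[dict, int]:
    """Per-chromosome per-base read depth from aligned blocks.

    Skip (intron) segments of spliced reads contribute no depth.  Returns
    (depths, n_unknown_chrom) where reads on chromosomes absent from
    ``chrom_lengths`` are tallied and skipped.
    """
    depths = {c: np.zeros(l, dtype=np.int64) for c, l in chrom_lengths.items()}
    n_unknown = 0

    def _reads():
        if isinstance(source, str) or hasattr(source, "__fspath__"):
            with pysam.AlignmentFile(str(source), "r", check_sq=False) as fh:
                yield from fh
        else:
            yield from source

    for read in _reads():
        if read.is_unmapped:
            continue
        if not include_secondary and (read.is_secondary or read.is_supplementary):
            continue
        arr = depths.get(read.reference_name)
        if arr is None:
            n_unknown += 1
            continue
        for start, end in read.get_blocks():
            arr[start:end] += 1
    return depths, n_unknown


def exonic_coverage(source, gene_models: Mapping[str, GeneModel],
                    chrom_lengths: Mapping[str, int] | None = None,
                    include_secondary: bool = False) -> dict:
    """Total aligned bases over each gene's exon union.

    ``source`` is a SAM path or an iterable of alignments.  When
    ``chrom_lengths`` is omitted it is taken from the SAM header.
    """
    if chrom_lengths is None:
        with pysam.AlignmentFile(str(source), "r", check_sq=False) as fh:
            chrom_lengths = dict(zip(fh.references, fh.lengths))
    depths, _ = depth_arrays(source, chrom_lengths, include_secondary)
    totals = {}
    for gene_id, gene in gene_models.items():
        arr = depths.get(gene.chrom)
        if arr is None:
            totals[gene_id] = 0
            continue
        totals[gene_id] = int(sum(arr[s:e].sum() for s, e in gene.exons))
    return totals


def gene_expression(coverage_by_tissue: Mapping[str, Mapping[str, int]],
                    gene_models: Mapping[str, GeneModel],
                    protein_coding_only: bool = True) -> ExpressionMatrix:
    """Mean exonic depth per gene per tissue: coverage total / exon-union length."""
    genes = {
        gid: g for gid, g in gene_models.items()
        if not protein_coding_only or g.biotype == "protein_coding"
    }
    for gid, g in genes.items():
        if g.length == 0:
            raise ValueError(f"gene {gid} has zero exon-union length")
    df = pd.DataFrame(
        {
            tissue: {gid: totals.get(gid, 0) / genes[gid].length for gid in genes}
            for tissue, totals in coverage_by_tissue.items()
        }
    )
    df = df[list(coverage_by_tissue)].sort_index()
    return ExpressionMatrix(df, kind="gene", normalized=False)


def normalize(matrix: ExpressionMatrix, sizes: LibrarySizes) -> ExpressionMatrix:
    """Scale tissue t's raw values by mean(N) / N_t.

    Linear and invertible given the sizes; equal library sizes leave the
    matrix unchanged.
    """
    missing = set(matrix.data.columns) - set(sizes.sizes)
    if missing:
        raise ValueError(f"library sizes missing for tissues: {sorted(missing)}")
    mean = sizes.mean
    factors = pd.Series({t: mean / sizes[t] for t in matrix.data.columns})
    return ExpressionMatrix(matrix.data * factors, kind=matrix.kind, normalized=True)


def count_aligned_reads(path, include_secondary: bool = False) -> int:
    """Aligned records in a SAM file; each paired-end mate counts once."""
    n = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for read in fh:
            if read.is_unmapped:
                continue
            if not include_secondary and (read.is_secondary or read.is_supplementary):
                continue
            n += 1
    return n


def write_bedgraph(depths: Mapping[str, np.ndarray], path) -> None:
    """Run-length-encoded per-base depth, zero runs omitted."""
    with open(path, "w") as fh:
        for chrom in sorted(depths):
            arr = depths[chrom]
            if arr.size == 0:
                continue
            boundaries = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], boundaries))
            ends = np.concatenate((boundaries, [arr.size]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v}\n")
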