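"""Intron annotation: known-intron index, donor/acceptor sites, gene models.

Junctions found in the data are compared against a reference intron set.  A
junction whose interval matches a known intron is *annotated*; otherwise it
is sub-classified by whether its two boundary positions individually match
any annotated donor/acceptor site: both sites known (a new pairing of known
sites), exactly one known, or neither.  The three novel classes partition the
unannotated junctions.

Donor/acceptor orientation follows transcript strand: on ``+`` the donor is
the intron start and the acceptor the intron end; on ``-`` the roles swap.
Site matching ignores strand when the query junction's strand is unknown
(unstranded libraries), and respects it otherwise.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .catalog import JunctionKey

__all__ = [
    "GeneModel",
    "AnnotationIndex",
    "JUNCTION_CLASSES",
    "build_annotation_index",
    "classify_junction",
    "classification_table",
    "read_intron_bed",
    "write_intron_bed",
    "read_introns_gtf",
]

JUNCTION_CLASSES = ("annotated", "novel_both_sites", "novel_one_site", "novel_neither")


def _merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


@dataclass(frozen=True)
class GeneModel:
    """A gene as its exon union on one chromosome.

    ``exons`` are 0-based half-open intervals; overlapping inputs are merged,
    so the stored tuple is the sorted, disjoint exon union.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple
    biotype: str = "protein_coding"

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        object.__setattr__(self, "exons", _merge_intervals(self.exons))

    @property
    def multi_exon(self) -> bool:
        return len(self.exons) >= 2

    @property
    def length(self) -> int:
        """Exon-union length in bp."""
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def introns(self) -> list[JunctionKey]:
        """Gaps between consecutive exon-union intervals."""
        return [
            JunctionKey(self.chrom, self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]


@dataclass(frozen=True)
class AnnotationIndex:
    """Known introns plus the derived donor/acceptor site sets."""

    known_introns: frozenset  # {(chrom, start, end)}
    donor_sites: frozenset    # {(chrom, pos, strand)}
    acceptor_sites: frozenset

    @property
    def site_positions(self) -> frozenset:
        """Strand-blind (chrom, pos) union of donor and acceptor sites."""
        return frozenset((c, p) for c, p, _ in self.donor_sites | self.acceptor_sites)

    def has_site(self, chrom: str, pos: int, strand: str = ".") -> bool:
        if strand in ("+", "-"):
            return ((chrom, pos, strand) in self.donor_sites
                    or (chrom, pos, strand) in self.acceptor_sites)
        return (chrom, pos) in self._positions

    def __post_init__(self):
        object.__setattr__(self, "_positions", self.site_positions)


def build_annotation_index(intron_records: Iterable[tuple]) -> AnnotationIndex:
    """Index introns given as ``(chrom, start, end, strand)`` tuples.

    The donor site is the 5' intron boundary with respect to strand (start on
    ``+``, end on ``-``) and the acceptor the 3' boundary.  Unstranded
    records contribute their start as donor and end as acceptor.  Zero- or
    negative-length intervals are rejected.
    """
    known: set[tuple] = set()
    donors: set[tuple] = set()
    acceptors: set[tuple] = set()
    n_rejected = 0
    for chrom, start, end, strand in intron_records:
        if end <= start:
            n_rejected += 1
            continue
        known.add((chrom, start, end))
        if strand == "-":
            donors.add((chrom, end, strand))
            acceptors.add((chrom, start, strand))
        else:
            donors.add((chrom, start, strand))
            acceptors.add((chrom, end, strand))
    index = AnnotationIndex(frozenset(known), frozenset(donors), frozenset(acceptors))
    return index


def classify_junction(key: JunctionKey, index: AnnotationIndex, strand: str = ".") -> str:
    """Classify one junction against the index.

    Returns ``annotated`` when the interval is a known intron, otherwise one
    of the three novel classes by boundary-site membership.
    """
    if (key.chrom, key.start, key.end) in index.known_introns:
        return "annotated"
    start_known = index.has_site(key.chrom, key.start, strand)
    end_known = index.has_site(key.chrom, key.end, strand)
    if start_known and end_known:
        return "novel_both_sites"
    if start_known or end_known:
        return "novel_one_site"
    return "novel_neither"


def classify_junctions(keys: Iterable[JunctionKey], index: AnnotationIndex) -> dict:
    return {k: classify_junction(k, index) for k in keys}


def classification_table(junctions: Iterable[JunctionKey], index: AnnotationIndex) -> dict:
    """Counts per class; the four classes partition the input."""
    counts = Counter(classify_junction(k, index) for k in junctions)
    return {cls: counts.get(cls, 0) for cls in JUNCTION_CLASSES}


# --- readers / writers -----------------------------------------------------

def read_intron_bed(path) -> list[tuple]:
    """BED intervals (0-based half-open) as intron records.

    Columns beyond chrom/start/end are optional; strand is column 6 when
    present, else '.'.
    """
    records = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) > 5 else "."
            records.append((chrom, start, end, strand))
    return records


def write_intron_bed(intron_records: Iterable[tuple], path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, strand in sorted(intron_records):
            fh.write(f"{chrom}\t{start}\t{end}\tintron\t0\t{strand}\n")


def _gtf_attr(attrs: str, name: str) -> str | None:
    for attr in attrs.split(";"):
        attr = attr.strip()
        if attr.startswith(name):
            return attr.split(None, 1)[1].strip('"')
    return None


def read_gene_models_gtf(path) -> dict:
    """Gene models from GTF exon records grouped by ``gene_id``.

    Exons are merged to the exon union per gene; GTF's 1-based inclusive
    coordinates are converted to 0-based half-open.
    """
    exons_by_gene: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            gid = _gtf_attr(fields[8], "gene_id")
            if gid is None:
                continue
            biotype = _gtf_attr(fields[8], "gene_biotype") or "protein_coding"
            exons_by_gene.setdefault(gid, []).append((int(fields[3]) - 1, int(fields[4])))
            meta[gid] = (fields[0], fields[6], biotype)
    return {
        gid: GeneModel(gid, meta[gid][0], meta[gid][1], tuple(exons), biotype=meta[gid][2])
        for gid, exons in exons_by_gene.items()
    }


def write_gene_models_gtf(genes: Mapping[str, GeneModel], path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(genes):
            g = genes[gid]
            for s, e in g.exons:
                fh.write(
                    f"{g.chrom}\tjuncspect\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f'gene_id "{gid}"; transcript_id "{gid}.t1"; gene_biotype "{g.biotype}";\n'
                )


def read_introns_gtf(path) -> list[tuple]:
    """Derive introns from GTF exon records as gaps between consecutive
    exons of each transcript.

    GTF is 1-based inclusive; the returned intron records are 0-based
    half-open: for consecutive exons ``..e1] [s2..`` the intron is
    ``[e1, s2-1)`` in 0-based coordinates.
    """
    by_transcript: dict[str, list] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "exon":
                continue
            chrom, start, end, strand, attrs = fields[0], int(fields[3]), int(fields[4]), fields[6], fields[8]
            tid = None
            for attr in attrs.split(";"):
                attr = attr.strip()
                if attr.startswith("transcript_id"):
                    tid = attr.split(None, 1)[1].strip('"')
                    break
            if tid is None:
                continue
            by_transcript.setdefault(tid, []).append((chrom, start - 1, end, strand))
    records = []
    for exons in by_transcript.values():
        exons.sort(key=lambda x: x[1])
        for (chrom, _s1, e1, strand), (_c2, s2, _e2, _st2) in zip(exons, exons[1:]):
            if s2 > e1:
                records.append((chrom, e1, s2, strand))
    return records
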