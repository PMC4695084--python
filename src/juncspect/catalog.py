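"""Splice-junction extraction from spliced alignments.

A spliced alignment encodes each excised intron as an ``N`` (reference skip)
operation in its CIGAR.  Every distinct skip interval observed in a SAM file
is a putative splice junction; the reads spanning it carry the evidence used
downstream to separate real junctions from alignment artifacts:

* the distribution of read alignment-start offsets around the junction
  (reads stacked at a single offset are the signature of a mis-alignment,
  quantified as Shannon entropy of the offset distribution),
* the mean per-read edit distance (``NM`` tag), and
* the implied intron length.

Coordinates are 0-based half-open internally; SAM's 1-based positions are
converted at the boundary by pysam.  Junctions are keyed by interval only, so
evidence from both strands merges; the strand (``XS`` tag majority vote) is
kept on the evidence object for reporting.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple, Union

import pysam

__all__ = [
    "JunctionKey",
    "JunctionEvidence",
    "JunctionStats",
    "ExtractionQC",
    "ExtractionResult",
    "extract_junctions",
    "merge_catalogs",
    "junction_entropy",
    "average_mismatches",
    "compute_stats",
    "write_catalog",
    "read_catalog",
]

# CIGAR operation codes that consume the reference.
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X
_SKIP = 3  # N


class JunctionKey(NamedTuple):
    """A putative intron: ``[start, end)`` on ``chrom``, 0-based half-open."""

    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # stable id used in matrices and TSVs
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_string(cls, s: str) -> "JunctionKey":
        chrom, _, span = s.rpartition(":")
        start, _, end = span.partition("-")
        return cls(chrom, int(start), int(end))


@dataclass
class JunctionEvidence:
    """Supporting reads for one junction.

    ``offsets`` maps a read's leftmost aligned position minus the junction's
    intron start (always negative: the read starts upstream of the intron) to
    the number of spanning reads aligned there.
    """

    key: JunctionKey
    offsets: Counter = field(default_factory=Counter)
    mismatches: list = field(default_factory=list)
    strands: Counter = field(default_factory=Counter)

    @property
    def read_count(self) -> int:
        return sum(self.offsets.values())

    @property
    def strand(self) -> str:
        """Majority strand among spanning reads' XS tags; '.' if unseen."""
        if not self.strands:
            return "."
        return self.strands.most_common(1)[0][0]

    def add_read(self, offset: int, mismatch: int, strand: str | None = None) -> None:
        self.offsets[offset] += 1
        self.mismatches.append(mismatch)
        if strand:
            self.strands[strand] += 1

    def merge(self, other: "JunctionEvidence") -> "JunctionEvidence":
        if other.key != self.key:
            raise ValueError(f"cannot merge evidence for {other.key} into {self.key}")
        out = JunctionEvidence(self.key)
        out.offsets = self.offsets + other.offsets
        out.mismatches = self.mismatches + other.mismatches
        out.strands = self.strands + other.strands
        return out


@dataclass(frozen=True)
class JunctionStats:
    """Per-junction summary used by the filters."""

    entropy: float
    avg_mismatch: float
    intron_length: int
    read_count: int


@dataclass
class ExtractionQC:
    n_records: int = 0
    n_unmapped: int = 0
    n_secondary_skipped: int = 0
    n_malformed: int = 0
    n_spliced: int = 0


@dataclass
class ExtractionResult:
    junctions: dict
    qc: ExtractionQC

    def __iter__(self) -> Iterator[JunctionKey]:
        return iter(self.junctions)

    def __len__(self) -> int:
        return len(self.junctions)

    def __getitem__(self, key: JunctionKey) -> JunctionEvidence:
        return self.junctions[key]


def _iter_alignments(source) -> Iterator[pysam.AlignedSegment]:
    if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
        with pysam.AlignmentFile(str(source), "r", check_sq=False) as fh:
            yield from fh
    else:
        yield from source


def extract_junctions(source, include_secondary: bool = False) -> ExtractionResult:
    """Collect one :class:`JunctionEvidence` per distinct skip interval.

    ``source`` is a SAM path or an iterable of ``pysam.AlignedSegment``.  A
    read with *k* skip operations contributes to *k* junctions, each with the
    same offset (read leftmost aligned position minus that junction's intron
    start).  Mismatches are the whole-read edit distance (``NM``; 0 if
    absent).  Unmapped reads are ignored; secondary/supplementary alignments
    are skipped unless ``include_secondary``.  Reads whose CIGAR is missing
    are tallied as malformed and skipped.
    """
    junctions: dict[JunctionKey, JunctionEvidence] = {}
    qc = ExtractionQC()
    for read in _iter_alignments(source):
        qc.n_records += 1
        if read.is_unmapped:
            qc.n_unmapped += 1
            continue
        if not include_secondary and (read.is_secondary or read.is_supplementary):
            qc.n_secondary_skipped += 1
            continue
        cigar = read.cigartuples
        if not cigar:
            qc.n_malformed += 1
            continue
        if not any(op == _SKIP for op, _ in cigar):
            continue
        qc.n_spliced += 1
        nm = read.get_tag("NM") if read.has_tag("NM") else 0
        xs = read.get_tag("XS") if read.has_tag("XS") else None
        chrom = read.reference_name
        read_start = read.reference_start
        pos = read_start
        for op, ln in cigar:
            if op == _SKIP:
                key = JunctionKey(chrom, pos, pos + ln)
                ev = junctions.get(key)
                if ev is None:
                    ev = junctions[key] = JunctionEvidence(key)
                ev.add_read(read_start - key.start, nm, xs)
            if op in _REF_CONSUMING:
                pos += ln
    return ExtractionResult(junctions, qc)


def merge_catalogs(*catalogs: Mapping[JunctionKey, JunctionEvidence]) -> dict:
    """Union of junction catalogs with per-junction evidence summed.

    Extracting from the concatenation of two SAM files is equivalent to
    merging their separately extracted catalogs.
    """
    out: dict[JunctionKey, JunctionEvidence] = {}
    for cat in catalogs:
        mapping = cat.junctions if isinstance(cat, ExtractionResult) else cat
        for key, ev in mapping.items():
            out[key] = out[key].merge(ev) if key in out else ev
    return out


def junction_entropy(offset_histogram: Mapping[int, int], log_base: float = 2.0) -> float:
    """Shannon entropy S = -sum p_i log(p_i) of the spanning-read offsets.

    ``p_i`` is the fraction of spanning reads whose alignment starts at
    offset ``i``.  A junction supported at a single offset scores 0; uniform
    support over *k* offsets scores ``log_base(k)``.  Base 2 by default (see
    the filtering module for why the 0.75 threshold presumes base 2).
    """
    counts = [c for c in offset_histogram.values() if c > 0]
    if not counts:
        raise ValueError("entropy of an empty offset histogram is undefined")
    total = sum(counts)
    log = math.log
    s = -sum((c / total) * log(c / total) for c in counts)
    return s / log(log_base)


def average_mismatches(mismatch_counts: Iterable[int]) -> float:
    """Arithmetic mean mismatches per spanning read."""
    counts = list(mismatch_counts)
    if not counts:
        raise ValueError("average mismatches of zero reads is undefined")
    return sum(counts) / len(counts)


def compute_stats(evidence: JunctionEvidence, log_base: float = 2.0) -> JunctionStats:
    return JunctionStats(
        entropy=junction_entropy(evidence.offsets, log_base),
        avg_mismatch=average_mismatches(evidence.mismatches),
        intron_length=evidence.key.length,
        read_count=evidence.read_count,
    )


_CATALOG_COLUMNS = (
    "chrom\tintron_start\tintron_end\tstrand\tread_count\tentropy\tavg_mismatch\tintron_length"
)


def write_catalog(stats: Mapping[JunctionKey, JunctionStats], path,
                  strands: Mapping[JunctionKey, str] | None = None) -> None:
    """Write the junction catalog as TSV, sorted by coordinate."""
    with open(path, "w") as fh:
        fh.write(_CATALOG_COLUMNS + "\n")
        for key in sorted(stats):
            st = stats[key]
            strand = strands.get(key, ".") if strands else "."
            fh.write(
                f"{key.chrom}\t{key.start}\t{key.end}\t{strand}\t{st.read_count}"
                f"\t{st.entropy:.6f}\t{st.avg_mismatch:.6f}\t{st.intron_length}\n"
            )


def read_catalog(path) -> dict[JunctionKey, JunctionStats]:
    out: dict[JunctionKey, JunctionStats] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            chrom, start, end, _strand, rc, ent, mm, ln = line.rstrip("\n").split("\t")
            out[JunctionKey(chrom, int(start), int(end))] = JunctionStats(
                entropy=float(ent), avg_mismatch=float(mm),
                intron_length=int(ln), read_count=int(rc),
            )
    return out
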