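"""Junction BED12 tracks, concept-score normalization, output manifests.

The junction track dialect draws each junction as the last base of the
upstream exon and the first base of the downstream exon as two 1 bp thick
boxes connected by a thin line, so a genome browser shows the splice rather
than the intron body: ``chromStart = intron_start - 1``, ``chromEnd =
intron_end + 1``, two blocks of size 1 at relative starts 0 and
``intron_length + 1``.  The score is the spanning-read count capped at the
BED maximum of 1000.  For a multi-tissue tissue-specific track the name
field carries the tissue and each tissue gets a fixed color.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .catalog import JunctionKey

__all__ = [
    "JunctionBedRecord",
    "write_junction_bed",
    "junction_bed_lines",
    "parse_junction_bed",
    "validate_bed12_line",
    "TISSUE_PALETTE",
    "normalize_concept_scores",
    "write_manifest",
]

# fixed 16-color palette (RGB strings) for the multi-tissue track
TISSUE_PALETTE = (
    "228,26,28", "55,126,184", "77,175,74", "152,78,163",
    "255,127,0", "255,255,51", "166,86,40", "247,129,191",
    "153,153,153", "102,194,165", "252,141,98", "141,160,203",
    "231,138,195", "166,216,84", "255,217,47", "229,196,148",
)


@dataclass(frozen=True)
class JunctionBedRecord:
    chrom: str
    chrom_start: int
    chrom_end: int
    name: str
    score: int
    strand: str
    thick_start: int
    thick_end: int
    item_rgb: str
    block_count: int
    block_sizes: str
    block_starts: str

    @property
    def junction(self) -> JunctionKey:
        return JunctionKey(self.chrom, self.chrom_start + 1, self.chrom_end - 1)

    def to_line(self) -> str:
        return "\t".join(
            str(v) for v in (
                self.chrom, self.chrom_start, self.chrom_end, self.name,
                self.score, self.strand, self.thick_start, self.thick_end,
                self.item_rgb, self.block_count, self.block_sizes, self.block_starts,
            )
        )


def _record_for(key: JunctionKey, name: str, score: int, strand: str,
                rgb: str) -> JunctionBedRecord:
    chrom_start = key.start - 1
    chrom_end = key.end + 1
    return JunctionBedRecord(
        chrom=key.chrom,
        chrom_start=chrom_start,
        chrom_end=chrom_end,
        name=name,
        score=min(int(score), 1000),
        strand=strand,
        thick_start=chrom_start,
        thick_end=chrom_end,
        item_rgb=rgb,
        block_count=2,
        block_sizes="1,1",
        block_starts=f"0,{key.length + 1}",
    )


def junction_bed_lines(
    junctions: Iterable[JunctionKey],
    names: Mapping[JunctionKey, str] | None = None,
    scores: Mapping[JunctionKey, int] | None = None,
    strands: Mapping[JunctionKey, str] | None = None,
    colors: Mapping[JunctionKey, str] | None = None,
) -> list:
    """BED12 lines for a junction set; junctions at intron_start 0 have no
    representable upstream exonic base and are skipped with a warning."""
    lines = []
    for key in sorted(set(junctions)):
        if key.start < 1:
            warnings.warn(f"junction {key} starts at position 0; skipped from BED track")
            continue
        rec = _record_for(
            key,
            name=(names or {}).get(key, str(key)),
            score=(scores or {}).get(key, 0),
            strand=(strands or {}).get(key, "."),
            rgb=(colors or {}).get(key, "0,0,0"),
        )
        lines.append(rec.to_line())
    return lines


def write_junction_bed(
    junctions: Iterable[JunctionKey],
    path,
    track_name: str | None = None,
    **kwargs,
) -> None:
    """Write the junction track; an optional ``track name=...`` header line
    is emitted only on request since strict BED consumers reject it."""
    lines = junction_bed_lines(junctions, **kwargs)
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track name="{track_name}" itemRgb="On"\n')
        for line in lines:
            fh.write(line + "\n")


def validate_bed12_line(line: str) -> None:
    """Raise ValueError unless the line is a well-formed BED12 record."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 12:
        raise ValueError(f"expected 12 columns, got {len(fields)}")
    chrom_start, chrom_end = int(fields[1]), int(fields[2])
    if chrom_end <= chrom_start or chrom_start < 0:
        raise ValueError("invalid interval")
    score = int(fields[4])
    if not 0 <= score <= 1000:
        raise ValueError("score outside 0-1000")
    if fields[5] not in ("+", "-", "."):
        raise ValueError("invalid strand")
    block_count = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != block_count or len(starts) != block_count:
        raise ValueError("blockSizes/blockStarts arity mismatch")
    if starts[0] != 0:
        raise ValueError("first blockStart must be 0")
    if chrom_start + starts[-1] + sizes[-1] != chrom_end:
        raise ValueError("last block must end at chromEnd")


def parse_junction_bed(path_or_lines) -> dict:
    """Parse a junction BED12 track back to {JunctionKey: name}."""
    if isinstance(path_or_lines, (str, Path)):
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    else:
        lines = list(path_or_lines)
    out: dict[JunctionKey, str] = {}
    for line in lines:
        if not line.strip() or line.startswith(("track", "browser", "#")):
            continue
        validate_bed12_line(line)
        fields = line.rstrip("\n").split("\t")
        chrom_start, chrom_end = int(fields[1]), int(fields[2])
        key = JunctionKey(fields[0], chrom_start + 1, chrom_end - 1)
        out[key] = fields[3]
    return out


# --------------------------------------------------------------------------
# concept-score normalization
# --------------------------------------------------------------------------

def normalize_concept_scores(
    scores: pd.DataFrame,
    set_sizes: Mapping[str, int],
    background: pd.Series | None = None,
    background_size: int = 1,
) -> pd.DataFrame:
    """Set-size normalization with background subtraction, clipped at zero.

    ``scores`` is concepts x gene-sets of summed association scores; each
    column is divided by its set size, the background column (itself divided
    by its own size) is subtracted, and negatives are set to 0:
    ``out(c, s) = max(0, score(c, s)/n_s - background(c)/n_bg)``.
    """
    for s in scores.columns:
        if set_sizes.get(s, 0) <= 0:
            raise ValueError(f"gene-set size for {s!r} must be positive")
    if background_size <= 0:
        raise ValueError("background set size must be positive")
    out = scores.div(pd.Series(dict(set_sizes)), axis=1)
    if background is not None:
        out = out.sub(background / background_size, axis=0)
    return out.clip(lower=0.0)


# --------------------------------------------------------------------------
# run manifests
# --------------------------------------------------------------------------

def write_manifest(out_dir, paths: Iterable, manifest_name: str = "manifest.json") -> dict:
    """Checksum every output file so reruns can be compared byte-for-byte."""
    out_dir = Path(out_dir)
    entries = {}
    for p in sorted(Path(p) for p in paths):
        digest = hashlib.sha256(p.read_bytes()).hexdigest()
        entries[str(p.relative_to(out_dir))] = {"sha256": digest, "bytes": p.stat().st_size}
    manifest_path = out_dir / manifest_name
    with open(manifest_path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True)
    return entries
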