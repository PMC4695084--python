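"""Synthetic multi-tissue spliced alignments with planted ground truth.

The generator emulates the design of a 16-tissue human RNA-seq survey: one
individual per tissue, one 75 bp single-end and one 2x50 bp paired-end
library (insert size ~210 bp) per tissue, a mix of ubiquitously expressed
and tissue-restricted genes, annotated and novel splice junctions, and
intron lengths between 50 and 100,000 nt.  Every planted structure —
which tissues express each gene and junction, each junction's annotation
status, the junction-to-gene map — is recorded in a :class:`TruthSet` so
that downstream analyses can be validated against known truth.

Reads are emitted pre-aligned: the pipeline under test consumes SAM, not
FASTQ, so sequences are left as ``*`` and per-read mismatch counts are
carried in the ``NM`` tag rather than realized as substituted bases.
Junction-spanning reads get spliced CIGARs (``aM <L>N bM``) whose skip
equals the intron length; their start offsets are uniform over all
positions leaving at least 1 bp on each side (a geometric "stacked" mode
plants low-entropy artifact junctions for filter testing).

Everything is driven by a single integer seed: the same seed yields
byte-identical SAM output.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .annotation import AnnotationIndex, GeneModel, build_annotation_index
from .catalog import JunctionKey

__all__ = [
    "BODYMAP_TISSUES",
    "SimulationConfig",
    "TruthSet",
    "GeneModelSet",
    "SimulationSizingError",
    "generate_reference",
    "simulate_alignments",
    "TissueSimulation",
    "write_sam",
    "export_truth",
    "load_truth",
]

BODYMAP_TISSUES = (
    "adipose", "adrenal", "brain", "breast", "colon", "kidney", "heart",
    "liver", "lung", "lymph_node", "prostate", "skeletal_muscle",
    "white_blood_cell", "ovary", "testes", "thyroid",
)

ANNOTATION_STATUSES = ("annotated", "novel_both_sites", "novel_one_site", "novel_neither")


class SimulationSizingError(ValueError):
    """Raised when the requested genes cannot be placed on the genome."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs for the synthetic cohort.

    Defaults mirror the emulated survey: 16 tissues, 75 bp single-end and
    2x50 bp paired-end libraries with ~210 bp inserts, introns between 50 bp
    and 100 kb.  ``depth_per_tissue`` is the mean number of spanning reads
    per expressed junction (and of body reads per expressed exon), Poisson
    distributed per junction/exon.
    """

    n_tissues: int = 16
    n_genes: int = 200
    frac_tissue_specific_genes: float = 0.2
    frac_ubiquitous_genes_with_specific_junction: float = 0.15
    frac_novel_junctions: float = 0.1
    frac_single_exon_genes: float = 0.05
    frac_artifact_junctions: float = 0.0
    read_length_se: int = 75
    read_length_pe: int = 50
    insert_size_pe: int = 210
    depth_per_tissue: float = 50.0
    novel_depth_factor: float = 1.0
    mismatch_rate: float = 0.5
    artifact_mismatch_rate: float = 3.0
    artifact_offset_p: float = 0.9
    intron_length_range: tuple = (50, 100_000)
    exons_per_gene: int = 5
    exon_length: int = 300
    n_chromosomes: int = 8
    intergenic_gap: int = 500
    chromosome_length: int | None = None
    seed: int = 0

    def __post_init__(self):
        fracs = (
            self.frac_tissue_specific_genes,
            self.frac_ubiquitous_genes_with_specific_junction,
            self.frac_novel_junctions,
            self.frac_single_exon_genes,
            self.frac_artifact_junctions,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must be in [0, 1]")
        if self.n_tissues < 2:
            raise ValueError("need at least 2 tissues")
        if self.intron_length_range[0] < 50:
            raise ValueError("minimum intron length must be >= 50")
        if self.intron_length_range[1] < self.intron_length_range[0]:
            raise ValueError("intron_length_range must be (min, max) with min <= max")
        # Flanking exons must hold a full single-end read on each side of a
        # junction and a whole paired-end fragment for body reads.
        min_exon = max(2 * self.read_length_se, self.insert_size_pe)
        if self.exon_length < min_exon:
            raise ValueError(f"exon_length must be >= {min_exon} for these read lengths")
        if self.exons_per_gene != 1 and self.exons_per_gene < 5:
            raise ValueError("multi-exon genes need >= 5 exons to host planted junction classes")

    def tissues(self) -> tuple:
        if self.n_tissues <= len(BODYMAP_TISSUES):
            return BODYMAP_TISSUES[: self.n_tissues]
        extra = tuple(f"tissue{i:02d}" for i in range(len(BODYMAP_TISSUES), self.n_tissues))
        return BODYMAP_TISSUES + extra


@dataclass
class TruthSet:
    """Planted ground truth emitted alongside the synthetic reads."""

    tissues: tuple
    gene_tissue_profile: dict          # gene_id -> frozenset of tissues
    junction_tissue_profile: dict      # JunctionKey -> frozenset of tissues
    junction_annotation_status: dict   # JunctionKey -> status string
    junction_gene: dict                # JunctionKey -> gene_id
    artifact_junctions: set = field(default_factory=set)

    def validate(self) -> None:
        for key, tissues in self.junction_tissue_profile.items():
            gene = self.junction_gene[key]
            if not tissues <= self.gene_tissue_profile[gene]:
                raise AssertionError(f"junction {key} expressed outside its gene's tissues")

    def __eq__(self, other) -> bool:
        if not isinstance(other, TruthSet):
            return NotImplemented
        return (
            tuple(self.tissues) == tuple(other.tissues)
            and self.gene_tissue_profile == other.gene_tissue_profile
            and self.junction_tissue_profile == other.junction_tissue_profile
            and self.junction_annotation_status == other.junction_annotation_status
            and self.junction_gene == other.junction_gene
            and set(self.artifact_junctions) == set(other.artifact_junctions)
        )


@dataclass
class GeneModelSet:
    genes: dict                        # gene_id -> GeneModel
    chrom_lengths: dict                # chrom -> length

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def __iter__(self):
        return iter(self.genes)


def _loguniform_int(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo == hi:
        return lo
    return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_reference(config: SimulationConfig):
    """Lay out genes, plant junction structure, and build the annotation.

    Returns ``(GeneModelSet, AnnotationIndex, TruthSet)``.  The annotation
    index contains every junction planted as annotated and omits the novel
    and artifact ones.  Genes are placed without overlap on synthetic
    chromosomes ``chrS1..chrSn``; a configured ``chromosome_length`` too
    small to hold its genes raises :class:`SimulationSizingError`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    tissues = config.tissues()

    n_specific = int(round(config.frac_tissue_specific_genes * config.n_genes))
    n_single = int(round(config.frac_single_exon_genes * config.n_genes))

    order = rng.permutation(config.n_genes)
    specific_ids = set(order[:n_specific])
    # single-exon genes drawn from the non-specific pool so the planted
    # tissue-specific gene count stays exact and junction-bearing
    single_ids = set(order[n_specific:n_specific + n_single])

    genes: dict[str, GeneModel] = {}
    cursors = {f"chrS{i + 1}": 0 for i in range(config.n_chromosomes)}
    chroms = list(cursors)

    gene_profiles: dict[str, frozenset] = {}
    junction_profile: dict[JunctionKey, frozenset] = {}
    junction_status: dict[JunctionKey, str] = {}
    junction_gene: dict[JunctionKey, str] = {}
    artifact_junctions: set[JunctionKey] = set()
    annotated_records: list[tuple] = []

    lo, hi = config.intron_length_range
    E, X = config.exons_per_gene, config.exon_length

    for i in range(config.n_genes):
        gid = f"g{i + 1:04d}"
        chrom = chroms[i % len(chroms)]
        start = cursors[chrom] + config.intergenic_gap
        n_exons = 1 if i in single_ids else E
        exons = []
        pos = start
        for j in range(n_exons):
            exons.append((pos, pos + X))
            pos += X
            if j < n_exons - 1:
                pos += _loguniform_int(rng, lo, hi)
        cursors[chrom] = pos
        if config.chromosome_length is not None and pos > config.chromosome_length:
            raise SimulationSizingError(
                f"chromosome_length={config.chromosome_length} too small: "
                f"{chrom} needs {pos} bp to place {config.n_genes} genes"
            )
        strand = "+" if rng.random() < 0.5 else "-"
        gene = GeneModel(gid, chrom, strand, tuple(exons))
        genes[gid] = gene

        if i in specific_ids:
            profile = frozenset({tissues[rng.integers(len(tissues))]})
        else:
            profile = frozenset(tissues)
        gene_profiles[gid] = profile

        for intron in gene.introns():
            junction_profile[intron] = profile
            junction_status[intron] = "annotated"
            junction_gene[intron] = gid
            annotated_records.append((intron.chrom, intron.start, intron.end, strand))

    multi_exon_ids = [gid for gid, g in genes.items() if g.multi_exon]
    ubiquitous_multi = [gid for gid in multi_exon_ids
                        if len(gene_profiles[gid]) == len(tissues)]
    n_constitutive = sum(len(genes[g].exons) - 1 for g in multi_exon_ids)

    # --- tissue-specific alternative junctions inside ubiquitous genes ----
    # exon-skip of the second exon: donor of intron 1, acceptor of intron 2;
    # both sites annotated, and the skip itself is entered in the annotation
    n_ue = int(round(
        config.frac_ubiquitous_genes_with_specific_junction * len(ubiquitous_multi)))
    for gid in ubiquitous_multi[:n_ue]:
        g = genes[gid]
        key = JunctionKey(g.chrom, g.exons[0][1], g.exons[2][0])
        junction_profile[key] = frozenset({tissues[rng.integers(len(tissues))]})
        junction_status[key] = "annotated"
        junction_gene[key] = gid
        annotated_records.append((key.chrom, key.start, key.end, g.strand))

    # --- novel junctions in the three sub-classes, equal proportions ------
    n_novel = int(round(config.frac_novel_junctions * n_constitutive))
    per_class = [n_novel // 3 + (1 if r < n_novel % 3 else 0) for r in range(3)]
    if max(per_class, default=0) > len(multi_exon_ids):
        raise SimulationSizingError(
            f"cannot plant {n_novel} novel junctions across {len(multi_exon_ids)} multi-exon genes"
        )

    def _plant(gid: str, kind: str) -> JunctionKey:
        g = genes[gid]
        if kind == "novel_both_sites":
            # skip of the third exon: known donor + known acceptor, new pair
            return JunctionKey(g.chrom, g.exons[1][1], g.exons[3][0])
        if kind == "novel_one_site":
            # known donor of the 4th intron, unannotated acceptor inside exon 4
            return JunctionKey(g.chrom, g.exons[2][1], g.exons[3][0] + 30)
        # novel_neither / artifact: an intron wholly inside the last exon
        s, e = g.exons[-1]
        length = int(rng.integers(60, 91))
        left = (X - length) // 2
        return JunctionKey(g.chrom, s + left, s + left + length)

    host_cycle = 0
    for kind, n_kind in zip(("novel_both_sites", "novel_one_site", "novel_neither"), per_class):
        for _ in range(n_kind):
            gid = multi_exon_ids[host_cycle % len(multi_exon_ids)]
            host_cycle += 1
            key = _plant(gid, kind)
            junction_profile[key] = gene_profiles[gid]
            junction_status[key] = kind
            junction_gene[key] = gid

    # --- low-entropy artifact junctions (geometric offsets, noisy reads) --
    n_art = int(round(config.frac_artifact_junctions * n_constitutive))
    art_hosts = [gid for gid in multi_exon_ids]
    for a in range(n_art):
        gid = art_hosts[a % len(art_hosts)]
        g = genes[gid]
        # inside the first exon, away from the novel_neither slot (last exon)
        s, e = g.exons[0]
        length = int(rng.integers(60, 91))
        left = (X - length) // 2
        key = JunctionKey(g.chrom, s + left, s + left + length)
        if key in junction_profile:
            continue
        junction_profile[key] = gene_profiles[gid]
        junction_status[key] = "novel_neither"
        junction_gene[key] = gid
        artifact_junctions.add(key)

    chrom_lengths = {c: cursors[c] + config.intergenic_gap for c in chroms}
    if config.chromosome_length is not None:
        chrom_lengths = {c: config.chromosome_length for c in chroms}

    truth = TruthSet(
        tissues=tuple(tissues),
        gene_tissue_profile=gene_profiles,
        junction_tissue_profile=junction_profile,
        junction_annotation_status=junction_status,
        junction_gene=junction_gene,
        artifact_junctions=artifact_junctions,
    )
    truth.validate()
    index = build_annotation_index(annotated_records)
    return GeneModelSet(genes, chrom_lengths), index, truth


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------

@dataclass
class TissueSimulation:
    """One simulated library: SAM lines plus generation-side bookkeeping."""

    tissue: str
    library: str                       # "SE" | "PE"
    header_lines: list
    read_lines: list
    junction_read_counts: Counter      # JunctionKey -> spanning reads emitted

    @property
    def n_records(self) -> int:
        return len(self.read_lines)


def _flank_room(gene: GeneModel, key: JunctionKey) -> tuple[int, int]:
    """Exonic room upstream of the intron start and downstream of its end."""
    left = right = 0
    for s, e in gene.exons:
        if s < key.start <= e:
            left = key.start - s
        if s <= key.end < e:
            right = e - key.end
        elif key.end == s:
            right = e - s
    return left, right


def _sam_header(chrom_lengths: Mapping[str, int]) -> list:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for chrom in sorted(chrom_lengths):
        lines.append(f"@SQ\tSN:{chrom}\tLN:{chrom_lengths[chrom]}")
    return lines


def simulate_alignments(
    truth: TruthSet,
    genes: GeneModelSet,
    tissue: str,
    library: str,
    config: SimulationConfig,
) -> TissueSimulation:
    """Emit pre-aligned reads for one tissue and one library type.

    Junction-spanning read counts are Poisson(depth) per expressed junction
    (times ``novel_depth_factor`` for planted novel junctions); exon body
    reads are Poisson(depth) per expressed exon.  Reads are generated only
    for genes/junctions whose truth profile includes this tissue.  Paired-end
    mode emits proper pairs; only the first mate spans the junction, so the
    spanning-read bookkeeping equals the fragment count.
    """
    if tissue not in truth.tissues:
        raise ValueError(f"unknown tissue {tissue!r}")
    if library not in ("SE", "PE"):
        raise ValueError("library must be 'SE' or 'PE'")
    t_idx = list(truth.tissues).index(tissue)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 1, t_idx, 0 if library == "SE" else 1])
    )
    R = config.read_length_se if library == "SE" else config.read_length_pe
    insert = config.insert_size_pe
    lines: list[str] = []
    spanning = Counter()
    serial = 0

    def emit_se(chrom, pos1, cigar, nm, strand):
        nonlocal serial
        serial += 1
        lines.append(
            f"r{tissue}.{library}.{serial}\t0\t{chrom}\t{pos1}\t60\t{cigar}\t*\t0\t0\t*\t*"
            f"\tNM:i:{nm}\tXS:A:{strand}"
        )

    def emit_pe(chrom, pos1_1, cigar1, pos1_2, nm1, nm2, strand, span2):
        nonlocal serial
        serial += 1
        name = f"r{tissue}.{library}.{serial}"
        tlen = pos1_2 + R - pos1_1
        lines.append(
            f"{name}\t99\t{chrom}\t{pos1_1}\t60\t{cigar1}\t=\t{pos1_2}\t{tlen}\t*\t*"
            f"\tNM:i:{nm1}\tXS:A:{strand}"
        )
        lines.append(
            f"{name}\t147\t{chrom}\t{pos1_2}\t60\t{R}M\t=\t{pos1_1}\t{-tlen}\t*\t*"
            f"\tNM:i:{nm2}\tXS:A:{strand}"
        )

    # --- junction-spanning reads ------------------------------------------
    for key in sorted(truth.junction_tissue_profile):
        if tissue not in truth.junction_tissue_profile[key]:
            continue
        gene = genes[truth.junction_gene[key]]
        left_room, right_room = _flank_room(gene, key)
        if left_room < 1 or right_room < 1:
            continue
        is_artifact = key in truth.artifact_junctions
        status = truth.junction_annotation_status[key]
        depth = config.depth_per_tissue
        if status != "annotated" and not is_artifact:
            depth *= config.novel_depth_factor
        n = int(rng.poisson(depth))
        if n == 0:
            continue
        a_max = min(R - 1, left_room)
        a_min = max(1, R - right_room)
        if library == "PE":
            a_min = 1  # mate placement clamps instead
        if a_min > a_max:
            continue  # read cannot span with >=1 bp each side
        mm_rate = config.artifact_mismatch_rate if is_artifact else config.mismatch_rate
        if is_artifact:
            draws = rng.geometric(config.artifact_offset_p, size=n) - 1
            offsets = a_min + np.minimum(draws, a_max - a_min)
        else:
            offsets = rng.integers(a_min, a_max + 1, size=n)
        nms = rng.poisson(mm_rate, size=n)
        spanning[key] += n
        L = key.length
        for a, nm in zip(offsets, nms):
            a = int(a)
            pos1 = key.start - a + 1
            if library == "SE":
                emit_se(key.chrom, pos1, f"{a}M{L}N{R - a}M", int(nm), gene.strand)
            else:
                cigar1 = f"{a}M{L}N{R - a}M"
                mate2_start = key.end + insert - 2 * R + (R - a)  # transcript spacing
                mate2_start = min(mate2_start, key.end + right_room - R)
                mate2_start = max(mate2_start, key.end)
                nm2 = int(rng.poisson(mm_rate))
                emit_pe(key.chrom, pos1, cigar1, mate2_start + 1, int(nm), nm2,
                        gene.strand, None)

    # --- exon body reads ---------------------------------------------------
    for gid in sorted(genes.genes):
        if tissue not in truth.gene_tissue_profile[gid]:
            continue
        gene = genes[gid]
        for s, e in gene.exons:
            span = e - s
            needed = R if library == "SE" else insert
            if span < needed:
                continue
            n = int(rng.poisson(config.depth_per_tissue))
            if n == 0:
                continue
            starts = rng.integers(s, e - needed + 1, size=n)
            nms = rng.poisson(config.mismatch_rate, size=n)
            for st, nm in zip(starts, nms):
                st = int(st)
                if library == "SE":
                    emit_se(gene.chrom, st + 1, f"{R}M", int(nm), gene.strand)
                else:
                    nm2 = int(rng.poisson(config.mismatch_rate))
                    emit_pe(gene.chrom, st + 1, f"{R}M", st + insert - R + 1,
                            int(nm), nm2, gene.strand, None)

    return TissueSimulation(
        tissue=tissue,
        library=library,
        header_lines=_sam_header(genes.chrom_lengths),
        read_lines=lines,
        junction_read_counts=spanning,
    )


def write_sam(sim: TissueSimulation, path) -> None:
    with open(path, "w") as fh:
        for line in sim.header_lines:
            fh.write(line + "\n")
        for line in sim.read_lines:
            fh.write(line + "\n")


# --------------------------------------------------------------------------
# truth table round-trip
# --------------------------------------------------------------------------

_TRUTH_HEADER = "record_type\tid\ttissues\tannotation_status\tgene\tartifact"


def export_truth(truth: TruthSet, path) -> None:
    """Write the truth set as a single TSV (lossless round-trip)."""
    with open(path, "w") as fh:
        fh.write(_TRUTH_HEADER + "\n")
        for tissue in truth.tissues:
            fh.write(f"tissue\t{tissue}\t\t\t\t\n")
        for gid in sorted(truth.gene_tissue_profile):
            tissues = ",".join(sorted(truth.gene_tissue_profile[gid]))
            fh.write(f"gene\t{gid}\t{tissues}\t\t\t\n")
        for key in sorted(truth.junction_tissue_profile):
            tissues = ",".join(sorted(truth.junction_tissue_profile[key]))
            status = truth.junction_annotation_status[key]
            gene = truth.junction_gene[key]
            art = 1 if key in truth.artifact_junctions else 0
            fh.write(f"junction\t{key}\t{tissues}\t{status}\t{gene}\t{art}\n")


def load_truth(path) -> TruthSet:
    tissues: list[str] = []
    gene_profiles: dict = {}
    junction_profile: dict = {}
    junction_status: dict = {}
    junction_gene: dict = {}
    artifacts: set = set()
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rec, ident, tiss, status, gene, art = line.rstrip("\n").split("\t")
            if rec == "tissue":
                tissues.append(ident)
            elif rec == "gene":
                gene_profiles[ident] = frozenset(t for t in tiss.split(",") if t)
            else:
                key = JunctionKey.from_string(ident)
                junction_profile[key] = frozenset(t for t in tiss.split(",") if t)
                junction_status[key] = status
                junction_gene[key] = gene
                if art == "1":
                    artifacts.add(key)
    return TruthSet(
        tissues=tuple(tissues),
        gene_tissue_profile=gene_profiles,
        junction_tissue_profile=junction_profile,
        junction_annotation_status=junction_status,
        junction_gene=junction_gene,
        artifact_junctions=artifacts,
    )
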