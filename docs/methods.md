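# Methods

## Junction model

A splice junction is represented by its intron: the genomic interval
`[intron_start, intron_end)` excised between two exonic segments, 0-based
half-open on a named chromosome. SAM input (1-based) is converted at the
boundary by pysam. Junctions are keyed by interval only; evidence from
reads on both strands merges, and the strand reported for a junction is the
majority vote of its spanning reads' `XS` tags (`.` when untagged). This
matches unstranded library chemistry, where the aligner infers strand from
splice motifs when it can.

A read with *k* reference-skip operations contributes evidence to *k*
junctions. The offset recorded per read is its leftmost aligned position
minus the junction's intron start — behaviorally equivalent to tracking the
flanking-segment length, and the quantity whose diversity the entropy
filter measures. Mismatches are the read's whole-read edit distance (`NM`
tag; 0 when absent): spanning reads are taken as wholes rather than split
into flanking pieces. Only primary alignments are counted by default; a
flag admits secondary/supplementary records.

## Filtering

Three per-junction predicates, all inclusive at the boundary:

| filter | default | reasoning |
|---|---|---|
| offset entropy `S` | ≥ 0.75 | reads stacked at one or two start positions are the classic mis-alignment signature |
| mean mismatches `m̄` | ≤ 1.5 (SE), ≤ 1.0 (PE) | junction-spanning mis-alignments accumulate edit distance; paired-end alignments tolerate fewer mismatches, so their threshold is tighter |
| intron length `L` | ≥ 50 nt | shorter gaps are more plausibly small deletions than introns; 50 nt is the lower bound of known intron lengths |

Entropy is Shannon entropy of the offset distribution, base 2 by default
and configurable. The base matters for the 0.75 threshold: under natural
log a junction supported equally at exactly two offsets scores
ln 2 ≈ 0.693 and would always fail, which is inconsistent with the filter
retaining roughly three-quarters of annotated junctions; under base 2 the
same junction scores 1.0. Base 2 is therefore the default.

The filter report attributes each removed junction to its first failing
rule (in the order entropy, mismatch, intron length), which partitions the
removals, and separately tallies every failed rule, since a junction can
fail several.

`suggest_thresholds` mechanizes the by-inspection calibration: given the
annotated (trusted) junctions and a target retention *r*, it takes the
nearest-rank (1−r)-quantile of annotated entropies (index ⌊(1−r)(n−1)⌋ on
the sorted sample) and the nearest-rank r-quantile of annotated mean
mismatches with the index rounded *up* (⌈r(n−1)⌉). The asymmetry is
deliberate: the mismatch criterion keeps values below its threshold, and
floor-rounding there can retain fewer than r·n junctions (e.g. sample
{0, 1} at r = 0.75 would yield threshold 0). With this rounding, each
single criterion provably retains at least r·n annotated junctions.
Defaults remain the published-style fixed thresholds; the suggester is a
tool for new data.

## Annotation and classification

The annotation index stores known introns as interval triples and derives
donor/acceptor sites by strand: donor = 5′ intron boundary (start on `+`,
end on `-`), acceptor = 3′ boundary. Classification is a total function
into four classes that partition any junction set: `annotated` (interval
match), else `novel_both_sites` / `novel_one_site` / `novel_neither` by how
many boundary positions match any known site. Site matching ignores strand
when the query's strand is unknown — the data the pipeline targets are
unstranded — and respects it otherwise. "One site" is exclusive
(exactly one boundary known), so the three novel classes partition the
unannotated junctions.

GTF (1-based inclusive) and BED (0-based half-open) readers are provided;
introns are derived from GTF exon records as gaps between consecutive
exons of each transcript.

## Expression and normalization

Junction expression in a tissue is the raw spanning-read count. Gene
expression is mean exonic depth: total aligned bases falling on the gene's
exon union divided by the union length, with intronic (skip) segments of
spliced reads contributing nothing. Gene length is defined as exon-union
length so that the ratio is exactly mean depth over the positions the
numerator counts. Genes default to a protein-coding biotype filter
(configurable).

Normalization scales tissue *t*'s raw values by `mean(N) / N_t`, where
`N_t` is the tissue's total aligned read count with each paired-end mate
counted separately. The transform is linear, invertible given the sizes,
and invariant to rescaling all libraries by a common factor. It is
RPKM-like but anchored to the mean library rather than per-million reads,
which keeps values on a read-count scale so a single threshold serves both
junctions and genes.

Presence calls use strict inequality (value > τ). The two library types
are processed separately end to end and meet only in the cross-library
analyses. Thresholds are applied per tissue per library; the retained
junction set of a library is the union over tissues of its per-tissue
retained sets, and expression values for that set are taken from every
tissue's evidence.

## Pairing and the specificity matrix

A junction is paired to a gene when its boundary positions match annotated
donor/acceptor sites of exactly one gene (sites derived from the gene's
exon-union gaps). Matching sites of two or more distinct genes — gene
overlap, or a donor from one gene with an acceptor from another — excludes
the junction; matching no site leaves it unpaired. A junction matching two
sites of the *same* gene in a new combination pairs to that gene.

The T×T specificity matrix counts pairs by (junction tissue count, gene
tissue count), dropping pairs silent on either side. On noiseless,
saturating-depth data every pair satisfies junction count ≤ gene count,
because junction reads come from the gene's transcripts; at low depth
threshold effects can violate this, which is why the upper triangle is
reported rather than forbidden.

The multi-exon gene summary counts genes (expressed at all / in >1 tissue
/ in all T tissues) carrying at least one junction present in exactly one
tissue; single-exon genes are excluded since they cannot host junctions.
Tissue-count distributions default to all genes, as the restriction is
only needed where junctions are involved.

## Synthetic cohorts

The generator emulates a 16-tissue, one-individual-per-tissue survey with
one 75 bp single-end and one 2×50 bp paired-end library (insert ≈ 210 bp)
per tissue. What it plants, all recorded in the emitted `TruthSet`:

- **Genes** on non-overlapping synthetic chromosomes (`chrS1..chrSn`),
  5 exons of 300 bp by default, intron lengths log-uniform on
  [50, 100 000] bp (log-uniform reproduces the heavy right tail of real
  intron-length histograms while keeping most introns short). A configured
  fraction of genes is single-exon. Strand is random per gene.
- **Expression profiles**: a fraction of genes is specific to one random
  tissue; the rest are ubiquitous. Intermediate breadths are deliberately
  not planted by default so that planted specific/ubiquitous counts are
  exact and recovery checks can assert equality rather than tolerance.
- **Tissue-specific junctions inside ubiquitous genes**: an exon-skip
  junction (annotated) planted in a fraction of ubiquitous genes and
  expressed in one random tissue — the structure the specificity matrix's
  (1, T) cell measures.
- **Novel junctions** in three equal sub-classes: a skip joining two
  annotated sites in a new pair; an annotated donor with a new acceptor
  inside the next exon; an intron wholly inside an exon (neither site
  known). Novel depth can be scaled down (`novel_depth_factor`) to model
  the empirical observation that undiscovered junctions sit near detection
  thresholds; the concordance analyses use 0.03 so that novel junctions
  frequently fail the entropy filter in one library.
- **Artifact junctions** (opt-in): geometric rather than uniform offsets
  (p = 0.9, asymptotic entropy ≈ 0.5 bits < 0.75) and an elevated mismatch
  rate, for testing that the filters remove stacked-read artifacts while
  retaining true junctions.

Read counts are Poisson(depth) per expressed junction and per expressed
exon (body reads); offsets are uniform over start positions leaving ≥ 1 bp
on each side of the junction. Mismatch counts are Poisson(mismatch rate)
stored in `NM` without altering bases — the pipeline consumes the count,
not the sequence, so sequences are `*`. Paired-end fragments place mate 1
on the junction and mate 2 downstream within exonic sequence (clamped to
the exon end when the insert would overrun it), flagged as proper pairs.
All randomness flows from one integer seed through per-(tissue, library)
seed sequences; identical seeds give byte-identical SAM output.

Defaults: 16 tissues, 200 genes, 20% tissue-specific genes, 15% of
ubiquitous genes with a planted specific junction, 10% novel junctions, 5%
single-exon genes, depth 50, mismatch rate 0.5. Depth 50 makes τ = 10
saturating: the probability of an expressed junction falling below
threshold after normalization is negligible (≲ 10⁻⁹ per junction), so
planted-truth recovery is exact.

### What the simulator does not model

No sequence content, base qualities, or realized sequencing errors; no
fragment GC or position bias; no multi-mapping reads; no biological
replicates (matching the emulated design, one individual per tissue); no
intermediate tissue breadths by default; no overlapping genes, so the
multi-gene exclusion path is exercised by dedicated unit fixtures rather
than by simulation. Passing planted-truth tests therefore demonstrates the
pipeline's bookkeeping and statistics are correct, not that the filters'
published thresholds are optimal for any particular real dataset.

## Numerical and degenerate-input choices

- Entropy of an empty histogram, mean of zero reads, empty annotated set
  in threshold calibration, τ < 0, empty filtered set in overlap, and
  non-positive library sizes are errors, not silent zeros.
- Junction catalogs, matrices and truth tables are written sorted for
  reproducible bytes; the pipeline manifest stores SHA-256 of every output.
- BED12 junctions need one representable exonic base upstream, so a
  junction starting at position 0 is skipped with a warning.
- Scores in BED are spanning-read counts capped at 1000 (the format's
  maximum); the tissue-specific track colors tissues from a fixed
  16-color palette.
- The concept-score operation (`max(0, score/n_s − background/n_bg)`)
  accepts any externally produced concept×set score matrix; no text-mining
  is performed.

## Problem sizes

The validation cohort is 16 tissues × 2 libraries over 200 genes at depth
50 (≈ 3–4 M alignments in total), chosen as the smallest design in which
every planted structure class appears in double digits; it completes in
under a minute on one CPU. Oracle tests use 1 000–10 000 randomized cases
per operation, and coverage oracles run on ≤ 12 kb toy genomes where a
per-base brute force is feasible.
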