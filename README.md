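# juncspect

Splice-junction discovery, entropy-based filtering, and tissue-specificity
analysis for multi-tissue RNA-seq.

Alternative splicing lets a single gene locus produce multiple transcript
isoforms, and many of those isoforms are restricted to particular tissues —
including isoforms of genes that are themselves expressed everywhere.
`juncspect` is a pipeline for quantifying that phenomenon from spliced
short-read alignments across a panel of tissues (the emulated design is a
16-tissue human survey with one 75 bp single-end and one 2×50 bp paired-end
library per tissue). It answers: which splice junctions exist, which are
novel, which are confined to a single tissue, and how does a junction's
tissue breadth relate to the breadth of its host gene?

## What it computes

**Junction extraction.** Every `N` (reference-skip) operation in a SAM CIGAR
defines a putative intron `[start, end)`. For each distinct interval the
pipeline records the spanning reads' alignment-start offsets, per-read edit
distances (`NM`), and count.

**Filtering.** A junction with spanning-read offsets $p_1,\dots,p_k$
(fractions of reads per distinct start position) is scored by Shannon
entropy $S = -\sum_i p_i \log_2 p_i$. Reads stacked at one offset ($S=0$)
are the signature of a mis-alignment. Junctions are retained iff

$$S \ge 0.75 \quad\text{and}\quad \bar m \le m_{\max} \quad\text{and}\quad L \ge 50\ \text{nt},$$

where $\bar m$ is the mean mismatches per spanning read ($m_{\max}$ = 1.5
for single-end, 1.0 for paired-end libraries) and $L$ the intron length
(shorter gaps are more likely small deletions than introns). A calibration
view (annotated-vs-novel entropy/mismatch scatter and intron-length
histograms) and a quantile-based threshold suggester support re-deriving
thresholds on new data.

**Annotation.** Junctions matching a known intron are *annotated*; the rest
are partitioned by whether both, exactly one, or neither of their boundary
positions is a known donor/acceptor site.

**Expression and normalization.** Junction expression is the spanning-read
count; gene expression is mean exonic depth (total aligned bases on the
exon union / union length). Each tissue's raw values are scaled by
$\bar N / N_t$, the mean total aligned read count over tissues divided by
the tissue's own, so one presence threshold (values strictly above
τ ∈ {5, 10, 50, 100, 500, 1000}; main analyses use 10) applies to junctions
and genes alike.

**Specificity.** From the boolean presence calls: tissue-count
distributions (typically U-shaped), junction→gene pairing by annotated
donor/acceptor site ownership (junctions matching sites of two genes are
excluded), the T×T matrix crossing junction tissue count against gene
tissue count, single-end/paired-end concordance, per-tissue lists of
entities specific to the same tissue in both libraries, and a multi-exon
gene summary (how many expressed genes carry ≥1 single-tissue junction).

**Reporting.** Junction tracks in a BED12 dialect that draws the last base
of the upstream exon and the first base of the downstream exon as 1 bp
boxes joined by a thin line, browser-ready; bedGraph coverage; TSV matrices
and tables; a checksummed output manifest.

**Synthetic cohorts.** Because the analyses are validated against planted
truth, the package ships a first-class simulator: genes laid out on
synthetic chromosomes with ubiquitous or single-tissue expression profiles,
annotated/novel junctions in the three novel sub-classes, tissue-specific
junctions planted inside ubiquitous genes, optional low-entropy artifact
junctions, Poisson read depths, and byte-identical output per seed.

## Worked example

```python
from juncspect.simulate import SimulationConfig
from juncspect.pipeline import run_pipeline

config = SimulationConfig(n_tissues=4, n_genes=40, seed=7,
                          intron_length_range=(50, 5000))
result = run_pipeline(config, tau=10.0)

print("PE junctions retained:", len(result.pe.retained_union))
print("classification:", result.pe.classification)
print("SE/PE concordance:", round(result.concordance["all"].fraction, 3))
print("tissue distribution (PE):", result.junction_distribution_pe.to_dict())
print("specificity matrix cell (1,4):", int(result.spec_matrix.loc[1, 4]))
```

prints

```
PE junctions retained: 171
classification: {'annotated': 156, 'novel_both_sites': 5, 'novel_one_site': 5, 'novel_neither': 5}
SE/PE concordance: 1.0
tissue distribution (PE): {1: 40, 2: 0, 3: 0, 4: 131}
specificity matrix cell (1,4): 4
```

171 junctions survive filtering in the paired-end libraries, 156 of them
annotated and 15 novel (5 per sub-class, as planted). At saturating depth
the two library types find identical junction sets (concordance 1.0). The
tissue-count distribution is U-shaped — 40 junctions in exactly one tissue,
131 in all four — and 4 junction–gene pairs sit in the matrix cell pairing
a single-tissue junction with a gene expressed in all four tissues: the
planted ubiquitous-gene/specific-junction events, recovered exactly.

The same run is available from the shell:

```sh
juncspect run --config cfg.yaml --out results/ --seed 7
```

with subcommands `simulate`, `extract`, `filter`, `quantify`, and
`specificity` exposing the individual stages.

## Layout

- `juncspect.simulate` — synthetic cohorts with planted truth
- `juncspect.catalog` — junction extraction and per-junction statistics
- `juncspect.annotation` — intron index, donor/acceptor classification, gene models
- `juncspect.filtering` — the three filters and threshold calibration
- `juncspect.expression` — junction/gene quantification and normalization
- `juncspect.specificity` — presence calls, distributions, pairing, concordance
- `juncspect.reporting` — BED12 tracks, concept-score normalization, manifests
- `juncspect.pipeline` / `juncspect.cli` — orchestration and shell interface

See `docs/methods.md` for the underlying model, parameter choices, and
limitations.
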