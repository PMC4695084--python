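"""End-to-end orchestration: simulate (or load), extract, filter, quantify,
characterize tissue specificity, and write reports.

The pipeline mirrors the study design it emulates: the single-end and
paired-end libraries are processed independently end to end (extraction,
per-tissue filtering, normalization, presence calls) and meet only in the
cross-library analyses — concordance, filtered-vs-unfiltered overlap, and
the tissue-specific lists that require an entity to be specific to the same
tissue in both libraries.
"""

from __future__ import annotations

import logging
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import annotation, catalog, expression, filtering, reporting, specificity
from .simulate import (
    GeneModelSet,
    SimulationConfig,
    TruthSet,
    export_truth,
    generate_reference,
    simulate_alignments,
    write_sam,
)

logger = logging.getLogger("juncspect")

__all__ = ["LibraryAnalysis", "PipelineResult", "run_pipeline", "analyze_library"]


@dataclass
class LibraryAnalysis:
    """All per-library intermediates, from raw evidence to presence calls."""

    library: str
    thresholds: filtering.FilterThresholds
    evidence_by_tissue: dict
    stats_by_tissue: dict
    retained_by_tissue: dict
    filter_reports: dict
    retained_union: set
    unfiltered_union: set
    classes: dict
    classification: dict
    sizes: expression.LibrarySizes
    junction_matrix: expression.ExpressionMatrix
    junction_matrix_norm: expression.ExpressionMatrix
    gene_matrix: expression.ExpressionMatrix
    gene_matrix_norm: expression.ExpressionMatrix
    presence_junction: specificity.PresenceMatrix
    presence_gene: specificity.PresenceMatrix


@dataclass
class PipelineResult:
    config: SimulationConfig
    truth: TruthSet
    genes: GeneModelSet
    index: annotation.AnnotationIndex
    se: LibraryAnalysis
    pe: LibraryAnalysis
    tau: float
    concordance: dict
    overlap_pe_filtered_in_se_unfiltered: float
    overlap_se_filtered_in_pe_unfiltered: float
    pairing: specificity.PairingResult
    spec_matrix: pd.DataFrame
    junction_distribution_se: pd.Series
    junction_distribution_pe: pd.Series
    gene_distribution_se: pd.Series
    gene_distribution_pe: pd.Series
    specific_junctions: dict
    specific_genes: dict
    table2: pd.DataFrame
    detection_ratio: pd.DataFrame


def analyze_library(
    sam_paths: dict,
    library: str,
    genes: GeneModelSet,
    index: annotation.AnnotationIndex,
    tau: float,
    thresholds: filtering.FilterThresholds | None = None,
    library_sizes: dict | None = None,
    log_base: float = 2.0,
) -> LibraryAnalysis:
    """Run one library type (tissue -> SAM path) through extraction,
    filtering, quantification and presence calls."""
    if thresholds is None:
        thresholds = (filtering.FilterThresholds.single_end() if library == "SE"
                      else filtering.FilterThresholds.paired_end())
    evidence_by_tissue: dict = {}
    stats_by_tissue: dict = {}
    retained_by_tissue: dict = {}
    reports: dict = {}
    sizes = dict(library_sizes) if library_sizes else {}
    for tissue, path in sam_paths.items():
        result = catalog.extract_junctions(path)
        evidence_by_tissue[tissue] = result.junctions
        stats = {k: catalog.compute_stats(ev, log_base) for k, ev in result.junctions.items()}
        stats_by_tissue[tissue] = stats
        classes_t = annotation.classify_junctions(stats, index)
        retained, report = filtering.apply_filters(stats, thresholds, classes_t)
        retained_by_tissue[tissue] = retained
        reports[tissue] = report
        if tissue not in sizes:
            sizes[tissue] = expression.count_aligned_reads(path)
        logger.info(
            "%s/%s: %d junctions in, %d retained (annotated retention %.3f)",
            library, tissue, report.n_input, report.n_retained,
            report.retention_annotated or float("nan"),
        )
    retained_union = set().union(*retained_by_tissue.values()) if retained_by_tissue else set()
    unfiltered_union = set().union(*(set(s) for s in stats_by_tissue.values())) if stats_by_tissue else set()
    classes = annotation.classify_junctions(unfiltered_union, index)

    gene_models = genes.genes if isinstance(genes, GeneModelSet) else dict(genes)
    chrom_lengths = genes.chrom_lengths if isinstance(genes, GeneModelSet) else None
    counts = {
        tissue: {k: ev for k, ev in evs.items() if k in retained_union}
        for tissue, evs in evidence_by_tissue.items()
    }
    jm = expression.junction_counts(counts)
    coverage = {
        tissue: expression.exonic_coverage(path, gene_models, chrom_lengths)
        for tissue, path in sam_paths.items()
    }
    gm = expression.gene_expression(coverage, gene_models)
    lib_sizes = expression.LibrarySizes(sizes)
    jm_norm = expression.normalize(jm, lib_sizes)
    gm_norm = expression.normalize(gm, lib_sizes)
    return LibraryAnalysis(
        library=library,
        thresholds=thresholds,
        evidence_by_tissue=evidence_by_tissue,
        stats_by_tissue=stats_by_tissue,
        retained_by_tissue=retained_by_tissue,
        filter_reports=reports,
        retained_union=retained_union,
        unfiltered_union=unfiltered_union,
        classes=classes,
        classification=annotation.classification_table(retained_union, index),
        sizes=lib_sizes,
        junction_matrix=jm,
        junction_matrix_norm=jm_norm,
        gene_matrix=gm,
        gene_matrix_norm=gm_norm,
        presence_junction=specificity.presence_calls(jm_norm, tau),
        presence_gene=specificity.presence_calls(gm_norm, tau),
    )


def run_pipeline(
    config: SimulationConfig,
    out_dir=None,
    tau: float = 10.0,
    keep_sams: bool = False,
) -> PipelineResult:
    """Simulate the cohort and run both libraries through the full analysis.

    With ``out_dir`` set, writes the truth table, annotation, per-library
    junction catalogs, matrices, distributions, specific lists, BED tracks
    and a checksum manifest.  Deterministic given ``config.seed``.
    """
    genes, index, truth = generate_reference(config)
    tissues = truth.tissues

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
    tmp_ctx = tempfile.TemporaryDirectory() if (out_path is None or not keep_sams) else None
    sam_dir = Path(tmp_ctx.name) if tmp_ctx else out_path / "sams"
    sam_dir.mkdir(parents=True, exist_ok=True)

    try:
        analyses = {}
        for library in ("SE", "PE"):
            paths = {}
            sizes = {}
            for tissue in tissues:
                sim = simulate_alignments(truth, genes, tissue, library, config)
                path = sam_dir / f"{tissue}.{library.lower()}.sam"
                write_sam(sim, path)
                paths[tissue] = path
                sizes[tissue] = sim.n_records
            analyses[library] = analyze_library(
                paths, library, genes, index, tau, library_sizes=sizes)
        se, pe = analyses["SE"], analyses["PE"]
    finally:
        if tmp_ctx:
            tmp_ctx.cleanup()

    classes_union = dict(pe.classes)
    classes_union.update(se.classes)
    conc = specificity.concordance_by_class(se.retained_union, pe.retained_union, classes_union)
    ov_pe_in_se = specificity.filtered_vs_unfiltered_overlap(pe.retained_union, se.unfiltered_union)
    ov_se_in_pe = specificity.filtered_vs_unfiltered_overlap(se.retained_union, pe.unfiltered_union)

    pairing = specificity.pair_junctions_to_genes(pe.retained_union, genes.genes)
    spec_matrix = specificity.specificity_matrix(
        pairing.pairs, pe.presence_junction, pe.presence_gene)

    specific_j = specificity.tissue_specific_lists(se.presence_junction, pe.presence_junction)
    specific_g = specificity.tissue_specific_lists(se.presence_gene, pe.presence_gene)
    table2 = specificity.genes_with_specific_junctions(
        pairing.pairs, pe.presence_junction, pe.presence_gene, genes.genes)
    ratio = specificity.detection_ratio(pe.junction_matrix_norm, pe.gene_matrix_norm)

    result = PipelineResult(
        config=config,
        truth=truth,
        genes=genes,
        index=index,
        se=se,
        pe=pe,
        tau=tau,
        concordance=conc,
        overlap_pe_filtered_in_se_unfiltered=ov_pe_in_se,
        overlap_se_filtered_in_pe_unfiltered=ov_se_in_pe,
        pairing=pairing,
        spec_matrix=spec_matrix,
        junction_distribution_se=specificity.tissue_distribution(se.presence_junction),
        junction_distribution_pe=specificity.tissue_distribution(pe.presence_junction),
        gene_distribution_se=specificity.tissue_distribution(se.presence_gene),
        gene_distribution_pe=specificity.tissue_distribution(pe.presence_gene),
        specific_junctions=specific_j,
        specific_genes=specific_g,
        table2=table2,
        detection_ratio=ratio,
    )
    if out_path is not None:
        _write_outputs(result, out_path)
    return result


def _write_outputs(result: PipelineResult, out: Path) -> None:
    paths = []

    def _save(name: str, writer) -> None:
        p = out / name
        writer(p)
        paths.append(p)

    _save("truth.tsv", lambda p: export_truth(result.truth, p))
    _save("annotation.introns.bed", lambda p: annotation.write_intron_bed(
        ((c, s, e, ".") for c, s, e in sorted(result.index.known_introns)), p))

    for lib, ana in (("se", result.se), ("pe", result.pe)):
        pooled = catalog.merge_catalogs(*ana.evidence_by_tissue.values())
        stats = {k: catalog.compute_stats(ev) for k, ev in pooled.items()}
        _save(f"catalog.{lib}.tsv", lambda p, s=stats: catalog.write_catalog(s, p))
        _save(f"junctions.{lib}.normalized.tsv", lambda p, m=ana.junction_matrix_norm: m.to_tsv(p))
        _save(f"genes.{lib}.normalized.tsv", lambda p, m=ana.gene_matrix_norm: m.to_tsv(p))
        _save(f"classification.{lib}.tsv", lambda p, a=ana: pd.Series(a.classification).to_csv(
            p, sep="\t", header=["n_junctions"], index_label="class"))

    dist = pd.DataFrame({
        "junctions_se": result.junction_distribution_se,
        "junctions_pe": result.junction_distribution_pe,
        "genes_se": result.gene_distribution_se,
        "genes_pe": result.gene_distribution_pe,
    })
    _save("tissue_distribution.tsv", lambda p: dist.to_csv(p, sep="\t"))
    _save("specificity_matrix.tsv", lambda p: result.spec_matrix.to_csv(p, sep="\t"))
    _save("table2_genes_with_specific_junctions.tsv",
          lambda p: result.table2.to_csv(p, sep="\t"))
    _save("detection_ratio.tsv", lambda p: result.detection_ratio.to_csv(p, sep="\t"))

    conc_rows = {
        cls: {"n_both": c.n_both, "n_se_only": c.n_a_only, "n_pe_only": c.n_b_only,
              "fraction": c.fraction}
        for cls, c in result.concordance.items()
    }
    _save("concordance.tsv", lambda p: pd.DataFrame.from_dict(conc_rows, orient="index")
          .to_csv(p, sep="\t", index_label="class"))

    specific_rows = [
        {"tissue": t, "entity": e, "kind": kind}
        for kind, lists in (("junction", result.specific_junctions),
                            ("gene", result.specific_genes))
        for t, entities in sorted(lists.items())
        for e in sorted(entities)
    ]
    _save("tissue_specific.tsv", lambda p: pd.DataFrame(
        specific_rows, columns=["tissue", "entity", "kind"]).to_csv(p, sep="\t", index=False))

    # BED tracks: novel junctions found in both libraries; tissue-specific track
    novel_both = {
        k for k in (result.se.retained_union & result.pe.retained_union)
        if result.pe.classes.get(k, result.se.classes.get(k)) != "annotated"
    }
    _save("novel_junctions.bed", lambda p: reporting.write_junction_bed(novel_both, p))

    tissue_color = {
        t: reporting.TISSUE_PALETTE[i % len(reporting.TISSUE_PALETTE)]
        for i, t in enumerate(result.truth.tissues)
    }
    ts_names, ts_colors, ts_keys = {}, {}, []
    for tissue, entities in result.specific_junctions.items():
        for e in entities:
            key = catalog.JunctionKey.from_string(e)
            ts_keys.append(key)
            ts_names[key] = tissue
            ts_colors[key] = tissue_color[tissue]
    _save("tissue_specific_junctions.bed", lambda p: reporting.write_junction_bed(
        ts_keys, p, names=ts_names, colors=ts_colors))

    reporting.write_manifest(out, paths)
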