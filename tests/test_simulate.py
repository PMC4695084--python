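"""Synthetic-cohort generator: planted structure, determinism, read realism."""

import io
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from juncspect.catalog import JunctionKey, extract_junctions
from juncspect.simulate import (
    SimulationConfig,
    SimulationSizingError,
    TruthSet,
    export_truth,
    generate_reference,
    load_truth,
    simulate_alignments,
    write_sam,
)


def _sam_text(sim):
    return "\n".join(sim.header_lines + sim.read_lines)


class TestConfig:
    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_novel_junctions=1.5)

    def test_intron_minimum_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(intron_length_range=(20, 1000))

    def test_at_least_two_tissues(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_tissues=1)


class TestGenerateReference:
    def test_planted_specific_gene_count_is_exact(self):
        cfg = SimulationConfig(n_tissues=4, n_genes=10, frac_tissue_specific_genes=0.3,
                               seed=1, intron_length_range=(50, 500))
        _, _, truth = generate_reference(cfg)
        n_specific = sum(1 for p in truth.gene_tissue_profile.values() if len(p) == 1)
        assert n_specific == 3

    def test_zero_novel_fraction_means_all_annotated(self):
        cfg = SimulationConfig(n_tissues=4, n_genes=10, frac_novel_junctions=0.0,
                               frac_ubiquitous_genes_with_specific_junction=0.0,
                               seed=2, intron_length_range=(50, 500))
        _, index, truth = generate_reference(cfg)
        assert set(truth.junction_annotation_status.values()) == {"annotated"}
        for key in truth.junction_tissue_profile:
            assert (key.chrom, key.start, key.end) in index.known_introns

    def test_same_seed_reproduces_identical_truth(self):
        cfg = SimulationConfig(n_tissues=4, n_genes=15, seed=7,
                               intron_length_range=(50, 800))
        _, _, t1 = generate_reference(cfg)
        _, _, t2 = generate_reference(cfg)
        assert t1 == t2

    def test_junction_profile_subset_of_gene_profile(self, small_reference):
        _, _, _, truth = small_reference
        for key, tissues in truth.junction_tissue_profile.items():
            assert tissues <= truth.gene_tissue_profile[truth.junction_gene[key]]

    def test_novel_junctions_absent_from_annotation(self, small_reference):
        _, _, index, truth = small_reference
        for key, status in truth.junction_annotation_status.items():
            in_annotation = (key.chrom, key.start, key.end) in index.known_introns
            assert in_annotation == (status == "annotated")

    def test_genes_do_not_overlap(self, small_reference):
        _, genes, _, _ = small_reference
        by_chrom = {}
        for g in genes.genes.values():
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_genome_too_small_raises_sizing_error(self):
        cfg = SimulationConfig(n_tissues=2, n_genes=50, seed=3,
                               intron_length_range=(50, 500),
                               chromosome_length=2000)
        with pytest.raises(SimulationSizingError):
            generate_reference(cfg)

    def test_planted_novel_subclass_counts_balanced(self):
        # 40 multi-exon genes x 4 introns = 160 constitutive junctions;
        # frac 30/160 plants 10 of each novel sub-class
        cfg = SimulationConfig(n_tissues=4, n_genes=40, frac_novel_junctions=30 / 160,
                               frac_single_exon_genes=0.0,
                               frac_ubiquitous_genes_with_specific_junction=0.0,
                               seed=4, intron_length_range=(50, 500))
        _, _, truth = generate_reference(cfg)
        counts = Counter(truth.junction_annotation_status.values())
        assert counts["novel_both_sites"] == 10
        assert counts["novel_one_site"] == 10
        assert counts["novel_neither"] == 10


class TestSimulateAlignments:
    def test_junction_reads_only_in_expressing_tissues(self, small_reference):
        cfg, genes, _, truth = small_reference
        specific = [k for k, p in truth.junction_tissue_profile.items() if len(p) == 1]
        assert specific
        key = specific[0]
        (expressing,) = truth.junction_tissue_profile[key]
        others = [t for t in truth.tissues if t != expressing]
        sim_off = simulate_alignments(truth, genes, others[0], "SE", cfg)
        assert key not in sim_off.junction_read_counts
        sim_on = simulate_alignments(truth, genes, expressing, "SE", cfg)
        assert sim_on.junction_read_counts[key] > 0

    def test_same_seed_gives_byte_identical_sam(self, small_reference):
        cfg, genes, _, truth = small_reference
        a = _sam_text(simulate_alignments(truth, genes, truth.tissues[0], "SE", cfg))
        b = _sam_text(simulate_alignments(truth, genes, truth.tissues[0], "SE", cfg))
        assert a == b

    def test_deep_junction_occupies_multiple_offsets(self, tmp_path):
        cfg = SimulationConfig(n_tissues=2, n_genes=4, depth_per_tissue=500.0, seed=5,
                               intron_length_range=(50, 500),
                               frac_tissue_specific_genes=0.0)
        genes, _, truth = generate_reference(cfg)
        sim = simulate_alignments(truth, genes, truth.tissues[0], "SE", cfg)
        path = tmp_path / "deep.sam"
        write_sam(sim, path)
        result = extract_junctions(str(path))
        for ev in result.junctions.values():
            if ev.read_count >= 100:
                assert len(ev.offsets) > 1

    def test_skip_length_equals_planted_intron_length(self, small_reference, tmp_path):
        cfg, genes, _, truth = small_reference
        sim = simulate_alignments(truth, genes, truth.tissues[1], "SE", cfg)
        path = tmp_path / "t.sam"
        write_sam(sim, path)
        extracted = extract_junctions(str(path))
        for key in extracted.junctions:
            assert key in truth.junction_tissue_profile
            assert key.length == (key.end - key.start)

    def test_extracted_counts_equal_simulator_bookkeeping(self, small_reference, tmp_path):
        cfg, genes, _, truth = small_reference
        for library in ("SE", "PE"):
            sim = simulate_alignments(truth, genes, truth.tissues[0], library, cfg)
            path = tmp_path / f"x.{library}.sam"
            write_sam(sim, path)
            extracted = extract_junctions(str(path))
            observed = {k: ev.read_count for k, ev in extracted.junctions.items()}
            assert observed == dict(sim.junction_read_counts)

    def test_paired_end_mates_form_proper_pairs(self, small_reference, tmp_path):
        import pysam
        cfg, genes, _, truth = small_reference
        sim = simulate_alignments(truth, genes, truth.tissues[0], "PE", cfg)
        path = tmp_path / "pe.sam"
        write_sam(sim, path)
        n_pairs = 0
        with pysam.AlignmentFile(str(path), "r") as fh:
            for read in fh:
                assert read.is_paired and read.is_proper_pair
                n_pairs += read.is_read1
        assert n_pairs * 2 == sim.n_records

    def test_spanning_depths_match_poisson_model(self):
        # planted depths are Poisson(depth); at n >= 100 junctions, ~99%
        # should fall within 4 sigma of the mean
        cfg = SimulationConfig(n_tissues=2, n_genes=40, depth_per_tissue=50.0, seed=6,
                               frac_tissue_specific_genes=0.0,
                               frac_single_exon_genes=0.0,
                               intron_length_range=(50, 500))
        genes, _, truth = generate_reference(cfg)
        sim = simulate_alignments(truth, genes, truth.tissues[0], "SE", cfg)
        counts = np.array([sim.junction_read_counts.get(k, 0)
                           for k, p in truth.junction_tissue_profile.items()
                           if truth.tissues[0] in p])
        assert len(counts) >= 100
        sigma = np.sqrt(50.0)
        within = np.abs(counts - 50.0) <= 4 * sigma
        assert within.mean() >= 0.99

    def test_unknown_tissue_rejected(self, small_reference):
        cfg, genes, _, truth = small_reference
        with pytest.raises(ValueError):
            simulate_alignments(truth, genes, "spleen", "SE", cfg)


class TestTruthRoundTrip:
    def test_empty_truth_exports_header_only(self, tmp_path):
        truth = TruthSet(tissues=(), gene_tissue_profile={}, junction_tissue_profile={},
                         junction_annotation_status={}, junction_gene={})
        path = tmp_path / "truth.tsv"
        export_truth(truth, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("record_type")

    def test_three_junction_truth_has_three_junction_rows(self, tmp_path):
        keys = [JunctionKey("chrS1", 100 * i, 100 * i + 60) for i in range(1, 4)]
        truth = TruthSet(
            tissues=("heart", "liver"),
            gene_tissue_profile={"g1": frozenset({"heart", "liver"})},
            junction_tissue_profile={k: frozenset({"heart"}) for k in keys},
            junction_annotation_status={k: "annotated" for k in keys},
            junction_gene={k: "g1" for k in keys},
        )
        path = tmp_path / "truth.tsv"
        export_truth(truth, path)
        rows = [l for l in path.read_text().splitlines() if l.startswith("junction\t")]
        assert len(rows) == 3

    def test_round_trip_on_generated_truth(self, small_reference, tmp_path):
        _, _, _, truth = small_reference
        path = tmp_path / "truth.tsv"
        export_truth(truth, path)
        assert load_truth(path) == truth

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_round_trip_on_randomized_truth(self, seed):
        import tempfile, os
        cfg = SimulationConfig(n_tissues=3, n_genes=8, seed=seed,
                               frac_artifact_junctions=0.2,
                               intron_length_range=(50, 300))
        _, _, truth = generate_reference(cfg)
        with tempfile.TemporaryDirectory() as d:
            path = os.path.join(d, "t.tsv")
            export_truth(truth, path)
            assert load_truth(path) == truth
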