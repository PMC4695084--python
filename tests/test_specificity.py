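"""Presence calls, tissue distributions, junction-gene pairing, concordance."""

import numpy as np
import pandas as pd
import pytest

from juncspect.annotation import GeneModel
from juncspect.catalog import JunctionKey
from juncspect.expression import ExpressionMatrix
from juncspect.specificity import (
    EXPRESSION_THRESHOLDS,
    concordance,
    concordance_by_class,
    detection_ratio,
    filtered_vs_unfiltered_overlap,
    genes_with_specific_junctions,
    pair_junctions_to_genes,
    presence_calls,
    specificity_matrix,
    tissue_distribution,
    tissue_specific_lists,
)


def _em(df, kind="junction"):
    return ExpressionMatrix(pd.DataFrame(df), kind=kind, normalized=True)


class TestPresenceCalls:
    def test_threshold_is_strict(self):
        m = _em({"heart": {"j": 10.0}, "liver": {"j": 10.5}})
        p = presence_calls(m, 10)
        assert not p.data.loc["j", "heart"]
        assert p.data.loc["j", "liver"]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            presence_calls(_em({"heart": {"j": 1.0}}), -1)

    def test_presence_counts_non_increasing_in_threshold(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame(rng.exponential(100, (300, 6)),
                          index=[f"j{i}" for i in range(300)],
                          columns=[f"t{i}" for i in range(6)])
        m = _em(df)
        n_present = [presence_calls(m, tau).data.values.sum()
                     for tau in EXPRESSION_THRESHOLDS]
        assert all(a >= b for a, b in zip(n_present, n_present[1:]))


class TestTissueDistribution:
    def test_ubiquitous_and_specific_entities_hit_extreme_bins(self):
        T = 4
        df = pd.DataFrame(
            {f"t{i}": {"ubiq": 100.0, "spec": 50.0 if i == 0 else 0.0, "off": 0.0}
             for i in range(T)})
        dist = tissue_distribution(presence_calls(_em(df), 10))
        assert dist[1] == 1 and dist[T] == 1
        assert dist.sum() == 2  # the absent entity is excluded

    def test_mass_shifts_toward_specificity_at_higher_thresholds(self):
        rng = np.random.default_rng(22)
        # entities with one dominant tissue and weaker background elsewhere
        base = rng.uniform(5, 30, (400, 8))
        dominant = rng.integers(0, 8, 400)
        base[np.arange(400), dominant] += rng.uniform(100, 2000, 400)
        m = _em(pd.DataFrame(base, index=[f"j{i}" for i in range(400)],
                             columns=[f"t{i}" for i in range(8)]))
        frac_specific = []
        for tau in (5, 10, 50, 100):
            dist = tissue_distribution(presence_calls(m, tau))
            if dist.sum():
                frac_specific.append(dist[1] / dist.sum())
        assert all(a <= b + 1e-12 for a, b in zip(frac_specific, frac_specific[1:]))


class TestPairing:
    @pytest.fixture
    def models(self):
        return {
            "gA": GeneModel("gA", "chr1", "+", ((0, 100), (200, 300), (400, 500))),
            "gB": GeneModel("gB", "chr1", "+", ((1000, 1100), (1200, 1300))),
        }

    def test_junction_with_one_known_site_pairs_to_owner(self, models):
        res = pair_junctions_to_genes([JunctionKey("chr1", 100, 170)], models)
        assert res.pairs == {JunctionKey("chr1", 100, 170): "gA"}

    def test_sites_from_two_genes_excluded(self, models):
        key = JunctionKey("chr1", 100, 1200)  # gA donor, gB acceptor
        res = pair_junctions_to_genes([key], models)
        assert key in res.excluded and not res.pairs

    def test_no_site_match_is_unpaired(self, models):
        key = JunctionKey("chr1", 50, 70)
        res = pair_junctions_to_genes([key], models)
        assert key in res.unpaired

    def test_matches_site_ownership_brute_force(self, models):
        rng = np.random.default_rng(23)
        site_owners = {}
        for gid, g in models.items():
            for intron in g.introns():
                site_owners.setdefault(intron.start, set()).add(gid)
                site_owners.setdefault(intron.end, set()).add(gid)
        keys = [JunctionKey("chr1", int(s), int(s) + int(l))
                for s, l in zip(rng.integers(0, 1300, 500), rng.integers(1, 400, 500))]
        res = pair_junctions_to_genes(keys, models)
        for key in set(keys):
            owners = site_owners.get(key.start, set()) | site_owners.get(key.end, set())
            if not owners:
                assert key in res.unpaired
            elif len(owners) == 1:
                assert res.pairs[key] == next(iter(owners))
            else:
                assert key in res.excluded


class TestSpecificityMatrix:
    def _presence(self, df, kind):
        return presence_calls(_em(df, kind), 10)

    def test_single_pair_lands_in_its_cell(self):
        T = 4
        key = JunctionKey("chr1", 100, 200)
        pj = self._presence({f"t{i}": {str(key): 100.0 if i == 0 else 0.0}
                             for i in range(T)}, "junction")
        pg = self._presence({f"t{i}": {"gA": 100.0} for i in range(T)}, "gene")
        grid = specificity_matrix({key: "gA"}, pj, pg)
        assert grid.loc[1, T] == 1
        assert grid.values.sum() == 1

    def test_identical_profiles_hit_the_diagonal(self):
        T = 3
        key = JunctionKey("chr1", 100, 200)
        df = {f"t{i}": {str(key): 100.0 if i < 2 else 0.0} for i in range(T)}
        pj = self._presence(df, "junction")
        pg = self._presence({f"t{i}": {"gA": 100.0 if i < 2 else 0.0} for i in range(T)}, "gene")
        grid = specificity_matrix({key: "gA"}, pj, pg)
        assert grid.loc[2, 2] == 1

    def test_silent_pairs_dropped_and_mass_conserved(self):
        T = 3
        k1, k2 = JunctionKey("chr1", 0, 60), JunctionKey("chr1", 100, 160)
        pj = self._presence({f"t{i}": {str(k1): 100.0, str(k2): 0.0} for i in range(T)},
                            "junction")
        pg = self._presence({f"t{i}": {"gA": 100.0} for i in range(T)}, "gene")
        grid = specificity_matrix({k1: "gA", k2: "gA"}, pj, pg)
        assert grid.values.sum() == 1


class TestConcordance:
    def test_identical_sets_fully_concordant(self):
        a = {JunctionKey("chr1", 0, 60)}
        assert concordance(a, a).fraction == 1.0

    def test_partial_overlap_hand_case(self):
        x, y, z = (JunctionKey("chr1", i, i + 60) for i in (0, 100, 200))
        res = concordance({x, y}, {y, z})
        assert (res.n_both, res.n_a_only, res.n_b_only) == (1, 1, 1)
        assert res.fraction == pytest.approx(1 / 3)

    def test_by_class_split(self):
        x, y = JunctionKey("chr1", 0, 60), JunctionKey("chr1", 100, 160)
        classes = {x: "annotated", y: "novel_neither"}
        res = concordance_by_class({x, y}, {x}, classes)
        assert res["annotated"].fraction == 1.0
        assert res["novel"].fraction == 0.0

    def test_filtered_vs_unfiltered_bounds(self):
        x, y, z = (JunctionKey("chr1", i, i + 60) for i in (0, 100, 200))
        assert filtered_vs_unfiltered_overlap({x, y}, {x, y, z}) == 1.0
        assert filtered_vs_unfiltered_overlap({x}, {y, z}) == 0.0
        with pytest.raises(ValueError):
            filtered_vs_unfiltered_overlap(set(), {x})

    def test_unfiltered_overlap_dominates_filtered_concordance(self):
        rng = np.random.default_rng(24)
        pool = [JunctionKey("chr1", int(100 * i), int(100 * i) + 60) for i in range(200)]
        for _ in range(25):
            unfilt_b = {k for k in pool if rng.random() < 0.8}
            filt_b = {k for k in unfilt_b if rng.random() < 0.6}
            filt_a = {k for k in pool if rng.random() < 0.5}
            if not filt_a:
                continue
            ov = filtered_vs_unfiltered_overlap(filt_a, unfilt_b)
            conc = concordance(filt_a, filt_b).fraction
            assert ov >= conc


class TestTissueSpecificLists:
    def _p(self, df):
        return presence_calls(_em(pd.DataFrame(df)), 10)

    def test_requires_same_tissue_in_both_libraries(self):
        se = self._p({"heart": {"j": 100.0}, "liver": {"j": 0.0}})
        pe = self._p({"heart": {"j": 0.0}, "liver": {"j": 100.0}})
        lists = tissue_specific_lists(se, pe)
        assert lists == {"heart": set(), "liver": set()}

    def test_concordant_specific_entity_listed_once(self):
        se = self._p({"heart": {"j": 0.0}, "testes": {"j": 100.0}})
        pe = self._p({"heart": {"j": 0.0}, "testes": {"j": 50.0}})
        assert tissue_specific_lists(se, pe) == {"heart": set(), "testes": {"j"}}

    def test_differing_tissue_universes_rejected(self):
        se = self._p({"heart": {"j": 1.0}})
        pe = self._p({"liver": {"j": 1.0}})
        with pytest.raises(ValueError):
            tissue_specific_lists(se, pe)

    def test_single_library_mode(self):
        se = self._p({"heart": {"j": 100.0}, "liver": {"j": 0.0}})
        assert tissue_specific_lists(se) == {"heart": {"j"}, "liver": set()}


class TestGenesWithSpecificJunctions:
    def test_single_exon_genes_never_counted(self):
        T = 2
        key = JunctionKey("chr1", 100, 200)
        genes = {"multi": GeneModel("multi", "chr1", "+", ((0, 100), (200, 300))),
                 "mono": GeneModel("mono", "chr2", "+", ((0, 300),))}
        pj = presence_calls(_em({f"t{i}": {str(key): 100.0 if i == 0 else 0.0}
                                 for i in range(T)}), 10)
        pg = presence_calls(_em({f"t{i}": {"multi": 100.0, "mono": 100.0}
                                 for i in range(T)}, "gene"), 10)
        table = genes_with_specific_junctions({key: "multi"}, pj, pg, genes)
        assert table.loc["expressed", "n_genes"] == 1  # mono excluded
        assert table.loc["expressed", "n_with_specific_junction"] == 1
        assert table.loc[f"expressed_all_{T}_tissues", "pct_with_specific_junction"] == 100.0


class TestDetectionRatio:
    def test_finite_positive_whenever_genes_detected(self):
        rng = np.random.default_rng(25)
        jm = _em(pd.DataFrame(rng.exponential(200, (100, 4)),
                              index=[f"j{i}" for i in range(100)],
                              columns=list("abcd")))
        gm = _em(pd.DataFrame(rng.exponential(200, (40, 4)),
                              index=[f"g{i}" for i in range(40)],
                              columns=list("abcd")), kind="gene")
        table = detection_ratio(jm, gm)
        detected = table[table.n_genes > 0]
        assert (detected.ratio > 0).all()
        assert np.isfinite(detected.ratio).all()
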