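"""Tissue-specificity analyses over junction and gene expression.

An entity (junction or gene) is *expressed* in a tissue when its normalized
value is strictly above a read threshold (5, 10, 50, 100, 500 or 1000; the
main analyses use 10).  From the boolean presence calls this module derives:

* the distribution of entities over the number of tissues they are found in
  (typically U-shaped: most entities are either ubiquitous or confined to a
  single tissue),
* the junction-gene pairing via annotated donor/acceptor site ownership and
  the T x T matrix crossing each pair's junction tissue count against its
  gene tissue count (tissue-restricted junctions inside broadly expressed
  genes populate the off-diagonal),
* concordance between the single-end and paired-end libraries, and
* per-tissue lists of entities specific to the same single tissue in both
  libraries.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .catalog import JunctionKey
from .expression import ExpressionMatrix

__all__ = [
    "PresenceMatrix",
    "presence_calls",
    "tissue_distribution",
    "pair_junctions_to_genes",
    "PairingResult",
    "specificity_matrix",
    "ConcordanceResult",
    "concordance",
    "concordance_by_class",
    "filtered_vs_unfiltered_overlap",
    "specific_entities",
    "tissue_specific_lists",
    "genes_with_specific_junctions",
    "detection_ratio",
]

EXPRESSION_THRESHOLDS = (5, 10, 50, 100, 500, 1000)


@dataclass
class PresenceMatrix:
    """Boolean entity x tissue calls at threshold tau (strict inequality)."""

    data: pd.DataFrame
    threshold: float
    kind: str

    @property
    def tissues(self) -> list:
        return list(self.data.columns)

    def n_tissues(self) -> pd.Series:
        """Number of tissues each entity is present in."""
        return self.data.sum(axis=1).astype(int)


def presence_calls(matrix: ExpressionMatrix, tau: float) -> PresenceMatrix:
    """Call an entity expressed in a tissue iff value > tau (strict)."""
    if tau < 0:
        raise ValueError("presence threshold must be nonnegative")
    return PresenceMatrix(matrix.data > tau, threshold=tau, kind=matrix.kind)


def tissue_distribution(presence: PresenceMatrix) -> pd.Series:
    """Histogram of expressed entities by tissue count, over bins 1..T.

    Entities present in zero tissues are excluded, so the histogram sums to
    the number of expressed entities.
    """
    T = len(presence.tissues)
    counts = presence.n_tissues()
    counts = counts[counts > 0]
    hist = counts.value_counts().reindex(range(1, T + 1), fill_value=0).sort_index()
    hist.index.name = "n_tissues"
    return hist


class PairingResult(NamedTuple):
    pairs: dict          # JunctionKey -> gene_id
    excluded: set        # junctions matching sites of >= 2 distinct genes
    unpaired: set        # junctions matching no annotated site


def pair_junctions_to_genes(
    junctions: Iterable[JunctionKey],
    gene_models: Mapping[str, GeneModel],
) -> PairingResult:
    """Assign each junction to the unique gene owning its donor and/or
    acceptor site.

    Site ownership comes from the gene models' exon-union gaps (their
    annotated introns).  A junction whose boundary positions match sites of
    two or more distinct genes (overlapping genes, or a donor from one gene
    with an acceptor from another) is excluded from pairing; a junction
    matching no site is unpaired.
    """
    site_owner: dict[tuple, set] = {}
    for gid, gene in gene_models.items():
        for intron in gene.introns():
            site_owner.setdefault((gene.chrom, intron.start), set()).add(gid)
            site_owner.setdefault((gene.chrom, intron.end), set()).add(gid)
    pairs: dict[JunctionKey, str] = {}
    excluded: set[JunctionKey] = set()
    unpaired: set[JunctionKey] = set()
    for key in junctions:
        owners = set()
        owners |= site_owner.get((key.chrom, key.start), set())
        owners |= site_owner.get((key.chrom, key.end), set())
        if not owners:
            unpaired.add(key)
        elif len(owners) == 1:
            pairs[key] = next(iter(owners))
        else:
            excluded.add(key)
    return PairingResult(pairs, excluded, unpaired)


def specificity_matrix(
    pairs: Mapping[JunctionKey, str],
    presence_junction: PresenceMatrix,
    presence_gene: PresenceMatrix,
) -> pd.DataFrame:
    """T x T grid: cell (j, g) counts pairs whose junction is present in j
    tissues and gene in g tissues.

    Pairs whose junction or gene is expressed in zero tissues are dropped;
    every remaining pair increments exactly one cell, so the grid sums to the
    number of retained pairs.
    """
    T = len(presence_junction.tissues)
    nj = presence_junction.n_tissues()
    ng = presence_gene.n_tissues()
    grid = pd.DataFrame(
        0, index=pd.RangeIndex(1, T + 1, name="junction_tissues"),
        columns=pd.RangeIndex(1, T + 1, name="gene_tissues"),
    )
    for key, gid in pairs.items():
        j = int(nj.get(str(key), 0))
        g = int(ng.get(gid, 0))
        if j == 0 or g == 0:
            continue
        grid.loc[j, g] += 1
    return grid


class ConcordanceResult(NamedTuple):
    n_both: int
    n_a_only: int
    n_b_only: int
    fraction: float


def concordance(set_a: Iterable, set_b: Iterable) -> ConcordanceResult:
    """Exact-key overlap between two junction sets: |A&B| / |A|B|."""
    a, b = set(set_a), set(set_b)
    both = a & b
    union = a | b
    frac = len(both) / len(union) if union else 1.0
    return ConcordanceResult(len(both), len(a - b), len(b - a), frac)


def concordance_by_class(set_a, set_b, classes: Mapping) -> dict:
    """Concordance for all junctions and for annotated vs novel subsets."""
    a, b = set(set_a), set(set_b)

    def _subset(keys, annotated: bool):
        return {k for k in keys if (classes.get(k) == "annotated") == annotated}

    return {
        "all": concordance(a, b),
        "annotated": concordance(_subset(a, True), _subset(b, True)),
        "novel": concordance(_subset(a, False), _subset(b, False)),
    }


def filtered_vs_unfiltered_overlap(filtered_a: Iterable, unfiltered_b: Iterable) -> float:
    """Fraction of filtered junctions from one library found anywhere in the
    other library's unfiltered catalog (threshold near-misses included)."""
    a = set(filtered_a)
    if not a:
        raise ValueError("filtered set is empty")
    return len(a & set(unfiltered_b)) / len(a)


def specific_entities(presence: PresenceMatrix) -> dict:
    """Per-tissue sets of entities present in exactly that one tissue."""
    nj = presence.n_tissues()
    single = presence.data.loc[nj[nj == 1].index]
    out: dict[str, set] = {t: set() for t in presence.tissues}
    for entity, row in single.iterrows():
        out[row.idxmax()].add(entity)
    return out


def tissue_specific_lists(
    presence_a: PresenceMatrix,
    presence_b: PresenceMatrix | None = None,
) -> dict:
    """Entities specific to the same single tissue in both libraries.

    With one matrix (single-library mode) returns its per-tissue specific
    sets directly.  The tissue universes must agree.
    """
    lists_a = specific_entities(presence_a)
    if presence_b is None:
        return lists_a
    if set(presence_a.tissues) != set(presence_b.tissues):
        raise ValueError("tissue universes differ between libraries")
    lists_b = specific_entities(presence_b)
    return {t: lists_a[t] & lists_b[t] for t in lists_a}


def genes_with_specific_junctions(
    pairs: Mapping[JunctionKey, str],
    presence_junction: PresenceMatrix,
    presence_gene: PresenceMatrix,
    gene_models: Mapping[str, GeneModel],
) -> pd.DataFrame:
    """Multi-exon gene summary: how many expressed genes contain at least
    one junction present in exactly one tissue.

    Rows cover genes expressed at all, in more than one tissue, and in every
    tissue; single-exon genes are excluded throughout.
    """
    T = len(presence_gene.tissues)
    ng = presence_gene.n_tissues()
    nj = presence_junction.n_tissues()
    specific_junctions = set(nj[nj == 1].index)
    genes_with_spec = {
        gid for key, gid in pairs.items() if str(key) in specific_junctions
    }
    multi = {gid for gid, g in gene_models.items() if g.multi_exon}
    rows = {}
    for label, pred in (
        ("expressed", lambda n: n >= 1),
        ("expressed_gt1_tissue", lambda n: n > 1),
        (f"expressed_all_{T}_tissues", lambda n: n == T),
    ):
        genes = {g for g in multi if pred(int(ng.get(g, 0)))}
        with_spec = genes & genes_with_spec
        rows[label] = {
            "n_genes": len(genes),
            "n_with_specific_junction": len(with_spec),
            "pct_with_specific_junction": 100.0 * len(with_spec) / len(genes) if genes else 0.0,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def detection_ratio(
    matrix_junction: ExpressionMatrix,
    matrix_gene: ExpressionMatrix,
    thresholds: Sequence[float] = EXPRESSION_THRESHOLDS,
) -> pd.DataFrame:
    """Detectable-junction / detectable-gene ratio per threshold.

    A flat ratio across thresholds argues against a detection bias toward
    contiguous gene sequence at low expression.
    """
    rows = {}
    for tau in thresholds:
        nj = int((presence_calls(matrix_junction, tau).n_tissues() > 0).sum())
        ng = int((presence_calls(matrix_gene, tau).n_tissues() > 0).sum())
        rows[tau] = {
            "n_junctions": nj,
            "n_genes": ng,
            "ratio": nj / ng if ng else float("nan"),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "threshold"
    return df
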