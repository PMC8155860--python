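"""Hypergeometric over-representation analysis with structure-composition scores.

A query gene list (typically the mRNAs of a filtered pair set) is tested
against each set of a GMT collection: with universe size N, set size K
(after intersecting the set with the universe), query size n and overlap k,
the p-value is the upper tail P(X >= k) of Hypergeometric(N, K, n). BH
correction runs across all tested sets (same step-up routine as the pair
inference stage).

Each significant set additionally gets a cell-structure composition score:
the fraction of its overlap genes found in a user-supplied structure-gene
list (cytoskeleton / cell adhesion / extracellular-matrix genes), normalized
by the maximum fraction among significant sets so the most structural
pathway scores exactly 1.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .io import GeneSetCollection
from .pair_inference import bh_adjust

logger = logging.getLogger("mirpair")


def hypergeometric_pvalue(k: int, big_k: int, n: int, big_n: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N=big_n, K=big_k, n)."""
    return float(stats.hypergeom.sf(k - 1, big_n, big_k, n))


def hypergeometric_enrichment(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Test every gene set for over-representation of the query.

    Returns one row per set, sorted by adjusted p ascending, with columns
    ``set_id``, ``k``, ``K``, ``n``, ``N``, ``p_value``, ``adj_p``,
    ``significant`` and the overlap gene list (``overlap_genes``). Gene sets
    are intersected with the universe before testing; the query must be a
    subset of the universe.
    """
    universe_set = set(universe)
    query_set = set(query)
    stray = sorted(query_set - universe_set)
    if stray:
        raise ValueError(f"query genes missing from universe: {stray[:10]}")
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")

    big_n, n = len(universe_set), len(query_set)
    rows = []
    for set_id, genes in collection.items():
        members = set(genes) & universe_set
        overlap = sorted(members & query_set)
        rows.append(
            {
                "set_id": set_id,
                "k": len(overlap),
                "K": len(members),
                "n": n,
                "N": big_n,
                "p_value": hypergeometric_pvalue(len(overlap), len(members), n, big_n),
                "overlap_genes": overlap,
            }
        )
    table = pd.DataFrame(rows)
    table["adj_p"] = bh_adjust(table["p_value"].to_numpy())
    table["significant"] = table["adj_p"] < alpha
    table = table.sort_values(
        by=["adj_p", "set_id"], kind="mergesort", ignore_index=True
    )
    logger.info(
        "enrichment: %d sets tested, %d significant at adj_p < %.2f",
        len(table), int(table["significant"].sum()), alpha,
    )
    return table


def structure_scores(records: pd.DataFrame, structure_genes: Iterable[str]) -> pd.DataFrame:
    """Per-record structure fraction and max-normalized structure score.

    ``structure_fraction`` is (#structure genes in overlap) / k (0 when the
    overlap is empty); ``structure_score`` divides by the maximum fraction
    over the supplied records, so at least one record scores 1 whenever any
    overlap contains a structure gene.
    """
    structure = set(structure_genes)
    if not structure:
        raise ValueError("structure gene list is empty")
    if "overlap_genes" not in records.columns:
        raise ValueError("records lack stored overlap gene lists")
    out = records.copy()
    out["structure_fraction"] = [
        (sum(g in structure for g in genes) / len(genes)) if genes else 0.0
        for genes in out["overlap_genes"]
    ]
    max_frac = out["structure_fraction"].max() if len(out) else 0.0
    out["structure_score"] = out["structure_fraction"] / max_frac if max_frac > 0 else 0.0
    return out


def fraction_structure_dominant(records: pd.DataFrame, threshold: float = 0.5) -> float:
    """Percent of records whose structure_fraction strictly exceeds threshold.

    "More than 50% structural" is a strict inequality: a record at exactly
    0.5 does not count. Returns 0.0 (with a warning) for an empty input.
    """
    if len(records) == 0:
        logger.warning("fraction_structure_dominant on empty record list; returning 0.0")
        return 0.0
    n_above = int((records["structure_fraction"] > threshold).sum())
    return round(100.0 * n_above / len(records), 1)


def enrichment_table(records: pd.DataFrame) -> pd.DataFrame:
    """Flat TSV-ready view (overlap lists joined with ';')."""
    out = records.copy()
    out["overlap_genes"] = out["overlap_genes"].map(";".join)
    return out
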