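"""Cross-condition comparison of pair sets.

Intersects two filtered pair sets on exact (mirna_id, mrna_id) keys, reports
shared-fraction percentages, and summarises regulator structure: distinct
targets per miRNA with cumulative unique-target coverage (Cum%), and distinct
regulators per mRNA with threshold queries ("more than k regulators", strict).

Cum% is deliberately truncated (floored), not rounded, at two decimals: the
cumulative coverage of a ranked regulator table is conventionally reported as
the floor so a rank never appears to cover more of the universe than it does.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

from .pair_inference import PairSet

logger = logging.getLogger("mirpair")


@dataclass
class IntersectionSummary:
    n_common: int
    pct_of_a: float  # 100 * n_common / |A|, rounded to 1 decimal
    pct_of_b: float
    n_common_mirnas: int
    n_common_mrnas: int


def truncate2(value: float) -> float:
    """Floor to 2 decimals (31.746 -> 31.74)."""
    return math.floor(value * 100.0 + 1e-9) / 100.0


def intersect_pair_sets(set_a: PairSet, set_b: PairSet) -> tuple[PairSet, IntersectionSummary]:
    """Exact-key intersection of two pair sets.

    Common records keep set A's values; set B's correlation/adjusted p are
    retained in ``cor_b`` / ``adj_p_b`` companion columns when present.
    """
    keys_b = set_b.pair_keys()
    rec_a = set_a.records
    mask = [k in keys_b for k in zip(rec_a["mirna_id"], rec_a["mrna_id"])]
    common = rec_a[mask].reset_index(drop=True)

    b_cols = [c for c in ("cor", "adj_p") if c in set_b.records.columns]
    if b_cols and len(common):
        b_idx = set_b.records.set_index(["mirna_id", "mrna_id"])
        b_idx = b_idx[~b_idx.index.duplicated()]
        aligned = b_idx.reindex(list(zip(common["mirna_id"], common["mrna_id"])))
        for c in b_cols:
            common[f"{c}_b"] = aligned[c].to_numpy()

    n_common = len(common)
    summary = IntersectionSummary(
        n_common=n_common,
        pct_of_a=round(100.0 * n_common / len(set_a), 1) if len(set_a) else 0.0,
        pct_of_b=round(100.0 * n_common / len(set_b), 1) if len(set_b) else 0.0,
        n_common_mirnas=common["mirna_id"].nunique(),
        n_common_mrnas=common["mrna_id"].nunique(),
    )
    label = f"{set_a.condition_label}&{set_b.condition_label}".strip("&")
    logger.info(
        "intersection: %d common pairs (%.1f%% of A, %.1f%% of B), %d miRNAs x %d mRNAs",
        n_common, summary.pct_of_a, summary.pct_of_b,
        summary.n_common_mirnas, summary.n_common_mrnas,
    )
    common_set = PairSet(common, {"n_predicted_intersection": n_common}, label)
    return common_set, summary


def targets_per_mirna(
    pair_set: PairSet, universe_size: int | None = None, top_n_targets: int = 20
) -> pd.DataFrame:
    """Distinct-target counts per miRNA with cumulative unique coverage.

    Rows are ranked by target count descending (ties: miRNA id lexicographic).
    ``cum_pct`` at rank k is 100 * |union of targets of ranks 1..k| /
    universe, truncated to 2 decimals. The universe defaults to the unique
    mRNAs of the pair set itself; pass ``universe_size`` (e.g. the DE-mRNA
    count) for coverage of a wider universe.
    """
    rec = pair_set.records[["mirna_id", "mrna_id"]].drop_duplicates()
    if rec.empty:
        raise ValueError("pair set is empty")
    n_unique = rec["mrna_id"].nunique()
    if universe_size is None:
        universe_size = n_unique
    elif universe_size < n_unique:
        raise ValueError(
            f"universe_size ({universe_size}) smaller than observed unique targets ({n_unique})"
        )

    grouped = rec.groupby("mirna_id")["mrna_id"].agg(sorted)
    order = sorted(grouped.index, key=lambda m: (-len(grouped[m]), m))
    rows = []
    covered: set[str] = set()
    for mirna in order:
        targets = grouped[mirna]
        covered |= set(targets)
        rows.append(
            {
                "mirna_id": mirna,
                "n_targets": len(targets),
                "cum_pct": truncate2(100.0 * len(covered) / universe_size),
                "top_targets": targets[:top_n_targets],
            }
        )
    return pd.DataFrame(rows)


def mirnas_per_mrna(pair_set: PairSet) -> pd.DataFrame:
    """Distinct-regulator counts per mRNA, sorted descending then lexicographic."""
    rec = pair_set.records[["mirna_id", "mrna_id"]].drop_duplicates()
    if rec.empty:
        raise ValueError("pair set is empty")
    counts = rec.groupby("mrna_id")["mirna_id"].nunique().rename("n_regulators")
    out = counts.reset_index()
    return out.sort_values(
        by=["n_regulators", "mrna_id"], ascending=[False, True], kind="mergesort", ignore_index=True
    )


def count_exceeding(counts: pd.Series | pd.DataFrame, threshold: int, column: str | None = None) -> tuple[int, float]:
    """How many entries exceed (strictly) a count threshold, and what percent.

    "More than 5 regulators" means > 5, never >= 5.
    """
    values = counts[column] if column is not None else counts
    if isinstance(values, pd.DataFrame):
        raise ValueError("pass a Series or name the count column")
    n = int((values > threshold).sum())
    pct = round(100.0 * n / len(values), 1) if len(values) else 0.0
    return n, pct
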