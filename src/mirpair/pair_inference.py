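"""Exhaustive miRNA-mRNA negative-correlation pair inference.

Every differentially expressed miRNA is correlated (Pearson, all samples
pooled) against every differentially expressed mRNA; two-sided p-values come
from the exact t transform t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of
freedom, Benjamini-Hochberg correction is applied jointly over the full
candidate family, and candidate pairs are filtered to negative, significant
(adj p < alpha, strict) and predicted in at least ``min_dbs`` of the supplied
target-prediction databases. The surviving records form a :class:`PairSet`
whose counters record the filtering funnel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import PredictionDB

logger = logging.getLogger("mirpair")

PAIR_TABLE_COLUMNS = ["miRNA", "mRNA", "Cor", "Adj.pval", "FC.miRNA", "FC.mRNA", "Dat.Sum"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    adj(i) = min_{j >= i in sort order} min(1, p(j) * m / j). Shared by every
    multiple-testing step in the pipeline.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass
class PairSet:
    """A filtered collection of candidate pairs for one condition.

    ``records`` carries one row per pair with columns ``mirna_id``,
    ``mrna_id``, ``cor``, ``p_value`` and, once populated, ``adj_p``,
    ``fc_mirna``, ``fc_mrna``, ``dat_sum``. ``counters`` records the funnel:
    total_candidates >= n_negative >= n_significant_negative >=
    n_predicted_intersection.
    """

    records: pd.DataFrame
    counters: dict[str, int] = field(default_factory=dict)
    condition_label: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def pair_keys(self) -> set[tuple[str, str]]:
        return set(zip(self.records["mirna_id"], self.records["mrna_id"]))


def correlate_all_pairs(mirna_matrix: pd.DataFrame, mrna_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson r and two-sided p for every (miRNA, mRNA) combination.

    Both matrices must share identical ordered sample columns; n >= 3 samples
    are required for the t transform. Zero-variance features are dropped with
    a warning (their correlation is undefined). |r| = 1 maps to p = 0.
    """
    if list(mirna_matrix.columns) != list(mrna_matrix.columns):
        raise ValueError("sample mismatch: miRNA and mRNA matrices must share ordered sample columns")
    n = mirna_matrix.shape[1]
    if n < 3:
        raise ValueError(f"need >= 3 samples for correlation p-values, got {n}")

    x = mirna_matrix.to_numpy(dtype=float)
    y = mrna_matrix.to_numpy(dtype=float)
    x_sd = x.std(axis=1)
    y_sd = y.std(axis=1)
    keep_x = x_sd > 0
    keep_y = y_sd > 0
    if not keep_x.all():
        logger.warning("dropping %d zero-variance miRNA(s) from correlation", int((~keep_x).sum()))
    if not keep_y.all():
        logger.warning("dropping %d zero-variance mRNA(s) from correlation", int((~keep_y).sum()))
    mirna_ids = mirna_matrix.index[keep_x]
    mrna_ids = mrna_matrix.index[keep_y]
    x = x[keep_x]
    y = y[keep_y]

    xc = (x - x.mean(axis=1, keepdims=True)) / (x.std(axis=1, keepdims=True) * np.sqrt(n))
    yc = (y - y.mean(axis=1, keepdims=True)) / (y.std(axis=1, keepdims=True) * np.sqrt(n))
    r = np.clip(xc @ yc.T, -1.0, 1.0)

    with np.errstate(divide="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    # the t transform diverges at |r| = 1; define p = 0 there (within float eps)
    p[np.abs(r) >= 1.0 - 1e-12] = 0.0

    out = pd.DataFrame(
        {
            "mirna_id": np.repeat(mirna_ids, len(mrna_ids)),
            "mrna_id": np.tile(mrna_ids, len(mirna_ids)),
            "cor": r.ravel(),
            "p_value": p.ravel(),
        }
    )
    logger.info("correlated %d miRNAs x %d mRNAs = %d candidate pairs", len(mirna_ids), len(mrna_ids), len(out))
    return out


def filter_pairs(pair_set: PairSet, alpha: float = 0.05) -> PairSet:
    """Retain negative, significant pairs (cor < 0 and adj_p < alpha, strict).

    Updates counters: n_negative counts cor < 0 regardless of significance;
    n_significant_negative counts pairs passing both filters.
    """
    rec = pair_set.records
    if "adj_p" not in rec.columns:
        raise ValueError("adj_p must be populated before filtering")
    negative = rec[rec["cor"] < 0]
    kept = negative[negative["adj_p"] < alpha].reset_index(drop=True)
    counters = dict(pair_set.counters)
    counters["n_negative"] = len(negative)
    counters["n_significant_negative"] = len(kept)
    return PairSet(kept, counters, pair_set.condition_label)


def annotate_predictions(
    pair_set: PairSet, databases: list[PredictionDB], min_dbs: int = 1
) -> PairSet:
    """Count supporting databases per pair (``dat_sum``) and apply the cut.

    A pair's dat_sum is the number of databases listing the exact
    (mirna_id, mrna_id) tuple; pairs below ``min_dbs`` are removed.
    """
    if not databases:
        raise ValueError("at least one prediction database is required")
    rec = pair_set.records.copy()
    keys = list(zip(rec["mirna_id"], rec["mrna_id"]))
    rec["dat_sum"] = [sum(k in db.pairs for db in databases) for k in keys]
    kept = rec[rec["dat_sum"] >= min_dbs].reset_index(drop=True)
    counters = dict(pair_set.counters)
    counters["n_predicted_intersection"] = len(kept)
    return PairSet(kept, counters, pair_set.condition_label)


def infer_pairs(
    mirna_matrix_de: pd.DataFrame,
    mrna_matrix_de: pd.DataFrame,
    de_mirna: pd.DataFrame,
    de_mrna: pd.DataFrame,
    databases: list[PredictionDB],
    alpha: float = 0.05,
    min_dbs: int = 1,
    condition_label: str = "",
) -> PairSet:
    """Full chain: correlate, BH-adjust jointly, filter, annotate.

    ``de_mirna`` / ``de_mrna`` are DE tables (feature_id, signed_fc, ...)
    supplying the fold-change columns of the output records.
    """
    records = correlate_all_pairs(mirna_matrix_de, mrna_matrix_de)
    records["adj_p"] = bh_adjust(records["p_value"].to_numpy())
    fc_mi = de_mirna.set_index("feature_id")["signed_fc"]
    fc_mr = de_mrna.set_index("feature_id")["signed_fc"]
    records["fc_mirna"] = records["mirna_id"].map(fc_mi).to_numpy()
    records["fc_mrna"] = records["mrna_id"].map(fc_mr).to_numpy()
    pair_set = PairSet(records, {"total_candidates": len(records)}, condition_label)
    pair_set = filter_pairs(pair_set, alpha=alpha)
    pair_set = annotate_predictions(pair_set, databases, min_dbs=min_dbs)
    c = pair_set.counters
    logger.info(
        "[%s] funnel: %d candidates -> %d negative -> %d significant -> %d predicted",
        condition_label or "pairs", c["total_candidates"], c["n_negative"],
        c["n_significant_negative"], c["n_predicted_intersection"],
    )
    return pair_set


def build_pair_table(pair_set: PairSet) -> pd.DataFrame:
    """Render a filtered PairSet as the seven-column report table.

    Columns: miRNA, mRNA, Cor, Adj.pval, FC.miRNA, FC.mRNA, Dat.Sum. Sorted
    by adj_p ascending, then |cor| descending, then (miRNA, mRNA)
    lexicographic. Cor and FCs are fixed to 2 decimals; Adj.pval uses
    3-significant-digit scientific notation.
    """
    rec = pair_set.records.copy()
    for col in ("adj_p", "dat_sum", "fc_mirna", "fc_mrna"):
        if col not in rec.columns:
            raise ValueError(f"pair set lacks required column {col!r}")
    rec["_abscor"] = rec["cor"].abs()
    rec = rec.sort_values(
        by=["adj_p", "_abscor", "mirna_id", "mrna_id"],
        ascending=[True, False, True, True],
        kind="mergesort",
        ignore_index=True,
    )
    return pd.DataFrame(
        {
            "miRNA": rec["mirna_id"],
            "mRNA": rec["mrna_id"],
            "Cor": rec["cor"].map("{:.2f}".format),
            "Adj.pval": rec["adj_p"].map("{:.2e}".format),
            "FC.miRNA": rec["fc_mirna"].map("{:.2f}".format),
            "FC.mRNA": rec["fc_mrna"].map("{:.2f}".format),
            "Dat.Sum": rec["dat_sum"].astype(int),
        }
    )


def write_pair_table(pair_set: PairSet, path: str | Path) -> None:
    build_pair_table(pair_set).to_csv(path, sep="\t", index=False)


def read_pair_records(path: str | Path) -> PairSet:
    """Load a pair TSV (either raw-record or report-table column names)."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) == ["miRNA", "mRNA"]:
        df = df.rename(
            columns={
                "miRNA": "mirna_id", "mRNA": "mrna_id", "Cor": "cor",
                "Adj.pval": "adj_p", "FC.miRNA": "fc_mirna",
                "FC.mRNA": "fc_mrna", "Dat.Sum": "dat_sum",
            }
        )
    return PairSet(df, {"n_predicted_intersection": len(df)})
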