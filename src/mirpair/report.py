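"""Run-level summaries: the filtering funnel, threshold queries, and a
machine-readable run report.

All percentages are recomputed from raw counts at full precision and only
then formatted, each with the convention of the statistic it reports:
funnel and threshold percentages to 1 decimal, the targeted-mRNA percentage
to the nearest integer, cumulative coverage truncated to 2 decimals. The
formatting conventions live here, in one place.
"""

from __future__ import annotations

import datetime
import json
import logging
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .comparative import (
    IntersectionSummary,
    count_exceeding,
    mirnas_per_mrna,
    targets_per_mirna,
)
from .enrichment import fraction_structure_dominant
from .pair_inference import PairSet

logger = logging.getLogger("mirpair")


# ---------------------------------------------------------------------------
# formatting conventions (single source of truth)
# ---------------------------------------------------------------------------

def pct_1dp(numerator: float, denominator: float) -> float:
    """Percentage rounded to 1 decimal (funnel / intersection style)."""
    return round(100.0 * numerator / denominator, 1) if denominator else 0.0


def pct_int(numerator: float, denominator: float) -> int:
    """Percentage rounded to nearest integer (targeted-mRNA style)."""
    return round(100.0 * numerator / denominator) if denominator else 0


# ---------------------------------------------------------------------------
# report schema
# ---------------------------------------------------------------------------

class FunnelSummary(BaseModel):
    condition: str
    total_candidates: int = Field(ge=0)
    n_negative: int = Field(ge=0)
    n_significant_negative: int = Field(ge=0)
    n_predicted_intersection: int = Field(ge=0)
    pct_significant_negative: float = Field(ge=0, le=100)
    n_paired_mirnas: int = Field(ge=0)
    n_paired_mrnas: int = Field(ge=0)


class ThresholdSummary(BaseModel):
    pct_mirnas_gt20_targets: float = Field(ge=0, le=100)
    pct_mrnas_gt5_regulators: float = Field(ge=0, le=100)
    pct_mrnas_targeted: int = Field(ge=0, le=100)


class IntersectionReport(BaseModel):
    n_common: int = Field(ge=0)
    pct_of_a: float = Field(ge=0, le=100)
    pct_of_b: float = Field(ge=0, le=100)
    n_common_mirnas: int = Field(ge=0)
    n_common_mrnas: int = Field(ge=0)


class EnrichmentHeadline(BaseModel):
    n_significant_sets: int = Field(ge=0)
    pct_structure_dominant: float = Field(ge=0, le=100)


class RunReport(BaseModel):
    """Machine-readable summary of one pipeline run."""

    version: str
    seed: Optional[int] = None
    timestamp: str = ""
    funnels: list[FunnelSummary]
    thresholds: Optional[ThresholdSummary] = None
    intersection: Optional[IntersectionReport] = None
    enrichment: Optional[EnrichmentHeadline] = None
    hubs: list[str] = []


def summarize_run(
    pair_sets: list[PairSet],
    de_mrna_count: int | None = None,
    intersection: IntersectionSummary | None = None,
    enrichment_records: pd.DataFrame | None = None,
    hub_nodes: list[str] | None = None,
    seed: int | None = None,
) -> RunReport:
    """Assemble the run report from upstream artifacts.

    ``pair_sets`` must carry complete funnel counters; threshold summaries
    are computed on the first pair set (the primary condition), with
    ``de_mrna_count`` as denominator for the targeted-mRNA percentage.
    """
    if not pair_sets:
        raise ValueError("missing upstream artifact: at least one pair set is required")
    funnels = []
    for ps in pair_sets:
        c = ps.counters
        for key in ("total_candidates", "n_negative", "n_significant_negative",
                    "n_predicted_intersection"):
            if key not in c:
                raise ValueError(f"missing upstream artifact: counter {key!r} in pair set "
                                 f"{ps.condition_label!r}")
        funnels.append(
            FunnelSummary(
                condition=ps.condition_label or "condition",
                total_candidates=c["total_candidates"],
                n_negative=c["n_negative"],
                n_significant_negative=c["n_significant_negative"],
                n_predicted_intersection=c["n_predicted_intersection"],
                pct_significant_negative=pct_1dp(c["n_significant_negative"], c["total_candidates"]),
                n_paired_mirnas=ps.records["mirna_id"].nunique() if len(ps) else 0,
                n_paired_mrnas=ps.records["mrna_id"].nunique() if len(ps) else 0,
            )
        )

    thresholds = None
    primary = pair_sets[0]
    if len(primary) and de_mrna_count:
        per_mirna = targets_per_mirna(primary)
        _, pct_gt20 = count_exceeding(per_mirna["n_targets"], 20)
        per_mrna = mirnas_per_mrna(primary)
        _, pct_gt5 = count_exceeding(per_mrna["n_regulators"], 5)
        thresholds = ThresholdSummary(
            pct_mirnas_gt20_targets=pct_gt20,
            pct_mrnas_gt5_regulators=pct_gt5,
            pct_mrnas_targeted=pct_int(primary.records["mrna_id"].nunique(), de_mrna_count),
        )

    inter_report = None
    if intersection is not None:
        inter_report = IntersectionReport(
            n_common=intersection.n_common,
            pct_of_a=intersection.pct_of_a,
            pct_of_b=intersection.pct_of_b,
            n_common_mirnas=intersection.n_common_mirnas,
            n_common_mrnas=intersection.n_common_mrnas,
        )

    enrich_headline = None
    if enrichment_records is not None:
        significant = enrichment_records[enrichment_records["significant"]]
        pct_dom = (
            fraction_structure_dominant(significant)
            if "structure_fraction" in significant.columns
            else 0.0
        )
        enrich_headline = EnrichmentHeadline(
            n_significant_sets=len(significant), pct_structure_dominant=pct_dom
        )

    return RunReport(
        version=__version__,
        seed=seed,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds"),
        funnels=funnels,
        thresholds=thresholds,
        intersection=inter_report,
        enrichment=enrich_headline,
        hubs=list(hub_nodes or []),
    )


def report_json(report: RunReport) -> str:
    return json.dumps(report.model_dump(), indent=2, sort_keys=True)


def report_text(report: RunReport) -> str:
    """Human-readable rendering; every number equals the JSON field after
    formatting."""
    lines = [f"mirpair run report (version {report.version}, seed {report.seed})"]
    for f in report.funnels:
        lines.append(
            f"[{f.condition}] {f.total_candidates} candidate pairs -> "
            f"{f.n_negative} negative -> {f.n_significant_negative} significant "
            f"({f.pct_significant_negative}%) -> {f.n_predicted_intersection} predicted; "
            f"{f.n_paired_mirnas} miRNAs x {f.n_paired_mrnas} mRNAs paired"
        )
    if report.thresholds:
        t = report.thresholds
        lines.append(
            f"targets per miRNA: {t.pct_mirnas_gt20_targets}% of paired miRNAs have >20 targets; "
            f"{t.pct_mrnas_gt5_regulators}% of paired mRNAs have >5 regulators; "
            f"{t.pct_mrnas_targeted}% of DE mRNAs are targeted"
        )
    if report.intersection:
        i = report.intersection
        lines.append(
            f"intersection: {i.n_common} common pairs ({i.pct_of_a}% of A, {i.pct_of_b}% of B), "
            f"{i.n_common_mirnas} miRNAs x {i.n_common_mrnas} mRNAs"
        )
    if report.enrichment:
        e = report.enrichment
        lines.append(
            f"enrichment: {e.n_significant_sets} significant sets, "
            f"{e.pct_structure_dominant}% structure-dominant"
        )
    if report.hubs:
        lines.append("hub regulators: " + ", ".join(report.hubs))
    return "\n".join(lines) + "\n"
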