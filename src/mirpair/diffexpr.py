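"""Two-group differential expression on log2 expression matrices.

Two test flavours are exposed:

* ``plain`` — Welch two-sample t-test per feature (unequal variances,
  Satterthwaite degrees of freedom).
* ``moderated`` — pooled-variance t with empirical-Bayes variance moderation:
  per-feature pooled variances are shrunk toward a cross-feature prior fitted
  by the scaled-inverse-chi-square moment method, and the residual degrees of
  freedom are augmented by the estimated prior degrees of freedom. This is the
  moderated t-statistic commonly used for small-sample microarray designs.

P-values are two-sided; multiple testing is corrected with Benjamini-Hochberg
within the matrix (i.e. per molecule type when miRNA and mRNA matrices are
processed separately). Fold changes follow the signed-magnitude convention:
+ratio when up in lesion, -1/ratio when down, so |signed FC| >= 1 always.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats

from .pair_inference import bh_adjust

logger = logging.getLogger("mirpair")

ALPHA_DEFAULT = 0.05


def log2p1(counts: pd.DataFrame) -> pd.DataFrame:
    """Convenience log2(x + 1) transform for raw-count input."""
    return np.log2(counts + 1.0)


def signed_fold_change(mean_lesion_log2, mean_control_log2):
    """Signed linear fold change from two log2 means.

    ratio = 2**(lesion - control); returns ratio if >= 1 else -1/ratio, so a
    4-fold drop is reported as -4.0 rather than 0.25. Accepts scalars or
    arrays.
    """
    diff = np.asarray(mean_lesion_log2, dtype=float) - np.asarray(mean_control_log2, dtype=float)
    ratio = np.exp2(diff)
    out = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    return float(out) if out.ndim == 0 else out


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-fit of a scaled inverse-chi-square prior to pooled variances.

    Works on log variances: if s2 ~ s0^2 * F(df, d0) then
    e = log(s2) - digamma(df/2) + log(df/2) has mean log(s0^2) + digamma(d0/2)
    - log(d0/2) and variance trigamma(df/2) + trigamma(d0/2). Returns
    (d0, s0^2); d0 = inf when the observed spread is no larger than expected
    under a single common variance.
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1))
    excess = e_var - float(special.polygamma(1, df / 2.0))
    if excess <= 0:
        # no over-dispersion beyond chi-square sampling: single common variance
        return np.inf, float(np.mean(s2))
    # invert trigamma(d0/2) = excess by Newton on x = d0/2
    x = 0.5 + 1.0 / excess  # asymptotic start: trigamma(x) ~ 1/x
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dtri = float(special.polygamma(2, x))
        x = max(x + tri * (1.0 - tri / excess) / dtri, 1e-8)
        if abs(tri - excess) < 1e-12 * excess:
            break
    d0 = 2.0 * x
    s0_sq = float(np.exp(e_mean + special.digamma(x) - np.log(x)))
    return d0, s0_sq


def differential_expression(
    matrix: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    method: str = "moderated",
) -> pd.DataFrame:
    """Per-feature two-group DE table (lesion vs control).

    Returns a DataFrame ordered by feature id with columns ``feature_id``,
    ``log2fc``, ``signed_fc``, ``p_value``, ``adj_p`` and ``direction``
    (up/down in lesion). Zero-variance features in both groups get p = 1
    with a logged warning rather than NaN.
    """
    if method not in ("plain", "moderated"):
        raise ValueError(f"unknown method {method!r}; expected 'plain' or 'moderated'")
    groups = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
    ctrl_cols = [c for c in matrix.columns if groups.get(c) == "control"]
    les_cols = [c for c in matrix.columns if groups.get(c) == "lesion"]
    if len(ctrl_cols) < 2 or len(les_cols) < 2:
        raise ValueError(
            f"each group needs >= 2 samples, got {len(ctrl_cols)} control / {len(les_cols)} lesion"
        )
    if matrix.isna().any().any():
        raise ValueError("expression matrix contains missing values")

    x = matrix[les_cols].to_numpy(dtype=float)
    y = matrix[ctrl_cols].to_numpy(dtype=float)
    n1, n2 = x.shape[1], y.shape[1]
    m1, m2 = x.mean(axis=1), y.mean(axis=1)
    v1, v2 = x.var(axis=1, ddof=1), y.var(axis=1, ddof=1)
    log2fc = m1 - m2

    degenerate = (v1 == 0) & (v2 == 0)
    if degenerate.any():
        logger.warning(
            "%d feature(s) with zero variance in both groups; p set to 1", int(degenerate.sum())
        )

    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "plain":
            se2 = v1 / n1 + v2 / n2
            t = log2fc / np.sqrt(se2)
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            p = 2.0 * stats.t.sf(np.abs(t), df)
        else:
            df_resid = n1 + n2 - 2
            s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df_resid
            d0, s0_sq = _fit_variance_prior(s2, df_resid)
            if np.isinf(d0):
                s2_post = np.full_like(s2, s0_sq)
                df_total = np.inf
            else:
                s2_post = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
                df_total = d0 + df_resid
            t = log2fc / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
            if np.isinf(df_total):
                p = 2.0 * stats.norm.sf(np.abs(t))
            else:
                p = 2.0 * stats.t.sf(np.abs(t), df_total)

    p = np.where(degenerate, 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    t = np.where(degenerate, 0.0, t)
    t = np.where(np.isnan(t), 0.0, t)

    table = pd.DataFrame(
        {
            "feature_id": matrix.index,
            "log2fc": log2fc,
            "signed_fc": signed_fold_change(m1, m2),
            "t_stat": t,
            "p_value": p,
        }
    ).sort_values("feature_id", kind="mergesort", ignore_index=True)
    table["adj_p"] = bh_adjust(table["p_value"].to_numpy())
    table["direction"] = np.where(table["log2fc"] > 0, "up", "down")
    logger.info(
        "differential expression (%s): %d features, %d with adj_p < %.2f",
        method, len(table), int((table["adj_p"] < ALPHA_DEFAULT).sum()), ALPHA_DEFAULT,
    )
    return table


def select_significant(de_table: pd.DataFrame, alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """The FDR < alpha selection defining the DE feature universe (strict <)."""
    return de_table[de_table["adj_p"] < alpha].reset_index(drop=True)
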