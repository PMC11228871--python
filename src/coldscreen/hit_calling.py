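"""Outlier-based hit calling within one query screen.

A "hit" is a gene whose log2 statistic is an outlier of the screen's
distribution, in a stated direction. Two callers are provided:

``two_sd``
    Genes at least 2 sample SDs away from the distribution center. The
    center is the median (robust to the interaction tails); the SD is the
    sample SD of the finite values (mean-centered by default, see
    :func:`coldscreen.scoring.summarize_distribution`).

``percentile25``
    The top quartile of the relevant tail: the ceil(0.25 * n) largest
    (direction ``positive``) or smallest (``negative``) values, rank-based
    rather than interpolated-quantile-based so the selection is identical
    across quantile dialects. Ties at the k-th value are all included when
    that grows the list by at most ceil(0.01 * n) genes; otherwise the tie
    is broken by lexicographic gene_id. The rule is deterministic and
    mirrored by the brute-force oracle in the test suite.

Genes whose chosen statistic is undefined (NaN or +/-inf, e.g. NGR voided
by a zero reference size) are excluded before calling; use
:func:`usable_scores` to obtain the excluded side table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AnalysisError, DegenerateDistributionError
from .scoring import DistributionSummary, summarize_distribution

VALID_STATISTICS = ("log2_ngr", "log2_ng_30", "log2_ng_19")
DIRECTIONS = ("positive", "negative")
METHODS = ("two_sd", "percentile25")

#: Analysis-goal -> statistic routing. The interaction measure at the
#: permissive temperature is log2 NG(30C); cold-specific effects are read
#: from log2 NGR.
GOAL_STATISTICS = {
    "permissive_interaction": "log2_ng_30",
    "cold_specific": "log2_ngr",
}


@dataclass(frozen=True)
class HitCall:
    """One gene flagged as an outlier in one screen."""

    gene_id: str
    query_label: str
    statistic_name: str
    value: float
    direction: str
    method: str
    threshold_used: float


def select_statistic(query_label: str, analysis_goal: str) -> str:
    """Route an analysis goal to the statistic it is read from."""
    try:
        return GOAL_STATISTICS[analysis_goal]
    except KeyError:
        raise AnalysisError(
            f"unknown analysis goal {analysis_goal!r} for query {query_label!r}; "
            f"expected one of {sorted(GOAL_STATISTICS)}"
        ) from None


def usable_scores(scores: pd.DataFrame, statistic_name: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a score table into rows with a finite statistic and the rest."""
    if statistic_name not in VALID_STATISTICS:
        raise AnalysisError(f"unknown statistic {statistic_name!r}")
    finite = np.isfinite(scores[statistic_name].to_numpy(dtype=float))
    return scores.loc[finite], scores.loc[~finite]


def _check_direction(direction: str) -> None:
    if direction not in DIRECTIONS:
        raise AnalysisError(f"direction must be one of {DIRECTIONS}, got {direction!r}")


def _query_label(scores: pd.DataFrame) -> str:
    if "query_label" in scores.columns and len(scores):
        return str(scores["query_label"].iloc[0])
    return str(scores.attrs.get("query_label", ""))


def call_hits_two_sd(
    scores: pd.DataFrame,
    statistic_name: str,
    direction: str,
    *,
    sd_center: str = "mean",
    min_genes: int = 10,
) -> tuple[list[HitCall], DistributionSummary]:
    """Call genes >= 2 SD beyond the distribution median, one direction.

    Returns the hit list (strongest first) together with the
    :class:`DistributionSummary` the threshold was derived from.
    """
    _check_direction(direction)
    ok, _ = usable_scores(scores, statistic_name)
    if len(ok) < min_genes:
        raise AnalysisError(f"need >= {min_genes} scored genes, got {len(ok)}")
    summary = summarize_distribution(ok[statistic_name], statistic_name, sd_center=sd_center)
    if summary.sd == 0:
        raise DegenerateDistributionError(
            f"{statistic_name}: zero spread, outlier threshold undefined"
        )
    label = _query_label(scores)
    if direction == "positive":
        threshold = summary.median + 2.0 * summary.sd
        sel = ok[ok[statistic_name] >= threshold]
        sel = sel.sort_values([statistic_name, "gene_id"], ascending=[False, True])
    else:
        threshold = summary.median - 2.0 * summary.sd
        sel = ok[ok[statistic_name] <= threshold]
        sel = sel.sort_values([statistic_name, "gene_id"], ascending=[True, True])
    hits = [
        HitCall(g, label, statistic_name, float(v), direction, "two_sd", float(threshold))
        for g, v in zip(sel["gene_id"], sel[statistic_name])
    ]
    return hits, summary


def call_hits_percentile(
    scores: pd.DataFrame,
    statistic_name: str,
    direction: str,
    *,
    fraction: float = 0.25,
    tie_slack: float = 0.01,
    min_genes: int = 4,
) -> list[HitCall]:
    """Call the top quartile of one tail (rank-based, deterministic ties)."""
    _check_direction(direction)
    if not 0 < fraction < 1:
        raise AnalysisError("fraction must be in (0, 1)")
    ok, _ = usable_scores(scores, statistic_name)
    n = len(ok)
    if n < min_genes:
        raise AnalysisError(f"need >= {min_genes} scored genes, got {n}")
    k = math.ceil(fraction * n)
    t_max = math.ceil(tie_slack * n)

    values = ok[statistic_name].to_numpy(dtype=float)
    genes = ok["gene_id"].to_numpy()
    order = np.argsort(-values if direction == "positive" else values, kind="stable")
    boundary = values[order[k - 1]]
    if direction == "positive":
        strict = values > boundary
    else:
        strict = values < boundary
    tied = values == boundary
    n_strict = int(strict.sum())
    if n_strict + int(tied.sum()) <= k + t_max:
        selected = strict | tied
        sel_genes = genes[selected]
        sel_values = values[selected]
    else:
        tied_genes = sorted(genes[tied])[: k - n_strict]
        selected = strict | (tied & np.isin(genes, tied_genes))
        sel_genes = genes[selected]
        sel_values = values[selected]

    label = _query_label(scores)
    sign = -1.0 if direction == "positive" else 1.0
    order_sel = np.lexsort((sel_genes, sign * sel_values))
    return [
        HitCall(str(sel_genes[i]), label, statistic_name, float(sel_values[i]),
                direction, "percentile25", float(boundary))
        for i in order_sel
    ]


def call_hits(
    scores: pd.DataFrame,
    statistic_name: str,
    direction: str,
    method: str,
    **kwargs,
) -> list[HitCall]:
    """Dispatch to the configured caller; two_sd summary is discarded here."""
    if method == "two_sd":
        hits, _ = call_hits_two_sd(scores, statistic_name, direction, **kwargs)
        return hits
    if method == "percentile25":
        return call_hits_percentile(scores, statistic_name, direction, **kwargs)
    raise AnalysisError(f"unknown hit-calling method {method!r}")


def hit_gene_set(hits: list[HitCall]) -> set[str]:
    return {h.gene_id for h in hits}


def hits_to_frame(hits: list[HitCall]) -> pd.DataFrame:
    """Tabulate hit calls for export."""
    return pd.DataFrame(
        [(h.gene_id, h.query_label, h.statistic_name, h.value, h.direction,
          h.method, h.threshold_used) for h in hits],
        columns=["gene_id", "query_label", "statistic_name", "value",
                 "direction", "method", "threshold_used"],
    )
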