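"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's code paths (plain Python,
``statistics`` and ``itertools``) so caller/oracle agreement is a genuine
dual-route check.
"""

from __future__ import annotations

import math
import statistics
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest


def make_scores(values: dict[str, float], statistic: str = "log2_ngr",
                query_label: str = "q") -> pd.DataFrame:
    """Minimal per-gene score table holding one statistic."""
    df = pd.DataFrame({"gene_id": list(values), "query_label": query_label})
    for stat in ("log2_ngr", "log2_ng_30", "log2_ng_19"):
        df[stat] = np.nan
    df[statistic] = [values[g] for g in values]
    df = df.set_index("gene_id", drop=False)
    df.index.name = None
    df.attrs["query_label"] = query_label
    return df


@pytest.fixture
def scores_factory():
    return make_scores


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_two_sd(values: dict[str, float], direction: str, sd_center: str = "mean") -> set[str]:
    """Direct enumeration of the 2 SD rule (median center, sample SD)."""
    finite = {g: v for g, v in values.items() if math.isfinite(v)}
    vals = list(finite.values())
    center = statistics.median(vals)
    if sd_center == "mean":
        sd = statistics.stdev(vals)
    else:
        sd = math.sqrt(sum((v - center) ** 2 for v in vals) / (len(vals) - 1))
    if direction == "positive":
        return {g for g, v in finite.items() if v >= center + 2 * sd}
    return {g for g, v in finite.items() if v <= center - 2 * sd}


def brute_percentile(values: dict[str, float], direction: str,
                     fraction: float = 0.25, tie_slack: float = 0.01) -> set[str]:
    """Full sort-and-slice with the documented tie rule."""
    finite = {g: v for g, v in values.items() if math.isfinite(v)}
    n = len(finite)
    k = math.ceil(fraction * n)
    t_max = math.ceil(tie_slack * n)
    items = sorted(finite.items(),
                   key=lambda gv: (-gv[1] if direction == "positive" else gv[1], gv[0]))
    boundary = items[k - 1][1]
    if direction == "positive":
        strict = {g for g, v in finite.items() if v > boundary}
    else:
        strict = {g for g, v in finite.items() if v < boundary}
    tied = sorted(g for g, v in finite.items() if v == boundary)
    if len(strict) + len(tied) <= k + t_max:
        return strict | set(tied)
    return strict | set(tied[: k - len(strict)])


def enumerate_hypergeom_pvalue(k: int, n_hits: int, K: int, N: int) -> float:
    """P(X >= k) by exhaustive enumeration of all C(N, n_hits) draws."""
    annotated = set(range(K))
    total = hits_at_least = 0
    for draw in combinations(range(N), n_hits):
        total += 1
        if len(annotated.intersection(draw)) >= k:
            hits_at_least += 1
    return hits_at_least / total


def closed_form_hypergeom_pvalue(k: int, n_hits: int, K: int, N: int) -> float:
    """P(X >= k) from binomial coefficients (independent of scipy)."""
    return sum(comb(K, j) * comb(N - K, n_hits - j)
               for j in range(k, min(n_hits, K) + 1)) / comb(N, n_hits)
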