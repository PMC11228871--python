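"""Ontology-group over-representation analysis of hit sets.

For each ontology group (term) with at least ``min_term_size`` annotated
genes in the universe, the overlap between the hit set and the term is
tested with the one-sided (upper-tail) hypergeometric test — drawing
``n_hits`` genes from a universe of ``N`` of which ``K`` carry the term,

    p = P(X >= k),   X ~ Hypergeom(N, K, n_hits)

— followed by Benjamini–Hochberg adjustment across the tested terms. The
universe should be the set of genes actually scored (post-QC) in the
relevant screen, conditioning on testability; genes without any annotation
stay in the universe (they inform N). The annotation is treated as a flat,
pre-slimmed term set: no ontology-graph ancestor propagation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Set

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import AnalysisError
from .plate_io import GeneAnnotation


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's overlap counts and hypergeometric test result."""

    term_id: str
    term_name: str
    k: int          # hits annotated to the term
    n_hits: int     # total hits tested
    K: int          # universe genes annotated to the term
    N: int          # universe size
    p_value: float
    adjusted_p: float
    fold_enrichment: float


def hypergeometric_pvalue(k: int, n_hits: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``k`` hits annotated to the term, out of ``n_hits`` hits drawn without
    replacement from ``N`` universe genes of which ``K`` carry the term.
    Evaluated through the survival function of
    :class:`scipy.stats.hypergeom`, which works in log space internally;
    the result is clipped into (0, 1].
    """
    if not (0 <= K <= N and 0 <= n_hits <= N and 0 <= k <= min(n_hits, K)):
        raise AnalysisError(
            f"invalid hypergeometric bounds: k={k}, n_hits={n_hits}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, n_hits))
    return min(1.0, max(p, np.nextafter(0.0, 1.0)))


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (monotone, order-preserving)."""
    arr = np.asarray(list(p_values), dtype=float)
    if arr.size == 0:
        return arr
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr > 1):
        raise AnalysisError("p-values must lie in (0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def enrich(
    hit_set: Set[str],
    annotation: GeneAnnotation,
    universe: Set[str],
    *,
    min_term_size: int = 3,
) -> list[EnrichmentResult]:
    """Test a hit set for term over-representation within a gene universe.

    Returns one :class:`EnrichmentResult` per term with at least
    ``min_term_size`` annotated universe genes, sorted by (p_value,
    term_id). The per-term hit counts (the ``k`` column) are the tallies
    plotted in per-ontology-group hit-count graphs.
    """
    universe = set(universe)
    hit_set = set(hit_set)
    outside = sorted(hit_set - universe)
    if outside:
        raise AnalysisError(f"hit gene {outside[0]!r} is not in the universe")
    if not annotation.gene_to_terms:
        raise AnalysisError("annotation is empty")
    N = len(universe)
    n_hits = len(hit_set)

    rows = []
    for term, genes in sorted(annotation.term_to_genes().items()):
        members = genes & universe
        K = len(members)
        if K < min_term_size:
            continue
        k = len(members & hit_set)
        p = hypergeometric_pvalue(k, n_hits, K, N)
        fold = (k / n_hits) / (K / N) if n_hits > 0 else float("nan")
        rows.append((term, annotation.term_names.get(term, ""), k, K, p, fold))
    if not rows:
        return []
    adjusted = bh_adjust([r[4] for r in rows])
    results = [
        EnrichmentResult(term, name, k, n_hits, K, N, p, float(adj), fold)
        for (term, name, k, K, p, fold), adj in zip(rows, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.term_id, r.term_name, r.k, r.n_hits, r.K, r.N, r.p_value,
          r.adjusted_p, r.fold_enrichment) for r in results],
        columns=["term_id", "term_name", "k", "n_hits", "K", "N",
                 "p_value", "adjusted_p", "fold_enrichment"],
    )
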