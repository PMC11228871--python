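"""Comparative classification across the five parallel query screens.

The study crosses the deletion library into five query genotypes — taz1,
rif1, S-rif1+ (a separation-of-function allele lacking only Rif1's mitotic
role), taz1 rif1 and taz1 S-rif1+ — and combines their hit lists into three
headline gene classes:

* **taz1-specific negative interactors at 30C** (synthetic sick/lethal with
  taz1 alone): negative log2 NG(30C) hits of the taz1 screen after
  filtering out genes that interact similarly with rif1.
* **cold-sensitivity suppressors**: positive log2 NGR hits of the taz1
  screen (relatively better growth of the double mutant in the cold).
* **reverters**: gene deletions that abolish the suppression of taz1 cold
  sensitivity conferred by rif1 loss, without harming the corresponding
  single mutants — the genetic readout of Rif1's anaphase pathway. A gene
  is a reverter iff it is a negative cold-specific hit in BOTH taz1 rif1
  and taz1 S-rif1+ (the intersection, not the union: the screens query
  the same mitotic function through two alleles) and is quiet in both
  rif1 and S-rif1+ alone.

"Quiet in the single mutant" combines two conditions: not an outlier (by
the 2 SD rule — mere top-quartile rank in a null-like screen is not
evidence of interaction) and |log2 NGR| within ``single_mutant_tolerance_sd``
spreads of that screen's own distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import AnalysisError
from .hit_calling import (
    HitCall,
    call_hits,
    call_hits_two_sd,
    hit_gene_set,
    usable_scores,
)
from .scoring import summarize_distribution

CLASS_PRIORITY = ("reverter", "cs_suppressor", "taz1_specific_negative_30", "none")


@dataclass(frozen=True)
class InteractionClassification:
    """Final class assignment for one gene, with its supporting evidence."""

    gene_id: str
    interaction_class: str
    supporting_calls: tuple[HitCall, ...] = ()
    exclusion_reasons: tuple[str, ...] = ()


@dataclass(frozen=True)
class VennPartition:
    """Disjoint region decomposition of named gene sets.

    ``regions`` maps the frozenset of labels a gene belongs to -> the genes
    with exactly that membership pattern; only nonempty regions appear.
    """

    labels: tuple[str, ...]
    regions: Mapping[frozenset[str], frozenset[str]] = field(repr=False)

    def region(self, *labels: str) -> frozenset[str]:
        return self.regions.get(frozenset(labels), frozenset())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("&".join(sorted(key)), len(genes), "|".join(sorted(genes)))
            for key, genes in sorted(self.regions.items(), key=lambda kv: sorted(kv[0]))
        ]
        return pd.DataFrame(rows, columns=["region", "size", "genes"])


# ---------------------------------------------------------------------------
# query-specific filtering
# ---------------------------------------------------------------------------

def filter_query_specific(
    hits_primary: list[HitCall],
    scores_other: pd.DataFrame,
    hits_other: list[HitCall] | None = None,
    *,
    similarity_fraction: float = 0.5,
) -> tuple[list[HitCall], list[tuple[str, str]]]:
    """Drop primary-screen hits that interact similarly with the other query.

    A gene is "similar" in screen B when its B statistic has the same sign
    as the hit's direction and at least ``similarity_fraction`` of the hit's
    magnitude, or when the gene is itself a same-direction hit in B. Returns
    the retained hits and ``(gene_id, reason)`` pairs for each removal.
    """
    if not hits_primary:
        return [], []
    statistics = {h.statistic_name for h in hits_primary}
    if len(statistics) != 1:
        raise AnalysisError(f"mixed statistics in primary hit list: {sorted(statistics)}")
    statistic = statistics.pop()
    if statistic not in scores_other.columns:
        raise AnalysisError(f"other screen was not scored on {statistic!r}")
    if hits_other is not None:
        wrong = {h.statistic_name for h in hits_other} - {statistic}
        if wrong:
            raise AnalysisError(f"other screen's hits use different statistic(s): {sorted(wrong)}")
    other_values = scores_other.set_index("gene_id")[statistic]
    other_hit_dirs = {h.gene_id: h.direction for h in hits_other or []}

    kept: list[HitCall] = []
    excluded: list[tuple[str, str]] = []
    for hit in hits_primary:
        v = float(other_values.get(hit.gene_id, np.nan))
        same_sign = np.isfinite(v) and v != 0 and ((v > 0) == (hit.direction == "positive"))
        if same_sign and abs(v) >= similarity_fraction * abs(hit.value):
            excluded.append((hit.gene_id, f"similar interaction in other screen ({statistic}={v:.3g})"))
        elif other_hit_dirs.get(hit.gene_id) == hit.direction:
            excluded.append((hit.gene_id, "same-direction hit in other screen"))
        else:
            kept.append(hit)
    return kept, excluded


# ---------------------------------------------------------------------------
# headline classes
# ---------------------------------------------------------------------------

def classify_suppressors(
    taz1_scores: pd.DataFrame,
    *,
    method: str = "percentile25",
    **caller_kwargs,
) -> tuple[set[str], list[HitCall]]:
    """Cold-sensitivity suppressors: positive log2 NGR hits of the taz1 screen."""
    hits = call_hits(taz1_scores, "log2_ngr", "positive", method, **caller_kwargs)
    return hit_gene_set(hits), hits


def classify_reverters(
    double_rif1_scores: pd.DataFrame,
    double_srif1_scores: pd.DataFrame,
    rif1_scores: pd.DataFrame,
    srif1_scores: pd.DataFrame,
    *,
    double_method: str = "percentile25",
    single_mutant_tolerance_sd: float = 1.0,
    sd_center: str = "mean",
    caller_kwargs: dict | None = None,
) -> tuple[set[str], pd.DataFrame]:
    """Select gene deletions that revert suppression in both double screens
    without affecting the single mutants.

    Returns the reverter gene set and a per-candidate evidence table
    (columns gene_id, status, reasons) covering every gene that was a
    negative cold-specific hit in at least one double screen. Genes lacking
    a usable log2 NGR in any required screen are reported as
    ``unclassifiable``, never silently dropped.
    """
    for scores, name in ((double_rif1_scores, "taz1rif1"), (double_srif1_scores, "taz1Srif1"),
                         (rif1_scores, "rif1"), (srif1_scores, "Srif1")):
        if scores is None or len(scores) == 0:
            raise AnalysisError(f"missing screen: {name}")
    kw = dict(caller_kwargs or {})
    hits_dd = call_hits(double_rif1_scores, "log2_ngr", "negative", double_method, **kw)
    hits_ds = call_hits(double_srif1_scores, "log2_ngr", "negative", double_method, **kw)
    set_dd, set_ds = hit_gene_set(hits_dd), hit_gene_set(hits_ds)

    singles = {}
    for name, scores in (("rif1", rif1_scores), ("Srif1", srif1_scores)):
        ok, _ = usable_scores(scores, "log2_ngr")
        summary = summarize_distribution(ok["log2_ngr"], "log2_ngr", sd_center=sd_center)
        if summary.sd == 0:
            # zero spread (noise-free construction): nothing is an outlier
            hits: set[str] = set()
        else:
            pos, _ = call_hits_two_sd(scores, "log2_ngr", "positive", sd_center=sd_center)
            neg, _ = call_hits_two_sd(scores, "log2_ngr", "negative", sd_center=sd_center)
            hits = hit_gene_set(pos) | hit_gene_set(neg)
        singles[name] = {
            "values": ok.set_index("gene_id")["log2_ngr"],
            "hits": hits,
            "tolerance": single_mutant_tolerance_sd * summary.sd,
        }

    reverters: set[str] = set()
    rows = []
    for gene in sorted(set_dd | set_ds):
        reasons: list[str] = []
        status = "reverter"
        if gene not in set_dd:
            reasons.append("not a cold-specific negative hit in taz1rif1")
        if gene not in set_ds:
            reasons.append("not a cold-specific negative hit in taz1Srif1")
        unclassifiable = False
        for name, s in singles.items():
            v = s["values"].get(gene)
            if v is None or not np.isfinite(v):
                reasons.append(f"no usable log2 NGR in {name}")
                unclassifiable = True
                continue
            if gene in s["hits"]:
                reasons.append(f"affects single mutant {name} (2 SD outlier)")
            elif abs(float(v)) > s["tolerance"]:
                reasons.append(
                    f"affects single mutant {name} (|log2 NGR|={abs(float(v)):.3g} > "
                    f"tolerance {s['tolerance']:.3g})"
                )
        if unclassifiable:
            status = "unclassifiable"
        elif reasons:
            status = "excluded"
        else:
            reverters.add(gene)
        rows.append((gene, status, "; ".join(reasons)))
    evidence = pd.DataFrame(rows, columns=["gene_id", "status", "reasons"])
    return reverters, evidence


def classify_interactions(
    scores: Mapping[str, pd.DataFrame],
    *,
    method: str = "percentile25",
    similarity_fraction: float = 0.5,
    single_mutant_tolerance_sd: float = 1.0,
    sd_center: str = "mean",
) -> list[InteractionClassification]:
    """Produce one classification per gene from the five canonical screens.

    ``scores`` must be keyed by "taz1", "rif1", "Srif1", "taz1rif1" and
    "taz1Srif1". A gene matching several class rules takes the highest-
    priority class in the order reverter > cs_suppressor >
    taz1_specific_negative_30 (reverters carry the most specific evidence).
    """
    required = ("taz1", "rif1", "Srif1", "taz1rif1", "taz1Srif1")
    missing = [q for q in required if q not in scores]
    if missing:
        raise AnalysisError(f"missing screen(s): {missing}")

    sup_set, sup_hits = classify_suppressors(scores["taz1"], method=method)
    neg30 = call_hits(scores["taz1"], "log2_ng_30", "negative", method)
    rif1_neg30 = call_hits(scores["rif1"], "log2_ng_30", "negative", method)
    specific, spec_excl = filter_query_specific(
        neg30, scores["rif1"], rif1_neg30, similarity_fraction=similarity_fraction
    )
    rev_set, rev_evidence = classify_reverters(
        scores["taz1rif1"], scores["taz1Srif1"], scores["rif1"], scores["Srif1"],
        double_method=method,
        single_mutant_tolerance_sd=single_mutant_tolerance_sd,
        sd_center=sd_center,
    )

    sup_by_gene = {h.gene_id: h for h in sup_hits}
    spec_by_gene = {h.gene_id: h for h in specific}
    excl_by_gene: dict[str, list[str]] = {}
    for gene, reason in spec_excl:
        excl_by_gene.setdefault(gene, []).append(reason)
    for gene, status, reasons in rev_evidence.itertuples(index=False):
        if status != "reverter" and reasons:
            excl_by_gene.setdefault(gene, []).append(reasons)

    out = []
    all_genes = sorted(set(scores["taz1"]["gene_id"]) | set(rev_evidence["gene_id"]))
    for gene in all_genes:
        if gene in rev_set:
            cls, calls = "reverter", ()
        elif gene in sup_set:
            cls, calls = "cs_suppressor", (sup_by_gene[gene],)
        elif gene in spec_by_gene:
            cls, calls = "taz1_specific_negative_30", (spec_by_gene[gene],)
        else:
            cls, calls = "none", ()
        out.append(InteractionClassification(
            gene, cls, tuple(calls), tuple(excl_by_gene.get(gene, ())),
        ))
    return out


def venn_partition(named_sets: Mapping[str, set[str]]) -> VennPartition:
    """Exact disjoint region decomposition of >= 2 named gene sets."""
    if len(named_sets) < 2:
        raise AnalysisError("venn_partition needs at least 2 sets")
    labels = tuple(named_sets)
    regions: dict[frozenset[str], set[str]] = {}
    for gene in set().union(*named_sets.values()):
        key = frozenset(lbl for lbl in labels if gene in named_sets[lbl])
        regions.setdefault(key, set()).add(gene)
    return VennPartition(labels, {k: frozenset(v) for k, v in regions.items()})


def classifications_to_frame(classifications: list[InteractionClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.gene_id, c.interaction_class,
          "|".join(f"{h.method}:{h.statistic_name}:{h.direction}" for h in c.supporting_calls),
          "; ".join(c.exclusion_reasons))
         for c in classifications],
        columns=["gene_id", "class", "evidence", "exclusion_reasons"],
    )
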