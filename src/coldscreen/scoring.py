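"""Normalized-growth (NG) and normalized-growth-ratio (NGR) scoring.

The screen measures colony sizes of double/triple mutants arrayed on agar
plates grown at a reference temperature (30C, permissive) and a cold
temperature (19C, where the query's entanglement-resolution defect is
lethal). Because each plate carries its own multiplicative growth offset
(media batch, incubation position), every colony is normalized to the
median colony size of its plate:

    NG(colony) = size / median(sizes of all non-missing colonies on plate)

Per gene and temperature, replicate NG values are aggregated by their
median (robust to a single failed pinning). The cold-specificity statistic
for a gene is the ratio

    NGR = NG(19C) / NG(30C)

NGR > 1 means relatively better growth in the cold (candidate suppressor
of the query's cold sensitivity); NGR < 1 means cold-specific sickness.
log2 NG and log2 NGR are the statistics on which outliers are called.

The per-gene score table produced by :func:`score_screen` uses fixed column
names ``*_30`` (reference temperature) and ``*_19`` (cold temperature)
regardless of the actual condition labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import AnalysisError, PlateNormalizationError
from .plate_io import EMPTY

logger = logging.getLogger(__name__)

#: QC flags attached to per-gene scores. LOW_REPLICATES is a warning (the
#: score is still reported); the MISSING_*/ZERO_SIZE flags void the NGR.
FLAG_MISSING_REF = "MISSING_REF"
FLAG_MISSING_COLD = "MISSING_COLD"
FLAG_ZERO_SIZE = "ZERO_SIZE"
FLAG_LOW_REPLICATES = "LOW_REPLICATES"

SCORE_COLUMNS = [
    "gene_id", "query_label", "ng_30", "ng_19", "ngr",
    "log2_ng_30", "log2_ng_19", "log2_ngr",
    "n_rep_30", "n_rep_19", "qc_flags",
]


@dataclass(frozen=True)
class GeneScore:
    """Per-gene growth statistics for one query screen."""

    gene_id: str
    query_label: str = ""
    ng_30: float | None = None
    ng_19: float | None = None
    ngr: float | None = None
    log2_ng_30: float | None = None
    log2_ng_19: float | None = None
    log2_ngr: float | None = None
    n_rep_30: int = 0
    n_rep_19: int = 0
    qc_flags: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class DistributionSummary:
    """Location/spread of one screen's log2 statistic distribution.

    ``median`` is the outlier-calling center. ``sd`` is the sample standard
    deviation (n-1 denominator) computed about the mean by default or about
    the median when ``sd_center == "median"``; the centering is recorded
    because outlier thresholds depend on it.
    """

    statistic_name: str
    median: float
    sd: float
    n: int
    sd_center: str = "mean"
    n_nonfinite: int = 0


def _log2(x: float) -> float:
    if x == 0:
        return float("-inf")
    return float(np.log2(x))


# ---------------------------------------------------------------------------
# per-colony normalization
# ---------------------------------------------------------------------------

def normalize_plate(sizes: Sequence[float] | np.ndarray | pd.Series) -> np.ndarray:
    """Normalize one plate's colony sizes to the plate median.

    ``sizes`` holds one entry per pinned position; NaN marks a missing
    colony and propagates (missing colonies get no NG). The median is taken
    over all non-missing colonies on the plate, including any hit genes —
    with ~1,500 colonies per plate a handful of strong interactions cannot
    move the median materially.

    Raises
    ------
    PlateNormalizationError
        If no colony has a defined size or the plate median is not > 0.
    """
    arr = np.asarray(sizes, dtype=float)
    valid = np.isfinite(arr)
    if not valid.any():
        raise PlateNormalizationError("all colonies on the plate are missing")
    med = float(np.median(arr[valid]))
    if med <= 0:
        raise PlateNormalizationError(f"plate median is {med}, cannot normalize")
    return arr / med


def aggregate_replicates(ng_values: Iterable[float], min_replicates: int = 2) -> tuple[float, int, frozenset[str]]:
    """Aggregate replicate NG values for one gene at one temperature.

    Returns ``(median NG, replicate count, qc flags)``. The median is robust
    to a single failed pinning in a triplicate design. Fewer than
    ``min_replicates`` usable values earns a LOW_REPLICATES flag; zero
    usable values is an error (the table-level path flags such genes
    MISSING instead).
    """
    vals = [v for v in ng_values if np.isfinite(v)]
    if not vals:
        raise AnalysisError("no replicate NG values to aggregate")
    flags = frozenset([FLAG_LOW_REPLICATES]) if len(vals) < min_replicates else frozenset()
    return float(np.median(vals)), len(vals), flags


def compute_ngr(score: GeneScore) -> GeneScore:
    """Fill NGR and the log2 fields of a score holding ng_30/ng_19.

    A zero reference NG is measured-but-dead at 30C: it is a legal numerator
    but an illegal denominator, so the gene is flagged ZERO_SIZE and its NGR
    left undefined (the gene remains usable for 30C-only analysis).
    """
    flags = set(score.qc_flags)
    ng30, ng19 = score.ng_30, score.ng_19
    log2_30 = _log2(ng30) if ng30 is not None else None
    log2_19 = _log2(ng19) if ng19 is not None else None
    ngr = None
    log2_ngr = None
    if ng30 is None:
        flags.add(FLAG_MISSING_REF)
    elif ng30 == 0:
        flags.add(FLAG_ZERO_SIZE)
    if ng19 is None:
        flags.add(FLAG_MISSING_COLD)
    if ng30 is not None and ng30 > 0 and ng19 is not None:
        ngr = ng19 / ng30
        log2_ngr = _log2(ngr)
    return replace(score, ngr=ngr, log2_ng_30=log2_30, log2_ng_19=log2_19,
                   log2_ngr=log2_ngr, qc_flags=frozenset(flags))


# ---------------------------------------------------------------------------
# screen-level scoring
# ---------------------------------------------------------------------------

def score_screen(
    colonies: pd.DataFrame,
    *,
    ref_temp: str = "30C",
    cold_temp: str = "19C",
    min_replicates: int = 2,
    query_label: str = "",
) -> pd.DataFrame:
    """Score one query screen: colony table -> per-gene score table.

    Order of operations is fixed: NG is computed per colony (plate-median
    normalization within each physical plate, i.e. each (plate_id,
    temperature, replicate) group), then replicate NG values are aggregated
    per gene and temperature by their median, then NGR is formed from the
    aggregates. Plates that cannot be normalized are excluded with a logged
    warning and listed in ``result.attrs["dropped_plates"]``.
    """
    df = colonies.loc[colonies["gene_id"].notna() & (colonies["gene_id"] != EMPTY)].copy()
    if df.empty:
        raise AnalysisError("colony table holds no library genes")
    universe = pd.Index(sorted(df["gene_id"].unique()), name="gene_id")

    plate_key = ["plate_id", "temperature", "replicate"]
    med = df.groupby(plate_key)["size"].transform("median")
    bad = ~np.isfinite(med) | (med <= 0)
    dropped_plates: list[tuple] = []
    if bad.any():
        dropped_plates = sorted(set(map(tuple, df.loc[bad, plate_key].itertuples(index=False))))
        for plate in dropped_plates:
            logger.warning("excluding plate %s: median undefined or <= 0", plate)
        df, med = df.loc[~bad], med.loc[~bad]
    df["ng"] = df["size"] / med

    obs = df.dropna(subset=["ng"])
    agg = obs.groupby(["gene_id", "temperature"])["ng"].agg(ng="median", n_rep="count")

    def _temp(col: str, temp: str, fill=np.nan):
        try:
            s = agg[col].xs(temp, level="temperature")
        except KeyError:
            s = pd.Series(dtype=float)
        return s.reindex(universe, fill_value=fill)

    ng_30 = _temp("ng", ref_temp)
    ng_19 = _temp("ng", cold_temp)
    n_30 = _temp("n_rep", ref_temp, fill=0).astype(int)
    n_19 = _temp("n_rep", cold_temp, fill=0).astype(int)

    with np.errstate(divide="ignore", invalid="ignore"):
        ngr = np.where(np.isfinite(ng_30) & (ng_30 > 0) & np.isfinite(ng_19), ng_19 / ng_30, np.nan)
        log2_ng_30 = np.log2(ng_30.to_numpy(dtype=float))
        log2_ng_19 = np.log2(ng_19.to_numpy(dtype=float))
        log2_ngr = np.log2(ngr)

    missing_ref = (n_30 == 0).to_numpy()
    missing_cold = (n_19 == 0).to_numpy()
    zero_size = (~missing_ref) & (ng_30.to_numpy() == 0)
    low_rep = (((n_30 > 0) & (n_30 < min_replicates)) | ((n_19 > 0) & (n_19 < min_replicates))).to_numpy()
    flags = [
        ";".join(sorted(
            ([FLAG_MISSING_REF] if mr else [])
            + ([FLAG_MISSING_COLD] if mc else [])
            + ([FLAG_ZERO_SIZE] if zs else [])
            + ([FLAG_LOW_REPLICATES] if lr else [])
        ))
        for mr, mc, zs, lr in zip(missing_ref, missing_cold, zero_size, low_rep)
    ]

    out = pd.DataFrame({
        "gene_id": universe,
        "query_label": query_label,
        "ng_30": ng_30.to_numpy(), "ng_19": ng_19.to_numpy(), "ngr": ngr,
        "log2_ng_30": log2_ng_30, "log2_ng_19": log2_ng_19, "log2_ngr": log2_ngr,
        "n_rep_30": n_30.to_numpy(), "n_rep_19": n_19.to_numpy(),
        "qc_flags": flags,
    }).set_index("gene_id", drop=False)
    out.index.name = None
    out.attrs["query_label"] = query_label
    out.attrs["dropped_plates"] = dropped_plates
    return out


def summarize_distribution(
    values: Sequence[float] | np.ndarray,
    statistic_name: str,
    *,
    sd_center: str = "mean",
) -> DistributionSummary:
    """Median and sample SD of a log2-statistic distribution.

    Non-finite entries are excluded and counted in ``n_nonfinite``. The SD
    uses the n-1 denominator; ``sd_center`` selects mean-centered (default)
    or median-centered spread — the outlier-calling center is always the
    median either way.
    """
    if sd_center not in ("mean", "median"):
        raise AnalysisError(f"unknown sd_center {sd_center!r}")
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    n = finite.size
    if n < 2:
        raise AnalysisError(f"need >= 2 finite values to summarize, got {n}")
    median = float(np.median(finite))
    if sd_center == "mean":
        sd = float(np.std(finite, ddof=1))
    else:
        sd = float(np.sqrt(np.sum((finite - median) ** 2) / (n - 1)))
    return DistributionSummary(statistic_name, median, sd, n, sd_center,
                               n_nonfinite=int(arr.size - n))


def scores_to_records(scores: pd.DataFrame) -> list[GeneScore]:
    """Convert a score table to :class:`GeneScore` records (NaN -> None)."""

    def _opt(x):
        return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)

    return [
        GeneScore(
            gene_id=r.gene_id, query_label=r.query_label,
            ng_30=_opt(r.ng_30), ng_19=_opt(r.ng_19), ngr=_opt(r.ngr),
            log2_ng_30=_opt(r.log2_ng_30), log2_ng_19=_opt(r.log2_ng_19),
            log2_ngr=_opt(r.log2_ngr),
            n_rep_30=int(r.n_rep_30), n_rep_19=int(r.n_rep_19),
            qc_flags=frozenset(r.qc_flags.split(";")) - {""},
        )
        for r in scores.itertuples(index=False)
    ]


def write_scores(scores: pd.DataFrame, path) -> None:
    """Write a per-gene score table as TSV."""
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# coldscreen per-gene scores; *_30 = reference temperature, *_19 = cold\n")
        scores.to_csv(fh, sep="\t", index=False, na_rep="", float_format="%.17g",
                      columns=SCORE_COLUMNS, lineterminator="\n")


def read_scores(path) -> pd.DataFrame:
    """Read a per-gene score table written by :func:`write_scores`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"qc_flags": str, "query_label": str},
                     keep_default_na=True, na_values=[""])
    df["qc_flags"] = df["qc_flags"].fillna("")
    df["query_label"] = df["query_label"].fillna("")
    df = df.set_index("gene_id", drop=False)
    df.index.name = None
    df.attrs["query_label"] = df["query_label"].iloc[0] if len(df) else ""
    return df
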