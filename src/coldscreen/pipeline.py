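"""End-to-end orchestration: simulate/load -> score -> call hits -> classify
-> enrich, as one reproducible run.

The run is driven by a :class:`RunConfig` (loadable from YAML); the
effective configuration, per-stage row counts, exclusion tallies and
distribution summaries are echoed into a JSON :class:`RunReport` — the
screens are threshold-sensitive, so provenance of every threshold is
mandatory. Given the same config (including the master seed) a run is
deterministic: all stage TSVs are byte-identical across repeats.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .exceptions import ConfigurationError, ParseError
from .enrichment import enrich, results_to_frame
from .hit_calling import call_hits, hits_to_frame, usable_scores
from .plate_io import (
    GeneAnnotation,
    read_annotation,
    read_colony_table,
    read_manifest,
    write_annotation,
    write_colony_table,
    write_layout,
)
from .scoring import score_screen, summarize_distribution, write_scores
from .screen_compare import (
    classifications_to_frame,
    classify_interactions,
    venn_partition,
)
from .synthetic_data import (
    STUDY_QUERIES,
    make_study_scenario,
    make_synthetic_annotation,
    simulate_parallel_screens,
    write_truth,
)

logger = logging.getLogger(__name__)

_METHODS = ("percentile25", "two_sd")
_SD_CENTERS = ("mean", "median")


@dataclass(frozen=True)
class RunConfig:
    """Single source of truth for one pipeline run.

    Either ``simulate`` (keyword arguments for
    :func:`coldscreen.synthetic_data.make_study_scenario`) or ``manifests``
    (one manifest per canonical query screen) must be provided.
    """

    out_dir: str
    seed: int = 0
    simulate: Mapping[str, Any] | None = None
    manifests: tuple[str, ...] | None = None
    annotation: str | None = None
    hit_method: str = "percentile25"
    sd_center: str = "mean"
    similarity_fraction: float = 0.5
    single_mutant_tolerance_sd: float = 1.0
    min_replicates: int = 2
    min_term_size: int = 3
    ref_temperature: str = "30C"
    cold_temperature: str = "19C"

    def __post_init__(self) -> None:
        if self.simulate is None and not self.manifests:
            raise ConfigurationError("config needs either 'simulate' parameters or 'manifests'")
        if self.simulate is not None and self.manifests:
            raise ConfigurationError("'simulate' and 'manifests' are mutually exclusive")
        if self.hit_method not in _METHODS:
            raise ConfigurationError(f"hit_method must be one of {_METHODS}")
        if self.sd_center not in _SD_CENTERS:
            raise ConfigurationError(f"sd_center must be one of {_SD_CENTERS}")
        if not 0.0 <= self.similarity_fraction <= 1.0:
            raise ConfigurationError("similarity_fraction must be in [0, 1]")
        if self.single_mutant_tolerance_sd < 0:
            raise ConfigurationError("single_mutant_tolerance_sd must be >= 0")
        if self.min_replicates < 1 or self.min_term_size < 1:
            raise ConfigurationError("min_replicates and min_term_size must be >= 1")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {unknown}")
        data = dict(data)
        if "manifests" in data and data["manifests"] is not None:
            data["manifests"] = tuple(data["manifests"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"{path}: config must be a mapping")
        return cls.from_dict(data)


@dataclass
class StageReport:
    name: str
    n_in: int
    n_out: int
    n_excluded: int
    seconds: float

    def __post_init__(self) -> None:
        assert self.n_in == self.n_out + self.n_excluded, \
            f"stage {self.name}: {self.n_in} != {self.n_out} + {self.n_excluded}"


@dataclass
class RunReport:
    """Structured account of one run: counts, summaries, config echo."""

    config: dict
    version: str = __version__
    stages: list[StageReport] = field(default_factory=list)
    distribution_summaries: dict = field(default_factory=dict)
    class_counts: dict = field(default_factory=dict)

    def add_stage(self, name: str, n_in: int, n_out: int, n_excluded: int, seconds: float) -> None:
        self.stages.append(StageReport(name, n_in, n_out, n_excluded, seconds))

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "stages": [dataclasses.asdict(s) for s in self.stages],
            "distribution_summaries": self.distribution_summaries,
            "class_counts": self.class_counts,
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _write_tsv(df: pd.DataFrame, path: Path, header: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# {header}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="", float_format="%.17g",
                  lineterminator="\n")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full analysis; returns the run report (also written to
    ``out_dir/report.json`` beside all stage TSVs)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config) | {"simulate": dict(config.simulate or {})})

    # -- stage 1: acquire colony tables -----------------------------------
    t0 = time.perf_counter()
    annotation: GeneAnnotation | None = None
    if config.simulate is not None:
        scenario = make_study_scenario(seed=config.seed, **dict(config.simulate))
        sims = simulate_parallel_screens(scenario.base_config, scenario.query_specs)
        colonies = {q: sim.colonies for q, sim in sims.items()}
        for q, sim in sims.items():
            write_colony_table(sim.colonies, out / f"colonies_{q}.tsv")
            write_layout(sim.layouts.values(), out / f"layout_{q}.tsv")
        write_truth(scenario.truth, out / "truth.tsv")
        class_map = dict(zip(scenario.truth["gene_id"], scenario.truth["class"]))
        annotation = make_synthetic_annotation(
            scenario.base_config.resolve_gene_ids(), class_map, seed=config.seed
        )
        write_annotation(annotation, out / "annotation.tsv")
    else:
        # fail fast: validate every referenced file before any computation
        manifests = [read_manifest(p) for p in config.manifests]
        for m in manifests:
            for table in m.colony_tables:
                if not Path(table).exists():
                    raise ParseError(f"manifest {m.query_label!r}: missing input file {table}")
        missing = set(STUDY_QUERIES) - {m.query_label for m in manifests}
        if missing:
            raise ConfigurationError(
                f"classification requires all five query screens; missing: {sorted(missing)}"
            )
        colonies = {
            m.query_label: pd.concat([read_colony_table(t) for t in m.colony_tables],
                                     ignore_index=True)
            for m in manifests
        }
        if config.annotation is not None:
            annotation = read_annotation(config.annotation)
    n_rows = sum(len(df) for df in colonies.values())
    report.add_stage("acquire", n_rows, n_rows, 0, time.perf_counter() - t0)

    # -- stage 2: score ----------------------------------------------------
    t0 = time.perf_counter()
    scores: dict[str, pd.DataFrame] = {}
    n_in = n_out = 0
    for q, table in colonies.items():
        s = score_screen(table, ref_temp=config.ref_temperature,
                         cold_temp=config.cold_temperature,
                         min_replicates=config.min_replicates, query_label=q)
        scores[q] = s
        write_scores(s, out / f"scores_{q}.tsv")
        genes_in = table.loc[table["gene_id"].notna(), "gene_id"].nunique()
        n_in += genes_in
        n_out += len(s)
        report.distribution_summaries[q] = dataclasses.asdict(
            summarize_distribution(s["log2_ngr"], "log2_ngr", sd_center=config.sd_center)
        )
    report.add_stage("score", n_in, n_out, n_in - n_out, time.perf_counter() - t0)

    # -- stage 3: hit calling ---------------------------------------------
    t0 = time.perf_counter()
    hit_tables = {
        ("taz1", "log2_ngr", "positive"),
        ("taz1", "log2_ng_30", "negative"),
        ("rif1", "log2_ng_30", "negative"),
        ("taz1rif1", "log2_ngr", "negative"),
        ("taz1Srif1", "log2_ngr", "negative"),
    }
    n_in = n_out = 0
    for q, statistic, direction in sorted(hit_tables):
        ok, excluded = usable_scores(scores[q], statistic)
        hits = call_hits(scores[q], statistic, direction, config.hit_method)
        _write_tsv(hits_to_frame(hits), out / f"hits_{q}_{statistic}_{direction}.tsv",
                   f"coldscreen hits; method={config.hit_method}")
        if len(excluded):
            _write_tsv(excluded[["gene_id", "qc_flags"]],
                       out / f"excluded_{q}_{statistic}.tsv",
                       "genes excluded from hit calling (statistic undefined)")
        n_in += len(scores[q])
        n_out += len(ok)
    report.add_stage("call_hits", n_in, n_out, n_in - n_out, time.perf_counter() - t0)

    # -- stage 4: classify -------------------------------------------------
    t0 = time.perf_counter()
    classifications = classify_interactions(
        scores,
        method=config.hit_method,
        similarity_fraction=config.similarity_fraction,
        single_mutant_tolerance_sd=config.single_mutant_tolerance_sd,
        sd_center=config.sd_center,
    )
    cls_frame = classifications_to_frame(classifications)
    _write_tsv(cls_frame, out / "classification.tsv", "coldscreen interaction classes")
    by_class = cls_frame["class"].value_counts().to_dict()
    report.class_counts = {k: int(v) for k, v in by_class.items()}
    sets = {
        q: {h.gene_id for h in call_hits(scores[q], "log2_ngr", "negative", config.hit_method)}
        for q in ("taz1rif1", "taz1Srif1")
    }
    venn = venn_partition(sets)
    _write_tsv(venn.to_frame(), out / "venn_doubles_negative.tsv",
               "venn regions of negative cold-specific hits in the double-query screens")
    report.add_stage("classify", len(cls_frame), len(cls_frame), 0,
                     time.perf_counter() - t0)

    # -- stage 5: enrichment ----------------------------------------------
    t0 = time.perf_counter()
    n_in = n_out = 0
    if annotation is not None:
        targets = {
            "cs_suppressor": ("taz1", set(cls_frame.loc[cls_frame["class"] == "cs_suppressor", "gene_id"])),
            "reverter": ("taz1rif1", set(cls_frame.loc[cls_frame["class"] == "reverter", "gene_id"])),
        }
        n_terms = len(annotation.term_to_genes())
        for label, (screen, genes) in targets.items():
            universe = set(usable_scores(scores[screen], "log2_ngr")[0]["gene_id"])
            results = enrich(genes & universe, annotation, universe,
                             min_term_size=config.min_term_size)
            _write_tsv(results_to_frame(results), out / f"enrichment_{label}.tsv",
                       f"hypergeometric term enrichment of {label} genes")
            n_in += n_terms
            n_out += len(results)
    report.add_stage("enrich", n_in, n_out, n_in - n_out, time.perf_counter() - t0)

    report.write(out / "report.json")
    logger.info("pipeline complete: %s", {s.name: s.n_out for s in report.stages})
    return report
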