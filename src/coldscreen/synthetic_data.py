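"""Simulation of arrayed deletion-library screens at two temperatures.

Generates colony-size tables with the statistical structure the analysis
assumes — multiplicative plate effects, log-normal colony noise, colony
dropout, technical triplicates at a reference (30C) and a cold (19C)
temperature — plus a ground-truth table of planted interactions, so every
downstream stage is testable without wet-lab data.

Model
-----
For gene *g* on physical plate *p* (one plate per temperature x replicate
x grid chunk) the simulated colony size is

    size = exp(mu + b_g + e_p + z) * f_g(T)

where ``mu`` is the baseline log size, ``b_g ~ N(0, baseline_log_size_sd)``
a per-strain intrinsic fitness offset shared across temperatures,
replicates and parallel screens (the same deletion library is crossed into
every query), ``e_p ~ N(0, plate_effect_sd)`` the per-plate multiplicative
offset that plate-median normalization exists to remove, ``z ~ N(0,
colony_noise_sd)`` independent per colony, and ``f_g(T)`` the planted
fitness factor at temperature ``T`` (1 for unplanted genes). Multiplying
by ``f`` outside the exponential keeps power-of-two planted factors exactly
recoverable in noise-free runs. Each colony is independently missing with
probability ``dropout_prob`` (absent row, not size 0).

All log-scale SDs are in natural-log units of the arbitrary colony-area
unit. Randomness is driven by one master seed; per (query, temperature,
replicate) child streams are derived by fixed arithmetic so adding a query
screen never perturbs the others.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .plate_io import COLONY_COLUMNS, PlateLayout
from .plate_io import GeneAnnotation

#: Phenotype classes a planted effect may encode.
PLANT_LABELS = frozenset({"synthetic_sick", "cs_suppressor", "cs_enhancer", "reverter", "neutral"})

#: Canonical query genotypes of the five-screen study design.
STUDY_QUERIES = ("taz1", "rif1", "Srif1", "taz1rif1", "taz1Srif1")

_BASELINE_STREAM = 0xBA5E11
_SCENARIO_STREAM = 0x5CEA01
_ANNOTATION_STREAM = 0xA07A70


def _u32(x: int) -> int:
    return int(x) & 0xFFFFFFFF


def _label_key(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


@dataclass(frozen=True)
class PlantedEffect:
    """A gene's planted fitness factors at the two temperatures.

    Factors multiply the expected colony size; e.g. a cold-specific
    suppressor of the query's cold sensitivity has ``fitness_factor_19 > 1``
    with ``fitness_factor_30 = 1`` (log2 NGR effect = log2 f19/f30).
    """

    gene_id: str
    fitness_factor_30: float = 1.0
    fitness_factor_19: float = 1.0
    label: str = "neutral"

    def __post_init__(self) -> None:
        if self.fitness_factor_30 <= 0 or self.fitness_factor_19 <= 0:
            raise ConfigurationError(f"{self.gene_id}: fitness factors must be > 0")
        if self.label not in PLANT_LABELS:
            raise ConfigurationError(f"{self.gene_id}: unknown label {self.label!r}")
        neutral = self.fitness_factor_30 == 1.0 and self.fitness_factor_19 == 1.0
        if neutral != (self.label == "neutral"):
            raise ConfigurationError(
                f"{self.gene_id}: label 'neutral' iff both fitness factors equal 1"
            )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated screen; defaults mirror the study design
    (32x48 grid, technical triplicates, 30C reference / 19C cold)."""

    n_genes: int
    grid_rows: int = 32
    grid_cols: int = 48
    n_replicates: int = 3
    temperatures: tuple[str, str] = ("30C", "19C")
    baseline_log_size_mean: float = 6.0
    baseline_log_size_sd: float = 0.1
    plate_effect_sd: float = 0.15
    colony_noise_sd: float = 0.5 * math.log(2)  # 0.5 on the log2 scale
    dropout_prob: float = 0.02
    edge_penalty: float = 1.0  # first/last-row multiplicative penalty; 1 = off
    planted_effects: tuple[PlantedEffect, ...] = ()
    seed: int = 0
    gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.grid_rows < 1 or self.grid_cols < 1 or self.n_replicates < 1:
            raise ConfigurationError("counts and grid dimensions must be positive")
        if len(self.temperatures) != 2 or self.temperatures[0] == self.temperatures[1]:
            raise ConfigurationError("temperatures must be an ordered pair of distinct labels")
        for name in ("baseline_log_size_sd", "plate_effect_sd", "colony_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ConfigurationError("dropout_prob must be in [0, 1]")
        if self.edge_penalty <= 0:
            raise ConfigurationError("edge_penalty must be > 0")
        if self.gene_ids is not None and len(self.gene_ids) != self.n_genes:
            raise ConfigurationError("gene_ids length must equal n_genes")

    @property
    def plate_capacity(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def n_plates(self) -> int:
        """Plates per (temperature, replicate); genes exceeding one grid are
        split across numbered plates."""
        return -(-self.n_genes // self.plate_capacity)

    def resolve_gene_ids(self) -> tuple[str, ...]:
        if self.gene_ids is not None:
            return self.gene_ids
        width = max(4, len(str(self.n_genes)))
        return tuple(f"gene_{i + 1:0{width}d}" for i in range(self.n_genes))


@dataclass(frozen=True)
class ScreenSim:
    """One simulated query screen: colony table, plate layouts, ground truth."""

    query_label: str
    config: SimConfig
    colonies: pd.DataFrame
    layouts: dict[str, PlateLayout] = field(repr=False)
    truth: pd.DataFrame = field(repr=False)


def _gene_baselines(config: SimConfig) -> np.ndarray:
    """Per-strain log-fitness offsets, shared across queries for one seed."""
    rng = np.random.default_rng(np.random.SeedSequence([_u32(config.seed), _BASELINE_STREAM]))
    return rng.normal(0.0, config.baseline_log_size_sd, config.n_genes)


def simulate_screen(config: SimConfig, query_label: str = "query") -> ScreenSim:
    """Simulate one query screen; identical config + seed => bit-identical output."""
    genes = np.array(config.resolve_gene_ids())
    gene_index = {g: i for i, g in enumerate(genes)}
    if len(gene_index) != len(genes):
        raise ConfigurationError("gene_ids must be unique")

    f30 = np.ones(config.n_genes)
    f19 = np.ones(config.n_genes)
    for eff in config.planted_effects:
        if eff.gene_id not in gene_index:
            raise ConfigurationError(f"planted effect names unknown gene {eff.gene_id!r}")
        i = gene_index[eff.gene_id]
        f30[i] = eff.fitness_factor_30
        f19[i] = eff.fitness_factor_19
    factors = {config.temperatures[0]: f30, config.temperatures[1]: f19}

    idx = np.arange(config.n_genes)
    chunk = idx // config.plate_capacity
    pos = idx % config.plate_capacity
    rows = pos // config.grid_cols + 1
    cols = pos % config.grid_cols + 1
    on_edge = (rows == 1) | (rows == config.grid_rows)
    baselines = _gene_baselines(config)

    frames = []
    layouts: dict[str, PlateLayout] = {}
    for ti, temp in enumerate(config.temperatures):
        for rep in range(1, config.n_replicates + 1):
            ss = np.random.SeedSequence([_u32(config.seed), _label_key(query_label), ti, rep])
            rng = np.random.default_rng(ss)
            plate_eff = rng.normal(0.0, config.plate_effect_sd, config.n_plates)
            noise = rng.normal(0.0, config.colony_noise_sd, config.n_genes)
            drop = rng.random(config.n_genes) < config.dropout_prob

            log_size = config.baseline_log_size_mean + baselines + plate_eff[chunk] + noise
            size = np.exp(log_size) * factors[temp]
            if config.edge_penalty != 1.0:
                size = np.where(on_edge, size * config.edge_penalty, size)

            plate_ids = np.array([f"{query_label}-{temp}-r{rep}-p{c + 1}" for c in chunk])
            keep = ~drop
            frames.append(pd.DataFrame({
                "plate_id": plate_ids[keep],
                "temperature": temp,
                "replicate": rep,
                "row": rows[keep],
                "col": cols[keep],
                "gene_id": genes[keep],
                "size": size[keep],
            }))
            for c in range(config.n_plates):
                mask = chunk == c
                pid = f"{query_label}-{temp}-r{rep}-p{c + 1}"
                layouts[pid] = PlateLayout(
                    pid, config.grid_rows, config.grid_cols,
                    {(int(r), int(k)): g for r, k, g in zip(rows[mask], cols[mask], genes[mask])},
                )

    colonies = pd.concat(frames, ignore_index=True)[COLONY_COLUMNS]
    truth = pd.DataFrame(
        [(e.gene_id, e.fitness_factor_30, e.fitness_factor_19, e.label)
         for e in config.planted_effects],
        columns=["gene_id", "fitness_factor_30", "fitness_factor_19", "label"],
    )
    return ScreenSim(query_label, config, colonies, layouts, truth)


def simulate_parallel_screens(
    base: SimConfig,
    query_specs: Mapping[str, Sequence[PlantedEffect]],
) -> dict[str, ScreenSim]:
    """Simulate one screen per query genotype over a shared gene universe.

    All screens share gene identities, grid layout and per-strain baseline
    offsets; each query's random streams are keyed by its label so screens
    are mutually independent and individually reproducible. This supports
    planting reverter genes that are deleterious at 19C only in the
    double/triple-query screens while neutral in the single-query screens.
    """
    if not query_specs:
        raise ConfigurationError("query_specs is empty: no screens to simulate")
    known = set(base.resolve_gene_ids())
    for label, effects in query_specs.items():
        for eff in effects:
            if eff.gene_id not in known:
                raise ConfigurationError(
                    f"screen {label!r}: planted effect names unknown gene {eff.gene_id!r}"
                )
    return {
        label: simulate_screen(replace(base, planted_effects=tuple(effects)), query_label=label)
        for label, effects in query_specs.items()
    }


# ---------------------------------------------------------------------------
# the five-screen study scenario
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyScenario:
    """A complete five-screen simulation design with per-class ground truth.

    ``truth`` maps each planted gene to its scenario class: ``suppressor``
    (cold-specific rescue planted in the taz1 screen), ``synthetic_sick``
    (sick at both temperatures in the taz1 screen), ``reverter``
    (cold-specific sickness planted in both double/triple-query screens,
    neutral in the singles), ``fake_reverter`` (sick in the doubles AND in
    the single-mutant screens — must be rejected by the reverter filter),
    and ``background`` (per-screen cold-specific interactors of mixed sign
    emulating the broad interaction spectrum a real query shows).
    """

    base_config: SimConfig
    query_specs: dict[str, tuple[PlantedEffect, ...]]
    truth: pd.DataFrame


def make_study_scenario(
    n_genes: int = 2000,
    seed: int = 0,
    *,
    n_suppressors: int = 40,
    n_synthetic_sick: int = 40,
    n_reverters: int = 40,
    n_fake_reverters: int = 20,
    background_fraction: float = 0.10,
    background_log2_range: tuple[float, float] = (2.0, 4.0),
    effect_log2: float = 3.0,
    **config_overrides,
) -> StudyScenario:
    """Build the default five-screen study design.

    Headline planted classes use a log2 effect of ``effect_log2`` (factor 8
    by default, exactly representable). Each screen additionally receives
    ``background_fraction`` of the library as cold-specific interactors with
    |log2 NGR| effects uniform over ``background_log2_range`` — real query
    screens show a broad spectrum of genuine interactions, and the
    single-mutant tolerance used by the reverter filter is defined relative
    to each screen's empirical spread.
    """
    n_planted = n_suppressors + n_synthetic_sick + n_reverters + n_fake_reverters
    if n_planted > n_genes:
        raise ConfigurationError("more planted genes than library genes")
    base = SimConfig(n_genes=n_genes, seed=seed, **config_overrides)
    genes = list(base.resolve_gene_ids())

    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = genes[cursor:cursor + k]
        cursor += k
        return out

    suppressors = take(n_suppressors)
    sick = take(n_synthetic_sick)
    reverters = take(n_reverters)
    fakes = take(n_fake_reverters)
    rest = genes[cursor:]

    up = 2.0 ** effect_log2
    down = 2.0 ** -effect_log2

    def planted(gene_ids, f30, f19, label):
        return [PlantedEffect(g, f30, f19, label) for g in gene_ids]

    specs: dict[str, list[PlantedEffect]] = {
        "taz1": planted(suppressors, 1.0, up, "cs_suppressor")
        + planted(sick, down, down, "synthetic_sick"),
        "rif1": planted(fakes, 1.0, down, "cs_enhancer"),
        "Srif1": planted(fakes, 1.0, down, "cs_enhancer"),
        "taz1rif1": planted(reverters, 1.0, down, "reverter")
        + planted(fakes, 1.0, down, "cs_enhancer"),
        "taz1Srif1": planted(reverters, 1.0, down, "reverter")
        + planted(fakes, 1.0, down, "cs_enhancer"),
    }

    truth_rows = (
        [(g, "suppressor") for g in suppressors]
        + [(g, "synthetic_sick") for g in sick]
        + [(g, "reverter") for g in reverters]
        + [(g, "fake_reverter") for g in fakes]
    )
    n_background = int(round(background_fraction * n_genes))
    lo, hi = background_log2_range
    for q in STUDY_QUERIES:
        rng = np.random.default_rng(
            np.random.SeedSequence([_u32(seed), _SCENARIO_STREAM, _label_key(q)])
        )
        chosen = rng.choice(len(rest), size=min(n_background, len(rest)), replace=False)
        for j in chosen:
            mag = rng.uniform(lo, hi)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            f19 = 2.0 ** (sign * mag)
            label = "cs_suppressor" if sign > 0 else "cs_enhancer"
            specs[q].append(PlantedEffect(rest[j], 1.0, f19, label))
            truth_rows.append((rest[j], "background"))

    truth = (
        pd.DataFrame(truth_rows, columns=["gene_id", "class"])
        .drop_duplicates()
        .sort_values(["gene_id", "class"])
        .reset_index(drop=True)
    )
    return StudyScenario(base, {q: tuple(v) for q, v in specs.items()}, truth)


def make_synthetic_annotation(
    gene_ids: Sequence[str],
    class_map: Mapping[str, str],
    seed: int = 0,
    *,
    n_random_terms: int = 15,
    term_size_range: tuple[int, int] = (10, 50),
) -> GeneAnnotation:
    """Build a synthetic flat ontology over the simulated library.

    One term per scenario class (its planted genes plus a few random
    members, so class hit sets come out enriched) plus ``n_random_terms``
    random gene groups that should show no enrichment. Term identifiers use
    the ``SYN:`` prefix to make their synthetic origin explicit.
    """
    rng = np.random.default_rng(np.random.SeedSequence([_u32(seed), _ANNOTATION_STREAM]))
    genes = list(gene_ids)
    gene_to_terms: dict[str, set[str]] = {}
    term_names: dict[str, str] = {}

    def add(term: str, name: str, members: Iterable[str]) -> None:
        term_names[term] = name
        for g in members:
            gene_to_terms.setdefault(g, set()).add(term)

    by_class: dict[str, list[str]] = {}
    for g, cls in class_map.items():
        by_class.setdefault(cls, []).append(g)
    for i, cls in enumerate(sorted(by_class)):
        members = sorted(by_class[cls])
        extras = rng.choice(len(genes), size=min(10, len(genes)), replace=False)
        add(f"SYN:{i + 1:04d}", f"synthetic module ({cls})", members + [genes[j] for j in extras])

    offset = len(by_class)
    lo, hi = term_size_range
    for i in range(n_random_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
        add(f"SYN:{offset + i + 1:04d}", f"synthetic random group {i + 1}", (genes[j] for j in members))
    return GeneAnnotation(gene_to_terms, term_names)


def write_truth(truth: pd.DataFrame, path) -> None:
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# coldscreen simulation ground truth\n")
        truth.to_csv(fh, sep="\t", index=False, float_format="%.17g", lineterminator="\n")
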