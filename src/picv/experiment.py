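"""Simulation-study orchestration: replicates, scenarios, study tables.

A replicate simulates one balanced case-control dataset from a
penetrance model, splits it with both the traditional random splitter
and PICV (paired by default, so both methods see the same data), fits
the main-effects and interaction logistic models on each training
partition, classifies train and test at the probability cutoff, and
records the four performance measures per partition.  A scenario runs
many replicates, assembles the |train - test| gap distributions, and
compares the two splitters with one-sided KS tests (PICV hypothesized
smaller).  A study aggregates scenarios into a per-scenario p-value
table and cross-scenario counts of where PICV yields the smaller
median/maximum gap.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasim import GenotypeDataset, simulate_balanced_dataset
from .evalstats import (
    MEASURES,
    GapSample,
    PerformanceQuad,
    confusion_measures,
    ks_one_sided,
    median_max_summary,
    train_test_gap,
)
from .glm import ModelSpec, classify, fit_logistic, likelihood_ratio_test, predict_prob
from .penetrance import PenetranceModel
from .splitting import genotype_stratum_labels, picv_split, traditional_split

__all__ = [
    "METHODS",
    "ScenarioConfig",
    "ScenarioResult",
    "run_replicate",
    "run_scenario",
    "run_study",
    "consistency_lrt",
]

logger = logging.getLogger(__name__)

METHODS = ("traditional", "picv")
_MAX_FAILURE_FRACTION = 0.10


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: a model plus sampling and splitting settings."""

    model: PenetranceModel
    n: int = 2000
    replicates: int = 1000
    train_fraction: float = 2.0 / 3.0
    base_seed: int = 0
    cutoff: float = 0.5
    specs: tuple[str, ...] = ("main_effects", "interaction")
    paired: bool = True
    resplit: bool = False
    scenario_index: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n < 2 or self.n % 2:
            raise ValueError("n must be even and >= 2")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class ScenarioResult:
    """Gap distributions, KS comparisons and summaries for one scenario."""

    config: ScenarioConfig
    gap_samples: dict  # (method, spec, measure) -> GapSample
    ks: dict  # (spec, measure) -> (D, p)
    summaries: dict  # (spec, measure) -> median/max comparison record
    failures: list
    runtime_s: float
    invalid: bool = False

    @property
    def label(self) -> str:
        return self.config.model.label


def _replicate_rng(config: ScenarioConfig, replicate: int) -> np.random.Generator:
    # counter-based seed derivation: every number in the study is a pure
    # function of (base_seed, scenario_index, replicate)
    return np.random.default_rng(
        np.random.SeedSequence(
            entropy=config.base_seed,
            spawn_key=(config.scenario_index, replicate),
        )
    )


def _evaluate_split(
    dataset: GenotypeDataset, split, specs, cutoff: float
) -> dict[str, dict[str, PerformanceQuad]]:
    train = dataset.subset(split.train)
    test = dataset.subset(split.test)
    out: dict[str, dict[str, PerformanceQuad]] = {}
    for kind in specs:
        fit = fit_logistic(train, ModelSpec(kind))
        out[kind] = {
            "train": confusion_measures(
                train.status, classify(predict_prob(fit, train), cutoff)
            ),
            "test": confusion_measures(
                test.status, classify(predict_prob(fit, test), cutoff)
            ),
        }
    return out


def run_replicate(
    model: PenetranceModel,
    n: int,
    train_fraction: float,
    cutoff: float,
    rng: np.random.Generator,
    specs: tuple[str, ...] = ("main_effects", "interaction"),
    paired: bool = True,
    dataset: GenotypeDataset | None = None,
) -> dict[str, dict[str, dict[str, PerformanceQuad]]]:
    """One replicate: returns quads[method][spec]['train'|'test'].

    By default both splitters are applied to the same simulated dataset
    (paired design, lower Monte-Carlo variance of the comparison); with
    ``paired=False`` each method gets its own dataset.  An explicit
    ``dataset`` skips simulation (re-split mode).
    """
    ds_trad = dataset if dataset is not None else simulate_balanced_dataset(model, n, rng)
    ds_picv = ds_trad
    if not paired and dataset is None:
        ds_picv = simulate_balanced_dataset(model, n, rng)
    split_trad = traditional_split(ds_trad.n, train_fraction, rng)
    split_picv = picv_split(genotype_stratum_labels(ds_picv), train_fraction, rng)
    return {
        "traditional": _evaluate_split(ds_trad, split_trad, specs, cutoff),
        "picv": _evaluate_split(ds_picv, split_picv, specs, cutoff),
    }


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Run all replicates of a scenario and assemble its comparisons.

    Replicate failures (degenerate partitions, single-class fits) are
    recorded with their replicate id and do not abort the scenario; a
    scenario with more than 10% failures is marked invalid.
    """
    t0 = time.monotonic()
    nspec = len(config.specs)
    gaps = np.full((config.replicates, len(METHODS), nspec, len(MEASURES)), np.nan)
    failures: list[tuple[int, str]] = []
    shared = None
    if config.resplit:
        shared = simulate_balanced_dataset(
            config.model, config.n, _replicate_rng(config, 0)
        )
    for rep in range(config.replicates):
        rng = _replicate_rng(config, rep + 1)
        try:
            quads = run_replicate(
                config.model,
                config.n,
                config.train_fraction,
                config.cutoff,
                rng,
                specs=config.specs,
                paired=config.paired,
                dataset=shared,
            )
        except Exception as exc:  # degenerate replicate: data, not a crash
            failures.append((rep, f"{type(exc).__name__}: {exc}"))
            logger.debug("scenario %s replicate %d failed: %s",
                         config.model.label, rep, exc)
            continue
        for m_i, method in enumerate(METHODS):
            for s_i, kind in enumerate(config.specs):
                cell = quads[method][kind]
                gaps[rep, m_i, s_i] = train_test_gap(cell["train"], cell["test"])
    invalid = len(failures) > _MAX_FAILURE_FRACTION * config.replicates
    gap_samples: dict = {}
    ks: dict = {}
    summaries: dict = {}
    for s_i, kind in enumerate(config.specs):
        for q_i, measure in enumerate(MEASURES):
            trad = gaps[:, 0, s_i, q_i]
            picv = gaps[:, 1, s_i, q_i]
            # undefined gaps are excluded pairwise: a replicate enters the
            # comparison only if both methods yielded a defined gap
            defined = ~np.isnan(trad) & ~np.isnan(picv)
            n_drop = int(config.replicates - defined.sum())
            sample_t = GapSample(trad[defined], n_dropped=n_drop)
            sample_p = GapSample(picv[defined], n_dropped=n_drop)
            gap_samples[("traditional", kind, measure)] = sample_t
            gap_samples[("picv", kind, measure)] = sample_p
            if sample_t.n and sample_p.n:
                ks[(kind, measure)] = ks_one_sided(sample_t.values, sample_p.values)
            else:
                ks[(kind, measure)] = (float("nan"), float("nan"))
            summaries[(kind, measure)] = median_max_summary(sample_t, sample_p)
    result = ScenarioResult(
        config=config,
        gap_samples=gap_samples,
        ks=ks,
        summaries=summaries,
        failures=failures,
        runtime_s=time.monotonic() - t0,
        invalid=invalid,
    )
    logger.info(
        "scenario %s: %d replicates, %d failures, %.1fs",
        config.model.label, config.replicates, len(failures), result.runtime_s,
    )
    return result


_SPEC_NAMES = {"main_effects": "without interaction", "interaction": "with interaction"}


def run_study(configs: list[ScenarioConfig]) -> dict:
    """Run several scenarios and emit study-level tables.

    Returns a dict with ``results`` (per-scenario ScenarioResult),
    ``ks_table`` (scenarios x measure/model KS p-values), ``summary_counts``
    (per measure/model, the number of scenarios where PICV had the
    strictly smaller median / maximum gap) and ``gaps`` (long-form
    per-replicate gap table for plotting).
    """
    if not configs:
        raise ValueError("need at least one scenario configuration")
    labels = [c.model.label for c in configs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate scenario labels")
    results = [run_scenario(c) for c in configs]
    for r in results:
        if r.config.replicates < 50:
            logger.warning("scenario %s has only %d replicates; summaries are noisy",
                           r.label, r.config.replicates)
    ks_rows = []
    for r in results:
        row: dict = {"scenario": r.label}
        for kind in r.config.specs:
            for measure in MEASURES:
                row[f"{measure}, {_SPEC_NAMES[kind]}"] = r.ks[(kind, measure)][1]
        ks_rows.append(row)
    ks_table = pd.DataFrame(ks_rows).set_index("scenario")
    count_rows = []
    for kind in configs[0].specs:
        for measure in MEASURES:
            med = sum(
                1 for r in results
                if r.summaries[(kind, measure)].get("picv_median_smaller", False)
            )
            mx = sum(
                1 for r in results
                if r.summaries[(kind, measure)].get("picv_max_smaller", False)
            )
            count_rows.append(
                {
                    "measure": measure,
                    "model": _SPEC_NAMES[kind],
                    "picv_median_smaller": med,
                    "picv_max_smaller": mx,
                    "n_scenarios": len(results),
                }
            )
    summary_counts = pd.DataFrame(count_rows)
    gap_rows = []
    for r in results:
        for (method, kind, measure), sample in r.gap_samples.items():
            for v in sample.values:
                gap_rows.append(
                    {
                        "scenario": r.label,
                        "method": method,
                        "model": _SPEC_NAMES[kind],
                        "measure": measure,
                        "gap": v,
                    }
                )
    gaps = pd.DataFrame(gap_rows)
    return {
        "results": results,
        "ks_table": ks_table,
        "summary_counts": summary_counts,
        "gaps": gaps,
    }


def consistency_lrt(
    dataset: GenotypeDataset,
    train_fraction: float,
    rng: np.random.Generator,
    method: str = "picv",
    covariate_names: tuple[str, ...] = (),
) -> dict:
    """Interaction LRT p-values on the full data and within one train/test split.

    Fits the main-effects and interaction models (optionally covariate
    adjusted) on the full dataset, then splits by the chosen method and
    refits within each partition, returning the three p-values.  A
    partition with a single outcome class yields NaN with a recorded
    reason.
    """
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}, got {method!r}")

    def lrt_p(ds: GenotypeDataset) -> float:
        null = fit_logistic(ds, ModelSpec("main_effects", covariate_names))
        alt = fit_logistic(ds, ModelSpec("interaction", covariate_names))
        return likelihood_ratio_test(null, alt)[2]

    if method == "traditional":
        split = traditional_split(dataset.n, train_fraction, rng)
    else:
        split = picv_split(genotype_stratum_labels(dataset), train_fraction, rng)
    out = {"overall_p": lrt_p(dataset), "method": method, "notes": []}
    for part, idx in (("train", split.train), ("test", split.test)):
        sub = dataset.subset(idx)
        try:
            out[f"{part}_p"] = lrt_p(sub)
        except ValueError as exc:
            out[f"{part}_p"] = float("nan")
            out["notes"].append(f"{part}: {exc}")
    return out
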