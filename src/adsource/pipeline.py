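"""End-to-end orchestration: aggregate trials, fit, test, summarize.

``run_full_analysis`` drives the whole analysis of one experiment: trial
aggregation into pooled frequency tables, descriptive attribution and
rating tables, the base-model fit with bootstrapped standard errors, the
named nested-hypothesis battery, and the design's prospective power
statement, all collected into a machine-readable :class:`AnalysisReport`.

Conventions:

* Data are pooled over participants into one frequency table per
  experiment (aggregate-data MPT fitting; a single G2 per experiment).
* The attribution table's default denominator is *all* items of a
  (credibility x source) cell, so a "new" response counts as
  not-attributed-to-advertising; ``denominator="old"`` conditions on items
  classified as old instead.
* Hypothesis-test p-values are reported unadjusted for multiple testing;
  this is recorded in the report metadata.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .fitting import (
    ComparisonResult,
    FitResult,
    FrequencyTable,
    bootstrap_se,
    compare,
    fit,
)
from .model_library import (
    CREDIBILITY_LEVELS,
    base_model,
    experiment_battery,
    hypothesis_submodel,
)
from .power import PowerQuery, PowerResult, power_chisq
from .synthetic_data import (
    ExperimentDesign,
    GenerativeParams,
    TrialRecord,
    generate_frame,
    trials_to_frame,
)

__all__ = [
    "AnalysisConfig",
    "AnalysisReport",
    "aggregate",
    "attribution_proportions",
    "rating_summary",
    "run_full_analysis",
]


def _as_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    return trials_to_frame(trials)


def _infer_experiment(frame: pd.DataFrame) -> str:
    return "exp2" if (frame["true_source"] == "unknown").any() else "exp1"


def aggregate(trials, experiment: str | None = None) -> FrequencyTable:
    """Pool test-phase trials into a frequency table per (tree, response).

    Tree labels are ``"<true_source>.<credibility>"``.  Raises if a
    response lies outside the experiment's category set or if any design
    tree has no test-phase records.  Aggregation is invariant to record
    order.
    """
    frame = _as_frame(trials)
    test = frame[frame["phase"] == "test"]
    if test.empty:
        raise ValueError("no test-phase records to aggregate")
    experiment = experiment or _infer_experiment(test)
    sources = ("ad", "test") if experiment == "exp1" else ("ad", "test", "unknown")
    categories = (*sources, "new")
    bad = set(test["response"]) - set(categories)
    if bad:
        raise ValueError(
            f"responses {sorted(bad)} outside the {experiment} category set {categories}"
        )
    counts: dict[tuple[str, str], float] = {}
    grouped = test.groupby(["true_source", "credibility", "response"]).size()
    for (src, lv, resp), n in grouped.items():
        counts[(f"{src}.{lv}", resp)] = float(n)
    expected_trees = {f"{s}.{lv}" for s in (*sources, "new") for lv in CREDIBILITY_LEVELS}
    present = {tree for tree, _ in counts}
    missing = expected_trees - present
    if missing:
        raise ValueError(f"no test-phase records for trees: {sorted(missing)}")
    return FrequencyTable(counts)


def attribution_proportions(trials, denominator: str = "all") -> pd.DataFrame:
    """Per-(credibility x source) proportion of items attributed to advertising.

    For each participant and cell the proportion of "ad" responses is
    computed over all items of the cell (``denominator="all"``; a "new"
    response counts as not attributed) or over the items the participant
    classified as old (``denominator="old"``).  The table reports the
    cross-participant mean, standard error of the mean, and the number of
    participants contributing; cells where a participant has an empty
    denominator are excluded for that participant (flagged by a smaller
    ``n_participants``), never treated as zero.
    """
    if denominator not in ("all", "old"):
        raise ValueError("denominator must be 'all' or 'old'")
    frame = _as_frame(trials)
    test = frame[frame["phase"] == "test"].copy()
    if test.empty:
        raise ValueError("no test-phase records")
    if denominator == "old":
        test = test[test["response"] != "new"]
    test["is_ad"] = (test["response"] == "ad").astype(float)
    per_part = (
        test.groupby(["credibility", "true_source", "participant"])["is_ad"]
        .mean()
        .rename("proportion")
        .reset_index()
    )
    out = (
        per_part.groupby(["credibility", "true_source"])["proportion"]
        .agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n_participants="count")
        .reset_index()
    )
    return out


def rating_summary(trials, phase: str) -> pd.DataFrame:
    """Mean credibility rating per (credibility x source) cell in one phase.

    Means are computed per participant first; the table reports the mean
    and standard error of the mean over the participant means.
    """
    frame = _as_frame(trials)
    sub = frame[frame["phase"] == phase]
    if sub.empty:
        raise ValueError(f"no records in phase {phase!r}")
    per_part = (
        sub.groupby(["credibility", "true_source", "participant"])["rating"]
        .mean()
        .rename("mean_rating")
        .reset_index()
    )
    out = (
        per_part.groupby(["credibility", "true_source"])["mean_rating"]
        .agg(mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n_participants="count")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------- #
# full analysis


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run."""

    experiment: str = "exp1"
    seed: int = 0
    trials_csv: str | None = None  # existing trial data; simulate when None
    n_participants: int | None = None  # simulation override
    n_starts: int = 20
    tol: float = 1e-9
    bootstrap_B: int = 1000
    run_bootstrap: bool = True
    attribution_denominator: str = "all"
    power_w: float = 0.03
    power_df: int = 1
    power_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError("experiment must be 'exp1' or 'exp2'")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        return cls(**dict(d))

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in (
                "experiment", "seed", "trials_csv", "n_participants", "n_starts",
                "tol", "bootstrap_B", "run_bootstrap", "attribution_denominator",
                "power_w", "power_df", "power_alpha",
            )
        }

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Machine-readable result of a full analysis run."""

    experiment: str
    frequency_table: FrequencyTable
    base_fits: dict[str, FitResult]
    comparisons: dict[str, ComparisonResult]
    attribution: pd.DataFrame | None
    ratings: dict[str, pd.DataFrame] | None
    power: PowerResult
    metadata: dict
    failures: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "frequency_table": self.frequency_table.to_frame().to_dict(orient="records"),
            "base_fits": {k: v.to_dict() for k, v in self.base_fits.items()},
            "comparisons": {k: v.to_dict() for k, v in self.comparisons.items()},
            "attribution": (
                self.attribution.to_dict(orient="records")
                if self.attribution is not None
                else None
            ),
            "ratings": (
                {k: v.to_dict(orient="records") for k, v in self.ratings.items()}
                if self.ratings is not None
                else None
            ),
            "power": self.power.to_dict(),
            "metadata": self.metadata,
            "failures": self.failures,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run the complete analysis of one experiment.

    Simulates trial data (or loads the configured CSV), aggregates, fits
    the experiment's base model(s), runs the named hypothesis battery,
    attaches bootstrap standard errors to the reporting base model, builds
    the descriptive tables, and computes the design's power statement.
    Individual fit failures are recorded in ``report.failures`` rather than
    aborting the run.
    """
    exp = config.experiment
    design = (
        ExperimentDesign.exp1(config.n_participants)
        if exp == "exp1" and config.n_participants
        else ExperimentDesign.exp2(config.n_participants)
        if exp == "exp2" and config.n_participants
        else ExperimentDesign.exp1()
        if exp == "exp1"
        else ExperimentDesign.exp2()
    )
    if config.trials_csv:
        frame = pd.read_csv(config.trials_csv)
        n_participants = frame["participant"].nunique()
    else:
        frame = generate_frame(design, seed=config.seed)
        n_participants = design.n_participants
    table = aggregate(frame, experiment=exp)

    base_names = ("exp1",) if exp == "exp1" else ("exp2_parsimonious", "exp2_final")
    reporting_base = base_names[-1]
    base_fits: dict[str, FitResult] = {}
    failures: dict[str, str] = {}
    for name in base_names:
        try:
            base_fits[name] = fit(
                base_model(name), table,
                n_starts=config.n_starts, seed=config.seed, tol=config.tol,
            )
        except Exception as exc:  # noqa: BLE001 - report, don't abort
            failures[f"fit:{name}"] = str(exc)

    comparisons: dict[str, ComparisonResult] = {}
    for parent_name, hypothesis in experiment_battery(exp):
        parent_fit = base_fits.get(parent_name)
        if parent_fit is None:
            failures[f"test:{hypothesis}"] = f"base fit {parent_name} unavailable"
            continue
        try:
            sub = hypothesis_submodel(parent_fit.model, hypothesis)
            comparisons[hypothesis] = compare(
                parent_fit, sub, table,
                hypothesis=hypothesis, n_starts=config.n_starts,
                seed=config.seed, tol=config.tol,
            )
        except Exception as exc:  # noqa: BLE001
            failures[f"test:{hypothesis}"] = str(exc)

    if config.run_bootstrap and reporting_base in base_fits:
        try:
            bootstrap_se(
                base_fits[reporting_base].model, table,
                B=config.bootstrap_B, seed=config.seed,
                fit_result=base_fits[reporting_base],
            )
        except Exception as exc:  # noqa: BLE001
            failures["bootstrap"] = str(exc)

    attribution = ratings = None
    if "rating" in frame.columns:
        attribution = attribution_proportions(frame, config.attribution_denominator)
        ratings = {
            phase: rating_summary(frame, phase) for phase in ("presentation", "test")
        }

    power = power_chisq(
        PowerQuery(
            w=config.power_w,
            N=n_participants * design.n_test_items,
            df=config.power_df,
            alpha=config.power_alpha,
        )
    )

    metadata = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "adsource_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_participants": int(n_participants),
        "n_test_items": design.n_test_items,
        "multiple_testing_adjustment": "none (unadjusted delta-G2 p-values)",
        "attribution_denominator": config.attribution_denominator,
    }
    return AnalysisReport(
        experiment=exp,
        frequency_table=table,
        base_fits=base_fits,
        comparisons=comparisons,
        attribution=attribution,
        ratings=ratings,
        power=power,
        metadata=metadata,
        failures=failures,
    )


def write_outputs(report: AnalysisReport, out_dir) -> None:
    """Write report JSON plus frequency/attribution/rating CSVs to a directory."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report.to_json(indent=2))
    report.frequency_table.to_csv(out / "frequencies.csv")
    if report.attribution is not None:
        report.attribution.to_csv(out / "attribution.csv", index=False)
    if report.ratings is not None:
        for phase, table in report.ratings.items():
            table.to_csv(out / f"ratings_{phase}.csv", index=False)
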