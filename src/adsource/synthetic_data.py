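"""Synthetic trial-level data with the structure the analysis assumes.

The generator emulates two source-memory experiments on product
statements:

* **exp1** — 122 participants; at study 40 high- and 40 low-credibility
  statements, half labeled "Advertisement" and half "Foundation for Brand
  Testing"; at test the 80 studied statements intermixed with 80 new ones
  (160 test trials per participant).
* **exp2** — 111 participants; 39 + 39 studied statements split evenly
  over three sources (advertisement / brand testing / no label), 13 per
  source and credibility; test on 78 old + 78 new statements (156 trials).

For every participant the item assignment is a fresh randomization from a
pool of 160 statements (80 per credibility level).  Test responses are
sampled by walking the generative source-monitoring tree of the item's
type with the supplied true parameters; credibility ratings are drawn from
a truncated normal on the continuous scale (cell-specific mean, common SD)
and rounded to the discrete -3..+3 grid.  All participants share the same
generative parameters (aggregate-level model; participant heterogeneity is
a documented extension point, not implemented).

Identical seeds yield identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FrequencyTable
from .model_library import (
    CREDIBILITY_LEVELS,
    build_three_source_model,
    build_two_source_model,
)
from .mpt_core import MPTModel

__all__ = [
    "ExperimentDesign",
    "GenerativeParams",
    "TrialRecord",
    "generate_experiment",
    "generate_frame",
    "trials_to_frame",
    "frame_to_trials",
    "expected_table",
    "sample_table",
    "design_totals",
]

RATING_GRID = tuple(range(-3, 4))
_POOL_PER_LEVEL = 80  # statements per credibility level in the item pool


@dataclass(frozen=True)
class ExperimentDesign:
    """Counts and structure of one experiment."""

    experiment: str
    n_participants: int
    n_per_source_cell: int  # studied items per credibility x source cell
    n_new_per_credibility: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.experiment not in ("exp1", "exp2"):
            raise ValueError("experiment must be 'exp1' or 'exp2'")
        if min(self.n_participants, self.n_per_source_cell, self.n_new_per_credibility) < 1:
            raise ValueError("design counts must be positive")
        per_level = len(self.sources) * self.n_per_source_cell + self.n_new_per_credibility
        if per_level > _POOL_PER_LEVEL:
            raise ValueError(
                f"design needs {per_level} items per credibility level; the pool has {_POOL_PER_LEVEL}"
            )

    @classmethod
    def exp1(cls, n_participants: int = 122) -> "ExperimentDesign":
        """Two-source design: 20 per credibility x source cell, 40 new per level."""
        return cls("exp1", n_participants, 20, 40)

    @classmethod
    def exp2(cls, n_participants: int = 111) -> "ExperimentDesign":
        """Three-source design: 13 per credibility x source cell, 39 new per level."""
        return cls("exp2", n_participants, 13, 39)

    @property
    def sources(self) -> tuple[str, ...]:
        return ("ad", "test") if self.experiment == "exp1" else ("ad", "test", "unknown")

    @property
    def response_categories(self) -> tuple[str, ...]:
        return (
            ("ad", "test", "new")
            if self.experiment == "exp1"
            else ("ad", "test", "unknown", "new")
        )

    @property
    def n_study_per_credibility(self) -> int:
        return len(self.sources) * self.n_per_source_cell

    @property
    def n_study_items(self) -> int:
        return 2 * self.n_study_per_credibility

    @property
    def n_test_items(self) -> int:
        return self.n_study_items + 2 * self.n_new_per_credibility

    def model(self) -> MPTModel:
        """The unrestricted generative model matching this design."""
        if self.experiment == "exp1":
            return build_two_source_model()
        return build_three_source_model()


@dataclass(frozen=True)
class TrialRecord:
    """One presentation or test event of one statement for one participant."""

    participant: int
    phase: str  # "presentation" | "test"
    item: int
    credibility: str  # "high" | "low"
    true_source: str  # "ad" | "test" | "unknown" | "new"
    rating: int  # -3 .. +3
    response: str | None  # test phase only; "new" encodes the no-source path

    def __post_init__(self) -> None:
        if self.rating not in RATING_GRID:
            raise ValueError(f"rating {self.rating} outside the -3..+3 grid")
        if (self.response is None) != (self.phase == "presentation"):
            raise ValueError("a response exists exactly for test-phase records")


@dataclass(frozen=True)
class GenerativeParams:
    """True parameters of the generative process.

    ``theta`` assigns a probability to every parameter of the design's
    unrestricted model (full names, e.g. ``"D_ad.high"``).  ``rating_means``
    maps ``(phase, source, credibility)`` cells to the latent mean on the
    continuous -3..+3 scale, including ``("test", "new", level)`` cells for
    unstudied statements; ``rating_sd`` is the common latent SD before
    discretization.

    The shipped defaults (:meth:`default_exp1`, :meth:`default_exp2`) are a
    synthetic fixture: memory parameters in the empirically typical range
    for this paradigm (detection around .8, source memory 0-.4, old-guessing
    .2-.35, advertisement-guessing higher for low- than for high-credibility
    statements) and rating means matching the descriptive pattern of real
    credibility judgments.  They are plausible generating values, not
    estimates from any dataset.
    """

    theta: dict[str, float]
    rating_means: dict[tuple[str, str, str], float]
    rating_sd: float = 1.5

    def __post_init__(self) -> None:
        for name, v in self.theta.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"parameter {name!r} = {v} outside [0, 1]")
        for cell, m in self.rating_means.items():
            if not -3.0 <= m <= 3.0:
                raise ValueError(f"rating mean {m} for cell {cell} outside [-3, 3]")
        if self.rating_sd <= 0:
            raise ValueError("rating_sd must be positive")

    def validate_for(self, design: ExperimentDesign) -> None:
        model = design.model()
        missing = set(model.parameter_names) - set(self.theta)
        if missing:
            raise ValueError(
                f"generative parameters missing for {design.experiment}: {sorted(missing)}"
            )
        cells = [
            ("presentation", s, lv)
            for s in design.sources
            for lv in CREDIBILITY_LEVELS
        ] + [
            ("test", s, lv)
            for s in (*design.sources, "new")
            for lv in CREDIBILITY_LEVELS
        ]
        missing_cells = [c for c in cells if c not in self.rating_means]
        if missing_cells:
            raise ValueError(f"rating means missing for cells: {missing_cells}")

    @classmethod
    def default_exp1(cls) -> "GenerativeParams":
        theta: dict[str, float] = {}
        spec = {
            "high": dict(D=0.77, d_ad=0.32, d_test=0.37, b=0.21, g=0.30),
            "low": dict(D=0.83, d_ad=0.02, d_test=0.32, b=0.33, g=0.60),
        }
        for lv, s in spec.items():
            theta |= {
                f"D_ad.{lv}": s["D"],
                f"D_test.{lv}": s["D"],
                f"D_new.{lv}": s["D"],
                f"d_ad.{lv}": s["d_ad"],
                f"d_test.{lv}": s["d_test"],
                f"b.{lv}": s["b"],
                f"a_ad.{lv}": s["g"],
                f"g_ad.{lv}": s["g"],
            }
        rating_means = {
            ("presentation", "ad", "high"): 0.66,
            ("presentation", "ad", "low"): -1.56,
            ("presentation", "test", "high"): 1.37,
            ("presentation", "test", "low"): -1.13,
            ("test", "ad", "high"): 0.64,
            ("test", "ad", "low"): -1.65,
            ("test", "test", "high"): 0.91,
            ("test", "test", "low"): -1.46,
            ("test", "new", "high"): 0.80,
            ("test", "new", "low"): -1.55,
        }
        return cls(theta, rating_means)

    @classmethod
    def default_exp2(cls) -> "GenerativeParams":
        theta: dict[str, float] = {}
        spec = {
            "high": dict(
                D=0.74, d_ad=0.08, d_test=0.24, d_unknown=0.04,
                b=0.23, g_ad=0.25, g_test=0.40 / 0.75,
            ),
            "low": dict(
                D=0.80, d_ad=0.08, d_test=0.14, d_unknown=0.00,
                b=0.33, g_ad=0.50, g_test=0.50,
            ),
        }
        for lv, s in spec.items():
            theta |= {
                f"D_ad.{lv}": s["D"],
                f"D_test.{lv}": s["D"],
                f"D_unknown.{lv}": s["D"],
                f"D_new.{lv}": s["D"],
                f"d_ad.{lv}": s["d_ad"],
                f"d_test.{lv}": s["d_test"],
                f"d_unknown.{lv}": s["d_unknown"],
                f"b.{lv}": s["b"],
                f"a_ad.{lv}": s["g_ad"],
                f"a_test.{lv}": s["g_test"],
                f"g_ad.{lv}": s["g_ad"],
                f"g_test.{lv}": s["g_test"],
            }
        rating_means = {
            ("presentation", "ad", "high"): 0.71,
            ("presentation", "ad", "low"): -1.40,
            ("presentation", "unknown", "high"): 0.83,
            ("presentation", "unknown", "low"): -1.48,
            ("presentation", "test", "high"): 1.20,
            ("presentation", "test", "low"): -1.16,
            ("test", "ad", "high"): 0.63,
            ("test", "ad", "low"): -1.51,
            ("test", "unknown", "high"): 0.65,
            ("test", "unknown", "low"): -1.54,
            ("test", "test", "high"): 0.72,
            ("test", "test", "low"): -1.49,
            ("test", "new", "high"): 0.70,
            ("test", "new", "low"): -1.55,
        }
        return cls(theta, rating_means)

    @classmethod
    def defaults(cls, experiment: str) -> "GenerativeParams":
        return cls.default_exp1() if experiment == "exp1" else cls.default_exp2()


# ---------------------------------------------------------------------- #
# generation


def _sample_ratings(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Truncated normal on [-3.5, 3.5], rounded to the integer grid."""
    a, b = (-3.5 - mean) / sd, (3.5 - mean) / sd
    x = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)
    return np.clip(np.rint(x), -3, 3).astype(int)


def generate_frame(
    design: ExperimentDesign,
    params: GenerativeParams | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate one experiment; returns the trial table as a DataFrame.

    Columns: ``participant, phase, item, credibility, true_source, rating,
    response`` (response is empty for presentation-phase rows).  Rows are
    ordered by participant, phase, and randomized display position.
    """
    params = params if params is not None else GenerativeParams.defaults(design.experiment)
    params.validate_for(design)
    rng = np.random.default_rng(seed if seed is not None else design.seed)
    model = design.model()
    probs = model.category_probabilities(params.theta)
    cats = design.response_categories
    P = design.n_participants
    sources = design.sources
    n_src = len(sources)
    k = design.n_per_source_cell
    n_study_lv = design.n_study_per_credibility
    n_new = design.n_new_per_credibility

    # fresh per-participant randomization of the 160-statement pool
    study_items: dict[str, np.ndarray] = {}
    new_items: dict[str, np.ndarray] = {}
    for li, lv in enumerate(CREDIBILITY_LEVELS):
        pool = np.tile(np.arange(_POOL_PER_LEVEL) + li * _POOL_PER_LEVEL, (P, 1))
        perm = rng.permuted(pool, axis=1)
        study_items[lv] = perm[:, :n_study_lv]
        new_items[lv] = perm[:, n_study_lv : n_study_lv + n_new]

    def block(level: str, phase: str) -> tuple[np.ndarray, np.ndarray]:
        """(items, source codes) per participant for one credibility level."""
        items = study_items[level]
        src = np.repeat(np.arange(n_src), k)[None, :].repeat(P, axis=0)
        if phase == "test":
            items = np.concatenate([items, new_items[level]], axis=1)
            src = np.concatenate(
                [src, np.full((P, n_new), n_src)], axis=1
            )  # code n_src == "new"
        return items, src

    frames = []
    for phase in ("presentation", "test"):
        item_mats, src_mats, lv_mats = [], [], []
        for li, lv in enumerate(CREDIBILITY_LEVELS):
            items, src = block(lv, phase)
            item_mats.append(items)
            src_mats.append(src)
            lv_mats.append(np.full(items.shape, li))
        items = np.concatenate(item_mats, axis=1)
        src = np.concatenate(src_mats, axis=1)
        lvl = np.concatenate(lv_mats, axis=1)
        # randomized display order within participant
        order = rng.permuted(np.tile(np.arange(items.shape[1]), (P, 1)), axis=1)
        items = np.take_along_axis(items, order, axis=1)
        src = np.take_along_axis(src, order, axis=1)
        lvl = np.take_along_axis(lvl, order, axis=1)

        n_trials = items.size
        flat_src = src.ravel()
        flat_lvl = lvl.ravel()
        ratings = np.zeros(n_trials, dtype=int)
        src_labels = (*sources, "new")
        for si, s in enumerate(src_labels):
            if phase == "presentation" and s == "new":
                continue
            for li, lv in enumerate(CREDIBILITY_LEVELS):
                mask = (flat_src == si) & (flat_lvl == li)
                if mask.any():
                    ratings[mask] = _sample_ratings(
                        rng, params.rating_means[(phase, s, lv)], params.rating_sd, int(mask.sum())
                    )
        if phase == "test":
            responses = np.empty(n_trials, dtype=object)
            for si, s in enumerate(src_labels):
                for li, lv in enumerate(CREDIBILITY_LEVELS):
                    mask = (flat_src == si) & (flat_lvl == li)
                    if not mask.any():
                        continue
                    p = np.array([probs[(f"{s}.{lv}", c)] for c in cats])
                    cum = np.cumsum(p)
                    cum[-1] = 1.0
                    draws = np.searchsorted(cum, rng.random(int(mask.sum())), side="right")
                    responses[mask] = np.array(cats, dtype=object)[draws]
        else:
            responses = np.full(n_trials, None, dtype=object)
        frames.append(
            pd.DataFrame(
                {
                    "participant": np.repeat(np.arange(P), items.shape[1]),
                    "phase": phase,
                    "item": items.ravel(),
                    "credibility": np.array(CREDIBILITY_LEVELS, dtype=object)[flat_lvl],
                    "true_source": np.array(src_labels, dtype=object)[flat_src],
                    "rating": ratings,
                    "response": responses,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(
        ["participant", "phase"], kind="stable", key=lambda s: s.map({"presentation": 0, "test": 1}) if s.name == "phase" else s
    ).reset_index(drop=True)


def generate_experiment(
    design: ExperimentDesign,
    params: GenerativeParams | None = None,
    seed: int | None = None,
) -> list[TrialRecord]:
    """Simulate one experiment as a list of :class:`TrialRecord`."""
    return frame_to_trials(generate_frame(design, params, seed))


def trials_to_frame(trials: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        {
            "participant": t.participant,
            "phase": t.phase,
            "item": t.item,
            "credibility": t.credibility,
            "true_source": t.true_source,
            "rating": t.rating,
            "response": t.response,
        }
        for t in trials
    ]
    return pd.DataFrame(rows)


def frame_to_trials(frame: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for row in frame.itertuples(index=False):
        resp = row.response
        if resp is None or (isinstance(resp, float) and np.isnan(resp)) or resp == "":
            resp = None
        records.append(
            TrialRecord(
                participant=int(row.participant),
                phase=str(row.phase),
                item=int(row.item),
                credibility=str(row.credibility),
                true_source=str(row.true_source),
                rating=int(row.rating),
                response=resp,
            )
        )
    return records


# ---------------------------------------------------------------------- #
# frequency-table fixtures


def design_totals(design: ExperimentDesign) -> dict[str, float]:
    """Pooled test-phase item counts per tree implied by a design."""
    totals: dict[str, float] = {}
    for lv in CREDIBILITY_LEVELS:
        for s in design.sources:
            totals[f"{s}.{lv}"] = float(design.n_participants * design.n_per_source_cell)
        totals[f"new.{lv}"] = float(design.n_participants * design.n_new_per_credibility)
    return totals


def expected_table(
    model: MPTModel, theta: Mapping[str, float], totals: Mapping[str, float]
) -> FrequencyTable:
    """Deterministic expected-count table: totals x category probabilities.

    Counts are real-valued; fitting the generating model to its own
    expected table recovers theta with G2 ~ 0.
    """
    probs = model.category_probabilities(theta)
    counts = {
        (tree, cat): float(totals[tree]) * p for (tree, cat), p in probs.items()
    }
    return FrequencyTable(counts)


def sample_table(
    model: MPTModel,
    theta: Mapping[str, float],
    totals: Mapping[str, float],
    seed: int | None = None,
) -> FrequencyTable:
    """Multinomial-sampled frequency table from the model at ``theta``."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    probs = model.category_probabilities(theta)
    counts: dict[tuple[str, str], float] = {}
    for tree in model.tree_labels:
        cats = model.tree(tree).categories
        p = np.array([probs[(tree, c)] for c in cats])
        p = np.maximum(p, 0.0)
        p /= p.sum()
        drawn = rng.multinomial(int(round(totals[tree])), p)
        for c, k in zip(cats, drawn):
            counts[(tree, c)] = float(k)
    return FrequencyTable(counts)
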