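"""Maximum-likelihood fitting of MPT models to pooled frequency tables.

Estimation minimizes the likelihood-ratio statistic

    G2(theta) = 2 * sum_cells f * ln( f / (n_tree * p(theta)) )

over the free parameters, with the convention 0 * ln(0) = 0 and expected
probabilities floored at 1e-12 inside the logarithm.  Minimizing G2 is
equivalent to maximizing the product-multinomial log-likelihood of the
per-tree counts.  Free parameters are optimized on the logit scale, which
handles the [0, 1] box constraints smoothly; analytic gradients are
propagated through the branch products.  Multi-start optimization guards
against local minima.

Nested model comparison refits the restricted model and reports
delta-G2 with delta-df equal to the drop in free parameters; standard
errors come from a parametric bootstrap (resample tables from the fitted
category probabilities at the observed per-tree totals, refit, take
per-parameter standard deviations), matching the convention of reporting
bootstrapped standard errors for aggregate MPT fits.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .mpt_core import MPTError, MPTModel

__all__ = [
    "FrequencyTable",
    "FitResult",
    "ComparisonResult",
    "UnidentifiableModelError",
    "FitError",
    "NotNestedError",
    "fit",
    "compare",
    "bootstrap_se",
]

logger = logging.getLogger(__name__)

_PROB_FLOOR = 1e-12
_LOGIT_CAP = 25.0  # |logit(theta)| bound; expit(25) differs from 1 by ~1e-11


class UnidentifiableModelError(MPTError):
    """The model has more free parameters than free data categories."""


class FitError(MPTError):
    """Optimization failed in a way that invalidates the result."""


class NotNestedError(MPTError):
    """The restricted model is not structurally nested in the full model."""


@dataclass
class FrequencyTable:
    """Observed response counts per (tree, category).

    ``counts`` maps ``(tree_label, category)`` to a nonnegative count;
    ``totals`` (items presented per tree) are derived as the per-tree sums.
    Counts may be non-integral for deterministic expected-count fixtures.
    """

    counts: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for cell, v in self.counts.items():
            if v < 0:
                raise ValueError(f"negative count in cell {cell}")

    @property
    def totals(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for (tree, _), v in self.counts.items():
            out[tree] = out.get(tree, 0.0) + v
        return out

    @property
    def tree_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for tree, _ in self.counts:
            seen.setdefault(tree)
        return tuple(seen)

    @property
    def n_observations(self) -> float:
        return float(sum(self.counts.values()))

    def is_integral(self, tol: float = 1e-9) -> bool:
        return all(abs(v - round(v)) <= tol for v in self.counts.values())

    # ------------------------------------------------------------------ #
    # CSV interchange: columns credibility,tree,category,count where the
    # internal tree label is "<tree>.<credibility>"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (tree, category), count in self.counts.items():
            item, _, cred = tree.partition(".")
            rows.append(
                {"credibility": cred, "tree": item, "category": category, "count": count}
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FrequencyTable":
        required = {"credibility", "tree", "category", "count"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"frequency table missing columns {sorted(missing)}")
        counts = {
            (f"{row.tree}.{row.credibility}", row.category): float(row.count)
            for row in frame.itertuples()
        }
        if len(counts) != len(frame):
            raise ValueError("duplicate (credibility, tree, category) rows")
        return cls(counts)

    @classmethod
    def from_csv(cls, path) -> "FrequencyTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class FitResult:
    """Outcome of a maximum-likelihood fit.

    ``estimates`` resolves every model parameter (members of an equality
    class share their representative's estimate; constants appear at their
    fixed value); ``free_estimates`` holds only the free parameters.
    ``log_likelihood`` is the multinomial kernel ``sum f * ln(p_hat)``
    (combinatorial constants omitted).
    """

    estimates: dict[str, float]
    free_estimates: dict[str, float]
    G2: float
    df: int
    p_value: float
    log_likelihood: float
    converged: bool
    n_starts_used: int
    se: dict[str, float] | None = None
    model: MPTModel | None = field(default=None, repr=False)
    data: FrequencyTable | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "free_estimates": self.free_estimates,
            "se": self.se,
            "G2": self.G2,
            "df": self.df,
            "p_value": self.p_value,
            "log_likelihood": self.log_likelihood,
            "convergence": {
                "converged": self.converged,
                "n_starts_used": self.n_starts_used,
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class ComparisonResult:
    """A nested likelihood-ratio test between two fits of the same data."""

    delta_G2: float
    delta_df: int
    p_value: float
    hypothesis: str = ""
    restricted_fit: FitResult | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "hypothesis": self.hypothesis,
            "delta_G2": self.delta_G2,
            "delta_df": self.delta_df,
            "p_value": self.p_value,
        }


# ---------------------------------------------------------------------- #
# internals


def _aligned_observations(model: MPTModel, data: FrequencyTable):
    comp = model.compiled()
    model_trees = set(model.tree_labels)
    data_trees = set(data.tree_labels)
    if model_trees != data_trees:
        raise ValueError(
            f"data trees {sorted(data_trees)} do not match model trees {sorted(model_trees)}"
        )
    totals = data.totals
    for tree, n in totals.items():
        if n <= 0:
            raise ValueError(f"tree {tree!r} has zero observations")
    f = np.zeros(len(comp.cells))
    n_cell = np.zeros(len(comp.cells))
    known_cells = set(comp.cells)
    for cell in data.counts:
        if cell not in known_cells:
            raise ValueError(f"data cell {cell} is not a model (tree, category) cell")
    for i, cell in enumerate(comp.cells):
        f[i] = data.counts.get(cell, 0.0)
        n_cell[i] = totals[cell[0]]
    return f, n_cell


def _g2_and_grad(model: MPTModel, x: np.ndarray, f: np.ndarray, n_cell: np.ndarray):
    """G2 and its gradient with respect to the free-parameter logits."""
    res = model._resolve()
    comp = model.compiled()
    theta_free = expit(x)
    full = res.T @ theta_free + res.const
    full_in = np.clip(full, 1e-12, 1.0 - 1e-12)
    log_b = comp.E1 @ np.log(full_in) + comp.E2 @ np.log1p(-full_in)
    b = np.exp(log_b)
    p = comp.M @ b
    mu = np.maximum(n_cell * p, _PROB_FLOOR)
    pos = f > 0
    g2 = 2.0 * float(np.sum(f[pos] * (np.log(f[pos]) - np.log(mu[pos]))))
    # dG2/dp = -2 f / p on cells with f > 0 (zero cells contribute nothing)
    dg_dp = np.zeros_like(p)
    live = pos & (n_cell * p > _PROB_FLOOR)
    dg_dp[live] = -2.0 * f[live] / p[live]
    u = comp.M.T @ dg_dp  # per-branch sensitivity
    ub = u * b
    grad_full = (ub @ (comp.E1 / full_in[None, :])) - (
        ub @ (comp.E2 / (1.0 - full_in)[None, :])
    )
    grad_free = res.T.T @ grad_full
    grad_x = grad_free * theta_free * (1.0 - theta_free)
    return g2, grad_x


def _loglik(f: np.ndarray, n_cell: np.ndarray, p: np.ndarray) -> float:
    pos = f > 0
    return float(np.sum(f[pos] * np.log(np.maximum(p[pos], _PROB_FLOOR))))


# ---------------------------------------------------------------------- #
# public operations


def fit(
    model: MPTModel,
    data: FrequencyTable,
    n_starts: int = 20,
    seed: int | None = None,
    tol: float = 1e-9,
) -> FitResult:
    """Fit ``model`` to ``data`` by multi-start G2 minimization.

    Parameters
    ----------
    n_starts:
        Number of optimization starts: one from the hypercube center, the
        rest uniform-random in (0, 1) per free parameter.
    seed:
        Seed for the random starts (fixed seed gives a reproducible fit).
    tol:
        Multi-start early-exit threshold on G2: a start reaching G2 <= tol
        has found a perfect fit and further starts are skipped.

    Raises
    ------
    UnidentifiableModelError
        If the model has negative degrees of freedom.
    ValueError
        If the data trees do not match the model or a tree has no
        observations.
    """
    if model.degrees_of_freedom < 0:
        raise UnidentifiableModelError(
            f"model has {len(model.free_parameters)} free parameters but only "
            f"{model.n_free_categories} free data categories (df = "
            f"{model.degrees_of_freedom}); add restrictions"
        )
    f, n_cell = _aligned_observations(model, data)
    n_free = len(model.free_parameters)
    rng = np.random.default_rng(seed)

    if n_free == 0:
        p = model.category_probability_matrix(np.zeros((1, 0)))[0]
        g2 = 2.0 * float(
            np.sum(f[f > 0] * (np.log(f[f > 0]) - np.log(np.maximum(n_cell[f > 0] * p[f > 0], _PROB_FLOOR))))
        )
        return _finalize(model, data, np.zeros(0), g2, True, 0, f, n_cell)

    best_x = None
    best_g2 = np.inf
    best_success = False
    starts_used = 0
    for s in range(max(1, int(n_starts))):
        theta0 = np.full(n_free, 0.5) if s == 0 else rng.uniform(0.02, 0.98, n_free)
        x0 = logit(theta0)
        res = optimize.minimize(
            lambda x: _g2_and_grad(model, x, f, n_cell),
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=[(-_LOGIT_CAP, _LOGIT_CAP)] * n_free,
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        starts_used += 1
        # a boundary estimate (theta at 0/1) flattens the logit-scale
        # gradient, which can abort the line search after the optimum is
        # reached; accept such starts on the gradient norm
        success = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-3
        if res.fun < best_g2:
            best_g2 = float(res.fun)
            best_x = res.x
            best_success = success
        elif res.fun < best_g2 + 1e-10 and success:
            best_success = True
        if best_g2 <= tol:
            break
    if best_x is None:  # pragma: no cover - minimize always returns
        raise FitError("no optimization start produced a result")
    if not best_success:
        logger.warning(
            "fit of %s did not report convergence after %d starts (G2=%.6g)",
            model.name or "model",
            starts_used,
            best_g2,
        )
    return _finalize(model, data, best_x, best_g2, best_success, starts_used, f, n_cell)


def _finalize(model, data, x, g2, converged, starts_used, f, n_cell) -> FitResult:
    res = model._resolve()
    theta_free = expit(x) if x.size else np.zeros(0)
    free_estimates = {n: float(v) for n, v in zip(res.free_names, theta_free)}
    full = res.T @ theta_free + res.const
    estimates = {n: float(v) for n, v in zip(model.parameter_names, full)}
    p = model.category_probability_matrix(theta_free[None, :])[0]
    df = model.degrees_of_freedom
    g2 = max(float(g2), 0.0)
    if df > 0:
        p_value = float(stats.chi2.sf(g2, df))
    else:
        p_value = 1.0 if g2 <= 1e-8 else 0.0
    return FitResult(
        estimates=estimates,
        free_estimates=free_estimates,
        G2=g2,
        df=df,
        p_value=p_value,
        log_likelihood=_loglik(f, n_cell, p),
        converged=bool(converged),
        n_starts_used=int(starts_used),
        model=model,
        data=data,
    )


def _canonical_restrictions(model: MPTModel) -> set:
    return {r.canonical() for r in model.restrictions}


def compare(
    full_fit: FitResult,
    restricted: MPTModel,
    data: FrequencyTable | None = None,
    hypothesis: str = "",
    n_starts: int = 20,
    seed: int | None = None,
    tol: float = 1e-9,
) -> ComparisonResult:
    """Likelihood-ratio test of ``restricted`` against a fitted parent model.

    ``restricted`` must be structurally nested in the parent: same trees,
    same parameter list, and a restriction set containing the parent's.
    The restricted model is refit (multi-start) on the same data; tiny
    negative delta-G2 values (> -1e-6, optimization noise) are clamped to
    zero, while larger negatives raise :class:`FitError` because they
    indicate a non-converged parent fit.
    """
    if full_fit.model is None:
        raise ValueError("full_fit must carry its model (obtained from fit())")
    parent = full_fit.model
    data = data if data is not None else full_fit.data
    if data is None:
        raise ValueError("no data supplied and the parent fit carries none")
    if restricted.tree_labels != parent.tree_labels or set(
        restricted.parameter_names
    ) != set(parent.parameter_names):
        raise NotNestedError("models are defined over different trees or parameters")
    if not _canonical_restrictions(parent) <= _canonical_restrictions(restricted):
        raise NotNestedError(
            "restricted model does not contain the parent's restriction set"
        )
    delta_df = restricted.degrees_of_freedom - parent.degrees_of_freedom
    if delta_df < 1:
        raise NotNestedError("restricted model adds no independent restriction")
    restricted_fit = fit(restricted, data, n_starts=n_starts, seed=seed, tol=tol)
    delta = restricted_fit.G2 - full_fit.G2
    if delta < -1e-6:
        raise FitError(
            f"restricted model fit better by {-delta:.3g}; "
            "the parent fit is likely a local minimum — refit with more starts"
        )
    delta = max(delta, 0.0)
    return ComparisonResult(
        delta_G2=float(delta),
        delta_df=int(delta_df),
        p_value=float(stats.chi2.sf(delta, delta_df)),
        hypothesis=hypothesis,
        restricted_fit=restricted_fit,
    )


def bootstrap_se(
    model: MPTModel,
    data: FrequencyTable,
    B: int = 1000,
    seed: int | None = None,
    n_starts: int = 4,
    fit_result: FitResult | None = None,
    max_failure_fraction: float = 0.10,
) -> dict[str, float]:
    """Parametric-bootstrap standard errors of the parameter estimates.

    ``B`` frequency tables are resampled from the fitted category
    probabilities at the observed per-tree totals and refit; the standard
    deviation of each free parameter's replicate estimates is its standard
    error.  Members of an equality class share their representative's SE;
    parameters restricted to a constant get SE 0.  Replicates whose refit
    does not converge are dropped with a logged count; more than
    ``max_failure_fraction`` failures raises :class:`FitError`.  Results are
    reproducible under a fixed seed.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    if fit_result is None:
        fit_result = fit(model, data, seed=seed)
    if not fit_result.converged:
        raise FitError("cannot bootstrap from a non-converged fit")
    res = model._resolve()
    comp = model.compiled()
    theta_hat = np.array([fit_result.free_estimates[n] for n in res.free_names])
    p = model.category_probability_matrix(theta_hat[None, :])[0]
    totals = data.totals
    rng = np.random.default_rng(seed)

    # per-tree probability slices in compiled cell order
    tree_cells: dict[str, list[int]] = {}
    for i, (tree, _) in enumerate(comp.cells):
        tree_cells.setdefault(tree, []).append(i)

    replicates = []
    failures = 0
    for b in range(int(B)):
        counts: dict[tuple[str, str], float] = {}
        for tree, idx in tree_cells.items():
            probs = np.maximum(p[idx], 0.0)
            probs = probs / probs.sum()
            drawn = rng.multinomial(int(round(totals[tree])), probs)
            for i, k in zip(idx, drawn):
                counts[comp.cells[i]] = float(k)
        table = FrequencyTable(counts)
        boot_seed = int(rng.integers(0, 2**31 - 1))
        try:
            bfit = fit(model, table, n_starts=n_starts, seed=boot_seed)
        except (FitError, ValueError):
            failures += 1
            continue
        if not bfit.converged:
            failures += 1
            continue
        replicates.append([bfit.free_estimates[n] for n in res.free_names])
    if failures:
        logger.warning("bootstrap: dropped %d of %d replicates", failures, B)
    if failures > max_failure_fraction * B:
        raise FitError(f"bootstrap failed on {failures}/{B} replicates")
    R = np.asarray(replicates)
    free_se = R.std(axis=0, ddof=1) if R.size else np.zeros(0)
    se_by_free = dict(zip(res.free_names, free_se))
    out: dict[str, float] = {}
    for name in model.parameter_names:
        kind, ref = res.assignment[name]
        out[name] = float(se_by_free[res.free_names[ref]]) if kind == "free" else 0.0
    fit_result.se = out
    return out
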