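"""Binary multinomial processing tree (MPT) models.

An MPT model explains observed response-category frequencies through a set
of latent cognitive processes.  Each item type (e.g. "statement studied with
an advertisement label, high a-priori credibility") has its own processing
tree.  A tree is a collection of branches; each branch is a product of
parameters ``theta`` or their complements ``1 - theta`` and terminates in an
observable response category.  The probability of a category is the sum of
the probabilities of all branches ending in it, so for any parameter vector
in the unit hypercube the category probabilities of a tree sum to one.

This module provides:

* the symbolic containers (:class:`ParameterSpec`, :class:`Branch`,
  :class:`Tree`, :class:`Restriction`, :class:`MPTModel`);
* evaluation of category probabilities for a parameter assignment;
* equality/constant restrictions with conflict detection, and the degrees
  of freedom of the restricted model (free response categories minus free
  parameters);
* a numerical local-identifiability check (rank of the Jacobian of the
  stacked category probabilities with respect to the free parameters);
* a small text format for model and restriction files (see
  :func:`parse_model` / :func:`parse_restrictions`).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MPTError",
    "RestrictionConflictError",
    "UnknownParameterError",
    "MissingParameterError",
    "ParameterSpec",
    "Branch",
    "Tree",
    "Restriction",
    "MPTModel",
    "IdentifiabilityReport",
    "category_probabilities",
    "apply_restrictions",
    "degrees_of_freedom",
    "check_local_identifiability",
    "parse_model",
    "parse_restrictions",
    "model_to_text",
    "restrictions_to_text",
]


class MPTError(Exception):
    """Base class for model-specification errors."""


class RestrictionConflictError(MPTError):
    """A parameter is forced to two distinct constants."""


class UnknownParameterError(MPTError):
    """A restriction or hypothesis references a parameter not in the model."""


class MissingParameterError(MPTError):
    """A free parameter was not assigned a value."""


#: parameter roles, following the source-monitoring nomenclature
ROLES = ("detection", "source-memory", "old-guess", "source-guess", "generic")


@dataclass(frozen=True)
class ParameterSpec:
    """A named probability parameter, bounded to the closed unit interval."""

    name: str
    role: str = "generic"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise MPTError(f"unknown parameter role {self.role!r}")


def _infer_role(name: str) -> str:
    stem = name.split(".")[0]
    if stem.startswith("D"):
        return "detection"
    if stem.startswith("d"):
        return "source-memory"
    if stem.startswith("b"):
        return "old-guess"
    if stem.startswith(("a", "g")):
        return "source-guess"
    return "generic"


@dataclass(frozen=True)
class Branch:
    """One root-to-leaf path: an ordered product of theta / (1 - theta) factors.

    ``factors`` is a tuple of ``(parameter_name, direct)`` pairs; ``direct``
    is True for a ``theta`` factor and False for ``1 - theta``.
    """

    factors: tuple[tuple[str, bool], ...]
    terminal: str

    def probability(self, theta: Mapping[str, float]) -> float:
        p = 1.0
        for name, direct in self.factors:
            v = theta[name]
            p *= v if direct else 1.0 - v
        return p


@dataclass(frozen=True)
class Tree:
    """The processing tree of one item type."""

    label: str
    branches: tuple[Branch, ...]
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.categories)) != len(self.categories):
            raise MPTError(f"tree {self.label!r}: duplicate response categories")
        for br in self.branches:
            if br.terminal not in self.categories:
                raise MPTError(
                    f"tree {self.label!r}: branch terminal {br.terminal!r} "
                    f"is not a response category"
                )

    @property
    def parameter_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for br in self.branches:
            for name, _ in br.factors:
                seen.setdefault(name)
        return tuple(seen)


@dataclass(frozen=True)
class Restriction:
    """An equality class of parameters, or a parameter pinned to a constant."""

    kind: str  # "equality" | "constant"
    names: tuple[str, ...]
    value: float | None = None

    @classmethod
    def equal(cls, *names: str) -> "Restriction":
        if len(names) < 2:
            raise MPTError("an equality restriction needs at least two parameters")
        return cls("equality", tuple(names))

    @classmethod
    def constant(cls, name: str, value: float) -> "Restriction":
        if not 0.0 <= value <= 1.0:
            raise MPTError(f"constant for {name!r} must lie in [0, 1], got {value}")
        return cls("constant", (name,), float(value))

    def canonical(self) -> tuple:
        if self.kind == "equality":
            return ("equality", frozenset(self.names))
        return ("constant", self.names[0], self.value)


@dataclass(frozen=True)
class IdentifiabilityReport:
    """Rank report of the probability Jacobian at a reference point."""

    rank: int
    n_free_parameters: int
    singular_values: tuple[float, ...]

    @property
    def locally_identified(self) -> bool:
        return self.rank == self.n_free_parameters


class _Resolution:
    """Outcome of collapsing the parameter list under the restriction set."""

    __slots__ = ("free_names", "assignment", "T", "const")

    def __init__(self, free_names, assignment, T, const):
        self.free_names: tuple[str, ...] = free_names
        #: name -> ("free", index) or ("constant", value)
        self.assignment: dict[str, tuple] = assignment
        self.T: np.ndarray = T          # (n_params, n_free) 0/1 map
        self.const: np.ndarray = const  # (n_params,) constants, 0 where free


class _Compiled:
    """Array form of the model for fast likelihood evaluation."""

    __slots__ = ("E1", "E2", "M", "cells", "cell_tree", "tree_labels")

    def __init__(self, E1, E2, M, cells, cell_tree, tree_labels):
        self.E1 = E1                # (n_branches, n_params) direct-factor indicator
        self.E2 = E2                # (n_branches, n_params) complement indicator
        self.M = M                  # (n_cells, n_branches) branch -> cell sum
        self.cells = cells          # list[(tree_label, category)]
        self.cell_tree = cell_tree  # (n_cells,) tree index per cell
        self.tree_labels = tree_labels


class MPTModel:
    """A joint MPT model: several trees over a shared parameter list.

    Parameters
    ----------
    trees:
        The processing trees, one per item type.
    parameters:
        Parameter specifications.  If omitted, parameters are collected from
        the branches in order of first appearance with roles inferred from
        their name stems (``D`` detection, ``d`` source memory, ``b``
        old-guess, ``a``/``g`` source guess).
    restrictions:
        Equality/constant restrictions active on the model.
    name:
        Optional label used in reports.
    """

    def __init__(
        self,
        trees: Sequence[Tree],
        parameters: Sequence[ParameterSpec] | None = None,
        restrictions: Iterable[Restriction] = (),
        name: str = "",
    ) -> None:
        self.trees: tuple[Tree, ...] = tuple(trees)
        if len({t.label for t in self.trees}) != len(self.trees):
            raise MPTError("duplicate tree labels")
        if parameters is None:
            seen: dict[str, None] = {}
            for tree in self.trees:
                for p in tree.parameter_names:
                    seen.setdefault(p)
            parameters = [ParameterSpec(n, _infer_role(n)) for n in seen]
        self.parameters: tuple[ParameterSpec, ...] = tuple(parameters)
        names = [p.name for p in self.parameters]
        if len(set(names)) != len(names):
            raise MPTError("duplicate parameter names")
        self._param_index = {n: i for i, n in enumerate(names)}
        for tree in self.trees:
            for p in tree.parameter_names:
                if p not in self._param_index:
                    raise UnknownParameterError(
                        f"tree {tree.label!r} uses undeclared parameter {p!r}"
                    )
        # dedupe restrictions on canonical form, preserving order
        canon_seen: set = set()
        uniq: list[Restriction] = []
        for r in restrictions:
            c = r.canonical()
            if c not in canon_seen:
                canon_seen.add(c)
                uniq.append(r)
        self.restrictions: tuple[Restriction, ...] = tuple(uniq)
        self.name = name
        self._resolution: _Resolution | None = None
        self._compiled_cache: _Compiled | None = None
        self._resolve()  # validate eagerly

    # ------------------------------------------------------------------ #
    # restriction resolution

    def _resolve(self) -> _Resolution:
        if self._resolution is not None:
            return self._resolution
        names = [p.name for p in self.parameters]
        parent = {n: n for n in names}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x: str, y: str) -> None:
            rx, ry = find(x), find(y)
            if rx == ry:
                return
            # keep the earlier-declared parameter as class representative
            if self._param_index[rx] <= self._param_index[ry]:
                parent[ry] = rx
            else:
                parent[rx] = ry

        constants: dict[str, float] = {}
        for r in self.restrictions:
            for n in r.names:
                if n not in self._param_index:
                    raise UnknownParameterError(f"restriction references unknown parameter {n!r}")
            if r.kind == "equality":
                for other in r.names[1:]:
                    union(r.names[0], other)
            elif r.kind == "constant":
                constants.setdefault(r.names[0], r.value)  # conflicts handled below
                if constants[r.names[0]] != r.value:
                    raise RestrictionConflictError(
                        f"{r.names[0]!r} fixed to both {constants[r.names[0]]} and {r.value}"
                    )
            else:  # pragma: no cover - guarded by Restriction constructors
                raise MPTError(f"unknown restriction kind {r.kind!r}")

        class_const: dict[str, float] = {}
        for n, value in constants.items():
            root = find(n)
            if root in class_const and class_const[root] != value:
                raise RestrictionConflictError(
                    f"equality class of {root!r} forced to both "
                    f"{class_const[root]} and {value}"
                )
            class_const[root] = value

        free_names = tuple(
            n for n in names if find(n) == n and n not in class_const
        )
        free_index = {n: i for i, n in enumerate(free_names)}
        assignment: dict[str, tuple] = {}
        T = np.zeros((len(names), len(free_names)))
        const = np.zeros(len(names))
        for i, n in enumerate(names):
            root = find(n)
            if root in class_const:
                assignment[n] = ("constant", class_const[root])
                const[i] = class_const[root]
            else:
                j = free_index[root]
                assignment[n] = ("free", j)
                T[i, j] = 1.0
        self._resolution = _Resolution(free_names, assignment, T, const)
        return self._resolution

    # ------------------------------------------------------------------ #
    # derived structure

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.parameters)

    @property
    def free_parameters(self) -> tuple[str, ...]:
        return self._resolve().free_names

    @property
    def n_free_categories(self) -> int:
        return sum(len(t.categories) - 1 for t in self.trees)

    @property
    def degrees_of_freedom(self) -> int:
        """Free response categories minus free parameters; negative values
        flag an over-parameterized (non-identifiable) model."""
        return self.n_free_categories - len(self.free_parameters)

    @property
    def tree_labels(self) -> tuple[str, ...]:
        return tuple(t.label for t in self.trees)

    def tree(self, label: str) -> Tree:
        for t in self.trees:
            if t.label == label:
                return t
        raise KeyError(label)

    def with_restrictions(self, restrictions: Iterable[Restriction]) -> "MPTModel":
        """Return a copy with additional restrictions (union with existing)."""
        return MPTModel(
            self.trees,
            self.parameters,
            tuple(self.restrictions) + tuple(restrictions),
            name=self.name,
        )

    # ------------------------------------------------------------------ #
    # evaluation

    def compiled(self) -> _Compiled:
        if self._compiled_cache is not None:
            return self._compiled_cache
        n_p = len(self.parameters)
        rows1, rows2 = [], []
        cells: list[tuple[str, str]] = []
        cell_tree: list[int] = []
        branch_cell: list[int] = []
        for ti, tree in enumerate(self.trees):
            base = len(cells)
            for c in tree.categories:
                cells.append((tree.label, c))
                cell_tree.append(ti)
            cat_index = {c: i for i, c in enumerate(tree.categories)}
            for br in tree.branches:
                e1 = np.zeros(n_p)
                e2 = np.zeros(n_p)
                for pname, direct in br.factors:
                    k = self._param_index[pname]
                    (e1 if direct else e2)[k] += 1.0
                rows1.append(e1)
                rows2.append(e2)
                branch_cell.append(base + cat_index[br.terminal])
        E1 = np.array(rows1)
        E2 = np.array(rows2)
        M = np.zeros((len(cells), len(rows1)))
        for b, cell in enumerate(branch_cell):
            M[cell, b] = 1.0
        self._compiled_cache = _Compiled(
            E1, E2, M, cells, np.array(cell_tree), self.tree_labels
        )
        return self._compiled_cache

    def resolve_theta(self, theta: Mapping[str, float]) -> np.ndarray:
        """Expand a free-parameter assignment to the full parameter vector.

        Raises :class:`MissingParameterError` naming any unassigned free
        parameter, and :class:`ValueError` for values outside [0, 1].
        """
        res = self._resolve()
        for n in res.free_names:
            if n not in theta:
                raise MissingParameterError(f"no value supplied for free parameter {n!r}")
        free = np.array([float(theta[n]) for n in res.free_names])
        if free.size and (np.any(free < 0.0) or np.any(free > 1.0)):
            bad = res.free_names[int(np.argmax((free < 0) | (free > 1)))]
            raise ValueError(f"parameter {bad!r} outside [0, 1]")
        return res.T @ free + res.const

    def category_probabilities(
        self, theta: Mapping[str, float]
    ) -> dict[tuple[str, str], float]:
        """Category probabilities for every (tree, category) cell.

        ``theta`` must assign a value in [0, 1] to every free parameter;
        restricted parameters are resolved first.
        """
        full = self.resolve_theta(theta)
        comp = self.compiled()
        # product form is exact at theta in {0, 1}
        B = np.where(comp.E1 > 0, full[None, :], 1.0) * np.where(
            comp.E2 > 0, 1.0 - full[None, :], 1.0
        )
        p = comp.M @ B.prod(axis=1)
        return {cell: float(v) for cell, v in zip(comp.cells, p)}

    def category_probability_matrix(self, free_theta: np.ndarray) -> np.ndarray:
        """Vectorized cell probabilities for a batch of free-parameter rows.

        Parameters
        ----------
        free_theta:
            Array of shape ``(n, n_free)`` ordered like :attr:`free_parameters`.

        Returns
        -------
        Array of shape ``(n, n_cells)`` in the order of ``compiled().cells``.
        """
        res = self._resolve()
        comp = self.compiled()
        free_theta = np.atleast_2d(np.asarray(free_theta, dtype=float))
        full = free_theta @ res.T.T + res.const  # (n, n_params)
        n, n_br = full.shape[0], comp.E1.shape[0]
        B = np.ones((n, n_br))
        for b in range(n_br):
            for k in np.nonzero(comp.E1[b])[0]:
                B[:, b] *= full[:, k]
            for k in np.nonzero(comp.E2[b])[0]:
                B[:, b] *= 1.0 - full[:, k]
        return B @ comp.M.T

    # ------------------------------------------------------------------ #
    # identifiability

    def check_local_identifiability(
        self, theta0: Mapping[str, float], step: float = 1e-6
    ) -> IdentifiabilityReport:
        """Numerical local-identifiability check at ``theta0``.

        Computes a central-difference Jacobian of the stacked category
        probabilities with respect to the free parameters and reports its
        rank.  Full rank (= number of free parameters) indicates local
        identifiability at ``theta0``.  Boundary values are perturbed inward
        with a warning, since the Jacobian is one-sided there.
        """
        res = self._resolve()
        x0 = np.array([float(theta0[n]) for n in res.free_names])
        eps = 1e-6
        if np.any(x0 <= 0.0) or np.any(x0 >= 1.0):
            warnings.warn(
                "theta0 on the boundary of the unit hypercube; perturbing inward",
                stacklevel=2,
            )
            x0 = np.clip(x0, eps, 1.0 - eps)
        n_f = len(res.free_names)
        cols = []
        for j in range(n_f):
            hi, lo = x0.copy(), x0.copy()
            h = min(step, (1.0 - x0[j]) / 2, x0[j] / 2)
            hi[j] += h
            lo[j] -= h
            p_hi = self.category_probability_matrix(hi[None, :])[0]
            p_lo = self.category_probability_matrix(lo[None, :])[0]
            cols.append((p_hi - p_lo) / (2 * h))
        if cols:
            J = np.column_stack(cols)
            s = np.linalg.svd(J, compute_uv=False)
            tol = max(J.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
            rank = int(np.sum(s > max(tol, 1e-8 * (s[0] if s.size else 1.0))))
        else:
            s = np.array([])
            rank = 0
        return IdentifiabilityReport(rank, n_f, tuple(float(v) for v in s))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"MPTModel({self.name or 'unnamed'}: {len(self.trees)} trees, "
            f"{len(self.parameters)} parameters, "
            f"{len(self.free_parameters)} free, df={self.degrees_of_freedom})"
        )


# ---------------------------------------------------------------------- #
# operation-style wrappers


def category_probabilities(
    model: MPTModel, theta: Mapping[str, float]
) -> dict[tuple[str, str], float]:
    """Category probabilities per (tree, category); see the method of the same name."""
    return model.category_probabilities(theta)


def apply_restrictions(
    model: MPTModel, restrictions: Iterable[Restriction]
) -> MPTModel:
    """Return ``model`` with additional restrictions applied."""
    return model.with_restrictions(restrictions)


def degrees_of_freedom(model: MPTModel) -> int:
    """Free response categories minus free parameters (may be negative)."""
    return model.degrees_of_freedom


def check_local_identifiability(
    model: MPTModel, theta0: Mapping[str, float]
) -> IdentifiabilityReport:
    """Rank report of the probability Jacobian at ``theta0``."""
    return model.check_local_identifiability(theta0)


# ---------------------------------------------------------------------- #
# text format
#
# One line per branch:
#
#     tree_label  category_label  factor1 * (1-factor2) * ...
#
# A directive line ``!categories tree_label: c1 c2 c3`` fixes the ordered
# response-category set of a tree (otherwise categories appear in file
# order).  Restrictions may be given inline or in a companion file:
#
#     restrict: p1 = p2 = p3
#     set: p = 0.5
#
# ``#`` starts a comment.

_FACTOR_RE = re.compile(r"^(?:\(\s*1\s*-\s*(?P<comp>[\w.]+)\s*\)|(?P<direct>[\w.]+))$")


def _parse_factor(token: str) -> tuple[str, bool]:
    m = _FACTOR_RE.match(token.strip())
    if not m:
        raise MPTError(f"cannot parse branch factor {token!r}")
    if m.group("comp"):
        return m.group("comp"), False
    return m.group("direct"), True


def parse_restrictions(text: str) -> list[Restriction]:
    """Parse restriction lines (``restrict: a = b = c`` / ``set: p = 0.5``)."""
    out: list[Restriction] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("restrict:"):
            names = [t.strip() for t in line[len("restrict:"):].split("=")]
            if any(not n for n in names):
                raise MPTError(f"malformed restriction line {raw!r}")
            out.append(Restriction.equal(*names))
        elif line.startswith("set:"):
            lhs, _, rhs = line[len("set:"):].partition("=")
            try:
                value = float(rhs)
            except ValueError as exc:
                raise MPTError(f"malformed constant line {raw!r}") from exc
            out.append(Restriction.constant(lhs.strip(), value))
        else:
            raise MPTError(f"unrecognized restriction line {raw!r}")
    return out


def parse_model(text: str, name: str = "") -> MPTModel:
    """Parse the branch-per-line model format into an :class:`MPTModel`."""
    branch_lines: dict[str, list[Branch]] = {}
    declared_cats: dict[str, tuple[str, ...]] = {}
    seen_cats: dict[str, dict[str, None]] = {}
    restrictions: list[Restriction] = []
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("!categories"):
            body = line[len("!categories"):].strip()
            tree_label, _, cats = body.partition(":")
            declared_cats[tree_label.strip()] = tuple(cats.split())
            continue
        if line.startswith(("restrict:", "set:")):
            restrictions.extend(parse_restrictions(line))
            continue
        parts = line.split(None, 2)
        if len(parts) != 3:
            raise MPTError(f"malformed branch line {raw!r}")
        tree_label, category, expr = parts
        factors = tuple(_parse_factor(tok) for tok in expr.split("*"))
        branch_lines.setdefault(tree_label, []).append(Branch(factors, category))
        seen_cats.setdefault(tree_label, {}).setdefault(category)
    trees = []
    for label, branches in branch_lines.items():
        cats = declared_cats.get(label, tuple(seen_cats[label]))
        trees.append(Tree(label, tuple(branches), cats))
    return MPTModel(trees, restrictions=restrictions, name=name)


def _factor_to_text(factor: tuple[str, bool]) -> str:
    name, direct = factor
    return name if direct else f"(1-{name})"


def model_to_text(model: MPTModel, header: str = "") -> str:
    """Serialize a model to the branch-per-line text format."""
    lines = [f"# {header}"] if header else []
    for tree in model.trees:
        lines.append(f"!categories {tree.label}: {' '.join(tree.categories)}")
    for tree in model.trees:
        for br in tree.branches:
            expr = " * ".join(_factor_to_text(f) for f in br.factors)
            lines.append(f"{tree.label}  {br.terminal}  {expr}")
    lines.extend(restrictions_to_text(model.restrictions).splitlines())
    return "\n".join(lines) + "\n"


def restrictions_to_text(restrictions: Iterable[Restriction]) -> str:
    lines = []
    for r in restrictions:
        if r.kind == "equality":
            lines.append("restrict: " + " = ".join(r.names))
        else:
            lines.append(f"set: {r.names[0]} = {r.value}")
    return "\n".join(lines) + ("\n" if lines else "")
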