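"""Concrete source-monitoring models and the named hypothesis catalogue.

Two experimental designs are covered:

* **Two sources** — statements studied with an "Advertisement" label or a
  "Foundation for Brand Testing" label, tested against new statements.
  Per credibility level the model has eight parameters: item-detection
  ``D_ad``, ``D_test``, ``D_new``; source memory ``d_ad``, ``d_test``;
  old-guessing ``b``; and source-guessing ``a_ad`` (recognized items) /
  ``g_ad`` (unrecognized items guessed old).

* **Three sources** — the same design plus statements studied without any
  source label ("unknown" source).  Source guessing is now over a
  three-point simplex; internally it is represented by two binary
  stick-breaking parameters per guess node, ``a_ad`` = P(guess "ad") and
  ``a_test`` = P(guess "test" | not "ad") (likewise ``g_ad``/``g_test``),
  which keeps every branch a product of theta / (1 - theta) factors.
  :func:`stick_to_simplex` / :func:`simplex_to_stick` convert between the
  two parameterizations for reporting.

Both models are duplicated over the two a-priori credibility levels with
suffixed parameter names (``D_ad.high``, ``D_ad.low``, ...); the base
models keep all parameters separate across credibility.

The module also registers the named base-restriction sets and nested
hypothesis contrasts used in the analysis battery, so degrees-of-freedom
bookkeeping for every reported test is derived from the model structure
rather than hard-coded.
"""

from __future__ import annotations

from importlib import resources

from .mpt_core import (
    Branch,
    MPTModel,
    MPTError,
    Restriction,
    Tree,
    UnknownParameterError,
    parse_model,
    parse_restrictions,
)

__all__ = [
    "CREDIBILITY_LEVELS",
    "TWO_SOURCE_CATEGORIES",
    "THREE_SOURCE_CATEGORIES",
    "build_two_source_model",
    "build_three_source_model",
    "base_restrictions",
    "base_model",
    "hypothesis_submodel",
    "hypothesis_names",
    "experiment_battery",
    "stick_to_simplex",
    "simplex_to_stick",
    "load_bundled_model",
    "load_bundled_restrictions",
]

CREDIBILITY_LEVELS = ("high", "low")
TWO_SOURCE_CATEGORIES = ("ad", "test", "new")
THREE_SOURCE_CATEGORIES = ("ad", "test", "unknown", "new")


def _p(name: str, level: str) -> str:
    return f"{name}.{level}"


def _two_source_trees(level: str) -> list[Tree]:
    D_ad, D_test, D_new = (_p(n, level) for n in ("D_ad", "D_test", "D_new"))
    d_ad, d_test = _p("d_ad", level), _p("d_test", level)
    b, a_ad, g_ad = _p("b", level), _p("a_ad", level), _p("g_ad", level)
    cats = TWO_SOURCE_CATEGORIES

    def guess_old(D: str) -> list[Branch]:
        # item not detected, guessed old, source guessed without memory
        return [
            Branch(((D, False), (b, True), (g_ad, True)), "ad"),
            Branch(((D, False), (b, True), (g_ad, False)), "test"),
            Branch(((D, False), (b, False)), "new"),
        ]

    ad = Tree(
        _p("ad", level),
        tuple(
            [
                Branch(((D_ad, True), (d_ad, True)), "ad"),
                Branch(((D_ad, True), (d_ad, False), (a_ad, True)), "ad"),
                Branch(((D_ad, True), (d_ad, False), (a_ad, False)), "test"),
            ]
            + guess_old(D_ad)
        ),
        cats,
    )
    test = Tree(
        _p("test", level),
        tuple(
            [
                Branch(((D_test, True), (d_test, True)), "test"),
                Branch(((D_test, True), (d_test, False), (a_ad, True)), "ad"),
                Branch(((D_test, True), (d_test, False), (a_ad, False)), "test"),
            ]
            + guess_old(D_test)
        ),
        cats,
    )
    new = Tree(
        _p("new", level),
        tuple([Branch(((D_new, True),), "new")] + guess_old(D_new)),
        cats,
    )
    return [ad, test, new]


def _three_source_trees(level: str) -> list[Tree]:
    D = {s: _p(f"D_{s}", level) for s in ("ad", "test", "unknown", "new")}
    d = {s: _p(f"d_{s}", level) for s in ("ad", "test", "unknown")}
    b = _p("b", level)
    a_ad, a_test = _p("a_ad", level), _p("a_test", level)
    g_ad, g_test = _p("g_ad", level), _p("g_test", level)
    cats = THREE_SOURCE_CATEGORIES

    def guess_simplex(prefix: tuple, p1: str, p2: str) -> list[Branch]:
        # stick-breaking over {ad, test, unknown}
        return [
            Branch(prefix + ((p1, True),), "ad"),
            Branch(prefix + ((p1, False), (p2, True)), "test"),
            Branch(prefix + ((p1, False), (p2, False)), "unknown"),
        ]

    def guess_old(Ds: str) -> list[Branch]:
        return guess_simplex(((Ds, False), (b, True)), g_ad, g_test) + [
            Branch(((Ds, False), (b, False)), "new")
        ]

    trees = []
    for src in ("ad", "test", "unknown"):
        branches = [Branch(((D[src], True), (d[src], True)), src)]
        branches += guess_simplex(((D[src], True), (d[src], False)), a_ad, a_test)
        branches += guess_old(D[src])
        trees.append(Tree(_p(src, level), tuple(branches), cats))
    trees.append(
        Tree(
            _p("new", level),
            tuple([Branch(((D["new"], True),), "new")] + guess_old(D["new"])),
            cats,
        )
    )
    return trees


def build_two_source_model(
    levels: tuple[str, ...] = CREDIBILITY_LEVELS,
) -> MPTModel:
    """Two-source source-monitoring model, one tree set per credibility level.

    With the default two levels: 6 trees (ad/test/new x high/low), 3
    response categories each, 16 parameters (8 per level) and no
    restrictions.
    """
    trees: list[Tree] = []
    for level in levels:
        trees.extend(_two_source_trees(level))
    return MPTModel(trees, name=f"two-source({','.join(levels)})")


def build_three_source_model(
    levels: tuple[str, ...] = CREDIBILITY_LEVELS,
) -> MPTModel:
    """Three-source source-monitoring model (ad / brand testing / unlabeled).

    With the default two levels: 8 trees (ad/test/unknown/new x high/low),
    4 response categories each, 24 parameters (12 per level, four more item
    types' worth than the two-source variant: ``D_unknown``, ``d_unknown``
    and the extra stick-breaking guess parameters).
    """
    trees: list[Tree] = []
    for level in levels:
        trees.extend(_three_source_trees(level))
    return MPTModel(trees, name=f"three-source({','.join(levels)})")


# ---------------------------------------------------------------------- #
# named base restriction sets

_BASE_NAMES = ("exp1", "exp1_unrestrictedD", "exp2_parsimonious", "exp2_final")


def base_restrictions(
    name: str, levels: tuple[str, ...] = CREDIBILITY_LEVELS
) -> tuple[Restriction, ...]:
    """Return the named base restriction set.

    * ``exp1`` — two-source identifiable base: ``D_ad = D_test = D_new``
      (two-high-threshold old/new symmetry plus no detection difference
      between sources) and ``a_ad = g_ad`` (guessing independent of
      recognition status), within each credibility level.
    * ``exp1_unrestrictedD`` — only ``a_ad = g_ad``; detection left free,
      which leaves the model over-parameterized (negative df) and is kept
      for identifiability demonstrations.
    * ``exp2_parsimonious`` — three-source identifiable base: only
      ``D_unknown = D_new`` per credibility level.
    * ``exp2_final`` — three-source base with detection equated across all
      item types and source guessing equated across recognition status
      (``a = g`` on both stick-breaking parameters), per credibility level.
    """
    if name not in _BASE_NAMES:
        raise KeyError(f"unknown base-restriction set {name!r}; choose from {_BASE_NAMES}")
    out: list[Restriction] = []
    for lv in levels:
        if name == "exp1":
            out.append(Restriction.equal(_p("D_ad", lv), _p("D_test", lv), _p("D_new", lv)))
            out.append(Restriction.equal(_p("a_ad", lv), _p("g_ad", lv)))
        elif name == "exp1_unrestrictedD":
            out.append(Restriction.equal(_p("a_ad", lv), _p("g_ad", lv)))
        elif name == "exp2_parsimonious":
            out.append(Restriction.equal(_p("D_unknown", lv), _p("D_new", lv)))
        elif name == "exp2_final":
            out.append(
                Restriction.equal(
                    _p("D_ad", lv), _p("D_test", lv), _p("D_unknown", lv), _p("D_new", lv)
                )
            )
            out.append(Restriction.equal(_p("a_ad", lv), _p("g_ad", lv)))
            out.append(Restriction.equal(_p("a_test", lv), _p("g_test", lv)))
    return tuple(out)


def base_model(name: str, levels: tuple[str, ...] = CREDIBILITY_LEVELS) -> MPTModel:
    """Build the experiment model with the named base restrictions applied."""
    if name.startswith("exp1"):
        model = build_two_source_model(levels)
    else:
        model = build_three_source_model(levels)
    model = model.with_restrictions(base_restrictions(name, levels))
    model.name = f"{name}({','.join(levels)})"
    return model


# ---------------------------------------------------------------------- #
# hypothesis catalogue
#
# Each entry maps a named contrast to the equality restrictions it adds.
# Level-specific contrasts are addressed as "name:level".


def _hyp_restrictions(key: str, levels: tuple[str, ...]) -> list[Restriction]:
    name, _, level = key.partition(":")
    if name == "D_equal_across_credibility":
        return [Restriction.equal(*(_p("D_ad", lv) for lv in levels))]
    if name == "g_ad_equal_across_credibility":
        return [Restriction.equal(*(_p("g_ad", lv) for lv in levels))]
    if name == "d_ad_equals_d_test":
        return [Restriction.equal(_p("d_ad", level), _p("d_test", level))]
    if name == "d_ad_equals_d_unknown":
        return [Restriction.equal(_p("d_ad", level), _p("d_unknown", level))]
    if name == "d_test_equals_d_unknown":
        return [Restriction.equal(_p("d_test", level), _p("d_unknown", level))]
    if name == "D_equal_across_sources":
        return [
            Restriction.equal(
                _p("D_ad", lv), _p("D_test", lv), _p("D_unknown", lv)
            )
            for lv in levels
        ]
    if name == "a_equals_g":
        out: list[Restriction] = []
        for lv in levels:
            out.append(Restriction.equal(_p("a_ad", lv), _p("g_ad", lv)))
            out.append(Restriction.equal(_p("a_test", lv), _p("g_test", lv)))
        return out
    raise KeyError(f"unknown hypothesis {key!r}")


def hypothesis_names() -> tuple[str, ...]:
    """The registered contrast names (level-specific ones take a ':level' suffix)."""
    return (
        "D_equal_across_credibility",
        "g_ad_equal_across_credibility",
        "d_ad_equals_d_test:<level>",
        "d_ad_equals_d_unknown:<level>",
        "d_test_equals_d_unknown:<level>",
        "D_equal_across_sources",
        "a_equals_g",
    )


def hypothesis_submodel(
    model: MPTModel, hypothesis: str, levels: tuple[str, ...] = CREDIBILITY_LEVELS
) -> MPTModel:
    """Return ``model`` with the named contrast's equality restrictions added.

    The submodel is nested in ``model`` by construction; the drop in free
    parameters equals the number of independent restrictions added.
    """
    restrictions = _hyp_restrictions(hypothesis, levels)
    names = set(model.parameter_names)
    for r in restrictions:
        for n in r.names:
            if n not in names:
                raise UnknownParameterError(
                    f"hypothesis {hypothesis!r} references {n!r}, absent from the model"
                )
    sub = model.with_restrictions(restrictions)
    sub.name = f"{model.name}+{hypothesis}"
    return sub


def experiment_battery(experiment: str) -> tuple[tuple[str, str], ...]:
    """The ordered hypothesis battery of an experiment.

    Returns tuples ``(parent_base_name, hypothesis_key)``.  Each test
    compares the parent base model with the base model plus the contrast's
    equality restrictions.
    """
    if experiment == "exp1":
        return (
            ("exp1", "D_equal_across_credibility"),
            ("exp1", "d_ad_equals_d_test:high"),
            ("exp1", "d_ad_equals_d_test:low"),
            ("exp1", "g_ad_equal_across_credibility"),
        )
    if experiment == "exp2":
        return (
            ("exp2_parsimonious", "D_equal_across_sources"),
            ("exp2_parsimonious", "a_equals_g"),
            ("exp2_final", "D_equal_across_credibility"),
            ("exp2_final", "d_ad_equals_d_test:high"),
            ("exp2_final", "d_ad_equals_d_test:low"),
            ("exp2_final", "d_test_equals_d_unknown:high"),
            ("exp2_final", "d_test_equals_d_unknown:low"),
            ("exp2_final", "d_ad_equals_d_unknown:high"),
            ("exp2_final", "d_ad_equals_d_unknown:low"),
            ("exp2_final", "g_ad_equal_across_credibility"),
        )
    raise KeyError(f"unknown experiment {experiment!r}")


# ---------------------------------------------------------------------- #
# simplex <-> stick-breaking conversion for the three-way guess nodes


def stick_to_simplex(p_ad: float, p_test_given_not_ad: float) -> dict[str, float]:
    """Convert stick-breaking guess parameters to simplex probabilities."""
    ad = p_ad
    test = (1.0 - p_ad) * p_test_given_not_ad
    return {"ad": ad, "test": test, "unknown": 1.0 - ad - test}


def simplex_to_stick(p_ad: float, p_test: float, p_unknown: float) -> tuple[float, float]:
    """Convert simplex guess probabilities to the two stick-breaking parameters.

    Returns ``(P(ad), P(test | not ad))``.  When ``p_ad == 1`` the
    conditional is undefined; 0.5 is returned by convention.
    """
    total = p_ad + p_test + p_unknown
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"guess probabilities must sum to 1, got {total}")
    rest = 1.0 - p_ad
    return p_ad, (p_test / rest if rest > 1e-12 else 0.5)


# ---------------------------------------------------------------------- #
# bundled model files

_BUNDLED_MODELS = {"exp1_two_source", "exp2_three_source"}


def load_bundled_model(name: str) -> MPTModel:
    """Load one of the shipped model-specification files by stem name."""
    if name not in _BUNDLED_MODELS:
        raise KeyError(f"unknown bundled model {name!r}; choose from {sorted(_BUNDLED_MODELS)}")
    text = resources.files("adsource.models").joinpath(f"{name}.mpt").read_text()
    return parse_model(text, name=name)


def load_bundled_restrictions(name: str) -> tuple[Restriction, ...]:
    """Load one of the shipped restriction files (``exp1``, ``exp2_parsimonious``, ...)."""
    if name not in _BASE_NAMES:
        raise KeyError(f"unknown bundled restriction set {name!r}")
    text = resources.files("adsource.models").joinpath(f"{name}.restrict").read_text()
    return tuple(parse_restrictions(text))
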