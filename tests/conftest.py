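import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import adsource as a
from adsource.model_library import base_model, build_three_source_model, build_two_source_model

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def two_source_model():
    return build_two_source_model()


@pytest.fixture(scope="session")
def three_source_model():
    return build_three_source_model()


@pytest.fixture(scope="session")
def exp1_base():
    return base_model("exp1")


@pytest.fixture(scope="session")
def exp1_base_single():
    """Two-source base model for one credibility level (5 free parameters)."""
    return base_model("exp1", ("high",))


@pytest.fixture(scope="session")
def exp2_parsimonious():
    return base_model("exp2_parsimonious")


@pytest.fixture(scope="session")
def exp2_final():
    return base_model("exp2_final")


def random_theta(model, rng):
    """Uniform-random full parameter assignment for a model's free parameters."""
    return {n: float(v) for n, v in zip(model.free_parameters, rng.uniform(0, 1, len(model.free_parameters)))}


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def brute_force_probabilities(model, theta):
    """Independent oracle: recursive walk over every branch of every tree.

    Uses only the symbolic Branch/Tree structure, not the compiled arrays.
    """
    full = dict(theta)
    # resolve restrictions by brute force: constants, then equality closure
    changed = True
    assignments = dict(theta)
    while changed:
        changed = False
        for r in model.restrictions:
            if r.kind == "constant":
                if assignments.get(r.names[0]) != r.value:
                    assignments[r.names[0]] = r.value
                    changed = True
            else:
                known = [n for n in r.names if n in assignments]
                if known:
                    v = assignments[known[0]]
                    for n in r.names:
                        if assignments.get(n) != v:
                            assignments[n] = v
                            changed = True
    out = {}
    for tree in model.trees:
        for cat in tree.categories:
            total = 0.0
            for br in tree.branches:
                if br.terminal != cat:
                    continue
                p = 1.0
                for name, direct in br.factors:
                    v = assignments[name]
                    p *= v if direct else 1.0 - v
                total += p
            out[(tree.label, cat)] = total
    return out
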