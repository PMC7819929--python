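"""Symbolic tree machinery: probabilities, restrictions, df, identifiability."""

import numpy as np
import pytest

from adsource.mpt_core import (
    Branch,
    MPTModel,
    MPTError,
    MissingParameterError,
    Restriction,
    RestrictionConflictError,
    Tree,
    UnknownParameterError,
    apply_restrictions,
    degrees_of_freedom,
    model_to_text,
    parse_model,
    parse_restrictions,
)
from adsource.model_library import base_model, build_two_source_model

from conftest import brute_force_probabilities, random_theta


def toy_model(restrictions=()):
    """One tree, two categories, single parameter p: hit with p, miss with 1-p."""
    tree = Tree("t", (Branch((("p", True),), "hit"), Branch((("p", False),), "miss")), ("hit", "miss"))
    return MPTModel([tree], restrictions=restrictions)


class TestCategoryProbabilities:
    def test_perfect_detection_and_source_memory(self):
        model = base_model("exp1", ("high",))
        theta = {"D_ad.high": 1.0, "d_ad.high": 1.0, "d_test.high": 0.3,
                 "b.high": 0.4, "a_ad.high": 0.7}
        p = model.category_probabilities(theta)
        assert p[("ad.high", "ad")] == pytest.approx(1.0)
        assert p[("ad.high", "test")] == pytest.approx(0.0)
        assert p[("ad.high", "new")] == pytest.approx(0.0)

    def test_no_detection_no_old_guessing_gives_new(self):
        model = base_model("exp1", ("high",))
        theta = {"D_ad.high": 0.0, "d_ad.high": 0.5, "d_test.high": 0.5,
                 "b.high": 0.0, "a_ad.high": 0.5}
        p = model.category_probabilities(theta)
        for tree in model.tree_labels:
            assert p[(tree, "new")] == pytest.approx(1.0)

    def test_half_probabilities_ad_tree(self):
        # hand enumeration of the three branches ending in "ad":
        # D*d + D*(1-d)*a + (1-D)*b*g = .25 + .125 + .125 = 0.5
        model = base_model("exp1", ("high",))
        theta = {"D_ad.high": 0.5, "d_ad.high": 0.5, "d_test.high": 0.5,
                 "b.high": 0.5, "a_ad.high": 0.5}
        p = model.category_probabilities(theta)
        assert p[("ad.high", "ad")] == pytest.approx(0.5, abs=1e-12)

    def test_missing_parameter_is_named(self):
        model = base_model("exp1", ("high",))
        with pytest.raises(MissingParameterError, match="b.high"):
            model.category_probabilities({n: 0.5 for n in model.free_parameters if n != "b.high"})

    def test_out_of_range_value_rejected(self):
        model = toy_model()
        with pytest.raises(ValueError, match="outside"):
            model.category_probabilities({"p": 1.5})

    @pytest.mark.parametrize("model_name", ["two", "three"])
    def test_normalization_random_theta(self, model_name, two_source_model, three_source_model):
        model = two_source_model if model_name == "two" else three_source_model
        rng = np.random.default_rng(11)
        for _ in range(200):
            probs = model.category_probabilities(random_theta(model, rng))
            for tree in model.tree_labels:
                total = sum(v for (t, _), v in probs.items() if t == tree)
                assert abs(total - 1.0) < 1e-12

    @pytest.mark.parametrize("restricted", [False, True])
    def test_agrees_with_brute_force_tree_walk(self, restricted, rng):
        model = base_model("exp1") if restricted else build_two_source_model()
        for _ in range(50):
            theta = random_theta(model, rng)
            fast = model.category_probabilities(theta)
            slow = brute_force_probabilities(model, theta)
            assert fast.keys() == slow.keys()
            for cell in fast:
                assert fast[cell] == pytest.approx(slow[cell], abs=1e-12)


class TestRestrictions:
    def test_empty_restriction_set_is_identity(self, two_source_model):
        same = apply_restrictions(two_source_model, ())
        assert same.free_parameters == two_source_model.free_parameters
        assert same.degrees_of_freedom == two_source_model.degrees_of_freedom

    def test_idempotence(self, two_source_model):
        rset = (
            Restriction.equal("D_ad.high", "D_test.high", "D_new.high"),
            Restriction.equal("a_ad.high", "g_ad.high"),
        )
        once = apply_restrictions(two_source_model, rset)
        twice = apply_restrictions(once, rset)
        assert once.free_parameters == twice.free_parameters
        assert once.degrees_of_freedom == twice.degrees_of_freedom

    def test_conflicting_constants_raise(self):
        with pytest.raises(RestrictionConflictError):
            toy_model((Restriction.constant("p", 0.2), Restriction.constant("p", 0.3)))

    def test_conflict_through_equality_class(self, two_source_model):
        with pytest.raises(RestrictionConflictError):
            apply_restrictions(
                two_source_model,
                (
                    Restriction.equal("D_ad.high", "D_test.high"),
                    Restriction.constant("D_ad.high", 0.2),
                    Restriction.constant("D_test.high", 0.7),
                ),
            )

    def test_unknown_parameter_raises(self, two_source_model):
        with pytest.raises(UnknownParameterError):
            apply_restrictions(two_source_model, (Restriction.equal("D_ad.high", "nope"),))

    def test_constant_propagates_to_probabilities(self):
        model = toy_model((Restriction.constant("p", 0.25),))
        assert model.free_parameters == ()
        assert model.category_probabilities({})[("t", "hit")] == pytest.approx(0.25)

    def test_constant_outside_unit_interval_rejected(self):
        with pytest.raises(MPTError):
            Restriction.constant("p", 1.2)


class TestDegreesOfFreedom:
    def test_unrestricted_two_source_single_level_is_overparameterized(self):
        model = build_two_source_model(("high",))
        assert model.n_free_categories == 6
        assert len(model.parameters) == 8
        assert degrees_of_freedom(model) == -2

    def test_saturated_toy_model(self):
        assert degrees_of_freedom(toy_model()) == 0

    def test_exp2_final_base(self, exp2_final):
        assert degrees_of_freedom(exp2_final) == 10


class TestIdentifiability:
    def test_exp1_base_full_rank(self, exp1_base):
        report = exp1_base.check_local_identifiability({n: 0.5 for n in exp1_base.free_parameters})
        assert report.n_free_parameters == 10
        assert report.rank == 10
        assert report.locally_identified

    def test_unrestricted_model_rank_deficient(self):
        model = build_two_source_model(("high",))
        report = model.check_local_identifiability({n: 0.5 for n in model.free_parameters})
        assert report.rank < report.n_free_parameters

    def test_single_parameter_toy_rank_one(self):
        report = toy_model().check_local_identifiability({"p": 0.5})
        assert report.rank == 1
        assert report.locally_identified

    def test_boundary_theta_warns_and_recovers(self):
        with pytest.warns(UserWarning, match="boundary"):
            report = toy_model().check_local_identifiability({"p": 1.0})
        assert report.rank == 1


class TestTextFormat:
    def test_round_trip_preserves_structure_and_probabilities(self, two_source_model, rng):
        text = model_to_text(two_source_model, header="round trip")
        loaded = parse_model(text)
        assert loaded.parameter_names == two_source_model.parameter_names
        assert loaded.tree_labels == two_source_model.tree_labels
        theta = random_theta(two_source_model, rng)
        a = two_source_model.category_probabilities(theta)
        b = loaded.category_probabilities(theta)
        for cell in a:
            assert a[cell] == pytest.approx(b[cell], abs=1e-14)

    def test_restriction_lines(self):
        parsed = parse_restrictions("restrict: a = b = c\nset: p = 0.5\n# comment\n")
        assert parsed[0].kind == "equality" and parsed[0].names == ("a", "b", "c")
        assert parsed[1].kind == "constant" and parsed[1].value == 0.5

    def test_malformed_lines_raise(self):
        with pytest.raises(MPTError):
            parse_restrictions("restrict: a = = b")
        with pytest.raises(MPTError):
            parse_model("tree cat p * q * ")

    def test_branch_terminal_must_be_category(self):
        with pytest.raises(MPTError, match="not a response category"):
            Tree("t", (Branch((("p", True),), "weird"),), ("hit", "miss"))
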