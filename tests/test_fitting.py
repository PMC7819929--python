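"""G2 estimation: recovery, comparison, null calibration, bootstrap."""

import numpy as np
import pytest
from scipy import stats

from adsource.fitting import (
    FitError,
    FrequencyTable,
    NotNestedError,
    UnidentifiableModelError,
    bootstrap_se,
    compare,
    fit,
)
from adsource.model_library import base_model, build_two_source_model, hypothesis_submodel
from adsource.mpt_core import Branch, MPTModel, Restriction, Tree
from adsource.synthetic_data import design_totals, expected_table, sample_table
from adsource.synthetic_data import ExperimentDesign

EXP1_THETA = {
    "D_ad.high": 0.77, "d_ad.high": 0.32, "d_test.high": 0.37,
    "b.high": 0.21, "a_ad.high": 0.30,
    "D_ad.low": 0.83, "d_ad.low": 0.15, "d_test.low": 0.32,
    "b.low": 0.33, "a_ad.low": 0.60,
}

EXP1_TOTALS = design_totals(ExperimentDesign.exp1())


def saturated_two_category_model():
    tree = Tree("t", (Branch((("p", True),), "hit"), Branch((("p", False),), "miss")), ("hit", "miss"))
    return MPTModel([tree])


class TestFit:
    def test_saturated_model_reproduces_proportions(self):
        model = saturated_two_category_model()
        table = FrequencyTable({("t", "hit"): 37.0, ("t", "miss"): 63.0})
        result = fit(model, table, n_starts=3, seed=0)
        assert result.G2 == pytest.approx(0.0, abs=1e-8)
        assert result.df == 0
        assert result.free_estimates["p"] == pytest.approx(0.37, abs=1e-6)

    def test_recovers_theta_from_expected_counts(self, exp1_base):
        table = expected_table(exp1_base, EXP1_THETA, EXP1_TOTALS)
        result = fit(exp1_base, table, n_starts=5, seed=1)
        assert result.converged
        assert result.G2 == pytest.approx(0.0, abs=1e-6)
        for name in exp1_base.free_parameters:
            assert result.free_estimates[name] == pytest.approx(EXP1_THETA[name], abs=1e-5)
        # resolved estimates honor the equality restrictions
        assert result.estimates["D_new.high"] == result.estimates["D_ad.high"]
        assert result.estimates["g_ad.low"] == result.estimates["a_ad.low"]

    def test_p_value_matches_chi2_survival(self, exp1_base):
        table = sample_table(exp1_base, EXP1_THETA, EXP1_TOTALS, seed=5)
        result = fit(exp1_base, table, n_starts=5, seed=2)
        assert result.G2 >= 0
        assert result.p_value == pytest.approx(stats.chi2.sf(result.G2, result.df))

    def test_seed_reproducible(self, exp1_base):
        table = sample_table(exp1_base, EXP1_THETA, EXP1_TOTALS, seed=6)
        r1 = fit(exp1_base, table, n_starts=5, seed=9)
        r2 = fit(exp1_base, table, n_starts=5, seed=9)
        assert r1.free_estimates == r2.free_estimates
        assert r1.G2 == r2.G2

    def test_unidentifiable_model_rejected(self):
        model = build_two_source_model(("high",))  # df = -2
        table = FrequencyTable({(f"{t}.high", c): 10.0 for t in ("ad", "test", "new")
                                for c in ("ad", "test", "new")})
        with pytest.raises(UnidentifiableModelError):
            fit(model, table)

    def test_zero_total_tree_rejected(self, exp1_base_single):
        counts = {(f"{t}.high", c): 10.0 for t in ("ad", "test") for c in ("ad", "test", "new")}
        counts.update({("new.high", c): 0.0 for c in ("ad", "test", "new")})
        with pytest.raises(ValueError, match="zero observations"):
            fit(exp1_base_single, FrequencyTable(counts))

    def test_mismatched_trees_rejected(self, exp1_base, exp1_base_single):
        table = expected_table(exp1_base_single,
                               {k: v for k, v in EXP1_THETA.items() if k.endswith(".high")},
                               {k: v for k, v in EXP1_TOTALS.items() if k.endswith(".high")})
        with pytest.raises(ValueError):
            fit(exp1_base, table)


class TestCompare:
    def test_restricted_g2_never_below_parent(self, exp1_base, rng):
        for trial in range(5):
            table = sample_table(exp1_base, EXP1_THETA, EXP1_TOTALS, seed=100 + trial)
            full = fit(exp1_base, table, n_starts=5, seed=trial)
            sub = hypothesis_submodel(exp1_base, "g_ad_equal_across_credibility")
            comp = compare(full, sub, table, n_starts=5, seed=trial)
            assert comp.delta_G2 >= 0.0
            assert comp.delta_df == 1

    def test_restriction_at_the_estimate_changes_nothing(self, exp1_base_single):
        theta = {k: v for k, v in EXP1_THETA.items() if k.endswith(".high")}
        totals = {k: v for k, v in EXP1_TOTALS.items() if k.endswith(".high")}
        table = expected_table(exp1_base_single, theta, totals)
        full = fit(exp1_base_single, table, n_starts=5, seed=0)
        pinned = exp1_base_single.with_restrictions(
            (Restriction.constant("b.high", full.free_estimates["b.high"]),)
        )
        comp = compare(full, pinned, table, n_starts=5, seed=0)
        assert comp.delta_G2 == pytest.approx(0.0, abs=1e-5)

    def test_delta_g2_grows_with_n_under_violation(self, exp1_base):
        # g differs across credibility in the generator; expected-count tables
        # at growing n should give growing (in fact proportional) delta-G2
        sub = hypothesis_submodel(exp1_base, "g_ad_equal_across_credibility")
        deltas = []
        for scale in (1e3, 1e4):
            totals = {t: scale * v / sum(EXP1_TOTALS.values()) for t, v in EXP1_TOTALS.items()}
            table = expected_table(exp1_base, EXP1_THETA, totals)
            full = fit(exp1_base, table, n_starts=5, seed=0)
            deltas.append(compare(full, sub, table, n_starts=5, seed=0).delta_G2)
        assert deltas[1] > 5 * deltas[0] > 0

    def test_non_nested_pair_rejected(self, exp1_base):
        table = expected_table(exp1_base, EXP1_THETA, EXP1_TOTALS)
        full = fit(exp1_base, table, n_starts=3, seed=0)
        other = build_two_source_model().with_restrictions(
            (Restriction.equal("D_ad.high", "D_test.high"),)
        )
        with pytest.raises(NotNestedError):
            compare(full, other, table)
        with pytest.raises(NotNestedError):
            compare(full, full.model, table)  # no added restriction

    def test_null_delta_g2_is_chi_square_one(self, exp1_base):
        """Under a true g equality, delta-G2(1) follows chi2(1) (KS check)."""
        theta = dict(EXP1_THETA)
        theta["a_ad.high"] = theta["a_ad.low"] = 0.45
        sub = hypothesis_submodel(exp1_base, "g_ad_equal_across_credibility")
        deltas = []
        for rep in range(300):
            table = sample_table(exp1_base, theta, EXP1_TOTALS, seed=2000 + rep)
            full = fit(exp1_base, table, n_starts=2, seed=rep)
            deltas.append(compare(full, sub, table, n_starts=2, seed=rep).delta_G2)
        ks = stats.kstest(deltas, "chi2", args=(1,))
        assert ks.pvalue > 0.01


class TestBootstrap:
    def test_reproducible_and_nonnegative(self, exp1_base_single):
        theta = {k: v for k, v in EXP1_THETA.items() if k.endswith(".high")}
        totals = {"ad.high": 600.0, "test.high": 600.0, "new.high": 1200.0}
        table = sample_table(exp1_base_single, theta, totals, seed=42)
        se1 = bootstrap_se(exp1_base_single, table, B=40, seed=7)
        se2 = bootstrap_se(exp1_base_single, table, B=40, seed=7)
        assert se1 == se2
        assert all(v >= 0 for v in se1.values())
        # equality-class members share their representative's SE
        assert se1["g_ad.high"] == se1["a_ad.high"]
        assert se1["D_new.high"] == se1["D_ad.high"]

    def test_constant_parameter_has_zero_se(self, exp1_base_single):
        model = exp1_base_single.with_restrictions(
            (Restriction.constant("d_test.high", 0.3),)
        )
        theta = {k: v for k, v in EXP1_THETA.items()
                 if k.endswith(".high") and k != "d_test.high"}
        totals = {"ad.high": 600.0, "test.high": 600.0, "new.high": 1200.0}
        table = sample_table(model, theta, totals, seed=43)
        se = bootstrap_se(model, table, B=30, seed=8)
        assert se["d_test.high"] == 0.0

    def test_requires_at_least_two_replicates(self, exp1_base_single):
        theta = {k: v for k, v in EXP1_THETA.items() if k.endswith(".high")}
        totals = {"ad.high": 60.0, "test.high": 60.0, "new.high": 120.0}
        table = sample_table(exp1_base_single, theta, totals, seed=44)
        with pytest.raises(ValueError):
            bootstrap_se(exp1_base_single, table, B=1, seed=0)


class TestFrequencyTableIO:
    def test_csv_round_trip(self, exp1_base, tmp_path):
        table = sample_table(exp1_base, EXP1_THETA, EXP1_TOTALS, seed=3)
        path = tmp_path / "freq.csv"
        table.to_csv(path)
        back = FrequencyTable.from_csv(path)
        assert back.counts == table.counts
        assert back.totals == table.totals

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            FrequencyTable({("t.high", "hit"): -1.0})

    def test_totals_are_row_sums(self):
        table = FrequencyTable({("t.high", "a"): 3.0, ("t.high", "b"): 7.0, ("u.high", "a"): 5.0})
        assert table.totals == {"t.high": 10.0, "u.high": 5.0}
        assert table.n_observations == 15.0
        assert table.is_integral()
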