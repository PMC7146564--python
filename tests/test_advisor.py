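import itertools

import numpy as np
import pandas as pd
import pytest

from poultrychain.advisor import (AM, ES, HH, HT, LT, CartParams, Condition,
                                  Rule, RuleSet, extract_rules, fit_cart,
                                  predict, recommend, reference_rule_set,
                                  reference_tree)
from poultrychain.errors import (ConfigurationError, InvalidInputError,
                                 MissingFeatureError)
from poultrychain.synth import ChainScenario, gen_chain_dataset

from .conftest import USE_CASE_KPIS

PLANTED = {AM: 40.0, ES: 65.0, HH: 20.0, HT: 50.0, LT: 35.0}
FEATURES = sorted(PLANTED)


def brute_force_best_split(x, y):
    """Enumerate every midpoint threshold, return the lowest weighted Gini."""
    def gini(labels):
        if len(labels) == 0:
            return 0.0
        _, counts = np.unique(labels, return_counts=True)
        p = counts / len(labels)
        return 1 - np.sum(p ** 2)

    xs = np.sort(np.unique(x))
    best = None
    for a, b in zip(xs, xs[1:]):
        thr = (a + b) / 2
        left, right = y[x <= thr], y[x > thr]
        imp = (len(left) * gini(left) + len(right) * gini(right)) / len(y)
        if best is None or imp < best[1]:
            best = (thr, imp)
    return best


class TestFitCart:
    def test_single_split_lands_in_the_separating_gap(self):
        rng = np.random.default_rng(1)
        x = np.r_[rng.uniform(0, 60, 100), rng.uniform(70, 100, 100)]
        y = np.array(["A"] * 100 + ["B"] * 100)
        table = pd.DataFrame({"f": x, "label": y})
        tree = fit_cart(table, "label", ["f"])
        assert tree.n_leaves() == 2
        (feat, thr), = tree.thresholds()
        assert feat == "f"
        assert x[x <= 65].max() < thr < x[x > 65].min()
        oracle_thr, _ = brute_force_best_split(x, y)
        assert thr == pytest.approx(oracle_thr)

    def test_every_split_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 100, 120)
        y = np.where(x > 42.0, "B", "A")
        flip = rng.random(120) < 0.1
        y = np.where(flip, np.where(y == "A", "B", "A"), y)
        table = pd.DataFrame({"f": x, "label": y})
        tree = fit_cart(table, "label", ["f"], CartParams(max_depth=1))
        (_, thr), = tree.thresholds()
        assert thr == pytest.approx(brute_force_best_split(x, y)[0])

    def test_single_class_input_gives_single_leaf(self):
        table = pd.DataFrame({"f": [1.0, 2.0, 3.0], "label": ["A", "A", "A"]})
        tree = fit_cart(table, "label", ["f"])
        assert tree.n_leaves() == 1
        assert tree.predict_row({"f": 99.0}) == "A"

    def test_empty_feature_set_rejected(self):
        table = pd.DataFrame({"label": ["A", "B"]})
        with pytest.raises(ConfigurationError):
            fit_cart(table, "label", [])

    def test_deterministic_refit(self):
        table = gen_chain_dataset(ChainScenario(n_chains=300, seed=8))
        t1 = fit_cart(table, "meat_quality", FEATURES)
        t2 = fit_cart(table, "meat_quality", FEATURES)
        assert t1.thresholds() == t2.thresholds()

    def test_training_accuracy_nondecreasing_in_depth(self):
        table = gen_chain_dataset(ChainScenario(n_chains=500, label_noise=0.1, seed=4))
        y = table["meat_quality"].to_numpy()
        accs = []
        for depth in (1, 2, 3, 5, 8):
            tree = fit_cart(table, "meat_quality", FEATURES,
                            CartParams(max_depth=depth))
            accs.append(np.mean(tree.predict(table[FEATURES]) == y))
        assert accs == sorted(accs)

    def test_zero_noise_partition_recovered(self):
        table = gen_chain_dataset(ChainScenario(n_chains=2000, label_noise=0.0, seed=3))
        tree = fit_cart(table, "meat_quality", FEATURES)
        # the fitted partition reproduces every training label ...
        assert np.all(tree.predict(table[FEATURES]) == table["meat_quality"].to_numpy())
        # ... and every planted boundary is recovered by some learned split
        # (the tree may also carry auxiliary splits inside pure-by-chance
        # regions; those do not alter the induced partition)
        learned = tree.thresholds()
        for feat, want in PLANTED.items():
            assert any(f == feat and abs(t - want) < 2.0 for f, t in learned), feat
        # fresh random vectors agree except inside the tiny threshold gaps
        rules, ref = extract_rules(tree), reference_rule_set()
        rng = np.random.default_rng(0)
        vectors = [dict(zip(FEATURES, rng.uniform(0, 100, 5))) for _ in range(1000)]
        disagreements = sum(predict(rules, v) != predict(ref, v) for v in vectors)
        assert disagreements <= 10

    def test_noisy_fit_recovers_all_planted_boundaries(self):
        table = gen_chain_dataset(ChainScenario(n_chains=2000, label_noise=0.05, seed=3))
        tree = fit_cart(table, "meat_quality", FEATURES,
                        CartParams(min_leaf=20, min_impurity_decrease=0.01))
        learned = tree.thresholds()
        for feat, want in PLANTED.items():
            assert any(f == feat and abs(t - want) < 2.0 for f, t in learned), feat

    def test_regression_target_supported_by_variance_reduction(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 10, 200)
        ytarget = np.where(x > 5, 10.0, 2.0) + rng.normal(0, 0.1, 200)
        table = pd.DataFrame({"f": x, "deaths": ytarget})
        tree = fit_cart(table, "deaths", ["f"], CartParams(max_depth=1))
        (_, thr), = tree.thresholds()
        assert abs(thr - 5.0) < 0.5
        with pytest.raises(ConfigurationError):
            extract_rules(tree)


class TestRuleExtraction:
    def test_single_leaf_gives_one_unconditional_rule(self):
        table = pd.DataFrame({"f": [1.0, 2.0], "label": ["A", "A"]})
        rules = extract_rules(fit_cart(table, "label", ["f"]))
        assert len(rules.rules) == 1
        assert rules.rules[0].conditions == ()

    def test_reference_tree_yields_exactly_six_rules(self):
        rules = reference_rule_set()
        assert len(rules.rules) == 6
        # the hot-branch/low-movement/low-temperature path predicts grade A
        wanted = Rule((Condition(ES, ">", 65.0), Condition(AM, "<=", 40.0),
                       Condition(HT, "<=", 50.0)), "A")
        assert wanted in rules.rules

    def test_rule_count_equals_leaf_count(self):
        table = gen_chain_dataset(ChainScenario(n_chains=400, label_noise=0.1, seed=2))
        tree = fit_cart(table, "meat_quality", FEATURES, CartParams(max_depth=4))
        assert len(extract_rules(tree).rules) == tree.n_leaves()

    def test_rule_prediction_equals_tree_traversal(self):
        rng = np.random.default_rng(14)
        for seed in range(3):
            table = gen_chain_dataset(ChainScenario(n_chains=300,
                                                    label_noise=0.2, seed=seed))
            tree = fit_cart(table, "meat_quality", FEATURES, CartParams(max_depth=5))
            rules = extract_rules(tree)
            for _ in range(300):
                v = dict(zip(FEATURES, rng.uniform(0, 100, 5)))
                assert predict(rules, v) == tree.predict_row(v)

    def test_round_trip_through_json(self):
        rules = reference_rule_set()
        back = RuleSet.from_json(rules.to_json())
        assert back == rules


class TestPredict:
    def test_use_case_vector_graded_a_through_the_hot_calm_cool_rule(self):
        rules = reference_rule_set()
        assert predict(rules, USE_CASE_KPIS) == "A"
        options = recommend(rules, USE_CASE_KPIS, "A")
        assert len(options) == 1 and options[0][1] == ()  # the full rule is satisfied

    def test_cool_but_cold_transport_graded_b(self):
        rules = reference_rule_set()
        assert predict(rules, {ES: 60.0, LT: 40.0}) == "B"

    def test_exactly_one_rule_matches_any_complete_vector(self):
        rules = reference_rule_set()
        rng = np.random.default_rng(27)
        for _ in range(1000):
            v = dict(zip(FEATURES, rng.uniform(0, 100, 5)))
            matching = [r for r in rules.rules
                        if all(c.holds(v[c.feature]) for c in r.conditions)]
            assert len(matching) == 1

    def test_missing_disambiguating_feature_reported(self):
        rules = reference_rule_set()
        with pytest.raises(MissingFeatureError) as exc:
            predict(rules, {ES: 68.30})
        assert AM in exc.value.features


class TestRecommend:
    def test_hot_breeding_leaves_two_paths_to_grade_a(self):
        rules = reference_rule_set()
        options = recommend(rules, {ES: 68.30}, "A")
        assert len(options) == 2
        residuals = {tuple(str(c) for c in residual) for _, residual in options}
        assert (f"{AM} <= 40", f"{HT} <= 50") in residuals
        assert (f"{AM} > 40", f"{HH} <= 20") in residuals

    def test_absent_class_rejected(self):
        with pytest.raises(InvalidInputError):
            recommend(reference_rule_set(), {ES: 68.30}, "Z")

    def test_unreachable_desired_class_gives_empty_list(self):
        rules = reference_rule_set()
        # cool breeding and cold transport force grade B
        assert recommend(rules, {ES: 60.0, LT: 40.0}, "A") == []

    def test_residuals_are_simplified_per_feature(self):
        rules = RuleSet((Rule((Condition("x", ">", 10.0), Condition("x", ">", 20.0),
                               Condition("x", "<=", 50.0)), "A"),
                         Rule((Condition("x", "<=", 10.0),), "B")), target="y")
        options = recommend(rules, {}, "A")
        (_, residual), = options
        assert residual == (Condition("x", ">", 20.0), Condition("x", "<=", 50.0))


class TestCrossCheckWithSklearn:
    def test_depth_limited_accuracy_matches_reference_learner(self):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        table = gen_chain_dataset(ChainScenario(n_chains=1000, label_noise=0.05,
                                                seed=11))
        X = table[FEATURES].to_numpy()
        y = table["meat_quality"].to_numpy()
        ours = fit_cart(table, "meat_quality", FEATURES, CartParams(max_depth=4))
        ref = sklearn_tree.DecisionTreeClassifier(max_depth=4, random_state=0).fit(X, y)
        acc_ours = np.mean(ours.predict(table[FEATURES]) == y)
        acc_ref = ref.score(X, y)
        assert abs(acc_ours - acc_ref) < 0.02

    def test_root_split_agrees_with_reference_learner(self):
        sklearn_tree = pytest.importorskip("sklearn.tree")
        table = gen_chain_dataset(ChainScenario(n_chains=800, seed=21))
        ours = fit_cart(table, "meat_quality", FEATURES, CartParams(max_depth=1))
        ref = sklearn_tree.DecisionTreeClassifier(max_depth=1, random_state=0).fit(
            table[FEATURES].to_numpy(), table["meat_quality"].to_numpy())
        (feat, thr), = ours.thresholds()
        assert FEATURES[ref.tree_.feature[0]] == feat
        assert thr == pytest.approx(ref.tree_.threshold[0], abs=1e-6)
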