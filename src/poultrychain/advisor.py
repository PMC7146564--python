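"""Decision support over historical chain KPIs: CART, DNF rules, advice.

A chain manager accumulates one row of KPIs per completed production
chain.  To turn that history into actionable advice this module:

1. fits a binary classification tree (CART: greedy recursive
   partitioning minimising Gini impurity, with midpoint split
   candidates) to predict a target KPI — by default the slaughterhouse
   meat-quality grade — from any subset of the other KPIs;
2. flattens the tree into its disjunctive normal form: one IF-THEN rule
   per leaf, the conjunction of the threshold conditions on the
   root-to-leaf path.  The rules partition the feature space, so exactly
   one rule fires for any complete feature vector;
3. answers "what must I still control to reach grade A?" by filtering
   the rules against the KPIs already fixed and returning, per surviving
   rule, the simplified residual constraints on the free KPIs.

The tree learner is implemented here rather than delegated so that node
internals (thresholds, class counts, paths) stay fully inspectable for
rule extraction; an off-the-shelf learner is used only as a cross-check
in the test suite.  Determinism: among equal-quality splits the
lexicographically smallest feature name wins, then the smallest
threshold; a mixed leaf predicts its majority class with ties going to
the lexicographically first label.

Regression targets are supported through variance-reduction splitting,
but DNF rules are extracted for classification trees only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError, MissingFeatureError


@dataclass(frozen=True)
class CartParams:
    max_depth: int | None = None
    min_leaf: int = 1
    min_impurity_decrease: float = 0.0

    def __post_init__(self):
        if self.max_depth is not None and self.max_depth < 0:
            raise ConfigurationError("max_depth must be >= 0")
        if self.min_leaf < 1:
            raise ConfigurationError("min_leaf must be >= 1")
        if self.min_impurity_decrease < 0:
            raise ConfigurationError("min_impurity_decrease must be >= 0")


@dataclass
class Node:
    """A tree node: internal (feature, threshold, children) or leaf.

    Left child holds rows with ``feature <= threshold``, right child rows
    with ``feature > threshold``.
    """

    n: int
    prediction: object
    class_counts: dict | None = None      # classification only
    feature: str | None = None
    threshold: float | None = None
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class DecisionTree:
    root: Node
    features: tuple
    target: str
    task: str                      # "classification" | "regression"
    classes: tuple = ()

    def predict_row(self, row: Mapping) -> object:
        node = self.root
        while not node.is_leaf:
            if node.feature not in row or pd.isna(row[node.feature]):
                raise MissingFeatureError([node.feature])
            node = node.left if row[node.feature] <= node.threshold else node.right
        return node.prediction

    def predict(self, table: pd.DataFrame):
        return np.array([self.predict_row(row) for _, row in table.iterrows()])

    def depth(self) -> int:
        def d(node):
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))
        return d(self.root)

    def n_leaves(self) -> int:
        def c(node):
            return 1 if node.is_leaf else c(node.left) + c(node.right)
        return c(self.root)

    def thresholds(self) -> list:
        """(feature, threshold) pairs of all internal nodes, preorder."""
        out = []
        def walk(node):
            if not node.is_leaf:
                out.append((node.feature, node.threshold))
                walk(node.left)
                walk(node.right)
        walk(self.root)
        return out


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split_classification(x: np.ndarray, y_codes: np.ndarray, n_classes: int,
                               min_leaf: int):
    """Best (threshold, children impurity) for one feature, or None.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values; impurity is the weighted Gini of the two children.
    """
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y_codes[order]
    n = len(xs)
    left = np.zeros(n_classes)
    total = np.bincount(ys, minlength=n_classes).astype(float)
    best = None
    for i in range(n - 1):
        left[ys[i]] += 1
        if xs[i + 1] <= xs[i]:           # not a boundary between distinct values
            continue
        n_left = i + 1
        n_right = n - n_left
        if n_left < min_leaf or n_right < min_leaf:
            continue
        child_imp = (n_left * _gini(left) + n_right * _gini(total - left)) / n
        thr = (xs[i] + xs[i + 1]) / 2.0
        if best is None or child_imp < best[1] - 1e-12 or (
                abs(child_imp - best[1]) <= 1e-12 and thr < best[0]):
            best = (thr, child_imp)
    return best


def _best_split_regression(x: np.ndarray, y: np.ndarray, min_leaf: int):
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = len(xs)
    csum = np.cumsum(ys)
    csq = np.cumsum(ys ** 2)
    best = None
    for i in range(n - 1):
        if xs[i + 1] <= xs[i]:
            continue
        n_left = i + 1
        n_right = n - n_left
        if n_left < min_leaf or n_right < min_leaf:
            continue
        sse_l = csq[i] - csum[i] ** 2 / n_left
        sum_r = csum[-1] - csum[i]
        sse_r = (csq[-1] - csq[i]) - sum_r ** 2 / n_right
        child_imp = (sse_l + sse_r) / n   # mean squared error as impurity
        thr = (xs[i] + xs[i + 1]) / 2.0
        if best is None or child_imp < best[1] - 1e-12 or (
                abs(child_imp - best[1]) <= 1e-12 and thr < best[0]):
            best = (thr, child_imp)
    return best


def fit_cart(table: pd.DataFrame, target: str, features, params: CartParams | None = None,
             ) -> DecisionTree:
    """Grow a CART over ``features`` predicting ``target``.

    Classification (categorical/string target) minimises Gini impurity;
    numeric targets are fitted by variance reduction.  Growth stops at
    purity, ``max_depth``, ``min_leaf`` or when the best split's impurity
    decrease falls below ``min_impurity_decrease``.
    """
    params = params or CartParams()
    features = sorted(features)
    if not features:
        raise ConfigurationError("empty feature set")
    for f in features + [target]:
        if f not in table.columns:
            raise ConfigurationError(f"column {f!r} not in table")
    X = table[features]
    if not all(np.issubdtype(X[f].dtype, np.number) for f in features):
        raise InvalidInputError("feature columns must be numeric")
    y = table[target]
    task = "regression" if np.issubdtype(y.dtype, np.number) else "classification"

    if task == "classification":
        classes = tuple(sorted(map(str, pd.unique(y))))
        codes = np.array([classes.index(str(v)) for v in y])

        def leaf(idx):
            counts = np.bincount(codes[idx], minlength=len(classes))
            best = counts.max()
            pred = classes[int(np.flatnonzero(counts == best)[0])]  # tie: first label
            return Node(n=len(idx), prediction=pred,
                        class_counts={c: int(k) for c, k in zip(classes, counts)})

        def impurity(idx):
            return _gini(np.bincount(codes[idx], minlength=len(classes)).astype(float))

        def best_split(idx, f):
            return _best_split_classification(
                X[f].to_numpy(float)[idx], codes[idx], len(classes), params.min_leaf)
    else:
        classes = ()
        yv = y.to_numpy(float)

        def leaf(idx):
            return Node(n=len(idx), prediction=float(np.mean(yv[idx])))

        def impurity(idx):
            return float(np.var(yv[idx]))

        def best_split(idx, f):
            return _best_split_regression(X[f].to_numpy(float)[idx], yv[idx], params.min_leaf)

    def grow(idx: np.ndarray, depth: int) -> Node:
        node_imp = impurity(idx)
        if (node_imp <= 1e-12 or len(idx) < 2 * params.min_leaf
                or (params.max_depth is not None and depth >= params.max_depth)):
            return leaf(idx)
        best = None  # (feature, threshold, child impurity)
        for f in features:          # features pre-sorted: lexicographic tie-break
            split = best_split(idx, f)
            if split is None:
                continue
            thr, child_imp = split
            if best is None or child_imp < best[2] - 1e-12:
                best = (f, thr, child_imp)
        if best is None or node_imp - best[2] < params.min_impurity_decrease - 1e-12:
            return leaf(idx)
        f, thr, _ = best
        mask = X[f].to_numpy(float)[idx] <= thr
        node = leaf(idx)
        node.feature, node.threshold = f, thr
        node.left = grow(idx[mask], depth + 1)
        node.right = grow(idx[~mask], depth + 1)
        return node

    if task == "classification" and len(classes) == 1:
        root = leaf(np.arange(len(table)))
    else:
        root = grow(np.arange(len(table)), 0)
    return DecisionTree(root=root, features=tuple(features), target=target,
                        task=task, classes=classes)


# ---------------------------------------------------------------------------
# DNF rules

@dataclass(frozen=True)
class Condition:
    """An atomic threshold condition: ``feature <= threshold`` or ``feature > threshold``."""

    feature: str
    op: str          # "<=" or ">"
    threshold: float

    def __post_init__(self):
        if self.op not in ("<=", ">"):
            raise InvalidInputError(f"bad operator {self.op!r}")

    def holds(self, value: float) -> bool:
        return value <= self.threshold if self.op == "<=" else value > self.threshold

    def __str__(self):
        return f"{self.feature} {self.op} {self.threshold:g}"


@dataclass(frozen=True)
class Rule:
    """A conjunction of conditions predicting a class (one root-to-leaf path)."""

    conditions: tuple
    klass: str

    def features(self) -> set:
        return {c.feature for c in self.conditions}

    def __str__(self):
        if not self.conditions:
            return f"TRUE -> {self.klass}"
        body = " AND ".join(str(c) for c in self.conditions)
        return f"{body} -> {self.klass}"


@dataclass(frozen=True)
class RuleSet:
    """The DNF of a classification tree: mutually exclusive, exhaustive rules."""

    rules: tuple
    target: str = "meat_quality"

    def classes(self) -> tuple:
        return tuple(sorted({r.klass for r in self.rules}))

    def to_text(self) -> str:
        lines = [f"Rule ({i}): {r}" for i, r in enumerate(self.rules, start=1)]
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps({
            "target": self.target,
            "rules": [{"conditions": [[c.feature, c.op, c.threshold] for c in r.conditions],
                       "class": r.klass} for r in self.rules],
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RuleSet":
        doc = json.loads(text)
        rules = tuple(
            Rule(tuple(Condition(f, op, float(t)) for f, op, t in r["conditions"]), r["class"])
            for r in doc["rules"])
        return cls(rules, target=doc.get("target", "meat_quality"))


def extract_rules(tree: DecisionTree) -> RuleSet:
    """One rule per leaf: the conjunction of edge conditions on its path."""
    if tree.task != "classification":
        raise ConfigurationError("DNF rules are extracted from classification trees only")
    rules = []

    def walk(node: Node, path: tuple):
        if node.is_leaf:
            rules.append(Rule(path, str(node.prediction)))
            return
        walk(node.left, path + (Condition(node.feature, "<=", node.threshold),))
        walk(node.right, path + (Condition(node.feature, ">", node.threshold),))

    walk(tree.root, ())
    return RuleSet(tuple(rules), target=tree.target)


def predict(rules: RuleSet, kpis: Mapping) -> str:
    """Class of the single rule matching a complete KPI vector.

    Rules partition the feature space, so exactly one matches when every
    needed feature is present; otherwise the missing features blocking the
    decision are reported.
    """
    missing: set = set()
    matches = []
    for rule in rules.rules:
        undecidable = False
        ok = True
        for cond in rule.conditions:
            if cond.feature not in kpis or pd.isna(kpis[cond.feature]):
                undecidable = True
                missing.add(cond.feature)
                continue
            if not cond.holds(float(kpis[cond.feature])):
                ok = False
                break
        if ok and not undecidable:
            matches.append(rule)
    if len(matches) == 1:
        return matches[0].klass
    if not matches and missing:
        raise MissingFeatureError(missing)
    raise InvalidInputError(f"{len(matches)} rules matched; rule set is not a partition")


def _simplify(conditions) -> tuple:
    """Merge conditions per feature: tightest upper bound, tightest lower bound."""
    upper: dict = {}
    lower: dict = {}
    order = []
    for c in conditions:
        if c.feature not in order:
            order.append(c.feature)
        if c.op == "<=":
            if c.feature not in upper or c.threshold < upper[c.feature]:
                upper[c.feature] = c.threshold
        else:
            if c.feature not in lower or c.threshold > lower[c.feature]:
                lower[c.feature] = c.threshold
    out = []
    for f in order:
        if f in lower:
            out.append(Condition(f, ">", lower[f]))
        if f in upper:
            out.append(Condition(f, "<=", upper[f]))
    return tuple(out)


def recommend(rules: RuleSet, fixed: Mapping, desired: str):
    """Rules that can still reach ``desired`` given the KPIs already fixed.

    A rule survives when its conditions on fixed features all hold and it
    predicts the desired class; it is returned together with the
    simplified residual constraints on the free features.  An empty list
    means the desired outcome is unreachable from the fixed values.
    """
    if desired not in rules.classes():
        raise InvalidInputError(
            f"desired class {desired!r} absent from rule set classes {rules.classes()}")
    out = []
    for rule in rules.rules:
        if rule.klass != desired:
            continue
        residual = []
        satisfied = True
        for cond in rule.conditions:
            if cond.feature in fixed and not pd.isna(fixed[cond.feature]):
                if not cond.holds(float(fixed[cond.feature])):
                    satisfied = False
                    break
            else:
                residual.append(cond)
        if satisfied:
            out.append((rule, _simplify(residual)))
    return out


# ---------------------------------------------------------------------------
# the published reference rule structure

#: canonical feature names for the cross-phase advisor demonstration
ES, AM, HH, HT, LT = ("emergency_situation", "abrupt_movements",
                      "high_relative_humidity", "high_temperature",
                      "low_temperature")


def reference_tree(thresholds: Mapping | None = None) -> DecisionTree:
    """The six-leaf demonstration tree over five chain KPIs.

    Splits: emergency_situation at 65, then abrupt_movements at 40 with
    high_relative_humidity at 20 / high_temperature at 50 below it on the
    hot branch, and low_temperature at 35 on the cool branch.  Leaves with
    the larger stressor predict grade B, the rest grade A.
    """
    t = {ES: 65.0, AM: 40.0, HH: 20.0, HT: 50.0, LT: 35.0}
    if thresholds:
        t.update(thresholds)

    def leaf(pred):
        return Node(n=0, prediction=pred, class_counts={pred: 0})

    root = Node(
        n=0, prediction="A", feature=ES, threshold=t[ES],
        left=Node(n=0, prediction="A", feature=LT, threshold=t[LT],
                  left=leaf("A"), right=leaf("B")),
        right=Node(
            n=0, prediction="A", feature=AM, threshold=t[AM],
            left=Node(n=0, prediction="A", feature=HT, threshold=t[HT],
                      left=leaf("A"), right=leaf("B")),
            right=Node(n=0, prediction="A", feature=HH, threshold=t[HH],
                       left=leaf("A"), right=leaf("B"))),
    )
    return DecisionTree(root=root, features=(AM, ES, HH, HT, LT),
                        target="meat_quality", task="classification", classes=("A", "B"))


def reference_rule_set(thresholds: Mapping | None = None) -> RuleSet:
    """DNF of :func:`reference_tree`: six mutually exclusive grade rules."""
    return extract_rules(reference_tree(thresholds))
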