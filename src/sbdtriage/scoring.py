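"""Blood Risk Score and the FIT + age + blood-score risk-assessment tool.

The Blood Risk Score (BRS) counts abnormal results among four routine blood
tests, each in its clinically scored direction only: high triglycerides
(> 1.5 mmol/L), high glucose (> 7.8 mmol/L), low magnesium (< 0.7 mmol/L)
and low creatinine (< 64 umol/L) — one point each, to a maximum of four.

The risk-assessment tool (RAT) combines FIT positivity, the age category
(>= 65) and the BRS into a binary high-risk flag.  Two interchangeable modes
are provided:

* ``tree`` — CART-style binary recursive partitioning over the three ordinal
  features, split by Gini impurity decrease, fully deterministic (ties broken
  by feature order, then by the lowest split point);
* ``fixed_rule`` — a configurable boolean expression over the same features,
  defaulting to ``fit_positive and (age_older or brs >= 2)``, a FIT-gated
  rule chosen for its rule-in (high specificity) character.

A record missing a feature at prediction time is returned as low-risk with
an audit flag rather than guessed at: absence of evidence must not trigger
urgent triage.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .cohort import (
    AgeCategory,
    OrdinalCategory,
    PatientRecord,
    ReferenceRange,
    categorize_age,
    categorize_value,
    default_reference_ranges,
)

__all__ = [
    "BloodRiskScore",
    "RatModelSpec",
    "RatPrediction",
    "RatModel",
    "TreeNode",
    "DEFAULT_RULE",
    "compute_brs",
    "induce_tree",
    "fit_rat",
    "predict_rat",
    "format_tree",
]

#: Maximum number of points the Blood Risk Score can accumulate.
BRS_MAX = 4

#: Default fixed decision rule; a calibration choice, fully configurable.
DEFAULT_RULE = "fit_positive and (age_older or brs >= 2)"


@dataclass(frozen=True)
class BloodRiskScore:
    """Integer 0-4 count of abnormal blood tests in their scored direction."""

    score: int
    contributing_markers: frozenset[str]
    missing_markers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.score != len(self.contributing_markers):
            raise ValueError("score must equal the number of contributing markers")
        if self.score > BRS_MAX:
            raise ValueError(f"score exceeds the {BRS_MAX}-point cap")


def _is_scored_abnormal(value: float | None, rng: ReferenceRange) -> bool | None:
    """True iff the value falls in the marker's scored-abnormal direction."""
    cat = categorize_value(value, rng)
    if cat is None:
        return None
    if rng.abnormal_direction == "high":
        return cat is OrdinalCategory.HIGH
    if rng.abnormal_direction == "low":
        return cat is OrdinalCategory.LOW
    return cat is not OrdinalCategory.NORMAL


def compute_brs(
    record: PatientRecord,
    markers: Mapping[str, ReferenceRange] | Iterable[ReferenceRange] | None = None,
) -> BloodRiskScore:
    """Blood Risk Score for one patient.

    ``markers`` selects the scored panel (default: the four shipped
    reference ranges).  Each marker whose value lies in its scored-abnormal
    direction adds one point, capped at four; abnormality in the opposite
    direction contributes nothing.  Missing markers contribute zero and are
    reported in ``missing_markers``.
    """
    if markers is None:
        ranges = list(default_reference_ranges().values())
    elif isinstance(markers, Mapping):
        ranges = list(markers.values())
    else:
        ranges = list(markers)
    contributing: list[str] = []
    missing: list[str] = []
    for rng in ranges:
        flag = _is_scored_abnormal(record.marker_value(rng.marker_name), rng)
        if flag is None:
            missing.append(rng.marker_name)
        elif flag:
            contributing.append(f"{rng.marker_name}_{rng.abnormal_direction}")
    contributing = contributing[:BRS_MAX]  # cap binds only on panels wider than four
    return BloodRiskScore(
        score=len(contributing),
        contributing_markers=frozenset(contributing),
        missing_markers=frozenset(missing),
    )


# ---------------------------------------------------------------------------
# Model specification and feature extraction

#: Ordinal encoding bounds per RAT feature (inclusive).
_FEATURE_LEVELS: dict[str, tuple[int, int]] = {
    "fit_positive": (0, 1),
    "age_older": (0, 1),
    "calprotectin_high": (0, 1),
    "brs": (0, BRS_MAX),
}


@dataclass(frozen=True)
class RatModelSpec:
    """Configuration of the risk-assessment tool.

    ``features`` is an ordered list; the order is the tie-break for equal
    Gini gains in tree mode.  ``fixed_rule`` is a boolean expression over the
    feature names (operators and/or/not, comparisons on ``brs``).
    """

    mode: str = "tree"
    features: tuple[str, ...] = ("fit_positive", "age_older", "brs")
    max_depth: int = 3
    min_leaf: int = 10
    fixed_rule: str = DEFAULT_RULE

    def __post_init__(self) -> None:
        if self.mode not in ("tree", "fixed_rule"):
            raise ValueError(f"mode must be 'tree' or 'fixed_rule', got {self.mode!r}")
        if not self.features:
            raise ValueError("feature list must be non-empty")
        unknown = [f for f in self.features if f not in _FEATURE_LEVELS]
        if unknown:
            raise ValueError(f"unknown RAT features: {unknown}")
        if self.max_depth < 0 or self.min_leaf < 1:
            raise ValueError("max_depth must be >= 0 and min_leaf >= 1")


def feature_value(
    record: PatientRecord,
    feature: str,
    markers: Mapping[str, ReferenceRange] | Iterable[ReferenceRange] | None = None,
) -> int | None:
    """Ordinal encoding of one RAT feature; ``None`` when unobserved."""
    if feature in ("fit_positive", "calprotectin_high"):
        v = getattr(record, feature)
        return None if v is None else int(v)
    if feature == "age_older":
        return int(categorize_age(record.age) is AgeCategory.OLDER)
    if feature == "brs":
        return compute_brs(record, markers).score
    raise ValueError(f"unknown RAT feature {feature!r}")


@dataclass(frozen=True)
class RatPrediction:
    """Outcome of applying the RAT to one record."""

    predicted_high_risk: bool
    leaf_path: tuple[str, ...]
    missing_feature: str | None = None


# ---------------------------------------------------------------------------
# CART-style tree induction


@dataclass
class TreeNode:
    """One node of the decision tree.

    Internal nodes route ``feature >= threshold`` to ``right``; leaves carry
    the majority-class ``prediction`` (ties labelled high-risk).
    """

    n_high: int
    n_low: int
    feature: str | None = None
    threshold: int | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    prediction: bool | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _gini(n_pos: int, n_neg: int) -> float:
    n = n_pos + n_neg
    if n == 0:
        return 0.0
    p = n_pos / n
    return 2.0 * p * (1.0 - p)


def _leaf(n_high: int, n_low: int) -> TreeNode:
    return TreeNode(n_high=n_high, n_low=n_low, prediction=n_high >= n_low)


_GAIN_EPS = 1e-12


def _grow(
    X: Sequence[Sequence[int]],
    y: Sequence[bool],
    features: Sequence[str],
    depth: int,
    max_depth: int,
    min_leaf: int,
) -> TreeNode:
    n_high = sum(y)
    n_low = len(y) - n_high
    parent_gini = _gini(n_high, n_low)
    if depth >= max_depth or parent_gini == 0.0 or len(y) < 2 * min_leaf:
        return _leaf(n_high, n_low)
    best: tuple[float, int, int] | None = None  # (gain, feature index, threshold)
    for fi, feat in enumerate(features):
        lo, hi = _FEATURE_LEVELS[feat]
        for t in range(lo + 1, hi + 1):  # "value >= t" splits, lowest first
            left_idx = [i for i in range(len(y)) if X[i][fi] < t]
            right_idx = [i for i in range(len(y)) if X[i][fi] >= t]
            if len(left_idx) < min_leaf or len(right_idx) < min_leaf:
                continue
            lh = sum(y[i] for i in left_idx)
            rh = sum(y[i] for i in right_idx)
            child = (
                len(left_idx) * _gini(lh, len(left_idx) - lh)
                + len(right_idx) * _gini(rh, len(right_idx) - rh)
            ) / len(y)
            gain = parent_gini - child
            if gain > _GAIN_EPS and (best is None or gain > best[0] + _GAIN_EPS):
                best = (gain, fi, t)
    if best is None:
        return _leaf(n_high, n_low)
    _, fi, t = best
    left_rows = [i for i in range(len(y)) if X[i][fi] < t]
    right_rows = [i for i in range(len(y)) if X[i][fi] >= t]
    node = TreeNode(n_high=n_high, n_low=n_low, feature=features[fi], threshold=t)
    node.left = _grow(
        [X[i] for i in left_rows], [y[i] for i in left_rows], features, depth + 1, max_depth, min_leaf
    )
    node.right = _grow(
        [X[i] for i in right_rows], [y[i] for i in right_rows], features, depth + 1, max_depth, min_leaf
    )
    return node


@dataclass(frozen=True)
class RatModel:
    """A fitted (tree) or configured (fixed-rule) risk-assessment tool."""

    spec: RatModelSpec
    root: TreeNode | None = None
    markers: tuple[ReferenceRange, ...] | None = None  # BRS panel used at fit time

    def __post_init__(self) -> None:
        if self.spec.mode == "tree" and self.root is None:
            raise ValueError("tree mode requires a fitted root node")


def induce_tree(
    records: Sequence[PatientRecord],
    spec: RatModelSpec,
    markers: Mapping[str, ReferenceRange] | Iterable[ReferenceRange] | None = None,
    outcomes: Sequence[bool] | None = None,
) -> RatModel:
    """Grow the RAT decision tree on labelled records.

    Outcomes default to SBD classification of each record's histology.
    Records missing the outcome or any model feature are excluded from
    induction.  Induction is deterministic: candidate splits are scanned in
    feature order then ascending split point, and only a strictly larger Gini
    gain displaces the incumbent.
    """
    if spec.mode != "tree":
        raise ValueError("induce_tree requires a spec with mode='tree'")
    if isinstance(markers, Mapping):
        marker_list: tuple[ReferenceRange, ...] | None = tuple(markers.values())
    elif markers is not None:
        marker_list = tuple(markers)
    else:
        marker_list = None
    if outcomes is None:
        from .stats import sbd_outcome  # local import: stats also imports scoring lazily

        outcomes = [sbd_outcome(r) for r in records]
    X, y = [], []
    for r, out in zip(records, outcomes):
        if out is None:
            continue
        row = [feature_value(r, f, marker_list) for f in spec.features]
        if any(v is None for v in row):
            continue
        X.append(row)
        y.append(bool(out))
    if not y:
        raise ValueError("no complete records available for tree induction")
    root = _grow(X, y, spec.features, 0, spec.max_depth, spec.min_leaf)
    return RatModel(spec=spec, root=root, markers=marker_list)


def fit_rat(
    records: Sequence[PatientRecord],
    spec: RatModelSpec,
    markers: Mapping[str, ReferenceRange] | Iterable[ReferenceRange] | None = None,
    outcomes: Sequence[bool] | None = None,
) -> RatModel:
    """Build a RAT in either mode; fixed rules need no training data."""
    if spec.mode == "fixed_rule":
        if isinstance(markers, Mapping):
            marker_list: tuple[ReferenceRange, ...] | None = tuple(markers.values())
        elif markers is not None:
            marker_list = tuple(markers)
        else:
            marker_list = None
        _rule_variables(spec.fixed_rule)  # validate the expression up front
        return RatModel(spec=spec, markers=marker_list)
    return induce_tree(records, spec, markers, outcomes)


# ---------------------------------------------------------------------------
# Prediction

_ALLOWED_RULE_NODES = (
    ast.Expression,
    ast.BoolOp,
    ast.And,
    ast.Or,
    ast.UnaryOp,
    ast.Not,
    ast.Compare,
    ast.Name,
    ast.Load,
    ast.Constant,
    ast.Eq,
    ast.NotEq,
    ast.Lt,
    ast.LtE,
    ast.Gt,
    ast.GtE,
)


def _parse_rule(rule: str) -> ast.Expression:
    # accept uppercase boolean connectives from config files
    text = rule.replace(" AND ", " and ").replace(" OR ", " or ").replace(" NOT ", " not ")
    try:
        tree = ast.parse(text, mode="eval")
    except SyntaxError as exc:
        raise ValueError(f"invalid fixed rule {rule!r}: {exc}") from exc
    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_RULE_NODES):
            raise ValueError(
                f"invalid fixed rule {rule!r}: disallowed construct {type(node).__name__}"
            )
    return tree


def _rule_variables(rule: str) -> list[str]:
    tree = _parse_rule(rule)
    names = sorted({n.id for n in ast.walk(tree) if isinstance(n, ast.Name)})
    unknown = [n for n in names if n not in _FEATURE_LEVELS]
    if unknown:
        raise ValueError(f"fixed rule references unknown features: {unknown}")
    return names


def predict_rat(model: RatModel, record: PatientRecord) -> RatPrediction:
    """Apply the RAT to one record.

    Deterministic traversal of the tree (or evaluation of the fixed rule);
    ``leaf_path`` records each comparison taken.  A record missing a needed
    feature is flagged and returned low-risk.
    """
    if model.spec.mode == "fixed_rule":
        names = _rule_variables(model.spec.fixed_rule)
        env: dict[str, int] = {}
        for name in names:
            v = feature_value(record, name, model.markers)
            if v is None:
                return RatPrediction(
                    predicted_high_risk=False,
                    leaf_path=(f"missing {name} -> low_risk",),
                    missing_feature=name,
                )
            env[name] = v
        verdict = bool(
            eval(compile(_parse_rule(model.spec.fixed_rule), "<rule>", "eval"), {"__builtins__": {}}, env)
        )
        return RatPrediction(
            predicted_high_risk=verdict,
            leaf_path=(f"rule({model.spec.fixed_rule}) = {verdict}",),
        )
    node = model.root
    assert node is not None
    path: list[str] = []
    while not node.is_leaf:
        v = feature_value(record, node.feature, model.markers)
        if v is None:
            return RatPrediction(
                predicted_high_risk=False,
                leaf_path=(*path, f"missing {node.feature} -> low_risk"),
                missing_feature=node.feature,
            )
        if v >= node.threshold:
            path.append(f"{node.feature} >= {node.threshold}")
            node = node.right
        else:
            path.append(f"{node.feature} < {node.threshold}")
            node = node.left
    label = "high_risk" if node.prediction else "low_risk"
    path.append(f"leaf: {label} ({node.n_high}/{node.n_high + node.n_low} SBD)")
    return RatPrediction(predicted_high_risk=bool(node.prediction), leaf_path=tuple(path))


def format_tree(model: RatModel) -> str:
    """Human-readable indented rendering of a fitted tree."""
    if model.spec.mode == "fixed_rule":
        return f"rule: {model.spec.fixed_rule}"
    lines: list[str] = []

    def walk(node: TreeNode, indent: int, prefix: str) -> None:
        pad = "  " * indent
        if node.is_leaf:
            label = "high_risk" if node.prediction else "low_risk"
            lines.append(f"{pad}{prefix}leaf {label} [{node.n_high} SBD / {node.n_low} non-SBD]")
        else:
            lines.append(
                f"{pad}{prefix}split {node.feature} >= {node.threshold} "
                f"[{node.n_high} SBD / {node.n_low} non-SBD]"
            )
            walk(node.left, indent + 1, "no:  ")
            walk(node.right, indent + 1, "yes: ")

    walk(model.root, 0, "")
    return "\n".join(lines)
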