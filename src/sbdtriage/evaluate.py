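"""Cross-validated evaluation of the risk-assessment tool.

Leave-one-out cross-validation (LOOCV) repeats, for every patient: remove
the patient, re-screen the blood markers on the remainder (FDR-corrected
odds-ratio tests), rebuild the in-fold Blood Risk Score from the markers that
survive screening, re-grow the decision tree, and predict the held-out
patient.  The n held-out predictions against confirmed significant bowel
disease (SBD) form a confusion matrix from which sensitivity, specificity,
predictive values and the odds ratio (with Woolf CI) are derived.

The comparator arm is the hospital's symptoms-based triage, dichotomized into
high risk (category 1) versus low risk (categories 2/3); records missing the
triage category are excluded from the comparator arm only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import PatientRecord, ReferenceRange, default_reference_ranges
from .errors import MissingDataError, UndefinedOddsRatioError
from .scoring import RatModelSpec, RatModel, compute_brs, fit_rat, induce_tree, predict_rat
from .stats import (
    ContingencyTable2x2,
    mass_univariate_screen,
    odds_ratio,
    sbd_outcome,
    woolf_ci,
)

__all__ = [
    "ConfusionMatrix",
    "MetricsFragment",
    "EvaluationReport",
    "BrsStrata",
    "metrics_from_counts",
    "loocv_evaluate",
    "brs_stratum_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Predicted high-risk vs confirmed SBD counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_table(self) -> ContingencyTable2x2:
        """Exposure = predicted high risk; disease = confirmed SBD."""
        return ContingencyTable2x2(self.tp, self.fp, self.fn, self.tn)


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


@dataclass(frozen=True)
class MetricsFragment:
    """Operating characteristics of one confusion matrix.

    Proportions with a zero denominator are reported as ``None`` (missing),
    never coerced to 0.
    """

    confusion: ConfusionMatrix
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    odds_ratio: float | None
    ci: tuple[float, float] | None


def metrics_from_counts(cm: ConfusionMatrix, z: float = 1.96) -> MetricsFragment:
    """Sensitivity, specificity, PPV, NPV, odds ratio and Woolf CI.

    An odds ratio undefined because a margin is empty (e.g. a constant
    predictor) is reported as missing, like any zero-denominator proportion.
    """
    t = cm.as_table()
    try:
        or_, ci = odds_ratio(t), woolf_ci(t, z=z)
    except UndefinedOddsRatioError:
        or_, ci = None, None
    return MetricsFragment(
        confusion=cm,
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        odds_ratio=or_,
        ci=ci,
    )


@dataclass(frozen=True)
class EvaluationReport:
    """LOOCV result with the symptoms-based triage comparator."""

    rat: MetricsFragment
    comparator: MetricsFragment | None
    n_records: int
    n_evaluated: int
    n_comparator: int
    n_folds_without_markers: int = 0
    #: held-out prediction per evaluated patient_id (one entry per fold)
    predictions: Mapping[str, bool] = field(default_factory=dict)


def _usable_outcome(record: PatientRecord) -> bool | None:
    try:
        return sbd_outcome(record)
    except MissingDataError:
        return None


def _select_panel(
    train: Sequence[PatientRecord],
    eligible: Sequence[ReferenceRange],
    alpha: float,
    p_method: str,
) -> list[ReferenceRange]:
    """Blood markers whose scored-direction level survives FDR screening."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sparse folds may skip single-level markers
        results = mass_univariate_screen(
            train,
            eligible,
            alpha,
            include_binary=False,
            include_symptoms=False,
            include_age=False,
            p_method=p_method,
        )
    selected = []
    for rng in eligible:
        hit = next(
            (
                r
                for r in results
                if r.significant
                and r.marker_name == rng.marker_name
                and (rng.abnormal_direction in ("either", r.level_tested))
            ),
            None,
        )
        if hit is not None:
            selected.append(rng)
    return selected


def loocv_evaluate(
    records: Sequence[PatientRecord],
    spec: RatModelSpec,
    alpha: float = 0.05,
    markers: Mapping[str, ReferenceRange] | Iterable[ReferenceRange] | None = None,
    *,
    p_method: str = "fisher",
    z: float = 1.96,
) -> EvaluationReport:
    """Leave-one-out evaluation of the RAT with in-fold feature selection.

    ``markers`` is the panel of blood markers eligible for the in-fold Blood
    Risk Score (default: the four shipped reference ranges).  In tree mode,
    each fold re-screens the panel on the training remainder and re-grows the
    tree; a fold in which no marker survives screening falls back to FIT and
    age alone (counted in ``n_folds_without_markers``).  Fixed-rule mode has
    nothing to train, so LOOCV reduces to direct application of the rule.
    Records without histology are excluded from evaluation; records missing
    the triage category are excluded from the comparator arm only.
    """
    if isinstance(markers, Mapping):
        eligible = list(markers.values())
    elif markers is not None:
        eligible = list(markers)
    else:
        eligible = list(default_reference_ranges().values())

    outcomes = [_usable_outcome(r) for r in records]
    idx = [i for i, o in enumerate(outcomes) if o is not None]
    predictions: dict[int, bool] = {}
    n_bare_folds = 0

    if spec.mode == "fixed_rule":
        model = fit_rat([], spec, eligible)
        for i in idx:
            predictions[i] = predict_rat(model, records[i]).predicted_high_risk
    else:
        base_features = spec.features
        for i in idx:
            train = [records[j] for j in idx if j != i]
            train_out = [outcomes[j] for j in idx if j != i]
            panel = _select_panel(train, eligible, alpha, p_method) if "brs" in base_features else []
            if "brs" in base_features and not panel:
                n_bare_folds += 1
                fold_features = tuple(f for f in base_features if f != "brs")
                if not fold_features:
                    fold_features = ("fit_positive", "age_older")
                logger.info("fold %d: no blood marker survived screening; using %s",
                            i, fold_features)
                fold_spec = RatModelSpec(
                    mode="tree",
                    features=fold_features,
                    max_depth=spec.max_depth,
                    min_leaf=spec.min_leaf,
                )
                model = induce_tree(train, fold_spec, None, train_out)
            else:
                model = induce_tree(train, spec, panel or None, train_out)
            predictions[i] = predict_rat(model, records[i]).predicted_high_risk

    tp = fp = fn = tn = 0
    for i in idx:
        pred, truth = predictions[i], outcomes[i]
        if pred and truth:
            tp += 1
        elif pred:
            fp += 1
        elif truth:
            fn += 1
        else:
            tn += 1
    rat_metrics = metrics_from_counts(ConfusionMatrix(tp, fp, fn, tn), z=z)

    ctp = cfp = cfn = ctn = 0
    n_comp = 0
    for i in idx:
        cat = records[i].triage_category
        if cat is None:
            continue
        n_comp += 1
        urgent, truth = cat == 1, outcomes[i]
        if urgent and truth:
            ctp += 1
        elif urgent:
            cfp += 1
        elif truth:
            cfn += 1
        else:
            ctn += 1
    comparator = None
    if n_comp:
        comparator = metrics_from_counts(ConfusionMatrix(ctp, cfp, cfn, ctn), z=z)

    return EvaluationReport(
        rat=rat_metrics,
        comparator=comparator,
        n_records=len(records),
        n_evaluated=len(idx),
        n_comparator=n_comp,
        n_folds_without_markers=n_bare_folds,
        predictions={records[i].patient_id: predictions[i] for i in idx},
    )


@dataclass(frozen=True)
class BrsStrata:
    """Per-score SBD proportions and the BRS x triage cross-tabulation."""

    by_score: pd.DataFrame  # columns: brs, n, n_sbd, pct_sbd
    by_triage: pd.DataFrame  # index: brs, columns: triage categories, counts


def brs_stratum_table(
    records: Sequence[PatientRecord],
    markers: Mapping[str, ReferenceRange] | Iterable[ReferenceRange] | None = None,
) -> BrsStrata:
    """Tabulate SBD prevalence by Blood Risk Score, and BRS against triage.

    Only records with a classifiable outcome enter the score table; empty
    strata are omitted.  Percentages are unrounded (round at presentation).
    """
    rows = []
    cross = []
    for r in records:
        score = compute_brs(r, markers).score
        out = _usable_outcome(r)
        if out is not None:
            rows.append((score, out))
        if r.triage_category is not None:
            cross.append((score, r.triage_category))
    by_score = (
        pd.DataFrame(rows, columns=["brs", "sbd"])
        .groupby("brs")
        .agg(n=("sbd", "size"), n_sbd=("sbd", "sum"))
        .reset_index()
    )
    by_score["pct_sbd"] = 100.0 * by_score["n_sbd"] / by_score["n"]
    if cross:
        cross_df = pd.DataFrame(cross, columns=["brs", "triage_category"])
        by_triage = pd.crosstab(cross_df["brs"], cross_df["triage_category"])
    else:
        by_triage = pd.DataFrame()
    return BrsStrata(by_score=by_score, by_triage=by_triage)
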