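"""Association statistics for binary clinical markers versus bowel disease.

The unit of analysis is the 2x2 contingency table of an exposure (an abnormal
marker level, a positive stool test, a referral symptom) against confirmed
significant bowel disease (SBD).  Effect size is the odds ratio with a Woolf
(log-normal) confidence interval; zero cells receive the Haldane–Anscombe
+0.5 correction so that perfectly-associated markers stay estimable during
cross-validated screening.  Mass univariate screening tests every marker
level against the normal reading and controls the family-wise false
discovery rate by Benjamini–Hochberg.

A baseline-category multinomial logit (reference: triage category 3, the
least urgent) quantifies how referral features drive the assigned triage
category.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import (
    BLOOD_MARKERS,
    AgeCategory,
    OrdinalCategory,
    PatientRecord,
    ReferenceRange,
    SYMPTOMS,
    categorize_age,
    categorize_value,
    classify_sbd,
)
from .errors import ConvergenceError, MissingDataError, SeparationError, UndefinedOddsRatioError

__all__ = [
    "ContingencyTable2x2",
    "AssociationResult",
    "TriageGlmResult",
    "odds_ratio",
    "woolf_ci",
    "table_p_value",
    "fdr_adjust",
    "mass_univariate_screen",
    "triage_glm",
    "sbd_outcome",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x disease counts: a,b exposed, c,d unexposed; a,c diseased."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v!r}")
        if self.total == 0:
            raise ValueError("contingency table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def margins(self) -> tuple[int, int, int, int]:
        """(exposed, unexposed, diseased, non-diseased) margin totals."""
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def corrected_cells(self) -> tuple[float, float, float, float]:
        """Cells with Haldane–Anscombe +0.5 applied iff any cell is zero."""
        if self.has_zero_cell():
            return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)
        return (float(self.a), float(self.b), float(self.c), float(self.d))


def _check_margins(t: ContingencyTable2x2) -> None:
    if min(t.margins()) == 0:
        raise UndefinedOddsRatioError(
            f"odds ratio undefined: table ({t.a}, {t.b}, {t.c}, {t.d}) has an empty margin"
        )


def odds_ratio(t: ContingencyTable2x2) -> float:
    """Odds ratio (a*d)/(b*c), continuity-corrected when a cell is zero."""
    _check_margins(t)
    a, b, c, d = t.corrected_cells()
    return (a * d) / (b * c)


def woolf_ci(t: ContingencyTable2x2, z: float = 1.96) -> tuple[float, float]:
    """Woolf confidence interval for the odds ratio.

    exp(ln OR +/- z * sqrt(1/a + 1/b + 1/c + 1/d)) on the (continuity
    corrected, if needed) cells; ``z`` is the normal quantile, 1.96 for 95%.
    """
    _check_margins(t)
    a, b, c, d = t.corrected_cells()
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def table_p_value(t: ContingencyTable2x2, method: str = "fisher") -> float:
    """Two-sided association p-value for a 2x2 table.

    ``fisher`` (default) is the exact conditional test; ``chi_square`` is the
    Pearson statistic on 1 df without continuity correction.  A table with an
    empty margin carries no evidence of association and returns 1.0.
    """
    if min(t.margins()) == 0:
        return 1.0
    table = [[t.a, t.b], [t.c, t.d]]
    if method == "fisher":
        return float(scipy.stats.fisher_exact(table, alternative="two-sided")[1])
    if method == "chi_square":
        stat, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
        return float(p)
    raise ValueError(f"unknown p-value method {method!r}")


def fdr_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


@dataclass(frozen=True)
class AssociationResult:
    """One marker-level association against SBD after FDR adjustment."""

    marker_name: str
    level_tested: str  # "high" / "low" for blood markers; "positive"; "present"
    table: ContingencyTable2x2
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    p_adjusted: float
    significant: bool

    @property
    def n_used(self) -> int:
        return self.table.total


def sbd_outcome(record: PatientRecord) -> bool | None:
    """SBD outcome for one record, ``None`` when histology is unavailable."""
    if record.histology is None:
        return None
    return classify_sbd(record.histology)


def _outcomes(records: Sequence[PatientRecord]) -> list[bool | None]:
    out: list[bool | None] = []
    n_incomplete = 0
    for r in records:
        try:
            out.append(sbd_outcome(r))
        except MissingDataError:
            out.append(None)
            n_incomplete += 1
    if n_incomplete:
        warnings.warn(
            f"{n_incomplete} record(s) had incomplete histology and were excluded "
            "from outcome-based analyses",
            stacklevel=3,
        )
    return out


def _build_table(exposed: list[bool], diseased: list[bool]) -> ContingencyTable2x2:
    a = b = c = d = 0
    for e, y in zip(exposed, diseased):
        if e and y:
            a += 1
        elif e:
            b += 1
        elif y:
            c += 1
        else:
            d += 1
    return ContingencyTable2x2(a, b, c, d)


def mass_univariate_screen(
    records: Sequence[PatientRecord],
    markers: Mapping[str, ReferenceRange] | Iterable[ReferenceRange],
    alpha: float = 0.05,
    *,
    include_binary: bool = True,
    include_symptoms: bool = True,
    include_age: bool = True,
    p_method: str = "fisher",
) -> list[AssociationResult]:
    """Screen every marker level against SBD with FDR control.

    For each continuous marker, the high and the low level are tested as two
    separate exposures against the normal reading, entering the same
    Benjamini–Hochberg family; FIT positivity, calprotectin, age >= 65 and
    referral symptoms are tested as binary exposures against the full
    complement.  Records missing a marker (or the outcome) are excluded
    pairwise from that marker's table.  A marker level never observed is
    skipped with a warning.  ``significant`` flags adjusted p < ``alpha``.
    """
    if isinstance(markers, Mapping):
        ranges = list(markers.values())
    else:
        ranges = list(markers)
    outcomes = _outcomes(records)

    # (marker_name, level, exposure values aligned with records; None = missing)
    tests: list[tuple[str, str, list[bool | None]]] = []
    for rng in ranges:
        cats = [
            categorize_value(r.marker_value(rng.marker_name), rng) if o is not None else None
            for r, o in zip(records, outcomes)
        ]
        for level in (OrdinalCategory.HIGH, OrdinalCategory.LOW):
            if level is OrdinalCategory.HIGH and rng.high is None:
                continue
            if level is OrdinalCategory.LOW and rng.low is None:
                continue
            # abnormal level vs normal reading; the other abnormal level excluded
            exposure = [
                None if c is None or c not in (level, OrdinalCategory.NORMAL) else c is level
                for c in cats
            ]
            tests.append((rng.marker_name, level.value, exposure))
    if include_binary:
        for attr in ("fit_positive", "calprotectin_high"):
            tests.append((attr, "positive", [getattr(r, attr) for r in records]))
    if include_age:
        tests.append(
            ("age_older", "positive", [categorize_age(r.age) is AgeCategory.OLDER for r in records])
        )
    if include_symptoms:
        for sym in SYMPTOMS:
            tests.append((sym, "present", [sym in r.symptoms for r in records]))

    kept: list[tuple[str, str, ContingencyTable2x2]] = []
    for name, level, exposure in tests:
        pairs = [
            (e, o) for e, o in zip(exposure, outcomes) if e is not None and o is not None
        ]
        if not pairs:
            warnings.warn(f"marker {name!r} level {level!r}: no usable records; skipped")
            continue
        exp, dis = zip(*pairs)
        if len(set(exp)) < 2:
            warnings.warn(
                f"marker {name!r} level {level!r}: single observed level; skipped"
            )
            continue
        kept.append((name, level, _build_table(list(exp), list(dis))))

    p_raw = [table_p_value(t, method=p_method) for _, _, t in kept]
    p_adj = fdr_adjust(p_raw)
    results = []
    for (name, level, table), p, q in zip(kept, p_raw, p_adj):
        or_ = odds_ratio(table)
        lo, hi = woolf_ci(table)
        results.append(
            AssociationResult(
                marker_name=name,
                level_tested=level,
                table=table,
                odds_ratio=or_,
                ci_low=lo,
                ci_high=hi,
                p_value=p,
                p_adjusted=q,
                significant=q < alpha,
            )
        )
    return results


# ---------------------------------------------------------------------------
# Triage-category generalised linear model


@dataclass(frozen=True)
class TriageGlmResult:
    """Baseline-category logit of triage category (reference: category 3).

    ``contrasts`` maps a contrast label ("1_vs_3", "2_vs_3") to a per-predictor
    mapping of (coefficient, standard error, Wald p-value); the intercept
    appears under ``const``.
    """

    contrasts: dict[str, dict[str, tuple[float, float, float]]]
    n_used: int
    converged: bool = True

    def coefficient(self, contrast: str, predictor: str) -> float:
        return self.contrasts[contrast][predictor][0]


def _predictor_value(record: PatientRecord, name: str) -> float | None:
    if name in ("fit_positive", "calprotectin_high"):
        v = getattr(record, name)
        return None if v is None else float(v)
    if name == "age_older":
        return float(categorize_age(record.age) is AgeCategory.OLDER)
    if name == "age":
        return float(record.age)
    if name == "bmi":
        return record.bmi
    if name == "sex_male":
        return float(record.sex == "male")
    if name in SYMPTOMS:
        return float(name in record.symptoms)
    if name == "brs":
        from .scoring import compute_brs  # local import to avoid a module cycle

        return float(compute_brs(record).score)
    if name in BLOOD_MARKERS:
        return getattr(record, name)
    value = record.extra_markers.get(name)
    if value is not None:
        return value
    raise ValueError(f"unknown predictor {name!r}")


_SEPARATION_COEF = 20.0  # |log-odds| beyond this on a 0/1 predictor implies separation


def triage_glm(
    records: Sequence[PatientRecord],
    predictors: Sequence[str],
    *,
    tol: float = 1e-8,
    maxiter: int = 200,
) -> TriageGlmResult:
    """Fit the triage-category model: multinomial logit, reference category 3.

    Categories 1 and 2 are each contrasted with category 3 (least urgent);
    with only two categories present the model reduces to binary logistic
    regression.  Fitting is Newton–Raphson to gradient tolerance ``tol``;
    standard errors come from the observed information matrix.  Records
    missing the triage category or any predictor are dropped.

    Raises
    ------
    SeparationError
        If a predictor perfectly separates categories (divergent coefficient).
    ConvergenceError
        If Newton–Raphson does not converge within ``maxiter``.
    """
    if not predictors:
        raise ValueError("at least one predictor is required")
    rows, ys = [], []
    for r in records:
        if r.triage_category is None:
            continue
        vals = [_predictor_value(r, p) for p in predictors]
        if any(v is None for v in vals):
            continue
        rows.append(vals)
        ys.append(r.triage_category)
    X = np.asarray(rows, dtype=float)
    y = np.asarray(ys)
    cats = sorted(set(ys))
    if 3 not in cats or len(cats) < 2:
        raise ValueError(
            f"need reference category 3 plus at least one other; observed {cats}"
        )
    # encode so category 3 is level 0 (statsmodels' baseline)
    other = [c for c in cats if c != 3]
    code = {3: 0, **{c: i + 1 for i, c in enumerate(other)}}
    endog = np.array([code[v] for v in ys])
    exog = sm.add_constant(X, has_constant="add")
    names = ["const", *predictors]
    model = sm.MNLogit(endog, exog)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # statsmodels warns en route to our own checks
            fit = model.fit(method="newton", maxiter=maxiter, gtol=tol, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"separation or singular information matrix: {exc}") from exc
    params = np.atleast_2d(fit.params)  # shape (k, J-1)
    bse = np.atleast_2d(fit.bse)
    pvals = np.atleast_2d(fit.pvalues)
    if params.shape[0] != len(names):
        params, bse, pvals = params.T, bse.T, pvals.T
    for j in range(params.shape[1]):
        for i, name in enumerate(names):
            if name != "const" and abs(params[i, j]) > _SEPARATION_COEF:
                raise SeparationError(
                    f"predictor {name!r} separates triage category {other[j]} from 3"
                )
    if not fit.mle_retvals.get("converged", False):
        raise ConvergenceError(f"multinomial logit did not converge in {maxiter} iterations")
    contrasts = {}
    for j, cat in enumerate(other):
        contrasts[f"{cat}_vs_3"] = {
            name: (float(params[i, j]), float(bse[i, j]), float(pvals[i, j]))
            for i, name in enumerate(names)
        }
    return TriageGlmResult(contrasts=contrasts, n_used=len(ys), converged=True)
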