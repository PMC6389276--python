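"""Synthetic GP-referral cohorts with the statistical structure of the study.

The generator emulates a symptomatic colonoscopy-referral population:
~467 patients, 45.1% male, age 54.3 +/- 13.8 years, BMI 27.8 +/- 6.2, a 26%
prevalence of significant bowel disease (SBD), FIT positivity of 16.6% given
SBD versus 6.4% given non-SBD, and referral-symptom frequencies matching the
observed SBD / non-SBD columns.  SBD status is drawn first; every other
variable is drawn conditionally on it, independently across variables
(the study reports only marginal and SBD-conditional frequencies, so no
correlation structure is asserted).  Histology findings are constructed to be
internally consistent: classifying the generated findings always reproduces
the drawn SBD label.

Identical configuration + seed yields a byte-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.stats import truncnorm

from .cohort import (
    AGE_CUTOFF,
    AGE_MAX,
    AGE_MIN,
    HistologyFindings,
    PatientRecord,
    SYMPTOMS,
    classify_sbd,
)

__all__ = ["SimulationConfig", "default_config", "generate_cohort"]

#: Within-category sampling intervals for each blood marker, keyed by marker:
#: (normal interval, scored-abnormal interval).  Intervals sit strictly inside
#: the normal range / strictly beyond the scored bound so the drawn value's
#: category always matches the drawn abnormal flag.
_MARKER_INTERVALS: dict[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "triglycerides": ((0.6, 1.5), (1.51, 4.5)),
    "glucose": ((3.5, 7.8), (7.81, 15.0)),
    "magnesium": ((0.7, 1.1), (0.40, 0.69)),
    "creatinine": ((64.0, 108.0), (35.0, 63.9)),
}


def _prob_pair(value, name: str) -> tuple[float, float]:
    pair = tuple(float(v) for v in value)
    if len(pair) != 2 or any(not 0 <= p <= 1 for p in pair):
        raise ValueError(f"{name} must be a (p_given_sbd, p_given_nonsbd) probability pair")
    return pair


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the cohort generator; defaults are the study conditions.

    Probability pairs are (given SBD, given non-SBD).  ``triage_model`` maps
    ``"base"`` and each symptom to multiplicative weights over categories
    (1, 2, 3); a patient's category distribution is the normalized product of
    the base weights and the weights of their present symptoms.
    ``missingness`` gives the per-field probability that a generated value is
    blanked (field names: any blood marker, ``bmi``, ``fit_positive``,
    ``calprotectin_high``, ``triage_category``, ``histology``).
    """

    n_patients: int = 467
    seed: int = 0
    sbd_prevalence: float = 0.26
    male_fraction: float = 0.451
    age_mean: float = 54.3
    age_sd: float = 13.8
    bmi_mean: float = 27.8
    bmi_sd: float = 6.2
    fit_pos_given_sbd: float = 0.166
    fit_pos_given_nonsbd: float = 0.064
    calprotectin_probs: tuple[float, float] = (0.30, 0.19)
    age_older_probs: tuple[float, float] = (0.354, 0.18)
    marker_abnormal_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "triglycerides": (0.50, 0.40),
            "glucose": (0.22, 0.13),
            "magnesium": (0.10, 0.055),
            "creatinine": (0.32, 0.26),
        }
    )
    symptom_probs: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "altered_bowel_habit": (0.385, 0.366),
            "rectal_bleeding": (0.385, 0.35),
            "diarrhoea": (0.316, 0.305),
            "abdominal_pain": (0.114, 0.194),
            "iron_deficiency_anaemia": (0.087, 0.178),
        }
    )
    triage_model: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "base": (0.30, 0.42, 0.28),
            "rectal_bleeding": (3.0, 1.0, 0.45),
            "abdominal_pain": (1.8, 1.0, 0.70),
            "diarrhoea": (1.3, 1.0, 0.85),
            "iron_deficiency_anaemia": (1.6, 1.0, 0.80),
            "altered_bowel_habit": (1.0, 1.0, 1.0),
        }
    )
    missingness: Mapping[str, float] = field(
        default_factory=lambda: {
            "bmi": 0.034,
            "triglycerides": 0.02,
            "glucose": 0.02,
            "magnesium": 0.02,
            "creatinine": 0.02,
            "calprotectin_high": 0.05,
            "triage_category": 0.011,
            "histology": 0.084,
        }
    )

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("sbd_prevalence", "male_fraction", "fit_pos_given_sbd", "fit_pos_given_nonsbd"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be a probability, got {v}")
        _prob_pair(self.calprotectin_probs, "calprotectin_probs")
        _prob_pair(self.age_older_probs, "age_older_probs")
        for name, pair in self.marker_abnormal_probs.items():
            if name not in _MARKER_INTERVALS:
                raise ValueError(f"no sampling intervals defined for marker {name!r}")
            _prob_pair(pair, f"marker_abnormal_probs[{name!r}]")
        for name, pair in self.symptom_probs.items():
            if name not in SYMPTOMS:
                raise ValueError(f"unknown symptom {name!r}")
            _prob_pair(pair, f"symptom_probs[{name!r}]")
        for name, p in self.missingness.items():
            if not 0 <= p <= 1:
                raise ValueError(f"missingness[{name!r}] must be a probability, got {p}")
        if self.age_sd <= 0 or self.bmi_sd <= 0:
            raise ValueError("age_sd and bmi_sd must be positive")


def default_config() -> SimulationConfig:
    """The study-calibrated default configuration (n=467, seed 0)."""
    return SimulationConfig()


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _draw_age(rng: np.random.Generator, cfg: SimulationConfig, sbd: bool) -> int:
    """Age category first (conditionally on SBD), then a truncated-normal age.

    Conditioning the >= 65 indicator on SBD reproduces the older-age risk
    signal while keeping the marginal age distribution near its configured
    mean +/- sd.
    """
    p_older = cfg.age_older_probs[0] if sbd else cfg.age_older_probs[1]
    older = rng.random() < p_older
    if older:
        age = _truncated_normal(rng, cfg.age_mean, cfg.age_sd, AGE_CUTOFF, AGE_MAX)
        return int(min(AGE_MAX, max(AGE_CUTOFF, round(age))))
    age = _truncated_normal(rng, cfg.age_mean, cfg.age_sd, AGE_MIN, AGE_CUTOFF - 1e-9)
    return int(min(AGE_CUTOFF - 1, max(AGE_MIN, round(age))))


def _draw_marker(rng: np.random.Generator, marker: str, abnormal: bool) -> float:
    normal_iv, abnormal_iv = _MARKER_INTERVALS[marker]
    lo, hi = abnormal_iv if abnormal else normal_iv
    return round(float(rng.uniform(lo, hi)), 2)


# Relative frequency of each qualifying mechanism among SBD-positive records.
# Cancer kept at the cohort's low ~1.2%/26% relative rate; IBD small; the
# remainder spread uniformly over the four high-risk-adenoma mechanisms.
_SBD_MECHANISMS = ("cancer", "ibd", "size", "count", "villous", "hgd")
_SBD_MECH_PROBS = (0.045, 0.05, 0.22625, 0.22625, 0.22625, 0.22625)


def _draw_histology(rng: np.random.Generator, sbd: bool) -> HistologyFindings:
    if not sbd:
        if rng.random() < 0.62:  # normal colonoscopy share among non-SBD
            return HistologyFindings(
                cancer=False,
                adenoma_count=0,
                max_adenoma_size_mm=0.0,
                villous_component=False,
                high_grade_dysplasia=False,
                ibd=False,
                normal=True,
            )
        count = int(rng.integers(1, 3))  # 1-2 small low-grade adenomas
        return HistologyFindings(
            cancer=False,
            adenoma_count=count,
            max_adenoma_size_mm=round(float(rng.uniform(2.0, 9.0)), 1),
            villous_component=False,
            high_grade_dysplasia=False,
            ibd=False,
            normal=False,
        )
    mech = _SBD_MECHANISMS[rng.choice(len(_SBD_MECHANISMS), p=_SBD_MECH_PROBS)]
    cancer = mech == "cancer"
    ibd = mech == "ibd"
    villous = mech == "villous"
    hgd = mech == "hgd"
    if mech == "count":
        count = int(rng.integers(3, 7))
        size = round(float(rng.uniform(3.0, 9.0)), 1)
    elif mech == "size":
        count = int(rng.integers(1, 3))
        size = round(float(rng.uniform(10.0, 30.0)), 1)
    elif mech in ("villous", "hgd"):
        count = int(rng.integers(1, 3))
        size = round(float(rng.uniform(3.0, 9.0)), 1)
    else:  # cancer, ibd: any incidental small adenomas
        count = int(rng.integers(0, 2))
        size = round(float(rng.uniform(2.0, 8.0)), 1) if count else 0.0
    return HistologyFindings(
        cancer=cancer,
        adenoma_count=count,
        max_adenoma_size_mm=size,
        villous_component=villous,
        high_grade_dysplasia=hgd,
        ibd=ibd,
        normal=False,
    )


def _triage_probs(cfg: SimulationConfig, symptoms: frozenset[str]) -> np.ndarray:
    weights = np.asarray(cfg.triage_model.get("base", (1.0, 1.0, 1.0)), dtype=float)
    for sym in symptoms:
        if sym in cfg.triage_model:
            weights = weights * np.asarray(cfg.triage_model[sym], dtype=float)
    return weights / weights.sum()


def generate_cohort(config: SimulationConfig | None = None) -> list[PatientRecord]:
    """Generate one synthetic cohort of :class:`PatientRecord`.

    SBD status is drawn first (Bernoulli at the configured prevalence), then
    every marker, test and symptom conditionally on it; the histology
    findings are built so that :func:`~sbdtriage.cohort.classify_sbd` of the
    generated findings equals the drawn label.  Field-level missingness is
    applied last.  Deterministic in (config, seed).
    """
    cfg = config or default_config()
    rng = np.random.default_rng(cfg.seed)
    miss = dict(cfg.missingness)

    def blank(name: str) -> bool:
        p = miss.get(name, 0.0)
        # consume one draw regardless so missingness never reshuffles the stream
        return rng.random() < p

    records: list[PatientRecord] = []
    for i in range(cfg.n_patients):
        sbd = bool(rng.random() < cfg.sbd_prevalence)
        sex = "male" if rng.random() < cfg.male_fraction else "female"
        age = _draw_age(rng, cfg, sbd)
        bmi = round(_truncated_normal(rng, cfg.bmi_mean, cfg.bmi_sd, 14.0, 60.0), 1)
        markers: dict[str, float | None] = {}
        for name, (p_sbd, p_non) in cfg.marker_abnormal_probs.items():
            abnormal = rng.random() < (p_sbd if sbd else p_non)
            markers[name] = _draw_marker(rng, name, abnormal)
        fit = bool(rng.random() < (cfg.fit_pos_given_sbd if sbd else cfg.fit_pos_given_nonsbd))
        cal = bool(rng.random() < (cfg.calprotectin_probs[0] if sbd else cfg.calprotectin_probs[1]))
        symptoms = frozenset(
            sym
            for sym in SYMPTOMS
            if sym in cfg.symptom_probs
            and rng.random() < (cfg.symptom_probs[sym][0] if sbd else cfg.symptom_probs[sym][1])
        )
        triage = int(rng.choice((1, 2, 3), p=_triage_probs(cfg, symptoms)))
        histology = _draw_histology(rng, sbd)
        assert classify_sbd(histology) == sbd

        record = PatientRecord(
            patient_id=f"P{i:04d}",
            age=age,
            sex=sex,
            bmi=None if blank("bmi") else bmi,
            triglycerides=None if blank("triglycerides") else markers.get("triglycerides"),
            glucose=None if blank("glucose") else markers.get("glucose"),
            magnesium=None if blank("magnesium") else markers.get("magnesium"),
            creatinine=None if blank("creatinine") else markers.get("creatinine"),
            fit_positive=None if blank("fit_positive") else fit,
            calprotectin_high=None if blank("calprotectin_high") else cal,
            symptoms=symptoms,
            triage_category=None if blank("triage_category") else triage,
            histology=None if blank("histology") else histology,
        )
        records.append(record)
    return records
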