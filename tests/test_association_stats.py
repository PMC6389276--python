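"""Odds ratios, Woolf CIs, exact tests, FDR, screening, and the triage GLM.

Each numerical routine is checked against an independent oracle: exhaustive
hypergeometric enumeration for Fisher's exact test, a hand-coded Pearson
statistic for the chi-square, the literal step-up definition for
Benjamini–Hochberg, and a hand-rolled IRLS fit for the logistic reduction of
the triage model.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from sbdtriage import (
    ContingencyTable2x2,
    SeparationError,
    SimulationConfig,
    UndefinedOddsRatioError,
    default_reference_ranges,
    fdr_adjust,
    generate_cohort,
    mass_univariate_screen,
    odds_ratio,
    table_p_value,
    triage_glm,
    woolf_ci,
)

from conftest import make_record


# ---------------------------------------------------------------------------
# Independent oracles


def fisher_p_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration over fixed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    lf = [math.lgamma(k + 1) for k in range(r1 + r2 + 1)]

    def log_prob(x: int) -> float:
        # hypergeometric: x successes in the exposed row
        y, z, w = r1 - x, c1 - x, r2 - (c1 - x)
        return (
            lf[r1] + lf[r2] + lf[c1] + lf[r1 + r2 - c1]
            - lf[r1 + r2] - lf[x] - lf[y] - lf[z] - lf[w]
        )

    lo, hi = max(0, c1 - r2), min(r1, c1)
    observed = log_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        lp = log_prob(x)
        if lp <= observed + 1e-9:  # tables as or less probable, two-sided
            total += math.exp(lp)
    return min(1.0, total)


def bh_oracle(p: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up straight from the definition."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adjusted[i] = running
    return adjusted


def pearson_x2_p(a: int, b: int, c: int, d: int) -> float:
    """Hand-coded Pearson chi-square p on 1 df (no continuity correction)."""
    import scipy.stats

    n = a + b + c + d
    obs = [a, b, c, d]
    exp = [
        (a + b) * (a + c) / n,
        (a + b) * (b + d) / n,
        (c + d) * (a + c) / n,
        (c + d) * (b + d) / n,
    ]
    x2 = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
    return float(scipy.stats.chi2.sf(x2, df=1))


def irls_logistic(X: np.ndarray, y: np.ndarray, iters: int = 50) -> np.ndarray:
    """Hand-rolled Newton/IRLS for binary logistic regression."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        eta = X @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = mu * (1 - mu)
        H = X.T @ (W[:, None] * X)
        g = X.T @ (y - mu)
        beta = beta + np.linalg.solve(H, g)
    return beta


# ---------------------------------------------------------------------------
# Odds ratio and Woolf CI


class TestOddsRatio:
    def test_fit_table_reproduces_published_value(self):
        assert round(odds_ratio(ContingencyTable2x2(19, 20, 95, 294)), 2) == 2.94

    def test_rat_table_rounds_to_nine(self):
        or_ = odds_ratio(ContingencyTable2x2(28, 11, 86, 303))
        assert round(or_, 2) == 8.97
        assert round(or_, 1) == 9.0

    def test_balanced_table_is_unity(self):
        assert odds_ratio(ContingencyTable2x2(1, 1, 1, 1)) == 1.0

    def test_zero_cell_gets_haldane_anscombe(self):
        # (5,0,3,7): +0.5 on every cell -> (5.5*7.5)/(0.5*3.5)
        assert odds_ratio(ContingencyTable2x2(5, 0, 3, 7)) == pytest.approx(
            (5.5 * 7.5) / (0.5 * 3.5)
        )

    def test_empty_margin_is_undefined(self):
        with pytest.raises(UndefinedOddsRatioError):
            odds_ratio(ContingencyTable2x2(0, 0, 3, 7))

    @given(
        a=hst.integers(1, 50), b=hst.integers(1, 50),
        c=hst.integers(1, 50), d=hst.integers(1, 50),
    )
    def test_exposure_relabel_antisymmetry(self, a, b, c, d):
        or1 = odds_ratio(ContingencyTable2x2(a, b, c, d))
        or2 = odds_ratio(ContingencyTable2x2(b, a, d, c))
        assert or1 * or2 == pytest.approx(1.0)


class TestWoolfCi:
    def test_fit_table_ci(self):
        lo, hi = woolf_ci(ContingencyTable2x2(19, 20, 95, 294))
        assert (round(lo, 2), round(hi, 2)) == (1.51, 5.74)

    def test_rat_table_ci(self):
        lo, hi = woolf_ci(ContingencyTable2x2(28, 11, 86, 303))
        assert (round(lo, 2), round(hi, 2)) == (4.29, 18.75)

    def test_degenerate_z_zero_collapses_to_point(self):
        t = ContingencyTable2x2(12, 7, 9, 30)
        lo, hi = woolf_ci(t, z=0.0)
        assert lo == pytest.approx(odds_ratio(t))
        assert hi == pytest.approx(odds_ratio(t))

    @given(
        a=hst.integers(1, 40), b=hst.integers(1, 40),
        c=hst.integers(1, 40), d=hst.integers(1, 40),
    )
    def test_interval_contains_point_estimate(self, a, b, c, d):
        t = ContingencyTable2x2(a, b, c, d)
        lo, hi = woolf_ci(t)
        assert lo <= odds_ratio(t) <= hi

    def test_width_non_increasing_in_every_cell(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            cells = rng.integers(1, 30, size=4)
            t = ContingencyTable2x2(*map(int, cells))
            lo, hi = woolf_ci(t)
            width = math.log(hi) - math.log(lo)
            for k in range(4):
                bigger = cells.copy()
                bigger[k] += 5
                lo2, hi2 = woolf_ci(ContingencyTable2x2(*map(int, bigger)))
                assert math.log(hi2) - math.log(lo2) <= width + 1e-12


# ---------------------------------------------------------------------------
# p-values


class TestTablePValues:
    def test_balanced_table_fisher_is_one(self):
        assert table_p_value(ContingencyTable2x2(1, 1, 1, 1), "fisher") == pytest.approx(1.0)

    def test_perfect_association_matches_enumeration(self):
        t = ContingencyTable2x2(10, 0, 0, 10)
        assert table_p_value(t, "fisher") == pytest.approx(fisher_p_oracle(10, 0, 0, 10))

    @given(
        a=hst.integers(0, 12), b=hst.integers(0, 12),
        c=hst.integers(0, 12), d=hst.integers(0, 12),
    )
    @settings(max_examples=200)
    def test_fisher_equals_hypergeometric_enumeration(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        t = ContingencyTable2x2(a, b, c, d)
        if min(t.margins()) == 0:
            assert table_p_value(t, "fisher") == 1.0
        else:
            assert table_p_value(t, "fisher") == pytest.approx(
                fisher_p_oracle(a, b, c, d), rel=1e-9, abs=1e-12
            )

    def test_chi_square_matches_hand_coded_pearson(self):
        t = ContingencyTable2x2(19, 20, 95, 294)
        assert table_p_value(t, "chi_square") == pytest.approx(pearson_x2_p(19, 20, 95, 294))


class TestFdrAdjust:
    def test_equal_ps_unchanged(self):
        assert fdr_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_single_p_unchanged(self):
        assert fdr_adjust([0.37]) == pytest.approx([0.37])

    def test_matches_step_up_definition(self):
        p = [0.01, 0.02, 0.03, 0.04]
        assert fdr_adjust(p) == pytest.approx(bh_oracle(p))

    @given(hst.lists(hst.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_oracle_agreement_and_bounds(self, p):
        adj = fdr_adjust(p)
        assert adj == pytest.approx(bh_oracle(p))
        for raw, a in zip(p, adj):
            assert raw - 1e-12 <= a <= 1.0 + 1e-12

    @given(hst.lists(hst.floats(0, 1, allow_nan=False), min_size=2, max_size=10),
           hst.randoms(use_true_random=False))
    def test_permutation_equivariance(self, p, rnd):
        perm = list(range(len(p)))
        rnd.shuffle(perm)
        adj = fdr_adjust(p)
        adj_perm = fdr_adjust([p[i] for i in perm])
        assert adj_perm == pytest.approx([adj[i] for i in perm])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])


# ---------------------------------------------------------------------------
# Mass univariate screening


class TestMassUnivariateScreen:
    def _perfect_cohort(self):
        records = [
            make_record(f"S{i}", 50, "female", sbd=True, glucose=9.0) for i in range(10)
        ] + [
            make_record(f"N{i}", 50, "female", sbd=False, glucose=5.0) for i in range(30)
        ]
        return records

    def test_perfect_association_is_flagged(self, ranges):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = mass_univariate_screen(self._perfect_cohort(), ranges)
        glucose = [r for r in results if r.marker_name == "glucose"]
        assert len(glucose) == 1
        assert glucose[0].significant
        assert glucose[0].odds_ratio > 1

    def test_alpha_zero_flags_nothing(self, ranges, default_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = mass_univariate_screen(default_cohort, ranges, alpha=0.0)
        assert not any(r.significant for r in results)

    def test_pairwise_exclusion_of_missing_markers(self, ranges):
        records = self._perfect_cohort()
        records += [make_record("M0", 50, "female", sbd=True, glucose=None)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            results = mass_univariate_screen(records, ranges)
        glucose = [r for r in results if r.marker_name == "glucose"][0]
        assert glucose.n_used == 40  # the missing-glucose record drops out pairwise

    def test_fit_detected_across_seeds_with_fdr_control(self, ranges):
        """FIT (true OR ~2.9) is usually significant; null symptoms rarely are."""
        n_seeds = 60
        fit_hits = 0
        null_hits = 0
        for seed in range(n_seeds):
            cohort = generate_cohort(SimulationConfig(seed=seed))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                results = mass_univariate_screen(cohort, ranges)
            by_key = {(r.marker_name, r.level_tested): r for r in results}
            fit_hits += by_key[("fit_positive", "positive")].significant
            # rectal bleeding and diarrhoea are near-null in the generator
            null_hits += by_key[("rectal_bleeding", "present")].significant
            null_hits += by_key[("diarrhoea", "present")].significant
        assert fit_hits > n_seeds / 2
        assert null_hits <= 0.1 * 2 * n_seeds


# ---------------------------------------------------------------------------
# Triage-category GLM


class TestTriageGlm:
    def test_independent_predictor_coefficient_near_zero(self):
        rng = np.random.default_rng(21)
        records = []
        for i in range(900):
            cat = int(rng.integers(1, 4))
            fit = bool(rng.random() < 0.5)  # independent of category
            records.append(
                make_record(f"R{i}", 50, "female", fit_positive=fit, triage_category=cat)
            )
        res = triage_glm(records, ["fit_positive"])
        for contrast in ("1_vs_3", "2_vs_3"):
            coef, se, _ = res.contrasts[contrast]["fit_positive"]
            assert abs(coef) < 3 * se

    def test_two_category_reduction_matches_irls_oracle(self):
        # 20 records, categories 1 and 3 only -> binary logistic regression
        layout = [(True, 1)] * 6 + [(True, 3)] * 2 + [(False, 1)] * 4 + [(False, 3)] * 8
        records = [
            make_record(f"R{i}", 50, "female", fit_positive=fit, triage_category=cat)
            for i, (fit, cat) in enumerate(layout)
        ]
        res = triage_glm(records, ["fit_positive"])
        X = np.array([[1.0, float(fit)] for fit, _ in layout])
        y = np.array([1.0 if cat == 1 else 0.0 for _, cat in layout])
        beta = irls_logistic(X, y)
        assert res.contrasts["1_vs_3"]["const"][0] == pytest.approx(beta[0], abs=1e-5)
        assert res.contrasts["1_vs_3"]["fit_positive"][0] == pytest.approx(beta[1], abs=1e-5)

    def test_perfect_predictor_raises_separation_error(self):
        records = []
        for i in range(60):
            cat = 1 if i < 20 else (2 if i < 40 else 3)
            symptoms = frozenset(["rectal_bleeding"]) if cat == 1 else frozenset()
            records.append(
                make_record(f"R{i}", 50, "female", symptoms=symptoms, triage_category=cat)
            )
        with pytest.raises(SeparationError):
            triage_glm(records, ["rectal_bleeding"])

    def test_recovers_known_multinomial_coefficients(self):
        rng = np.random.default_rng(33)
        true = {"1_vs_3": (0.2, 0.9), "2_vs_3": (0.1, -0.5)}  # (intercept, slope)
        records = []
        for i in range(2000):
            x = float(rng.random() < 0.5)
            l1 = true["1_vs_3"][0] + true["1_vs_3"][1] * x
            l2 = true["2_vs_3"][0] + true["2_vs_3"][1] * x
            w = np.array([math.exp(l1), math.exp(l2), 1.0])
            cat = int(rng.choice([1, 2, 3], p=w / w.sum()))
            records.append(
                make_record(f"R{i}", 50, "female", fit_positive=bool(x), triage_category=cat)
            )
        res = triage_glm(records, ["fit_positive"])
        for contrast, (a0, b0) in true.items():
            coef, se, _ = res.contrasts[contrast]["fit_positive"]
            assert abs(coef - b0) < 3 * se
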