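"""Mass univariate odds-ratio screen of every marker against SBD.

Each abnormal marker level (high/low blood values, positive stool tests,
age >= 65, referral symptoms) is tested against the normal reading in a 2x2
table; p-values are Benjamini-Hochberg corrected as one family.
"""

import warnings

from sbdtriage import (
    SimulationConfig,
    default_reference_ranges,
    generate_cohort,
    mass_univariate_screen,
)

cohort = generate_cohort(SimulationConfig(seed=42))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # one-sided markers skip their unused level
    results = mass_univariate_screen(cohort, default_reference_ranges(), alpha=0.05)

print(f"{'marker':<26}{'level':<10}{'OR':>7}{'95% CI':>16}{'p(FDR)':>9}  sig")
for r in sorted(results, key=lambda r: r.p_adjusted):
    ci = f"{r.ci_low:.2f}-{r.ci_high:.2f}"
    print(f"{r.marker_name:<26}{r.level_tested:<10}{r.odds_ratio:>7.2f}"
          f"{ci:>16}{r.p_adjusted:>9.3f}  {'*' if r.significant else ''}")

# Blood/stool markers and age carry the signal (generator ORs ~1.5-2.9);
# which of them clear the FDR bar in a single cohort is down to sampling
# noise.  Referral symptoms carry almost none, mirroring why symptoms-based
# triage performs poorly.
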