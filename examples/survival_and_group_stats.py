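"""Survival analysis and group statistics on the default simulated cohort.

Reproduces the published survival pattern (control deaths at resuscitation
x2, 24 h and 48 h; no deaths in the restricted group), runs the log-rank
test, and compares blood analytes between groups.
"""

from ca_recovery.stats import (
    km_estimate,
    logrank_test,
    rm_anova_two_way,
    sidak_posthoc,
    welch_t,
)
from ca_recovery.synthetic import CohortSimConfig, simulate_analytes, simulate_survival

cfg = CohortSimConfig(seed=5)

ds = simulate_survival(cfg)
for group, curve in km_estimate(ds).items():
    print(f"{group:8s} survival at 72 h: {curve.at(72.0):.3f}")
res = logrank_test(ds)
print(f"log-rank chi2({res.df}) = {res.statistic:.3f}, p = {res.p_value:.4f}")

panel = simulate_analytes(cfg)
ket = panel[panel.variable == "ketone"]
t = welch_t(
    ket[ket.group == "control"]["value"],
    ket[ket.group == "cr"]["value"],
    labels=("control", "cr"),
)
print(f"ketone Welch t = {t.statistic:.2f} (df {t.df:.1f}), p = {t.p_value:.2e}")

glu = panel[panel.variable == "glucose"]
aov = rm_anova_two_way(glu, dv="value")
for key, r in aov.items():
    print(f"glucose {key:11s} F{tuple(int(d) for d in r.df)} = "
          f"{r.statistic:.1f}, p = {r.p_value:.2e}")
adj = sidak_posthoc([aov["interaction"].p_value, aov["group"].p_value], alpha=0.05)
print(f"Sidak-adjusted alpha for m=2 comparisons: {adj.alpha_adjusted:.4f}")

# Expected pattern: control survival ~0.71 vs 1.0, chi2 ~ 4.5 (p < 0.05);
# restricted animals have higher ketones (negative t for control - cr);
# the glucose group x time interaction (control rises after arrest, cr
# flat) is strongly significant.
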