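"""Risk-stratified life tables and bootstrap life-expectancy losses.

Population mortality is partitioned across joint exposure-SES groups by
prevalence-weighted hazard-ratio normalization; each group's life table
gives its remaining expectancy at 50, and a parametric bootstrap over the
log hazard ratios yields percentile confidence intervals.
"""

import pandas as pd

from airses.lifetable import (
    GroupRiskProfile,
    build_life_table,
    life_expectancy_difference,
    monte_carlo_ci,
    partition_mortality,
    synthetic_reference,
)

refs = synthetic_reference()
for sex in ("female", "male"):
    e50 = build_life_table(refs[sex]).loc[50, "e"]
    print(f"reference e(50), {sex}: {e50:.2f} years")

# a graded mortality-risk ladder across SES within the top exposure tertile
profile = GroupRiskProfile(
    pd.DataFrame(
        {
            "group": ["T3xhigh", "T3xmedium", "T3xlow"],
            "prevalence": [0.35, 0.45, 0.20],
            "hr": [1.0, 1.25, 1.65],
            "se_loghr": [0.0, 0.06, 0.08],
        }
    ),
    reference="T3xhigh",
)

rates = partition_mortality(refs["male"], profile)
tables = {g: build_life_table(rates[g].rename(None)) for g in rates.columns}
delta = life_expectancy_difference(tables, "T3xhigh")
print("\nyears lost at 50 vs the most favourable group (point estimates):")
print(delta.round(2).to_string())

ci = monte_carlo_ci(profile, refs["male"], runs=10000, seed=1)
print("\nwith 10,000-run parametric-bootstrap 95% CIs:")
print(ci.round(2).to_string(index=False))

# A mortality HR of 1.65 for the low-SES group translates into roughly
# 4-5 years of life lost at age 50 under this reference schedule; the
# interval reflects only hazard-ratio uncertainty (prevalences fixed).
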