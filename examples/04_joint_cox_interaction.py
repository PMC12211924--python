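"""Joint 3x3 exposure-SES Cox analysis with interaction measures.

Fits proportional-hazards models for incident AMD across the nine joint
cells (score tertile x SES level), tests the interaction by likelihood
ratio, and computes the additive-interaction measures (RERI, AP, S).
"""

import numpy as np
import pandas as pd

from airses import cohort as sc
from airses.cohort import CohortConfig, generate_cohort
from airses.cox import (
    fit_hazard_model,
    joint_hazard_table,
    lr_interaction_test,
    make_joint_exposure,
)
from airses.interaction import additive_interaction
from airses.lca import assign_and_order_classes, fit_lca
from airses.scores import fit_pca_score, tertile_cut

cfg = CohortConfig(
    n=30000, seed=11,
    baseline_rates=[0.004, 0.006, 0.28, 0.012, 0.012],
    log_hr={"T3xlow": [np.log(1.6), 0, 0, 0, 0],
            "T3xmedium": [np.log(1.25), 0, 0, 0, 0],
            "T2xlow": [np.log(1.2), 0, 0, 0, 0]},
)
df, truth = generate_cohort(cfg)

# fitted exposure tertiles and SES classes (not the generator truth)
tert = tertile_cut(fit_pca_score(df[sc.POLLUTANTS]).scores)
model = fit_lca(df[sc.SES_ITEMS], n_classes=3, n_starts=8, seed=12)
ses = assign_and_order_classes(model, df[sc.SES_ITEMS])
df["joint"] = make_joint_exposure(tert.labels, ses.labels)

end = df["amd_date"].fillna(df["death_date"]).fillna(df["censor_date"])
df["T"] = np.maximum((end - df["entry_date"]).dt.days / sc.DAYS_PER_YEAR, 1e-3)
df["E"] = df["amd_date"].notna().astype(int)

covs = ["age_entry", "sex", "smoking", "bmi_cat"]
full = fit_hazard_model(df, "T", "E", ["joint"] + covs)
print(joint_hazard_table(full, prefix="joint_").round(3).to_string(index=False))

# LR test: joint cross-classification vs main effects only
df["aps1_tertile"] = tert.labels
df["ises"] = ses.labels
reduced = fit_hazard_model(df, "T", "E", ["aps1_tertile", "ises"] + covs)
stat, dof, p = lr_interaction_test(full, reduced)
print(f"\nLR interaction test: chi2={stat:.2f}, df={dof}, p={p:.3f}")

inter = additive_interaction(full, "joint_T3xhigh", "joint_T1xlow", "joint_T3xlow")
print(f"RERI = {inter.reri.value:.2f} (95% CI {inter.reri.lo:.2f} to {inter.reri.hi:.2f})")
print(f"AP   = {inter.ap.value:.2f} (95% CI {inter.ap.lo:.2f} to {inter.ap.hi:.2f})")

# The T3xlow cell's hazard ratio is noticeably attenuated from its
# generating value of 1.6: tertiles of the fitted score and modal latent
# classes both misclassify, diluting the cell contrast — the same
# regression-dilution behaviour expected with composite exposure scores.
# A positive RERI means the joint cell exceeds the sum of the separate
# excess risks on the additive scale.
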