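"""Generate a seeded synthetic cohort and inspect its event structure.

The generator draws a correlated five-pollutant panel (log-normal,
moment-matched to typical UK annual means), three-class latent SES
indicators, and illness-death event histories (baseline -> AMD -> ocular
comorbidity, death from every state) under proportional hazards.
"""

import numpy as np

from airses.cohort import CohortConfig, generate_cohort

cfg = CohortConfig(
    n=20000,
    seed=42,
    # raise the risk of the worst exposure/SES cell on the AMD transition
    log_hr={"T3xlow": [np.log(1.5), 0.0, 0.0, 0.0, 0.0]},
    tie_fraction=0.02,
)
cohort, truth = generate_cohort(cfg)

n = len(cohort)
n_amd = cohort["amd_date"].notna().sum()
n_ocmd = cohort["ocmd_date"].notna().sum()
n_death = cohort["death_date"].notna().sum()

print(f"cohort size:          {n}")
print(f"incident AMD:         {n_amd} ({100 * n_amd / n:.2f}%)")
print(f"ocular comorbidity:   {n_ocmd} ({100 * n_ocmd / max(n_amd, 1):.1f}% of AMD cases)")
print(f"deaths:               {n_death} ({100 * n_death / n:.2f}%)")
print(f"truth groups:         {truth['group'].nunique()} joint exposure-SES cells")

# Roughly 1.2% AMD incidence and 7.3% mortality over 12.5 years of
# follow-up are the event proportions the generator is calibrated to;
# the truth table records each subject's latent class, joint group and
# latent transition times for downstream recovery checks.
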