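"""Generate a virtual cohort and compute cohort-level correlations.

Builds a 25-patient cohort with the default archetype mix (responders,
partial responders, antigen-positive and antigen-negative relapses),
writes nothing to disk, and asks which single patient-level indicators
predict the IL-6 fold change - mirroring the clinical question of whether
dose or tumor burden anticipate cytokine release.
"""

import numpy as np
import pandas as pd

from cartmac.scenario_engine import cohort_metrics
from cartmac.simulation import observables
from cartmac.synthetic_data import generate_cohort

cohort = generate_cohort(25, seed=42)
rows = []
for pt in cohort:
    obs = observables(pt.true_trajectory(), pt.extras["dose"])
    rows.append({
        "patient": pt.patient_id, "archetype": pt.archetype,
        "dose": pt.extras["dose"],
        "initial_burden": pt.extras["T_P0"] + pt.extras["T_N0"],
        "il6_fold_change": obs.il6_fold_change,
        "cart_fold_change": obs.cart_fold_change,
        "il6_peak_day": obs.il6_peak_day, "cmax_day": obs.cmax_day,
        "macrophage_peak_day": obs.macrophage_peak_day,
        "tumor_day28": obs.tumor_day28, "tumor_day90": obs.tumor_day90,
    })
table = pd.DataFrame(rows)
print(table[["patient", "archetype", "il6_fold_change", "cmax_day",
             "il6_peak_day"]].to_string(index=False))

m = cohort_metrics(table)
print("\nR^2 of IL-6 fold change against single indicators:")
for key in ("r2_il6_fold_vs_dose", "r2_il6_fold_vs_burden",
            "r2_il6_fold_vs_cart_fold", "r2_il6_fold_vs_il6_peak_day"):
    print(f"  {key:32s} {m[key]:.2f}")
gaps = m["cart_minus_il6_peak_days"]
print(f"\nCAR-T peak minus IL-6 peak: median {np.median(gaps):+.1f} days "
      f"(IL-6 first in {np.mean(gaps >= 0) * 100:.0f}% of patients)")
print(f"day-28 vs day-90 tumor burden R^2 = {m['r2_day28_vs_day90']:.2f}")
print("\nNo single indicator predicts the IL-6 fold change well, but the")
print("temporal coupling (macrophages -> IL-6 -> CAR-T peak) is robust.")
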