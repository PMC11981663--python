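"""Counterfactual interventions: dose scaling and timed CD40 blocking.

For a CD40-dominant virtual patient the script compares the reference
response against (i) 10x/100x smaller or larger CAR-T doses, (ii) scaled
initial tumor burden, and (iii) a 50% CD40 block applied in different time
windows, reporting the change in IL-6 peak, its timing and the tumor
response.
"""

from cartmac.scenario_engine import (
    InterventionSpec,
    PatientModel,
    blocking_grid,
    run_scenario,
)
from cartmac.synthetic_data import cd40_dominant_archetype, generate_patient

pm = PatientModel.from_synthetic(generate_patient(cd40_dominant_archetype(), 1))
ref = pm.simulate()

print("dose scaling (vs fitted reference):")
for f in (0.01, 0.1, 10.0, 100.0):
    o = run_scenario(pm, InterventionSpec("dose_scale", f), reference=ref)
    print(f"  {f:6g}x dose: IL-6 fold x{o.il6_fold_ratio:5.2f}, "
          f"IL-6 peak day {o.il6_peak_day_shift:+5.1f} d, "
          f"CAR-T peak day {o.cmax_day_shift:+5.1f} d, "
          f"day-28 tumor x{o.tumor_day28_ratio:.2g}")

print("\ninitial tumor burden scaling:")
for f in (0.1, 10.0):
    o = run_scenario(pm, InterventionSpec("tumor_scale", f), reference=ref)
    print(f"  {f:6g}x burden: CAR-T peak x{o.cmax_ratio:5.2f}, "
          f"IL-6 fold x{o.il6_fold_ratio:5.2f}")

print("\n50% CD40 block, window from start day to 5 days post CAR-T peak:")
grid = blocking_grid(pm, "CD40", residual=0.5, start_days=(0, 1, 3, 5, 7, 10),
                     stop_offsets=(5.0,))
mean = grid[grid["patient"] == "mean"]
for _, row in mean.iterrows():
    print(f"  start day {row['start_day']:4.0f}: "
          f"IL-6 peak reduced {row['il6_peak_reduction_pct']:5.1f}%")

print("\nSmaller doses blunt and delay the IL-6 peak at nearly unchanged")
print("tumor control; early CD40 blocking (before the activation cascade")
print("ignites) achieves the largest cytokine-peak reduction.")
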