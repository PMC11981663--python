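"""Forward-simulate a virtual patient and summarise the response.

Builds a typical responder parameter set (CAR-T layer plus macrophage/IL-6
layer), infuses a single 1e8-cell dose against a 3e10-cell leukemic burden,
and prints the response hallmarks clinicians track: CAR-T expansion peak and
day, minimum tumor burden, IL-6 fold change and the relative peak timing.
"""

from cartmac import (
    CartTumorParams,
    CytokineParams,
    DoseRegimen,
    ModelState,
    observables,
    simulate,
)

params = CartTumorParams(eta=0.3, mu_I=1.0, kappa=1.2, mu_E=0.35,
                         epsilon=1e-3, mu_P=0.01, rho=0.1, gamma=1.2,
                         A=1e8, B=1e8)
cytokine = CytokineParams(sigma_M=1e8, delta_M=0.15, sigma_I=10.0,
                          delta_I=2.0, alpha=4e-8, beta_B=3e-12,
                          beta_K=1e-11, beta_C=3e-9)
init = ModelState(T_P=3e10, M_i=1e10, IL6=5.0)
regimen = DoseRegimen.single(1e8)

traj = simulate(params, cytokine, init, regimen, horizon=90.0)
obs = observables(traj, regimen.total_dose)

print(f"CAR-T peak:        {obs.cmax:.3g} cells on day {obs.cmax_day:.1f} "
      f"({obs.cart_fold_change:.0f}x the infused dose)")
print(f"post-distribution minimum: {obs.cmin:.3g} cells on day {obs.cmin_day:.1f}")
print(f"tumor minimum:     {obs.tmin:.3g} cells on day {obs.tmin_day:.1f} "
      f"(from {init.T_P:.3g}); relapse within horizon: {obs.relapse}")
print(f"IL-6:              {obs.il6_baseline:.1f} -> {obs.il6_peak:.1f} ng/L "
      f"({obs.il6_fold_change:.1f}x) peaking day {obs.il6_peak_day:.1f}")
print(f"peak order:        macrophages day {obs.macrophage_peak_day:.1f} "
      f"< IL-6 day {obs.il6_peak_day:.1f} < CAR-T day {obs.cmax_day:.1f}")
print("\nThe IL-6 peak precedes the CAR-T peak (as observed clinically), and")
print("activated macrophages peak shortly before IL-6 - the model's basis for")
print("anticipating cytokine release by monitoring macrophage activation.")
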