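"""Two-step parameter estimation on a synthetic patient record.

Generates a noisy virtual responder (sparse clinical schedule, copies/µg
and %blasts units, detection censoring), fits the ten CAR-T/tumor
parameters by slope-informed weighted least squares, then fits the
macrophage/IL-6 layer by Monte-Carlo search with trust-region refinement,
and compares the estimates against the generating truth.

Runs in a couple of minutes with the reduced search budget used here.
"""

import numpy as np

from cartmac.parameter_estimation import FitConfig, fit_cytokine_layer, fit_layer1
from cartmac.synthetic_data import ARCHETYPES, PatientArchetype, generate_patient

arch = ARCHETYPES["responder_CR"]
patient = generate_patient(
    PatientArchetype(label=arch.label, ranges=arch.ranges,
                     cv={"cart": 0.10, "tumor": 0.10, "il6": 0.10}),
    seed=2)
tc = patient.timecourse
cfg = FitConfig(n_mc=1500, n_refine=8, seed=7)

layer1 = fit_layer1(tc, cfg)
truth = patient.params.to_dict()
print(f"layer 1 (CAR-T/tumor) WLS = {layer1.objective:.3e}, "
      f"{layer1.nfev} evaluations")
print(f"{'param':9s}{'truth':>12s}{'fitted':>12s}{'rel.err':>9s}")
errs = {}
for k in ("mu_I", "kappa", "mu_E", "mu_P", "gamma", "rho", "eta",
          "epsilon", "A", "B"):
    errs[k] = abs(layer1.params[k] - truth[k]) / truth[k]
    print(f"{k:9s}{truth[k]:12.3g}{layer1.params[k]:12.3g}{errs[k]:9.0%}")
slope_med = np.median([errs[k] for k in ("mu_I", "kappa", "mu_E",
                                         "gamma", "rho")])
print(f"median error, slope-dominant parameters "
      f"(mu_I, kappa, mu_E, gamma, rho): {slope_med:.0%}")

layer2 = fit_cytokine_layer(tc, layer1, cfg)
qt = patient.cytokine.to_dict()
qt["M_i0"] = patient.extras["M_i0"]
print(f"\nlayer 2 (macrophage/IL-6) LR = {layer2.objective:.3f}")
print("identifiable products (IL-6 capacity and CD40 feedback strength):")
for a, b, label in (("alpha", "M_i0", "alpha*M_i0"),
                    ("beta_C", "M_i0", "beta_C*M_i0")):
    t = qt[a] * qt[b]
    f = layer2.params[a] * layer2.params[b]
    print(f"  {label:12s} truth={t:.3g} fitted={f:.3g} "
          f"({100 * abs(f - t) / t:.0f}% off)")
print("\nThe slope-dominant CAR-T parameters are the best determined under")
print("measurement noise, while (eta, epsilon, mu_P, A, B) are weakly")
print("identified from a single sparse record. In the cytokine layer the")
print("IL-6 production capacity alpha*M_i0 is well determined; the CD40")
print("feedback strength beta_C*M_i0 is pinned down only on records where")
print("CD40 activation actually shapes the IL-6 curve (high-CRS patients),")
print("not on mild responders like this one. Individual factors always")
print("trade off against the naive macrophage pool size.")
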