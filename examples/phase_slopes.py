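"""Segment multiphasic dynamics and read parameters off the slopes.

Simulates a responder with known parameters, segments the CAR-T and tumor
series into their kinetic phases, and compares each extremal log-slope with
the parameter combination that drives it: distribution ~ -mu_I, expansion
~ kappa - mu_E, contraction ~ -mu_E, persistence ~ -mu_P, tumor shrinkage
~ rho - gamma and regrowth ~ rho.  This correspondence is what lets the
fitting pipeline start from data-derived initial guesses.
"""

from cartmac import CartTumorParams, DoseRegimen, ModelState, simulate
from cartmac.phase_analysis import segment_phases

truth = CartTumorParams(eta=0.3, mu_I=1.0, kappa=1.2, mu_E=0.35,
                        epsilon=1e-3, mu_P=0.01, rho=0.1, gamma=1.2,
                        A=1e8, B=1e8)
traj = simulate(truth, init=ModelState(T_P=3e10),
                regimen=DoseRegimen.single(1e8), horizon=90.0)
seg = segment_phases(traj)

print(seg.to_frame().to_string(index=False))
print()
pairs = [("m_D", seg.m_D, -truth.mu_I, "-mu_I"),
         ("m_E", seg.m_E, truth.kappa - truth.mu_E, "kappa-mu_E"),
         ("m_C", seg.m_C, -truth.mu_E, "-mu_E"),
         ("m_Pst", seg.m_Pst, -truth.mu_P, "-mu_P"),
         ("m_S", seg.m_S, truth.rho - truth.gamma, "rho-gamma"),
         ("m_R", seg.m_R, truth.rho, "rho")]
for name, got, want, label in pairs:
    print(f"{name:6s} = {got:+.3f} /day   vs {label:11s} = {want:+.3f} /day "
          f"({100 * abs(got - want) / abs(want):.0f}% off)")
print("\nEach phase slope tracks its mechanistic parameter combination to")
print("within a few percent on noiseless dynamics - the basis of")
print("slope-informed initial estimates for patient fitting.")
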