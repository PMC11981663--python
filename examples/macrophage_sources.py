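"""Attribute macrophage activation to its three source mechanisms.

Simulates a CD40-dominant virtual patient with the activated pool split
into DAMP-, antigen- and CD40-activated sub-populations (integrated
alongside the full system, so the split is exact), prints the activation
timeline and the cumulative share of each mechanism, and shows the
single-mechanism counterfactuals.
"""

import numpy as np

from cartmac.macrophage_analysis import (
    activation_timeline,
    decompose_activation,
    single_mechanism_simulation,
)
from cartmac.model_core import ModelState
from cartmac.synthetic_data import cd40_dominant_archetype, generate_patient

patient = generate_patient(cd40_dominant_archetype(), seed=0)
traj = patient.true_trajectory(track_activation=True)
dec = decompose_activation(traj)

print("cumulative activation by source:")
print(dec.summary().to_string(index=False))
print("\nevent timeline:")
print(activation_timeline(dec, traj).to_string(index=False))

q = patient.cytokine
init = ModelState(T_P=patient.init.T_P, M_i=patient.init.M_i,
                  IL6=q.sigma_I / q.delta_I)
for subset, label in [({"DAMP"}, "DAMP release only"),
                      ({"antigen"}, "antigen binding only"),
                      ({"CD40"}, "CD40 contact only")]:
    tr = single_mechanism_simulation(patient.params, q, init,
                                     patient.regimen, subset, horizon=90.0)
    il6 = tr.column("IL6")
    peak_day = tr.t[int(np.argmax(il6))]
    print(f"{label:22s}: IL-6 peak {il6.max():7.1f} ng/L on day {peak_day:5.1f}")

print("\nDAMP-driven activation peaks first (during tumor shrinkage),")
print("antigen-driven next (with CAR-T expansion), CD40-driven last - and")
print("CD40 contact alone cannot start the cascade: it needs previously")
print("activated macrophages, so IL-6 stays at baseline in that scenario.")
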