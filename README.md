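# cartmac

Mechanistic modelling of CAR-T cell therapy, tumor response and
macrophage-mediated cytokine release.

## The problem

Anti-CD19 CAR-T cell therapy shows characteristic multiphasic kinetics —
a distribution dip after infusion, antigen-driven expansion, contraction,
and long-term persistence — while the tumor shrinks and sometimes relapses
with antigen-positive or antigen-negative cells. Its most frequent severe
toxicity, cytokine release syndrome (CRS), is driven by macrophage
activation and tracked clinically through serum IL-6, which typically peaks
*before* the CAR-T cells do. `cartmac` implements a three-layer ordinary
differential equation model of this process together with the analysis
pipeline built around it, for researchers in mathematical oncology and
quantitative systems pharmacology.

## The model

**Layer 1 — CAR-T phenotypes and antigen-positive tumor.** Injected cells
C_I activate into expanders C_E at rate η·F, with the antigen-binding
fraction F(T_P) = T_P/(A+T_P). Expanders proliferate (κ·F), convert to
persisters C_P at ε·(1−F), die/exhaust at μ_E; persisters reactivate at
θ·F and decay at μ_P. The tumor grows logistically (ρ, K) and is killed at
γ·C_E/(B+C_E) (Holling type II in the effector number). Proliferation is
gated to zero for any population below one cell (zero-limit rule).

**Layer 2 — antigen-negative escape.** A second tumor compartment T_N
shares the logistic crowding 1−(T_P+T_N)/K but is killed at only a
fraction g0 of the rate and does not feed antigen-dependent CAR-T
switching.

**Layer 3 — macrophages and IL-6.** Naive macrophages M_i (production σ_M,
death δ_M) are activated at rate

h = β_K·(C_E/(B+C_E))·(T_P+g0·T_N) + β_B·F(T_P)·C_E + β_C·(M_a/(C+M_a))·C_E

combining DAMP release from tumor killing, antigen-binding-mediated
signalling, and contact-dependent CD40–CD40L engagement (a positive
feedback through M_a). Activated macrophages release IL-6:
dIL6/dt = σ_I + α·M_a − δ_I·IL6.

On top of the simulator the package provides phase segmentation with
extremal log-slope analysis (each phase slope estimates a parameter
combination: −μ_I, κ−μ_E, −μ_E, −μ_P, ρ−γ, ρ), a slope-informed two-step
fitting pipeline (bounded Nelder–Mead WLS for layer 1; Monte-Carlo search
plus trust-region least-squares refinement of LR = ln Σ wᵢ(IL6ᵢ−IL6(tᵢ))²
for layer 3), exact decomposition of activated macrophages by source
mechanism, counterfactual interventions (dose/burden scaling, timed
fractional blocking of activation mechanisms), AIC-based comparison of
reduced model variants (DAC, DC, AC, DA, D, A; AIC = 2k + n_d(1 + LR −
ln n_d + ln 2π)), and a virtual-patient generator that emulates clinical
records (sparse schedules, copies/µg DNA / cells/µL / %blasts units,
2.5×10⁵-cell detection limit, multiplicative lognormal noise).

## Worked example

```bash
python examples/simulate_patient.py
```

prints, for a typical responder (10⁸-cell dose against 3×10¹⁰ tumor
cells):

```
CAR-T peak:        6.16e+09 cells on day 8.8 (62x the infused dose)
post-distribution minimum: 5.59e+07 cells on day 1.1
tumor minimum:     79 cells on day 28.5 (from 3e+10); relapse within horizon: False
IL-6:              5.0 -> 81.2 ng/L (16.2x) peaking day 7.1
peak order:        macrophages day 6.6 < IL-6 day 7.1 < CAR-T day 8.8
```

The CAR-T population expands ~60-fold and peaks on day 8.8; the tumor is
driven essentially extinct; IL-6 rises 16-fold and peaks 1.7 days *before*
the CAR-T peak, preceded by the activated-macrophage peak — the temporal
signature observed clinically. The other scripts in `examples/` each
demonstrate one capability: `phase_slopes.py` (slope↔parameter mapping),
`fit_virtual_patient.py` (two-step estimation), `macrophage_sources.py`
(activation decomposition), `interventions.py` (dose scaling and CD40
blocking), `model_comparison.py` (AIC variant ranking) and
`make_cohort.py` (cohort correlations). A thin CLI mirrors the library:
`cartmac synth|simulate|phases|fit|decompose|scenarios|compare`.

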