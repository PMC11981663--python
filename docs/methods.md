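# Methods

## Model structure and assumptions

The model couples three layers in a single, well-mixed 5 L blood
compartment. Time is measured in days, cell populations as absolute
counts, IL-6 in ng/L (≡ pg/mL).

**CAR-T / tumor layer.** Three CAR-T phenotypes — injected C_I, expander
C_E, persister C_P — plus antigen-positive tumor T_P:

    dC_I/dt = −η F C_I − μ_I C_I
    dC_E/dt =  η F C_I + κ F C_E − ε (1−F) C_E + θ F C_P − μ_E C_E
    dC_P/dt =  ε (1−F) C_E − θ F C_P − μ_P C_P
    dT_P/dt =  ρ T_P (1 − (T_P+T_N)/K) − γ C_E/(B+C_E) · T_P

with F(T_P) = T_P/(A+T_P). All phenotype transitions are driven by the
antigen-binding fraction F: high antigen activates injected cells, fuels
expander proliferation and suppresses persister formation; when antigen is
cleared, 1−F → 1 and the expander pool drains into persisters. Killing is
Holling type II in the effector number (half-saturation B), so the
per-tumor-cell kill rate saturates at γ.

**Antigen-negative escape.** T_N obeys the same logistic growth under the
shared crowding term but is killed at only g0·γ·C_E/(B+C_E) (bystander
effect and endogenous TCR; g0 ≪ 1) and contributes nothing to F.

**Macrophage / IL-6 layer.** Naive macrophages M_i are produced at σ_M and
die at δ_M (one death rate for both pools, an identifiability-motivated
assumption); activation moves them to M_a at rate h with three additive
mechanisms — DAMP release proportional to the tumor-killing flux, antigen
mediated signalling proportional to F·C_E, and CD40–CD40L contact
β_C·M_a/(C+M_a)·C_E, a positive feedback that requires previously
activated macrophages. IL-6 follows dIL6/dt = σ_I + α M_a − δ_I IL6, so
absent activation it sits at the baseline σ_I/δ_I. There is no IL-6
feedback on activation (treated as second-order) and no other cytokines.

**Zero-limit rule.** Proliferation/growth terms (expander proliferation,
both tumor growth terms) are multiplied by an indicator (population ≥ 1
cell) evaluated inside the right-hand side. Death, killing and phenotype
transitions stay active, and the gate re-opens if influx repopulates the
compartment. This prevents regrowth from sub-cell numerical remnants
without making extinction irreversible by fiat.

**Universal constants.** K = 4.25e12 cells, θ = 1e−8 /day, C = 1e10
cells, M_a(0) = 0, C_E(0) = C_P(0) = 0; the infused dose enters C_I at the
dosing times (split regimens supported, e.g. 10/30/60% on days 0/1/3).
Unit conventions: 1 transgene copy/µg DNA = 1e4 cells; 1 cell/µL PB = 5e6
cells (5 L blood); 1 cell/µL BM = 5e8 cells (1% PB fraction); tumor cells
= WBC × %blasts with WBC defaulting to 4.25e10 (mean of the 2.0–6.5e10
range); CAR-T detection limit 25 copies/µg ≡ 2.5e5 cells.

## Numerics

LSODA (stiffness-switching) with rtol 1e−8 and atol 1e−6 cells (1e−8 ng/L
for IL-6) for presentation-quality runs; the fitting paths use rtol 1e−6
(layer 1) and 1e−5/1e−7 (cytokine screening/refinement) with
scale-appropriate atol, which changes objectives by far less than either
measurement noise or optimizer tolerances. Dose events and blocking-window
edges are hard integrator restarts with state jumps — never delta terms in
the RHS. Dense output on a 0.05-day grid for peak detection (peaks are
cited at ~1-day resolution, so this is comfortably oversampled); fitting
evaluates the solution only at observation times. Solver output is clipped
at zero; residual solver noise is below 1e−9 cells.

The activation-source decomposition (dM_a,j/dt = h_j M_i − δ_M M_a,j and
the cumulative integrals ∫h_j M_i dt) is integrated as six extra states of
the same solver run, so M_a1+M_a2+M_a3 = M_a holds to integrator tolerance
(observed ≤ 1e−12 relative) and the cumulative fractions need no post-hoc
quadrature.

## Phase segmentation and slope analysis

Log-slopes are centred finite differences of ln y on the dense grid
(pairwise differences on sampled records). CAR-T phases: distribution from
dosing to the first local minimum within 5 days; expansion to the global
peak; contraction until the log-slope first rises above half its most
negative post-peak value (the change-point from fast expander contraction
to slow persister decay); persistence thereafter. Tumor phases: transient
growth to the tumor maximum (often empty), shrinkage to the minimum, and a
response phase scored as regrowth when the series ends ≥ 3× above a
minimum that stayed ≥ 1 cell. The extremal slopes estimate (−μ_I, κ−μ_E,
−μ_E, −μ_P, ρ−γ, ρ) at first order; on noiseless cohorts the median
absolute relative error is a few percent (the persistence slope is the
weakest because contraction leaks into the late window).

The slope→parameter map supplies initial estimates: algebra for the six
slope combinations, 1-D root finding of η against the post-distribution
minimum, a bounded 2-D Nelder–Mead of (A, B) in log space against
(Cmax, Tmin), and a one-simulation linear update of ε against the
persistence level.

## Two-step estimation

Because the CAR-T/tumor equations are independent of the macrophage and
IL-6 states, the joint fit factorises exactly; the layer-1 optimum is
unaffected by any cytokine parameter.

**Layer 1.** Weighted least squares over the CAR-T and tumor series with
weights 1/max(observed)² per series; points below the CAR-T detection
limit excluded. Optimisation: adaptive Nelder–Mead in log10 parameter
space with box bounds, plus one fresh-simplex restart. The bounds of the
slope-dominant parameters (μ_I, κ, μ_E, μ_P) are narrowed per patient to
[est/4, est·4] around their slope estimates: the WLS objective has almost
no leverage on μ_P (persistence-phase values are ~1e−6 of the series
maximum under the 1/max² weighting), and without the data-informed box it
drifts to the global bound edge. Antigen-negative relapse records
additionally free g0 and T_N(0) (bounded above by the detection limit).

**Layer 2.** With the layer-1 trajectory frozen, only the 3-state
macrophage/IL-6 subsystem is integrated, driven by interpolants of C_E,
T_P, T_N — an order-of-magnitude speedup that is exact up to driver
interpolation. Fixed per patient: M_a(0)=0, IL6(0)=first observation,
σ_I = δ_I·min(IL6) (baseline steady state), C=1e10. The 8 free parameters
(σ_M, δ_M, δ_I, α, β_B, β_K, β_C, M_i(0)) are sampled log-uniformly
(n_mc = 1e4 by default) within bounds; the objective is
LR = ln Σ wᵢ (IL6(tᵢ)−IL6ᵢ)² with wᵢ = w0 + (1−w0)·IL6ᵢ/max(IL6), w0 =
0.15, which weights the peak ≈ 7× the baseline. The best n_refine tuples
— plus a grid of physics-informed structured starts (δ_I seeded from the
post-peak decline slope, α from the peak height over the activated pool,
β's scaled so the cumulative trigger integral is order one and the CD40
feedback rate is order one per day) — are refined by bounded trust-region
least squares on the weighted residual vector (log10 parameters,
tighter integrator tolerance for a clean numerical Jacobian). Plain
simplex refinement was rejected: the CD40 feedback creates a narrow
curved valley in which Nelder–Mead started 0.3 decades off the optimum
stalls several LR units short, while the trust-region method descends it
in seconds and routinely reaches LR below the generating parameters'
value. Bounds for δ_I, δ_M and α are additionally narrowed per patient
from the IL-6 decline slope (which lower-bounds both clearance rates) and
the peak height. One master seed drives sampling; repeated runs are
bit-identical.

**Identifiability.** The cytokine layer carries a near-exact scaling
degeneracy — M_i(0) → cM_i(0), σ_M → cσ_M, α → α/c leaves the IL-6 path
almost unchanged (broken only weakly through the CD40 saturation
M_a/(C+M_a)) — so α and β_C are individually sloppy against the pool
size while the products α·M_i(0) and β_C·M_i(0) are well determined
(tested to within 50%, typically ~10%). Reported per-parameter values
should be read with this in mind; the `top_fit_correlations` table over
the refined tuples makes the trade-offs visible per patient.

## Model comparison

Variants remove one or two activation mechanisms by structurally zeroing
the corresponding β (k = 8, 7, 6 free parameters; CD40-only is invalid
because the feedback cannot start from M_a(0)=0). Each variant is fitted
with the same budgets and seed stream; in addition, variants are fitted in
ascending complexity with each warm-started from its sub-variants' optima,
and a downward/upward polish pass projects super-variant optima into
reduced spaces and back. This guarantees at finite search budget the
nesting inequality LR(full) ≤ LR(reduced) that exact optimisation would
give, and makes AIC differences reflect model capacity rather than search
luck. Ranking is by AIC = 2k + n_d(1 + LR − ln n_d + ln 2π), ties broken
toward fewer parameters. With few IL-6 points (n_d ≈ 13) AIC sits in its
small-sample regime and spurious mechanisms — whose drivers are strongly
collinear in time — can win on noise; the variant-selection test therefore
uses a dense sampling schedule (n_d ≈ 35).

## Scenario engine

Counterfactuals re-simulate the calibrated patient with: every dose event
scaled; the initial tumor compartments scaled; or one activation
coefficient multiplied by a residual fraction inside a time window
(piecewise-constant, integrator restarts at the edges). Window stops given
relative to "the CAR-T peak" resolve against the REFERENCE simulation's
peak day — a clinical schedule cannot depend on the counterfactual's own
peak. Outcomes are reported as deltas against the unmodified reference
(IL-6 peak reduction %, peak-day shifts, Cmax and day-28/90 ratios).

## Virtual patients

Five archetypes (complete and partial responders, antigen-positive and
antigen-negative relapse, high-CRS) draw parameters log-uniformly from
ranges calibrated once so that noiseless cohorts reproduce the
qualitative clinical orderings: multiphasic CAR-T kinetics with peaks
around days 8–14 and 10–1000× expansion, IL-6 peaking 0–5 days before the
CAR-T peak and 0–2 days after the activated-macrophage peak, DAMP →
antigen → CD40 activation-peak sequence, antigen-negative relapse emerging
from below the detection limit within the 150-day analysis window.
A separate CD40-dominant recipe (`cd40_dominant_archetype`) places the
cytokine layer in the marginal-feedback regime — small trigger seeds,
sub-exponential CD40 amplification — where essentially all activation is
CD40-sourced and a 50% CD40 block reduces the IL-6 peak by tens of
percent; pool-exhaustion-limited regimes respond far more weakly to
blocking, which is itself an informative model behaviour.

Records are sampled on a clinical schedule (days 0,1,2,3,5,7,10,14,21,28,
45,60,90, extended for relapse archetypes), converted to reporting units,
censored at the detection limits (censored rows carry the limit), and
perturbed with multiplicative lognormal noise (default CV 20% CAR-T, 15%
tumor, 25% IL-6 — conventions, as qPCR/flow error models are not
standardised). Every patient regenerates bit-identically from its seed,
and the ground-truth manifest is the oracle for recovery experiments.

**What passing tests show — and don't.** The generator emulates the
statistical shape of clinical records, not real patients: noise is
independent across time points (no assay batch effects), schedules are
regular, unit conversions are exact, and the data-generating model is the
fitted model itself. Recovery and concordance results therefore
demonstrate internal consistency of the pipeline (no structural model
error), an upper bound on what real-data fits can achieve.

## Problem sizes

Default analysis sizes were chosen to characterise each property with
modest compute: 22-patient cohorts for slope concordance, 50 draws for
conservation, 3–4 noise-free plus 10 noisy patients for recovery, 8
patients for activation/blocking summaries, one patient × six variants at
n_mc = 300–500 for the nested-model check (the full default budget is
n_mc = 1e4, n_refine = 100).

## Known limitations

Single blood compartment (no marrow/tissue trafficking); one cytokine; no
IL-6 feedback on activation; no tocilizumab or antibody pharmacology
(blocks are abstract fractional reductions); the manual phase-endpoint
choices of expert annotators are replaced by a fixed change-point rule;
AIC (not AICc) with small n_d; per-parameter cytokine estimates are
sloppy along the pool-size degeneracy.
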