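"""Virtual patients with the statistical structure of clinical time courses.

Real CAR-T time courses combine multiphasic kinetics spanning several orders
of magnitude, sparse clinical sampling (dense in the first two weeks, then
monthly), heterogeneous reporting units (transgene copies/µg DNA or
cells/µL for CAR-T, %blasts for tumor burden, ng/L for IL-6), an assay
detection limit of 2.5e5 cells, and multiplicative measurement noise.  The
generator draws mechanistic parameters log-uniformly from archetype-specific
ranges calibrated so that noiseless cohorts reproduce the qualitative
orderings seen clinically (IL-6 peak 0-5 days before the CAR-T peak,
activated-macrophage peak 0-2 days before IL-6, DAMP -> antigen -> CD40
activation peak sequence, CD40 as the dominant cumulative source in the
high-CRS regime), then simulates, samples, converts units, censors and
perturbs.

Each patient regenerates bit-identically from its seed; the ground-truth
parameters travel with the patient and serve as the oracle for
parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_cli import CART_DETECTION_LIMIT, PatientTimecourse
from .model_core import (
    CartTumorParams,
    CytokineParams,
    DoseRegimen,
    ModelState,
    UnitContext,
    convert_units,
)
from .simulation import Trajectory, simulate

__all__ = ["PatientArchetype", "SyntheticPatient", "ARCHETYPES",
           "sample_parameters", "generate_patient", "generate_cohort"]

#: clinically-patterned sampling schedule, days (dense early, sparse late)
DEFAULT_SCHEDULE = (0, 1, 2, 3, 5, 7, 10, 14, 21, 28, 45, 60, 90)

#: default multiplicative lognormal noise, CV per series
DEFAULT_CV = {"cart": 0.20, "tumor": 0.15, "il6": 0.25}


@dataclass(frozen=True)
class PatientArchetype:
    """Sampling recipe for one response class.

    ``ranges`` maps parameter symbols to (lo, hi) for log-uniform draws.
    ``kappa`` is parameterised through the net expansion rate
    ``net_expansion`` = kappa - mu_E so every draw shows a rising expansion
    phase.  ``constraints`` are predicates re-drawn until satisfied.
    """

    label: str
    ranges: dict
    schedule: tuple = DEFAULT_SCHEDULE
    cv: dict = field(default_factory=lambda: dict(DEFAULT_CV))
    cart_unit: str = "copies/ug"
    tumor_unit: str = "%blasts"
    il6_unit: str = "ng/L"
    split_dose: bool = False
    antigen_negative: bool = False
    horizon: float = 90.0

    def __post_init__(self) -> None:
        if list(self.schedule) != sorted(self.schedule):
            raise ValueError("sampling schedule must be sorted")
        if any(v < 0 for v in self.cv.values()):
            raise ValueError("noise CV must be >= 0")
        for k, (lo, hi) in self.ranges.items():
            if not lo <= hi or lo <= 0:
                raise ValueError(f"empty or non-positive range for {k}")


_BASE_RANGES = {
    "dose": (5e7, 3e8),            # infused CAR-T cells
    "T_P0": (1e10, 6e10),          # initial antigen-positive burden
    "eta": (0.1, 0.6),
    "mu_I": (0.5, 1.5),
    "net_expansion": (0.6, 1.1),   # kappa - mu_E
    "mu_E": (0.25, 0.5),
    "epsilon": (3e-4, 3e-3),
    "mu_P": (0.005, 0.03),
    "rho": (0.05, 0.2),
    "gamma": (0.9, 1.4),
    "A": (1e8, 6e8),
    "B": (5e7, 5e8),
    # cytokine layer (CD40-dominant regime)
    "sigma_M": (3e7, 3e8),
    "delta_M": (0.1, 0.3),
    "delta_I": (1.0, 4.0),
    "alpha": (2e-8, 8e-8),
    "beta_K": (3e-12, 3e-11),
    "beta_B": (1e-12, 1e-11),
    "beta_C": (1e-9, 4e-9),
    "M_i0": (5e9, 2e10),
    "IL6_0": (2.0, 10.0),
}


def _with(base: dict, **over) -> dict:
    d = dict(base)
    d.update(over)
    return d


ARCHETYPES: dict = {
    "responder_CR": PatientArchetype(
        label="responder_CR",
        ranges=_with(_BASE_RANGES),
    ),
    "responder_PR": PatientArchetype(
        label="responder_PR",
        ranges=_with(_BASE_RANGES, gamma=(0.7, 1.0), rho=(0.05, 0.1),
                     B=(2e8, 1e9), net_expansion=(0.5, 0.8)),
        split_dose=True,
    ),
    "Ag+_relapse": PatientArchetype(
        label="Ag+_relapse",
        ranges=_with(_BASE_RANGES, gamma=(0.55, 0.75), rho=(0.18, 0.28),
                     B=(3e8, 1e9), net_expansion=(0.5, 0.7)),
        schedule=DEFAULT_SCHEDULE + (120, 150, 180),
        horizon=180.0,
    ),
    "Ag-_relapse": PatientArchetype(
        label="Ag-_relapse",
        ranges=_with(_BASE_RANGES, rho=(0.12, 0.22), g0=(0.02, 0.08),
                     T_N0=(1e5, 2.5e5)),
        schedule=DEFAULT_SCHEDULE + (120, 150),
        horizon=150.0,
        antigen_negative=True,
    ),
    "high_CRS": PatientArchetype(
        label="high_CRS",
        ranges=_with(_BASE_RANGES, gamma=(0.9, 1.2), T_P0=(2e10, 6e10),
                     mu_I=(0.7, 1.5), net_expansion=(0.9, 1.2),
                     eta=(0.08, 0.25), dose=(3e7, 8e7),
                     beta_C=(2e-9, 6e-9), alpha=(5e-8, 2e-7),
                     beta_K=(1e-11, 1e-10)),
    ),
}


def cd40_dominant_archetype() -> PatientArchetype:
    """A high-CRS variant in the marginal CD40-feedback regime.

    Triggers (DAMP, antigen) are small seeds and the CD40 loop amplifies
    sub-exponentially, so essentially all activation is CD40-sourced and the
    IL-6 peak responds strongly to fractional CD40 blocking — the regime
    used for activation-decomposition and intervention analyses.
    """
    return PatientArchetype(
        label="high_CRS",
        ranges=_with(ARCHETYPES["high_CRS"].ranges,
                     beta_K=(1e-15, 1e-14), beta_B=(3e-16, 3e-15),
                     beta_C=(4e-10, 1e-9), alpha=(3e-7, 1e-6),
                     delta_M=(0.1, 0.2), sigma_M=(1e7, 6e7),
                     M_i0=(5e9, 2e10)),
    )


@dataclass
class SyntheticPatient:
    """A virtual patient: ground truth plus the sampled, noisy record."""

    patient_id: str
    archetype: str
    seed: int
    params: CartTumorParams
    cytokine: CytokineParams
    init: ModelState
    regimen: DoseRegimen
    timecourse: PatientTimecourse
    extras: dict = field(default_factory=dict)   # dose, T_P0, T_N0, IL6_0 ...
    regenerate: bool = False

    def true_trajectory(self, grid_step: float = 0.05,
                        track_activation: bool = False,
                        horizon: float | None = None) -> Trajectory:
        """Re-simulate the noiseless ground truth."""
        return simulate(self.params, self.cytokine, self.init, self.regimen,
                        horizon=horizon or self.timecourse.horizon,
                        grid_step=grid_step, track_activation=track_activation)

    def truth_dict(self) -> dict:
        d = {**self.params.to_dict()}
        d.update({f"q_{k}": v for k, v in self.cytokine.to_dict().items()})
        d.update(self.extras)
        return d


def sample_parameters(archetype, seed: int):
    """Draw (CartTumorParams, CytokineParams, extras) for one patient.

    Draws are log-uniform within the archetype ranges; the responder
    constraint gamma > rho and the expansion constraint kappa > mu_E hold by
    construction of the ranges.
    """
    arch = ARCHETYPES[archetype] if isinstance(archetype, str) else archetype
    rng = np.random.default_rng(seed)

    def draw(name):
        lo, hi = arch.ranges[name]
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    vals = {k: draw(k) for k in arch.ranges}
    mu_E = vals["mu_E"]
    p = CartTumorParams(
        eta=vals["eta"], mu_I=vals["mu_I"], kappa=mu_E + vals["net_expansion"],
        mu_E=mu_E, epsilon=vals["epsilon"], theta=1e-8, mu_P=vals["mu_P"],
        rho=vals["rho"], K=4.25e12, gamma=vals["gamma"],
        A=vals["A"], B=vals["B"], g0=vals.get("g0", 0.0),
    )
    q = CytokineParams(
        sigma_M=vals["sigma_M"], delta_M=vals["delta_M"],
        sigma_I=vals["delta_I"] * vals["IL6_0"], delta_I=vals["delta_I"],
        alpha=vals["alpha"], beta_B=vals["beta_B"], beta_K=vals["beta_K"],
        beta_C=vals["beta_C"], C=1e10,
    )
    extras = {"dose": vals["dose"], "T_P0": vals["T_P0"],
              "T_N0": vals.get("T_N0", 0.0), "IL6_0": vals["IL6_0"],
              "M_i0": vals["M_i0"]}
    return p, q, extras


def _lognormal_factor(rng, cv: float, size) -> np.ndarray:
    if cv <= 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def generate_patient(archetype, seed: int, params=None,
                     patient_id: str | None = None) -> SyntheticPatient:
    """Simulate one virtual patient and sample it like a clinical record.

    ``params`` may supply a pre-drawn (CartTumorParams, CytokineParams,
    extras) triple; otherwise parameters are drawn from the archetype with
    the same seed.  The record is sampled on the archetype schedule, unit
    converted, noise-perturbed (multiplicative lognormal per series) and
    detection-censored: CAR-T below 2.5e5 cells and %blasts below 0.01 are
    reported censored at the limit.
    """
    arch = ARCHETYPES[archetype] if isinstance(archetype, str) else archetype
    rng = np.random.default_rng(np.random.SeedSequence([seed, 20250409]))
    if params is None:
        p, q, extras = sample_parameters(arch, seed)
    else:
        p, q, extras = params
    regimen = (DoseRegimen.split(extras["dose"]) if arch.split_dose
               else DoseRegimen.single(extras["dose"]))
    init = ModelState(T_P=extras["T_P0"], T_N=extras["T_N0"],
                      M_i=extras["M_i0"], IL6=extras["IL6_0"])
    traj = simulate(p, q, init, regimen, horizon=arch.horizon, grid_step=0.05)

    ctx = UnitContext()
    sched = np.array([d for d in arch.schedule if d <= arch.horizon], dtype=float)
    rows = []
    series_spec = [
        ("cart", traj.total_cart, arch.cart_unit),
        ("tumor", traj.total_tumor, arch.tumor_unit),
        ("il6", traj.column("IL6"), arch.il6_unit),
    ]
    for name, dense, unit in series_spec:
        truth = np.interp(sched, traj.t, dense)
        noisy = truth * _lognormal_factor(rng, arch.cv.get(name, 0.0), len(sched))
        for t, v in zip(sched, noisy):
            if name == "il6":
                rows.append({"series": name, "time": t, "value": v,
                             "unit": unit, "censored": False})
                continue
            cells = v
            if name == "cart" and cells < CART_DETECTION_LIMIT:
                rows.append({"series": name, "time": t,
                             "value": convert_units(CART_DETECTION_LIMIT,
                                                    "cells", unit, ctx),
                             "unit": unit, "censored": True})
                continue
            reported = convert_units(cells, "cells", unit, ctx)
            censored = name == "tumor" and unit == "%blasts" and reported < 0.01
            if censored:
                reported = 0.01
            rows.append({"series": name, "time": t, "value": reported,
                         "unit": unit, "censored": censored})

    data = pd.DataFrame(rows)
    pid = patient_id or f"{arch.label}-{seed}"
    tc = PatientTimecourse(
        patient_id=pid, data=data, regimen=regimen, disease="synthetic",
        unit_context=ctx, horizon=arch.horizon,
        initial_tumor_burden=extras["T_P0"],
        antigen_negative_relapse=arch.antigen_negative,
        meta={"archetype": arch.label, "seed": int(seed)},
    )
    n_cart_ok = int((~data[(data["series"] == "cart")]["censored"]).sum())
    n_tumor_ok = int((~data[(data["series"] == "tumor")]["censored"]).sum())
    patient = SyntheticPatient(
        patient_id=pid, archetype=arch.label, seed=int(seed), params=p,
        cytokine=q, init=init, regimen=regimen, timecourse=tc, extras=extras,
        regenerate=(n_cart_ok < 4 or n_tumor_ok < 2),
    )
    return patient


def generate_cohort(n: int, mix=None, seed: int = 0,
                    max_retries: int = 5) -> list:
    """Generate ``n`` patients with deterministic per-patient sub-seeds.

    ``mix`` maps archetype labels to fractions summing to 1 (default: the
    19-base + 6-antigen-negative composition, i.e. 76% / 24%).  Patients
    whose record collapses below the minimum usable points (regenerate flag)
    are re-drawn with fresh deterministic sub-seeds.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mix = mix or {"responder_CR": 0.40, "responder_PR": 0.18,
                  "Ag+_relapse": 0.18, "Ag-_relapse": 0.24}
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("mix fractions must sum to 1")
    labels = []
    # largest-remainder apportionment keeps counts deterministic
    quotas = {k: n * f for k, f in mix.items()}
    counts = {k: int(np.floor(v)) for k, v in quotas.items()}
    leftover = n - sum(counts.values())
    for k in sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True):
        if leftover <= 0:
            break
        counts[k] += 1
        leftover -= 1
    for k, c in counts.items():
        labels += [k] * c

    ss = np.random.SeedSequence(seed)
    cohort = []
    for i, label in enumerate(labels):
        for attempt in range(max_retries):
            sub = int(np.random.SeedSequence([seed, i, attempt]).generate_state(1)[0]
                      % (2 ** 31))
            patient = generate_patient(label, sub, patient_id=f"S{i:02d}-{label}")
            if not patient.regenerate:
                break
        cohort.append(patient)
    return cohort


def cohort_manifest(cohort) -> pd.DataFrame:
    """Ground-truth manifest: one row per patient with seeds and parameters."""
    rows = []
    for pt in cohort:
        row = {"patient_id": pt.patient_id, "archetype": pt.archetype,
               "seed": pt.seed}
        row.update(pt.truth_dict())
        rows.append(row)
    return pd.DataFrame(rows)
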