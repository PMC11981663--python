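"""Core model layer: states, parameters, right-hand sides and unit conversions.

The model couples three layers in a single 5 L blood compartment, with time in
days and cell populations as absolute counts:

1. CAR-T / antigen-positive tumor layer.  Three CAR-T phenotypes — injected
   ``C_I``, expander ``C_E`` and persister ``C_P`` — interact with
   antigen-positive tumor cells ``T_P``.  Phenotype switching is driven by the
   antigen-binding fraction ``F(T_P) = T_P/(A+T_P)``: injected cells activate
   into expanders at rate ``eta*F``, expanders proliferate at ``kappa*F`` and
   convert to persisters at ``epsilon*(1-F)``, persisters reactivate at
   ``theta*F``.  Tumor cells grow logistically (rate ``rho``, capacity ``K``)
   and are killed by expanders with a saturating (Holling type II) response
   ``gamma*C_E/(B+C_E)``.

2. Antigen-negative extension.  A second tumor compartment ``T_N`` shares the
   logistic crowding term ``1-(T_P+T_N)/K`` but, lacking the target antigen,
   is killed at only a fraction ``g0`` of the rate and does not feed the
   antigen-dependent CAR-T phenotype switching.

3. Macrophage / IL-6 layer.  Naive macrophages ``M_i`` (basal production
   ``sigma_M``, death ``delta_M``) become activated ``M_a`` at a
   state-dependent rate ``h`` combining three mechanisms: DAMP release from
   tumor killing, antigen-binding-mediated cytokine signalling by CAR-T cells,
   and contact-dependent CD40-CD40L engagement with already-activated
   macrophages.  Activated macrophages secrete IL-6 at rate ``alpha`` on top
   of an endogenous production ``sigma_I`` and first-order decay ``delta_I``.

A zero-limit rule suppresses proliferation/growth (never death, killing or
phenotype transitions) for any cell population below one cell, preventing
artificial regrowth from sub-cell remnants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict

import numpy as np

__all__ = [
    "CartTumorParams",
    "CytokineParams",
    "ModelState",
    "DoseRegimen",
    "UnitContext",
    "antigen_binding",
    "cart_tumor_rhs",
    "zero_limit",
    "activation_rate",
    "macrophage_rhs",
    "convert_units",
    "STATE_NAMES",
]

#: Canonical ordering of the full state vector.
STATE_NAMES = ("C_I", "C_E", "C_P", "T_P", "T_N", "M_i", "M_a", "IL6")


class InvalidParameterError(ValueError):
    """A parameter violates its domain constraint."""


class UnsupportedConversionError(ValueError):
    """Requested unit pair is not recognised."""


@dataclass
class CartTumorParams:
    """Rate constants of the CAR-T / tumor layer (rates in /day, sizes in cells).

    ``K`` (tumor carrying capacity) and ``theta`` (persister reactivation) are
    universal constants in the default analysis; the remaining ten parameters
    are patient-specific.  ``g0`` is the residual kill fraction on
    antigen-negative cells (bystander effect / endogenous TCR).
    """

    eta: float = 0.3       # activation of injected CAR-T, /day
    mu_I: float = 1.0      # injected decay (death + tissue distribution), /day
    kappa: float = 1.2     # expander proliferation, /day
    mu_E: float = 0.35     # expander depletion (death + exhaustion), /day
    epsilon: float = 1e-3  # persister formation, /day
    theta: float = 1e-8    # persister reactivation, /day (universal)
    mu_P: float = 0.01     # persister decay, /day
    rho: float = 0.15      # tumor growth, /day
    K: float = 4.25e12     # tumor carrying capacity, cells (universal)
    gamma: float = 1.0     # maximal kill rate, /day
    A: float = 1e9         # antigen-binding half-saturation, cells
    B: float = 1e7         # kill half-saturation, cells
    g0: float = 0.0        # antigen-negative kill fraction, dimensionless

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise InvalidParameterError(f"{f.name} must be finite, got {v}")
            if v < 0:
                raise InvalidParameterError(f"{f.name} must be >= 0, got {v}")
        if self.K <= 0 or self.A <= 0 or self.B <= 0:
            raise InvalidParameterError("K, A and B must be strictly positive")
        if not 0.0 <= self.g0 <= 1.0:
            raise InvalidParameterError(f"g0 must lie in [0, 1], got {self.g0}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CartTumorParams":
        return cls(**{f.name: d[f.name] for f in fields(cls) if f.name in d})


@dataclass
class CytokineParams:
    """Rate constants of the macrophage / IL-6 layer.

    IL-6 concentrations are in ng/L (equivalently pg/mL).  ``beta_K``,
    ``beta_B`` and ``beta_C`` weight the DAMP, antigen-binding and CD40
    activation mechanisms; ``C`` is the CD40 half-saturation in cells
    (universal constant, 1e10).
    """

    sigma_M: float = 3e9   # naive macrophage production, cells/day
    delta_M: float = 0.3   # macrophage death, /day
    sigma_I: float = 10.0  # endogenous IL-6 production, ng/L/day
    delta_I: float = 2.0   # IL-6 decay, /day
    alpha: float = 1e-6    # IL-6 release per activated macrophage, ng/L/(cell day)
    beta_B: float = 0.0    # antigen-binding activation coefficient
    beta_K: float = 0.0    # DAMP activation coefficient
    beta_C: float = 0.0    # CD40-contact activation coefficient
    C: float = 1e10        # CD40 half-saturation, cells (universal)

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{f.name} must be finite and >= 0, got {v}")
        if self.C <= 0:
            raise InvalidParameterError("C must be strictly positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CytokineParams":
        return cls(**{f.name: d[f.name] for f in fields(cls) if f.name in d})


@dataclass
class ModelState:
    """Full model state: cells in absolute counts, IL-6 in ng/L."""

    C_I: float = 0.0
    C_E: float = 0.0
    C_P: float = 0.0
    T_P: float = 0.0
    T_N: float = 0.0
    M_i: float = 0.0
    M_a: float = 0.0
    IL6: float = 0.0

    def __post_init__(self) -> None:
        for name in STATE_NAMES:
            if getattr(self, name) < 0:
                raise ValueError(f"state component {name} must be >= 0")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ModelState":
        return cls(**dict(zip(STATE_NAMES, np.asarray(arr, dtype=float))))


@dataclass
class DoseRegimen:
    """Dosing schedule: (time in days, cell count) pairs added to ``C_I``.

    The split-dose convention used for CLL patients gives 10% on day 0, 30% on
    day 1 and 60% on day 3.
    """

    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [t for t, _ in self.events]
        if any(t < 0 for t in times):
            raise ValueError("dose times must be >= 0")
        if times != sorted(times):
            raise ValueError("dose events must be ordered in time")
        if any(c <= 0 for _, c in self.events):
            raise ValueError("dose counts must be > 0")

    @property
    def total_dose(self) -> float:
        return float(sum(c for _, c in self.events))

    def scaled(self, factor: float) -> "DoseRegimen":
        """Return a regimen with every dose multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("dose scale factor must be > 0")
        return DoseRegimen([(t, c * factor) for t, c in self.events])

    @classmethod
    def single(cls, dose: float, time: float = 0.0) -> "DoseRegimen":
        return cls([(time, dose)])

    @classmethod
    def split(cls, total: float,
              fractions=((0.0, 0.10), (1.0, 0.30), (3.0, 0.60))) -> "DoseRegimen":
        return cls([(t, total * f) for t, f in fractions])


@dataclass
class UnitContext:
    """Conversion constants between clinical reporting units and model units.

    ``copies_per_ug_factor``: 1 CAR-T transgene copy/µg DNA corresponds to
    1e4 circulating CAR-T cells.  ``blood_volume`` of 5 L gives
    1 cell/µL PB = 5e6 cells; bone-marrow concentrations are scaled by the
    peripheral-blood fraction (1%), i.e. 1 cell/µL BM = 5e8 cells in PB.
    %blasts converts via tumor cells = WBC x %blasts with WBC the mean of
    ``wbc_range``.
    """

    blood_volume: float = 5.0               # L
    copies_per_ug_factor: float = 1e4       # cells per (copy/µg DNA)
    pb_fraction_of_bm: float = 0.01         # PB cells per BM cell
    wbc_range: tuple = (2.0e10, 6.5e10)     # total WBC, cells

    def __post_init__(self) -> None:
        if self.blood_volume <= 0 or self.copies_per_ug_factor <= 0:
            raise InvalidParameterError("blood_volume and copies_per_ug_factor must be > 0")
        if not 0 < self.pb_fraction_of_bm <= 1:
            raise InvalidParameterError("pb_fraction_of_bm must lie in (0, 1]")
        if min(self.wbc_range) <= 0:
            raise InvalidParameterError("wbc_range must be positive")

    @property
    def wbc_mean(self) -> float:
        return 0.5 * (self.wbc_range[0] + self.wbc_range[1])

    @property
    def cells_per_uL_pb(self) -> float:
        # 5 L = 5e6 µL, so 1 cell/µL PB = 5e6 absolute cells
        return self.blood_volume * 1e6


def antigen_binding(T_P: float, A: float) -> float:
    """Antigen-receptor binding fraction F(T_P) = T_P/(A + T_P) in [0, 1]."""
    if A <= 0:
        raise InvalidParameterError(f"half-saturation A must be > 0, got {A}")
    T_P = np.maximum(T_P, 0.0)
    return T_P / (A + T_P)


def zero_limit(state) -> np.ndarray:
    """Growth-gating flags for (C_E, C_P, T_P, T_N): 1.0 if >= 1 cell else 0.

    Only proliferation/growth terms are multiplied by these gates; death,
    killing and phenotype-transition terms remain active, so a population can
    be repopulated by influx and resume growth.
    """
    if isinstance(state, ModelState):
        vals = (state.C_E, state.C_P, state.T_P, state.T_N)
    else:
        arr = np.asarray(state, dtype=float)
        vals = (arr[1], arr[2], arr[3], arr[4])
    return np.array([1.0 if v >= 1.0 else 0.0 for v in vals])


def cart_tumor_rhs(state, p: CartTumorParams, gated: bool = True) -> np.ndarray:
    """Time derivatives of (C_I, C_E, C_P, T_P, T_N).

    ``state`` may be a ModelState or any array whose first five components are
    (C_I, C_E, C_P, T_P, T_N).  The antigen-binding fraction F is evaluated on
    T_P only; T_N enters through the shared logistic crowding and the
    g0-reduced killing.  With ``gated`` the zero-limit rule multiplies the
    expander proliferation and both tumor growth terms by an indicator
    (population >= 1 cell).
    """
    arr = state.to_array() if isinstance(state, ModelState) else np.asarray(state, dtype=float)
    if np.any(arr[:5] < 0):
        raise ValueError("state components must be non-negative")
    C_I, C_E, C_P, T_P, T_N = arr[:5]

    F = antigen_binding(T_P, p.A)
    kill = p.gamma * C_E / (p.B + C_E)           # per-tumor-cell kill rate
    crowd = 1.0 - (T_P + T_N) / p.K

    if gated:
        g_CE, _, g_TP, g_TN = zero_limit(arr)
    else:
        g_CE = g_TP = g_TN = 1.0

    dC_I = -p.eta * F * C_I - p.mu_I * C_I
    dC_E = (p.eta * F * C_I + g_CE * p.kappa * F * C_E
            - p.epsilon * (1.0 - F) * C_E + p.theta * F * C_P - p.mu_E * C_E)
    dC_P = p.epsilon * (1.0 - F) * C_E - p.theta * F * C_P - p.mu_P * C_P
    dT_P = g_TP * p.rho * T_P * crowd - kill * T_P
    dT_N = g_TN * p.rho * T_N * crowd - p.g0 * kill * T_N
    return np.array([dC_I, dC_E, dC_P, dT_P, dT_N])


def activation_rate(C_E: float, T_P: float, T_N: float, M_a: float,
                    q: CytokineParams, p: CartTumorParams):
    """Macrophage activation rate h and its mechanism components, /day.

    Returns ``(h_total, h_DAMP, h_antigen, h_CD40)`` with

    - DAMP release from tumor killing:  beta_K * C_E/(B+C_E) * (T_P + g0*T_N)
    - antigen-binding signalling:       beta_B * T_P/(A+T_P) * C_E
    - CD40-CD40L contact:               beta_C * M_a/(C+M_a) * C_E
    """
    C_E = max(C_E, 0.0)
    M_a = max(M_a, 0.0)
    h_damp = q.beta_K * (C_E / (p.B + C_E)) * (max(T_P, 0.0) + p.g0 * max(T_N, 0.0))
    h_antigen = q.beta_B * antigen_binding(T_P, p.A) * C_E
    h_cd40 = q.beta_C * (M_a / (q.C + M_a)) * C_E
    return h_damp + h_antigen + h_cd40, h_damp, h_antigen, h_cd40


def macrophage_rhs(state, q: CytokineParams, h: float) -> np.ndarray:
    """Time derivatives of (M_i, M_a, IL6) given total activation rate ``h``."""
    if isinstance(state, ModelState):
        M_i, M_a, IL6 = state.M_i, state.M_a, state.IL6
    else:
        arr = np.asarray(state, dtype=float)
        M_i, M_a, IL6 = arr[-3], arr[-2], arr[-1]
    if min(M_i, M_a) < 0:
        raise ValueError("macrophage states must be non-negative")
    dM_i = q.sigma_M - h * M_i - q.delta_M * M_i
    dM_a = h * M_i - q.delta_M * M_a
    dIL6 = q.sigma_I + q.alpha * M_a - q.delta_I * IL6
    return np.array([dM_i, dM_a, dIL6])


# unit label -> factor converting one unit to absolute cells (ctx-dependent)
def _cells_factor(unit: str, ctx: UnitContext) -> float:
    table = {
        "cells": 1.0,
        "copies/ug": ctx.copies_per_ug_factor,
        "cells/uL_pb": ctx.cells_per_uL_pb,
        "cells/uL_bm": ctx.cells_per_uL_pb / ctx.pb_fraction_of_bm,
        "%blasts": ctx.wbc_mean / 100.0,
    }
    try:
        return table[unit]
    except KeyError:
        raise UnsupportedConversionError(
            f"unknown unit {unit!r}; supported: {sorted(table)}") from None


#: Aliases accepted for unit labels in input files.
UNIT_ALIASES = {
    "cells": "cells", "cell": "cells", "absolute": "cells",
    "copies/ug": "copies/ug", "copies/ug dna": "copies/ug",
    "copies/µg": "copies/ug", "copies/µg dna": "copies/ug",
    "cells/ul": "cells/uL_pb", "cells/ul_pb": "cells/uL_pb",
    "cells/ul pb": "cells/uL_pb", "cells/µl": "cells/uL_pb",
    "cells/ul_bm": "cells/uL_bm", "cells/ul bm": "cells/uL_bm",
    "%blasts": "%blasts", "percent_blasts": "%blasts", "pct_blasts": "%blasts",
    "ng/l": "ng/L", "ng/L": "ng/L", "pg/ml": "ng/L",
}


def normalize_unit(unit: str) -> str:
    key = unit.strip().lower().replace("µ", "u")
    try:
        return UNIT_ALIASES[key]
    except KeyError:
        raise UnsupportedConversionError(f"unknown unit {unit!r}") from None


def convert_units(value: float, from_unit: str, to_unit: str,
                  ctx: UnitContext | None = None) -> float:
    """Exact linear conversion between recognised cell-count units.

    Supported units: ``cells`` (absolute count), ``copies/ug`` (transgene
    copies per µg DNA), ``cells/uL_pb``, ``cells/uL_bm`` and ``%blasts``
    (converted through the mean WBC count).  IL-6 units ``ng/L`` and
    ``pg/mL`` are identical and pass through unchanged.
    """
    ctx = ctx or UnitContext()
    fu, tu = normalize_unit(from_unit), normalize_unit(to_unit)
    if fu == tu:
        return float(value)
    if "ng/L" in (fu, tu):
        raise UnsupportedConversionError(
            f"cannot convert between {from_unit!r} and {to_unit!r}")
    return float(value) * _cells_factor(fu, ctx) / _cells_factor(tu, ctx)
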