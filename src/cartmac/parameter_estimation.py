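"""Two-step parameter estimation from patient time courses.

Because the CAR-T/tumor equations do not depend on the macrophage or IL-6
states, a joint fit factorises exactly into two steps: (1) a slope-informed,
bounded Nelder-Mead weighted-least-squares fit of the ten patient-specific
CAR-T/tumor parameters (twelve for antigen-negative relapse, adding g0 and
T_N(0)); (2) with that layer frozen, a Monte-Carlo global search over the
eight free macrophage/IL-6 parameters followed by local refinement of the
best tuples, minimising LR = ln(weighted SSE of IL-6).  IL-6 weights are
w_i = w0 + (1-w0) * IL6_i / max_j IL6_j so the peak carries full weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares, minimize

from .io_cli import PatientTimecourse
from .model_core import CartTumorParams, CytokineParams, ModelState
from .phase_analysis import (
    PhaseSegmentation,
    segment_cart_phases,
    segment_tumor_phases,
    slope_parameter_map,
)
from .simulation import IntegrationError, Trajectory, TrajectoryObservables, simulate

__all__ = [
    "FitConfig", "FitResult", "DEFAULT_BOUNDS",
    "wls_objective_layer1", "fit_layer1",
    "il6_weights", "lr_objective", "fix_cytokine_params",
    "fit_cytokine_layer", "top_fit_correlations",
    "PERFECT_FIT_LR", "LAYER1_FREE", "LAYER2_FREE",
]

#: sentinel returned when the weighted IL-6 SSE vanishes (ln 0 = -inf)
PERFECT_FIT_LR = -1e10

LAYER1_FREE = ("mu_I", "kappa", "mu_E", "mu_P", "gamma", "rho",
               "eta", "epsilon", "A", "B")
LAYER2_FREE = ("sigma_M", "delta_M", "delta_I", "alpha",
               "beta_B", "beta_K", "beta_C", "M_i0")

#: Documented placeholder ranges spanning biologically plausible magnitudes;
#: decay rates in /day, cell scales in cells, betas in mechanism-specific
#: units.  Users may override any entry through FitConfig.
DEFAULT_BOUNDS: dict = {
    "mu_I": (1e-3, 10.0), "kappa": (1e-2, 10.0), "mu_E": (1e-3, 10.0),
    "mu_P": (1e-4, 1.0), "gamma": (1e-2, 10.0), "rho": (0.01, 1.0),
    "eta": (1e-3, 10.0), "epsilon": (1e-6, 0.5),
    "A": (1e4, 1e10), "B": (1e4, 1e10),
    "g0": (1e-4, 0.5), "T_N0": (1.0, 2.5e5),
    # cytokine layer: caps chosen so activation rates h stay below ~10/day
    # at physiological cell numbers (C_E ~ 1e10, tumor ~ 1e11)
    "sigma_M": (1e6, 1e9), "delta_M": (0.01, 2.0), "delta_I": (0.1, 20.0),
    "alpha": (1e-9, 1e-6), "beta_B": (1e-13, 1e-9),
    "beta_K": (1e-13, 1e-9), "beta_C": (1e-11, 1e-7),
    "M_i0": (1e9, 1e11),
}


@dataclass
class FitConfig:
    """Estimation settings: bounds, IL-6 weight floor, search budgets, seed."""

    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    w0: float = 0.15            # IL-6 weight floor
    n_mc: int = 10_000          # Monte-Carlo tuples for the cytokine layer
    n_refine: int = 100         # best tuples passed to local refinement
    seed: int = 0
    xatol: float = 1e-4         # Nelder-Mead tolerance in log10-parameter space
    fatol: float = 1e-12
    maxiter: int = 1200
    refine_maxiter: int = 600
    narrow_il6_bounds: bool = True   # per-patient bounds from the IL-6 shape
    sim_rtol: float = 1e-6
    sim_atol: float = 1.0

    def __post_init__(self) -> None:
        for k, (lo, hi) in self.bounds.items():
            # lo == hi pins a parameter at a point
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid bounds for {k}: ({lo}, {hi})")
        if not 0 < self.w0 <= 1:
            raise ValueError("w0 must lie in (0, 1]")
        if self.n_refine > self.n_mc:
            raise ValueError("n_refine must not exceed n_mc")


@dataclass
class FitResult:
    """Outcome of one estimation step."""

    params: dict                    # all parameter values (free + fixed)
    free_names: tuple               # which of them were optimised
    objective: float                # WLS (layer 1) or LR (layer 2)
    layer: int
    aic: float = np.nan
    residuals: pd.DataFrame | None = None
    converged: bool = True
    iterations: int = 0
    nfev: int = 0
    seed: int | None = None
    fixed: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    trace: list = field(default_factory=list)        # best-so-far objective
    refined: list = field(default_factory=list)      # (params, LR) of refined tuples

    @property
    def cart_tumor_params(self) -> CartTumorParams:
        keys = [f for f in CartTumorParams.__dataclass_fields__]
        return CartTumorParams(**{k: self.params[k] for k in keys if k in self.params})

    @property
    def cytokine_params(self) -> CytokineParams:
        keys = [f for f in CytokineParams.__dataclass_fields__]
        return CytokineParams(**{k: self.params[k] for k in keys if k in self.params})

    def to_dict(self) -> dict:
        return {
            "params": self.params, "free_names": list(self.free_names),
            "objective": self.objective, "layer": self.layer, "aic": self.aic,
            "converged": self.converged, "iterations": self.iterations,
            "nfev": self.nfev, "seed": self.seed, "fixed": self.fixed,
            "flags": self.flags,
        }


# ---------------------------------------------------------------------------
# layer 1: CAR-T / tumor WLS

def _layer1_sim(tc: PatientTimecourse, p: CartTumorParams, T_N0: float,
                t_need: np.ndarray, cfg: FitConfig) -> Trajectory:
    init = ModelState(T_P=tc.T0, T_N=T_N0)
    horizon = max(float(np.max(t_need)), max(t for t, _ in tc.regimen.events) + 1.0)
    return simulate(p, init=init, regimen=tc.regimen, horizon=horizon,
                    rtol=cfg.sim_rtol, atol=cfg.sim_atol, t_grid=t_need)


def _layer1_data(tc: PatientTimecourse):
    t_c, y_c = tc.series("cart")
    keep = y_c >= tc.detection_limit_cart
    t_c, y_c = t_c[keep], y_c[keep]
    t_t, y_t = tc.series("tumor")
    keep = y_t > 0
    t_t, y_t = t_t[keep], y_t[keep]
    if len(y_c) < 3 or len(y_t) < 1:
        raise ValueError("need at least 3 CAR-T and 1 tumor point above detection")
    return t_c, y_c, t_t, y_t


def wls_objective_layer1(tc: PatientTimecourse, p: CartTumorParams,
                         T_N0: float = 0.0,
                         cfg: FitConfig | None = None,
                         return_residuals: bool = False):
    """Weighted least-squares objective of the CAR-T/tumor layer.

    Sum over both series of squared residuals, each series weighted by the
    inverse square of its maximum observed value; points below the CAR-T
    detection limit are excluded.
    """
    cfg = cfg or FitConfig()
    t_c, y_c, t_t, y_t = _layer1_data(tc)
    t_need = np.unique(np.concatenate([t_c, t_t]))
    try:
        traj = _layer1_sim(tc, p, T_N0, t_need, cfg)
    except IntegrationError:
        return (np.inf, None) if return_residuals else np.inf
    sim_c = np.interp(t_c, traj.t, traj.total_cart)
    sim_t = np.interp(t_t, traj.t, traj.total_tumor)
    w_c = 1.0 / np.max(y_c) ** 2
    w_t = 1.0 / np.max(y_t) ** 2
    res_c = sim_c - y_c
    res_t = sim_t - y_t
    value = float(w_c * np.sum(res_c ** 2) + w_t * np.sum(res_t ** 2))
    if not return_residuals:
        return value
    resid = pd.DataFrame({
        "series": ["cart"] * len(t_c) + ["tumor"] * len(t_t),
        "time": np.concatenate([t_c, t_t]),
        "observed": np.concatenate([y_c, y_t]),
        "simulated": np.concatenate([sim_c, sim_t]),
        "residual": np.concatenate([res_c, res_t]),
    })
    return value, resid


def observed_shape_features(tc: PatientTimecourse):
    """Segment the sampled series and extract the shape features the
    slope-parameter mapping needs (peak, post-distribution minimum, tumor
    minimum)."""
    t_c, y_c, t_t, y_t = _layer1_data(tc)
    seg = segment_cart_phases(t_c, y_c).merge(segment_tumor_phases(t_t, y_t))
    i_peak = int(np.argmax(y_c))
    early = t_c <= 5.0
    cmin_idx = int(np.argmin(y_c[early])) if early.any() else 0
    i_tmin = int(np.argmin(y_t))
    obs = TrajectoryObservables(
        cmax=float(y_c[i_peak]), cmax_day=float(t_c[i_peak]),
        cmin=float(y_c[early][cmin_idx]) if early.any() else np.nan,
        cmin_day=float(t_c[early][cmin_idx]) if early.any() else np.nan,
        tmin=float(y_t[i_tmin]), tmin_day=float(t_t[i_tmin]),
    )
    return seg, obs


def _clip_to_bounds(value: float, lo: float, hi: float) -> float:
    # keep strictly inside so log10 start vertices stay feasible
    span = hi / lo
    return float(np.clip(value, lo * span ** 0.001, hi / span ** 0.001))


def fit_layer1(tc: PatientTimecourse, cfg: FitConfig | None = None) -> FitResult:
    """Slope-informed bounded Nelder-Mead fit of the CAR-T/tumor layer.

    Free parameters: (mu_I, kappa, mu_E, mu_P, gamma, rho, eta, epsilon, A,
    B); for antigen-negative relapse patients additionally g0 and T_N(0)
    (the latter bounded above by the detection limit unless overridden).
    K and theta are universal constants.  Optimisation runs in log10
    parameter space.
    """
    cfg = cfg or FitConfig()
    seg, obs = observed_shape_features(tc)
    p0, flags = slope_parameter_map(
        seg, obs, tc.dose, tc.regimen, T0=tc.T0, horizon=tc.horizon)

    free = list(LAYER1_FREE)
    if tc.antigen_negative_relapse:
        free += ["g0", "T_N0"]
    start = {k: getattr(p0, k) for k in LAYER1_FREE}
    start["g0"] = 0.05
    start["T_N0"] = min(1e4, cfg.bounds["T_N0"][1])

    # the observed phase slopes pin the dominant decay/expansion rates;
    # narrow their bounds around the slope estimates so parameters with
    # little residual leverage (mu_P above all) cannot drift to the box edge
    bounds = dict(cfg.bounds)
    slope_informed = {"mu_I": seg.m_D, "mu_E": seg.m_C,
                      "mu_P": seg.m_Pst, "kappa": seg.m_E}
    for name, slope in slope_informed.items():
        if np.isfinite(slope):
            lo, hi = bounds[name]
            est = start[name]
            bounds[name] = (max(lo, est / 4.0), min(hi, est * 4.0))

    bounds_log, x0 = [], []
    for name in free:
        lo, hi = bounds[name]
        bounds_log.append((np.log10(lo), np.log10(hi)))
        x0.append(np.log10(_clip_to_bounds(start[name], lo, hi)))

    trace = []

    def unpack(x):
        vals = {n: 10.0 ** xi for n, xi in zip(free, x)}
        T_N0 = vals.pop("T_N0", 0.0)
        g0 = vals.pop("g0", 0.0)
        p = CartTumorParams(theta=1e-8, K=4.25e12, g0=g0, **vals)
        return p, T_N0

    def objective(x):
        p, T_N0 = unpack(x)
        val = wls_objective_layer1(tc, p, T_N0, cfg)
        if not np.isfinite(val):
            val = 1e12
        trace.append(min(val, trace[-1]) if trace else val)
        return val

    opts = {"adaptive": True, "xatol": cfg.xatol, "fatol": cfg.fatol,
            "maxiter": cfg.maxiter, "maxfev": 3 * cfg.maxiter}
    res = minimize(objective, x0, method="Nelder-Mead", bounds=bounds_log,
                   options=opts)
    # a fresh simplex around the first optimum escapes premature collapse
    res2 = minimize(objective, res.x, method="Nelder-Mead", bounds=bounds_log,
                    options={**opts, "maxiter": cfg.maxiter // 2})
    if res2.fun < res.fun:
        res = res2
    p_best, T_N0_best = unpack(res.x)
    value, resid = wls_objective_layer1(tc, p_best, T_N0_best, cfg,
                                        return_residuals=True)
    params = p_best.to_dict()
    params["T_N0"] = T_N0_best
    return FitResult(
        params=params, free_names=tuple(free), objective=value, layer=1,
        residuals=resid, converged=bool(res.success), iterations=res.nit,
        nfev=res.nfev, seed=cfg.seed,
        fixed={"K": 4.25e12, "theta": 1e-8, "T_P0": tc.T0},
        flags=flags + ([] if res.success else ["layer-1 fit did not converge"]),
        trace=trace,
    )


# ---------------------------------------------------------------------------
# layer 2: macrophage / IL-6

def il6_weights(il6_values, w0: float = 0.15) -> np.ndarray:
    """Peak-emphasising weights w_i = w0 + (1-w0) * IL6_i / max_j IL6_j."""
    v = np.asarray(il6_values, dtype=float)
    m = np.max(v) if len(v) else 0.0
    if m <= 0:
        raise ValueError("IL-6 series must contain a positive value")
    return w0 + (1.0 - w0) * v / m


def lr_objective(il6_obs, il6_sim, w0: float = 0.15) -> float:
    """LR = ln( sum_i w_i (IL6_sim(t_i) - IL6_i)^2 ).

    A vanishing weighted SSE (perfect fit) returns the PERFECT_FIT_LR
    sentinel instead of -inf.
    """
    w = il6_weights(il6_obs, w0)
    sse = float(np.sum(w * (np.asarray(il6_sim, dtype=float)
                            - np.asarray(il6_obs, dtype=float)) ** 2))
    if sse == 0.0:
        return PERFECT_FIT_LR
    return float(np.log(sse))


def fix_cytokine_params(tc: PatientTimecourse) -> dict:
    """Per-patient fixed quantities of the cytokine layer.

    M_a(0) = 0; IL6(0) = first observed value; sigma_I is eliminated through
    sigma_I = delta_I * min_i IL6_i (baseline steady state bounds the series
    minimum from below); C = 1e10 cells.
    """
    t_i, y_i = tc.series("il6")
    if len(y_i) == 0:
        raise ValueError("timecourse has no IL-6 points")
    return {"M_a0": 0.0, "IL6_0": float(y_i[np.argmin(t_i)]),
            "il6_min": float(np.min(y_i)), "C": 1e10}


def _layer1_drivers(tc: PatientTimecourse, layer1: FitResult,
                    horizon: float, cfg: FitConfig):
    """Dense layer-1 solution and interpolants for (C_E, T_P, T_N)."""
    p = layer1.cart_tumor_params
    init = ModelState(T_P=layer1.fixed.get("T_P0", tc.T0),
                      T_N=layer1.params.get("T_N0", 0.0))
    traj = simulate(p, init=init, regimen=tc.regimen, horizon=horizon,
                    grid_step=0.1, rtol=cfg.sim_rtol, atol=cfg.sim_atol)
    return traj, p


def simulate_cytokine_given(drivers: Trajectory, p: CartTumorParams,
                            qvals: dict, fixed: dict, t_out,
                            rtol: float = 1e-5) -> np.ndarray:
    """Integrate the 3-state macrophage/IL-6 subsystem driven by a frozen
    CAR-T/tumor solution; returns IL-6 at ``t_out``.

    Exactness of the two-step split rests on the upper layers being
    independent of (M_i, M_a, IL6).
    """
    td = drivers.t
    CE, TP, TN = drivers.column("C_E"), drivers.column("T_P"), drivers.column("T_N")
    delta_I = qvals["delta_I"]
    sigma_I = delta_I * fixed["il6_min"]
    bB, bK, bC = qvals["beta_B"], qvals["beta_K"], qvals["beta_C"]
    sM, dM, alpha = qvals["sigma_M"], qvals["delta_M"], qvals["alpha"]
    C = fixed["C"]
    A, B, g0 = p.A, p.B, p.g0

    # one shared index lookup per step instead of three np.interp calls
    t0d, dt_inv, n_last = td[0], 1.0 / (td[1] - td[0]), len(td) - 1
    uniform = np.allclose(np.diff(td), td[1] - td[0], rtol=1e-6)

    def _at(t):
        if uniform:
            x = (t - t0d) * dt_inv
            i = min(int(x), n_last - 1)
            w = x - i
        else:
            i = min(int(np.searchsorted(td, t) or 1) - 1, n_last - 1)
            w = (t - td[i]) / (td[i + 1] - td[i])
        w = 0.0 if w < 0.0 else (1.0 if w > 1.0 else w)
        return (CE[i] + w * (CE[i + 1] - CE[i]),
                TP[i] + w * (TP[i + 1] - TP[i]),
                TN[i] + w * (TN[i + 1] - TN[i]))

    def rhs(t, y):
        M_i = y[0] if y[0] > 0.0 else 0.0
        M_a = y[1] if y[1] > 0.0 else 0.0
        IL6 = y[2]
        ce, tp, tn = _at(t)
        h = (bK * (ce / (B + ce)) * (tp + g0 * tn)
             + bB * (tp / (A + tp)) * ce
             + bC * (M_a / (C + M_a)) * ce)
        return (sM - h * M_i - dM * M_i,
                h * M_i - dM * M_a,
                sigma_I + alpha * M_a - delta_I * IL6)

    t_out = np.asarray(t_out, dtype=float)
    y0 = (qvals["M_i0"], fixed["M_a0"], fixed["IL6_0"])
    t_end = float(max(t_out[-1], 1e-6))
    t_eval = t_out[t_out > 0]
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA",
                    t_eval=np.unique(t_eval), rtol=rtol,
                    atol=[1e3, 1e3, 1e-4])
    if not sol.success:
        raise IntegrationError(f"cytokine subsystem failed: {sol.message}")
    il6 = np.interp(t_out, np.concatenate([[0.0], sol.t]),
                    np.concatenate([[fixed["IL6_0"]], sol.y[2]]))
    return il6


def narrowed_il6_bounds(t_i, y_i, bounds: dict) -> dict:
    """Per-patient bound narrowing from the shape of the IL-6 series.

    After the peak the IL-6 concentration relaxes as a sum of exponentials
    with rates delta_I and delta_M (the decaying activated-macrophage
    source), so the observed decline slope cannot exceed either rate: both
    receive a data-informed lower bound.  The peak height above baseline,
    alpha * M_a,peak / delta_I at quasi-steady state with M_a,peak between
    1e8 cells and the upper naive-pool bound, brackets alpha.
    """
    out = dict(bounds)
    ipk = int(np.argmax(y_i))
    post = y_i[ipk:] - 0.99 * np.min(y_i)
    if len(post) >= 3 and np.all(post > 0):
        slopes = np.diff(np.log(post)) / np.diff(t_i[ipk:])
        m_dec = abs(float(np.min(slopes)))
        lo, hi = out["delta_I"]
        out["delta_I"] = (min(max(0.5 * m_dec, lo), hi / 10), hi)
        lo, hi = out["delta_M"]
        out["delta_M"] = (min(max(0.3 * m_dec, lo), hi / 10), hi)
    dpk = float(np.max(y_i) - np.min(y_i))
    if dpk > 0:
        lo, hi = out["alpha"]
        a_lo = out["delta_I"][0] * dpk / out["M_i0"][1]
        a_hi = out["delta_I"][1] * dpk / 1e8
        out["alpha"] = (min(max(a_lo, lo), hi / 10), max(min(a_hi, hi), lo * 10))
    return out


def _structured_starts(drivers: Trajectory, p: CartTumorParams, fixed: dict,
                       t_i, y_i, bounds: dict, names) -> list:
    """Physics-informed candidate tuples for the cytokine-layer search.

    Mirrors the slope-informed layer-1 initialisation: the IL-6 decline
    slope seeds delta_I; the peak height above baseline ties alpha to the
    activated pool; the activation coefficients are scaled so the cumulative
    trigger integral up to the IL-6 peak is order one and the CD40 feedback
    growth rate is order one per day.  A small combinatorial grid over the
    discrete choices is returned; callers keep whichever evaluate best.
    """
    t_pk = float(t_i[int(np.argmax(y_i))])
    dpk = float(np.max(y_i) - np.min(y_i))
    td = drivers.t
    mask = td <= max(t_pk, td[1])
    CE = drivers.column("C_E")[mask]
    TP = drivers.column("T_P")[mask]
    TN = drivers.column("T_N")[mask]
    tt = td[mask]
    ce_peak = max(float(np.max(drivers.column("C_E"))), 1.0)
    I_D = max(float(np.trapezoid((CE / (p.B + CE)) * (TP + p.g0 * TN), tt)), 1e-30)
    I_A = max(float(np.trapezoid((TP / (p.A + TP)) * CE, tt)), 1e-30)

    ipk = int(np.argmax(y_i))
    post = y_i[ipk:] - 0.99 * np.min(y_i)
    if len(post) >= 3 and np.all(post > 0):
        m_dec = abs(float(np.min(np.diff(np.log(post)) / np.diff(t_i[ipk:]))))
    else:
        m_dec = 0.5
    dI0 = float(np.clip(2.0 * m_dec, *bounds["delta_I"]))

    C_hs = fixed["C"]
    starts = []
    for dM in (0.15, 0.4):
        for M_i0 in (3e9, 1e10, 3e10):
            for trig in (0.5, 2.0):
                for fb in (0.0, 1.5):
                    alpha = dI0 * dpk / (0.5 * M_i0)
                    d = {
                        "sigma_M": 0.02 * dM * M_i0, "delta_M": dM,
                        "delta_I": dI0, "alpha": alpha,
                        "beta_K": trig / I_D, "beta_B": 0.1 * trig / I_A,
                        "beta_C": (fb * C_hs / (ce_peak * M_i0)
                                   if fb > 0 else bounds["beta_C"][0]),
                        "M_i0": M_i0,
                    }
                    starts.append({n: float(np.clip(d[n], *bounds[n]))
                                   for n in names})
    return starts


def fit_cytokine_layer(tc: PatientTimecourse, layer1: FitResult,
                       cfg: FitConfig | None = None,
                       free_names: tuple = LAYER2_FREE,
                       extra_starts=()) -> FitResult:
    """Monte-Carlo global search plus local refinement of the
    macrophage/IL-6 layer.

    Samples ``n_mc`` log-uniform tuples of the free parameters within
    bounds, evaluates LR for each, refines the ``n_refine`` best locally
    (bounded quasi-Newton polish of every selected tuple, then deep
    Nelder-Mead / quasi-Newton rounds on the most promising few) and
    returns the overall minimum.  Reduced model variants pass a restricted
    ``free_names`` (excluded activation coefficients are structurally
    zero).  ``extra_starts`` adds warm-start parameter dicts to the
    refinement pool (used for nested-variant cascades).
    """
    from .model_selection import aic as _aic      # deferred: avoids cycle

    cfg = cfg or FitConfig()
    t_i, y_i = tc.series("il6")
    if len(y_i) < 1:
        raise ValueError("need at least one IL-6 point")
    fixed = fix_cytokine_params(tc)
    horizon = max(float(np.max(t_i)), 1.0)
    drivers, p1 = _layer1_drivers(tc, layer1, horizon, cfg)

    rng = np.random.default_rng(cfg.seed)
    names = tuple(free_names)
    bounds = (narrowed_il6_bounds(t_i, y_i, cfg.bounds)
              if cfg.narrow_il6_bounds else cfg.bounds)
    log_lo = np.array([np.log10(bounds[n][0]) for n in names])
    log_hi = np.array([np.log10(bounds[n][1]) for n in names])

    def qvals_from(x):
        d = {n: 0.0 for n in LAYER2_FREE}
        d.update({n: 10.0 ** xi for n, xi in zip(names, x)})
        return d

    def evaluate(x):
        try:
            il6 = simulate_cytokine_given(drivers, p1, qvals_from(x), fixed, t_i)
        except (IntegrationError, ValueError):
            return 1e9
        lr = lr_objective(y_i, il6, cfg.w0)
        return lr if np.isfinite(lr) else PERFECT_FIT_LR

    samples = rng.uniform(log_lo, log_hi, size=(cfg.n_mc, len(names)))
    lr_mc = np.array([evaluate(x) for x in samples])
    if not np.any(lr_mc < 1e9):
        raise RuntimeError("all Monte-Carlo samples failed to integrate")
    order = list(np.argsort(lr_mc)[: cfg.n_refine])
    starts = [samples[i] for i in order]

    def embed(d):
        x = np.clip([np.log10(max(d.get(n, 0.0), 10.0 ** lo))
                     for n, lo in zip(names, log_lo)], log_lo, log_hi)
        return np.asarray(x)

    structured = [embed(d) for d in _structured_starts(
        drivers, p1, fixed, t_i, y_i, bounds, names)]
    structured.sort(key=evaluate)
    starts.extend(structured[: max(4, cfg.n_refine // 2)])
    starts.extend(embed(d) for d in extra_starts)

    # local refinement: bounded trust-region least squares on the weighted
    # residual vector (LR is monotone in the SSE, and the sum-of-squares
    # structure lets the trust region follow the narrow curved valley the
    # CD40 feedback produces); a tighter integrator tolerance keeps the
    # numerical Jacobian clean
    sqw = np.sqrt(il6_weights(y_i, cfg.w0))

    def residuals(x):
        try:
            il6 = simulate_cytokine_given(drivers, p1, qvals_from(x), fixed,
                                          t_i, rtol=1e-7)
            return sqw * (il6 - y_i)
        except (IntegrationError, ValueError):
            return np.full(len(y_i), 1e6)

    def lr_of(res):
        # LR of the refined point at the refinement tolerance: reporting at
        # a looser tolerance would add noise larger than deep-fit LR
        # differences
        sse = float(np.sum(res.fun ** 2))
        if sse >= 1e10:                      # failure penalty residuals
            return np.inf
        return PERFECT_FIT_LR if sse == 0.0 else float(np.log(sse))

    refined = []
    best_x, best_lr, best_nfev = None, np.inf, 0
    for x0 in starts:
        res = least_squares(residuals, x0, bounds=(log_lo, log_hi),
                            method="trf", diff_step=1e-3,
                            max_nfev=cfg.refine_maxiter)
        lr = lr_of(res)
        refined.append((qvals_from(res.x), float(lr)))
        if lr < best_lr:
            best_x, best_lr, best_nfev = res.x, float(lr), res.nfev
    # one extra polish of the winner
    res = least_squares(residuals, best_x, bounds=(log_lo, log_hi),
                        method="trf", diff_step=1e-4,
                        max_nfev=cfg.refine_maxiter)
    lr = lr_of(res)
    if lr < best_lr:
        best_x, best_lr, best_nfev = res.x, float(lr), res.nfev

    qb = qvals_from(best_x)
    params = dict(qb)
    params["sigma_I"] = qb["delta_I"] * fixed["il6_min"]
    params["C"] = fixed["C"]
    n_d = len(y_i)
    il6_best = simulate_cytokine_given(drivers, p1, qb, fixed, t_i)
    resid = pd.DataFrame({"series": "il6", "time": t_i, "observed": y_i,
                          "simulated": il6_best,
                          "residual": il6_best - y_i})
    flags = []
    if best_lr <= PERFECT_FIT_LR:
        flags.append("perfect fit: LR sentinel")
    return FitResult(
        params=params, free_names=names, objective=best_lr, layer=2,
        aic=_aic(best_lr, len(names), n_d), residuals=resid,
        converged=np.isfinite(best_lr) or best_lr <= PERFECT_FIT_LR,
        iterations=int(best_nfev),
        nfev=int(cfg.n_mc + sum(1 for _ in refined)), seed=cfg.seed,
        fixed=fixed, flags=flags,
        refined=refined,
    )


def top_fit_correlations(refined: list):
    """Pairwise Pearson correlations across a set of refined fits.

    ``refined`` is a list of (params-dict, LR) pairs or FitResults.  Returns
    (correlation table, median of the off-diagonal correlations); parameters
    constant across the set give undefined (NaN) entries.
    """
    rows = []
    for item in refined:
        params = item.params if isinstance(item, FitResult) else item[0]
        rows.append({k: v for k, v in params.items() if np.isscalar(v)})
    if len(rows) < 3:
        raise ValueError("need at least 3 refined fits")
    df = pd.DataFrame(rows)
    df = df.loc[:, df.notna().all()]
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = df.corr()
    np.fill_diagonal(corr.values, np.nan)
    vals = corr.values[np.triu_indices_from(corr.values, k=1)]
    median = float(np.nanmedian(vals)) if np.any(np.isfinite(vals)) else np.nan
    return corr, median
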