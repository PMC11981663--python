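"""Forward simulation of the coupled CAR-T / tumor / macrophage system.

Dose events and piecewise-constant parameter changes (mechanism-blocking
windows) are handled exactly by restarting the adaptive integrator at each
breakpoint with a state jump, never by delta functions in the right-hand
side.  The activated-macrophage population can optionally be tracked as three
mechanism-specific sub-populations integrated simultaneously with the full
system, together with the cumulative activation integrals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model_core import (
    CartTumorParams,
    CytokineParams,
    DoseRegimen,
    ModelState,
    activation_rate,
    cart_tumor_rhs,
    macrophage_rhs,
)

__all__ = ["Trajectory", "TrajectoryObservables", "simulate", "observables",
           "IntegrationError", "BetaWindow"]

#: extra state columns appended when activation decomposition is tracked
DECOMP_NAMES = ("M_a1", "M_a2", "M_a3", "J1", "J2", "J3")

MECHANISMS = ("DAMP", "antigen", "CD40")
_BETA_OF = {"DAMP": "beta_K", "antigen": "beta_B", "CD40": "beta_C"}


class IntegrationError(RuntimeError):
    """The ODE solver failed to complete a segment."""


@dataclass(frozen=True)
class BetaWindow:
    """Piecewise-constant scaling of one activation coefficient.

    Inside ``[t_start, t_stop]`` the coefficient for ``mechanism`` (one of
    ``DAMP``, ``antigen``, ``CD40``) is multiplied by ``residual`` (0 blocks
    it completely, 1 leaves it untouched).
    """

    mechanism: str
    residual: float
    t_start: float
    t_stop: float

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 <= self.residual <= 1.0:
            raise ValueError("residual fraction must lie in [0, 1]")
        if self.t_start > self.t_stop:
            raise ValueError("t_start must be <= t_stop")


@dataclass
class Trajectory:
    """Dense solution on a time grid with named state columns."""

    t: np.ndarray
    y: np.ndarray                   # shape (len(t), len(names))
    names: tuple
    params: CartTumorParams = None
    cytokine_params: CytokineParams | None = None
    regimen: DoseRegimen | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("trajectory states must be finite")

    def column(self, name: str) -> np.ndarray:
        return self.y[:, self.names.index(name)]

    @property
    def total_cart(self) -> np.ndarray:
        return self.column("C_I") + self.column("C_E") + self.column("C_P")

    @property
    def total_tumor(self) -> np.ndarray:
        return self.column("T_P") + self.column("T_N")

    @property
    def has_cytokine_layer(self) -> bool:
        return "IL6" in self.names

    def interp(self, name: str, times) -> np.ndarray:
        return np.interp(np.asarray(times, dtype=float), self.t, self.column(name))

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table with columns time, variable, value."""
        frames = []
        cols = list(self.names) + ["C_T", "T"]
        data = np.column_stack([self.y, self.total_cart, self.total_tumor])
        for j, name in enumerate(cols):
            frames.append(pd.DataFrame(
                {"time": self.t, "variable": name, "value": data[:, j]}))
        return pd.concat(frames, ignore_index=True)


@dataclass
class TrajectoryObservables:
    """Scalar summaries of a simulated response.

    Day-28/90 fields are NaN when the horizon is shorter; IL-6 fields are NaN
    when the cytokine layer was not simulated.
    """

    cmax: float
    cmax_day: float
    cmin: float                  # CAR-T minimum after the distribution phase
    cmin_day: float
    tmin: float
    tmin_day: float
    il6_baseline: float = np.nan
    il6_peak: float = np.nan
    il6_peak_day: float = np.nan
    il6_fold_change: float = np.nan
    macrophage_peak_day: float = np.nan
    tumor_day28: float = np.nan
    tumor_day90: float = np.nan
    persister_day28: float = np.nan
    persister_day90: float = np.nan
    cart_fold_change: float = np.nan   # Cmax / total dose
    relapse: bool = False

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _beta_scales(q: CytokineParams, windows: Sequence[BetaWindow], t0: float,
                 t1: float) -> CytokineParams:
    """Cytokine parameters effective on the open segment (t0, t1)."""
    mid = 0.5 * (t0 + t1)
    scale = {"beta_K": 1.0, "beta_B": 1.0, "beta_C": 1.0}
    for w in windows:
        if w.t_start <= mid < w.t_stop or (w.t_start <= mid <= w.t_stop and w.t_start == w.t_stop):
            scale[_BETA_OF[w.mechanism]] *= w.residual
    d = q.to_dict()
    for k, s in scale.items():
        d[k] *= s
    return CytokineParams(**d)


def _make_rhs(p: CartTumorParams, q: CytokineParams | None, track: bool):
    # the solver calls this thousands of times: the model equations are
    # inlined here (cart_tumor_rhs/macrophage_rhs express the same maths
    # with validation for direct use)
    eta, mu_I, kappa, mu_E = p.eta, p.mu_I, p.kappa, p.mu_E
    eps, theta, mu_P = p.epsilon, p.theta, p.mu_P
    rho, K, gamma, A, B, g0 = p.rho, p.K, p.gamma, p.A, p.B, p.g0
    if q is not None:
        sM, dM, sI, dI, alpha = q.sigma_M, q.delta_M, q.sigma_I, q.delta_I, q.alpha
        bB, bK, bC, Chs = q.beta_B, q.beta_K, q.beta_C, q.C

    def rhs(t, y):
        y = np.maximum(y, 0.0)
        C_I, C_E, C_P, T_P, T_N = y[:5]
        F = T_P / (A + T_P)
        kill = gamma * C_E / (B + C_E)
        crowd = 1.0 - (T_P + T_N) / K
        d = np.empty_like(y)
        d[0] = -eta * F * C_I - mu_I * C_I
        d[1] = (eta * F * C_I + (kappa * F * C_E if C_E >= 1.0 else 0.0)
                - eps * (1.0 - F) * C_E + theta * F * C_P - mu_E * C_E)
        d[2] = eps * (1.0 - F) * C_E - theta * F * C_P - mu_P * C_P
        d[3] = (rho * T_P * crowd if T_P >= 1.0 else 0.0) - kill * T_P
        d[4] = (rho * T_N * crowd if T_N >= 1.0 else 0.0) - g0 * kill * T_N
        if q is not None:
            M_i, M_a, IL6 = y[5], y[6], y[7]
            h1 = bK * (C_E / (B + C_E)) * (T_P + g0 * T_N)
            h2 = bB * F * C_E
            h3 = bC * (M_a / (Chs + M_a)) * C_E
            h = h1 + h2 + h3
            d[5] = sM - h * M_i - dM * M_i
            d[6] = h * M_i - dM * M_a
            d[7] = sI + alpha * M_a - dI * IL6
            if track:
                # mechanism-specific sub-populations and cumulative integrals
                d[8] = h1 * M_i - dM * y[8]
                d[9] = h2 * M_i - dM * y[9]
                d[10] = h3 * M_i - dM * y[10]
                d[11] = h1 * M_i
                d[12] = h2 * M_i
                d[13] = h3 * M_i
        return d
    return rhs


def simulate(p: CartTumorParams,
             q: CytokineParams | None = None,
             init: ModelState | None = None,
             regimen: DoseRegimen | None = None,
             horizon: float = 90.0,
             grid_step: float = 0.05,
             rtol: float = 1e-8,
             atol: float | None = None,
             track_activation: bool = False,
             beta_windows: Sequence[BetaWindow] = (),
             t_grid: np.ndarray | None = None) -> Trajectory:
    """Integrate the model and return the dense solution.

    The cytokine layer is simulated only when ``q`` is given;
    ``track_activation`` additionally carries the three mechanism-specific
    activated-macrophage sub-populations and their cumulative activation
    integrals as extra states.  LSODA switches automatically between stiff
    and non-stiff steppers, which the 12-orders-of-magnitude spread of the
    cell populations requires.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if track_activation and q is None:
        raise ValueError("track_activation requires cytokine parameters")
    init = init or ModelState()
    regimen = regimen or DoseRegimen()
    if any(t >= horizon for t, _ in regimen.events):
        raise ValueError("dose times must lie before the horizon")

    nvar = 5 if q is None else (14 if track_activation else 8)
    names = ("C_I", "C_E", "C_P", "T_P", "T_N")
    if q is not None:
        names += ("M_i", "M_a", "IL6")
        if track_activation:
            names += DECOMP_NAMES

    y0 = init.to_array()[:8] if q is not None else init.to_array()[:5]
    if track_activation:
        y0 = np.concatenate([y0, np.zeros(6)])

    if atol is None:
        atol = np.full(nvar, 1e-6)
        if q is not None:
            atol[7] = 1e-8                      # IL-6 is O(1)-O(1000) ng/L

    if t_grid is not None:
        grid = np.unique(np.clip(np.asarray(t_grid, dtype=float), 0.0, horizon))
    else:
        grid = np.arange(0.0, horizon + 0.5 * grid_step, grid_step)
        grid[-1] = min(grid[-1], horizon)
    breaks = {0.0, float(horizon)}
    breaks.update(float(t) for t, _ in regimen.events)
    for w in beta_windows:
        for edge in (w.t_start, w.t_stop):
            if 0.0 < edge < horizon:
                breaks.add(float(edge))
    breaks = sorted(breaks)

    dose_at = {}
    for t, c in regimen.events:
        dose_at[float(t)] = dose_at.get(float(t), 0.0) + c

    ts, ys = [], []
    y = y0.copy()
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        if t0 in dose_at:
            y = y.copy()
            y[0] += dose_at[t0]
        q_eff = _beta_scales(q, beta_windows, t0, t1) if q is not None else None
        rhs = _make_rhs(p, q_eff, track_activation)
        mask = (grid > t0 + 1e-12) & (grid < t1 - 1e-12)
        t_eval = np.concatenate([[t0], grid[mask], [t1]])
        sol = solve_ivp(rhs, (t0, t1), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{t0}, {t1}]: {sol.message}")
        seg_t, seg_y = sol.t, np.maximum(sol.y.T, 0.0)
        if ts:                               # drop duplicated breakpoint
            seg_t, seg_y = seg_t[1:], seg_y[1:]
        ts.append(seg_t)
        ys.append(seg_y)
        y = np.maximum(sol.y[:, -1], 0.0)

    t = np.concatenate(ts)
    Y = np.vstack(ys)
    keep = np.concatenate([[True], np.diff(t) > 1e-12])
    return Trajectory(t[keep], Y[keep], names, params=p, cytokine_params=q,
                      regimen=regimen)


def _local_min_index(y: np.ndarray) -> int | None:
    """Index of the first strict local minimum, or None."""
    for i in range(1, len(y) - 1):
        if y[i] <= y[i - 1] and y[i] < y[i + 1]:
            return i
    return None


def observables(traj: Trajectory, dose: float | None = None,
                detection_limit: float = 2.5e5) -> TrajectoryObservables:
    """Extract scalar response summaries from a dense trajectory.

    The CAR-T minimum after distribution is the first local minimum of total
    CAR-T within the first 5 days (falling back to the minimum on that
    window); IL-6 baseline is the value at t=0; relapse means total tumor
    exceeding its initial burden at any time after the tumor minimum.
    """
    if len(traj.t) == 0:
        raise ValueError("empty trajectory")
    t = traj.t
    C = traj.total_cart
    T = traj.total_tumor
    if dose is None:
        dose = traj.regimen.total_dose if traj.regimen and traj.regimen.events else np.nan

    i_cmax = int(np.argmax(C))
    cmax, cmax_day = float(C[i_cmax]), float(t[i_cmax])

    early = t <= min(5.0, t[-1])
    i_loc = _local_min_index(C[early])
    if i_loc is None:
        i_loc = int(np.argmin(C[early]))
    cmin, cmin_day = float(C[early][i_loc]), float(t[early][i_loc])

    i_tmin = int(np.argmin(T))
    tmin, tmin_day = float(T[i_tmin]), float(t[i_tmin])
    after = t >= tmin_day
    relapse = bool(np.any(T[after] > T[0])) if T[0] > 0 else False

    def at_day(series: np.ndarray, day: float) -> float:
        if t[-1] < day:
            return np.nan
        return float(np.interp(day, t, series))

    obs = TrajectoryObservables(
        cmax=cmax, cmax_day=cmax_day, cmin=cmin, cmin_day=cmin_day,
        tmin=tmin, tmin_day=tmin_day,
        tumor_day28=at_day(T, 28.0), tumor_day90=at_day(T, 90.0),
        persister_day28=at_day(traj.column("C_P"), 28.0),
        persister_day90=at_day(traj.column("C_P"), 90.0),
        cart_fold_change=cmax / dose if dose and dose > 0 else np.nan,
        relapse=relapse,
    )

    if traj.has_cytokine_layer:
        il6 = traj.column("IL6")
        i_peak = int(np.argmax(il6))
        obs.il6_baseline = float(il6[0])
        obs.il6_peak = float(il6[i_peak])
        obs.il6_peak_day = float(t[i_peak])
        obs.il6_fold_change = (obs.il6_peak / obs.il6_baseline
                               if obs.il6_baseline > 0 else np.nan)
        obs.macrophage_peak_day = float(t[int(np.argmax(traj.column("M_a")))])
    return obs
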