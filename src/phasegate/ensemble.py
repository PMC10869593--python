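"""Mean-field coupled heterogeneous Bonhoeffer-van der Pol ensemble.

The population obeys

    dx_k/dt = x_k - x_k^3/3 - y_k + I_k + eps(t) * X + cos(psi) * P(t)
    dy_k/dt = c1 * (x_k - c2 * y_k + c3) + sin(psi) * P(t)

with the mean field X = N^-1 sum_k x_k, a piecewise-constant random
coupling strength eps(t), a common pulsatile stimulus P(t) entering
along the (unknown to the controller) direction psi, and random
heterogeneity currents I_k.  Near the synchronization transition a
fluctuating eps(t) produces a collective rhythm whose envelope waxes
and wanes, intermittently almost vanishing.

Integration is classical fixed-step RK4 (default dt = 0.1); the noisy
observable X_N = X + sigma*xi (unit white Gaussian xi) is emitted once
per step, so the controller and the integrator share one clock.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy.optimize import brentq

from . import _kernels as _k

__all__ = [
    "EnsembleParams",
    "CouplingSchedule",
    "EnsembleState",
    "ObservationRecord",
    "sample_heterogeneity",
    "generate_coupling_schedule",
    "constant_schedule",
    "coupling_at",
    "ensemble_deriv",
    "rk4_step",
    "observe",
    "initial_state",
    "simulate",
    "fixed_point",
    "is_self_sustained",
]


@dataclass(frozen=True)
class EnsembleParams:
    """Static parameters of the oscillator population.

    N          number of oscillators
    psi        stimulation direction angle (radians); the controller
               treats it as unknown
    dt         RK4 step = sampling interval of the observable
    het_dist   heterogeneity family: "gaussian" (default; a unimodal
               frequency distribution gives a sharp synchronization
               transition), "bimodal" (two equal sub-populations, as in
               models with two cell classes), or "uniform"
    het_mean/het_std
               centre and within-mode spread of the currents I_k
    het_sep    distance between the two mode centres (bimodal only)
    het_low/het_high
               support bounds: truncation interval for the Gaussian,
               or the full range for the uniform family.  Every I in
               [het_low, het_high] must leave the unit self-sustained.
    sigma      measurement-noise standard deviation (observable only)
    seed       seed for heterogeneity draws
    c1, c2, c3 coefficients of the slow (y) equation,
               dy/dt = c1*(x - c2*y + c3)
    """

    N: int = 1000
    psi: float = np.pi / 4
    dt: float = 0.1
    het_dist: str = "gaussian"
    het_mean: float = 0.53
    het_std: float = 0.10
    het_sep: float = 0.15
    het_low: float = 0.36
    het_high: float = 1.2
    sigma: float = 3.0
    seed: int = 0
    c1: float = 0.1
    c2: float = 0.8
    c3: float = 0.7

    def __post_init__(self):
        if self.N < 1:
            raise ValueError(f"N must be >= 1, got {self.N}")
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        if self.het_low > self.het_high:
            raise ValueError(
                f"het_low {self.het_low} > het_high {self.het_high}")
        if self.het_dist not in ("bimodal", "gaussian", "uniform"):
            raise ValueError(f"unknown het_dist {self.het_dist!r}")
        if self.het_std < 0 or self.het_sep < 0:
            raise ValueError("het_std and het_sep must be >= 0")
        for I in (self.het_low, self.het_high):
            if not is_self_sustained(I, self.c1, self.c2, self.c3):
                raise ValueError(
                    f"oscillator with I = {I} is not self-sustained "
                    "(fixed-point Jacobian trace <= 0)")


def fixed_point(I: float, c1: float = 0.1, c2: float = 0.8,
                c3: float = 0.7) -> tuple[float, float]:
    """Unique equilibrium of a single uncoupled, unforced oscillator."""
    # y* = (x* + c3)/c2;  g(x) = x - x^3/3 - y*(x) + I is strictly
    # decreasing whenever 1 - 1/c2 < 0 fails only for |x| small; bracket
    # widely and bisect.
    def g(x):
        return x - x ** 3 / 3.0 - (x + c3) / c2 + I

    xs = brentq(g, -10.0, 10.0, xtol=1e-12)
    return xs, (xs + c3) / c2


def is_self_sustained(I: float, c1: float = 0.1, c2: float = 0.8,
                      c3: float = 0.7) -> bool:
    """True if the equilibrium is unstable (Jacobian trace > 0).

    The Jacobian at (x*, y*) is [[1 - x*^2, -1], [c1, -c1*c2]]; an
    unstable focus (trace > 0, det > 0) surrounded by a limit cycle is
    what makes the unit an active, self-sustained oscillator.
    """
    xs, _ = fixed_point(I, c1, c2, c3)
    trace = (1.0 - xs ** 2) - c1 * c2
    det = -(1.0 - xs ** 2) * c1 * c2 + c1
    return trace > 0.0 and det > 0.0


@dataclass(frozen=True)
class CouplingSchedule:
    """Piecewise-constant coupling eps(t).

    Plateau n holds level ``levels[n]`` on
    [switch_times[n], switch_times[n+1]); ``switch_times`` therefore has
    one more entry than ``levels`` and starts at 0.
    """

    switch_times: np.ndarray
    levels: np.ndarray
    eps_c: float
    delta_eps: float
    tau_min: float
    tau_max: float
    seed: int = 0

    def __post_init__(self):
        sw = np.asarray(self.switch_times, dtype=float)
        lv = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "switch_times", sw)
        object.__setattr__(self, "levels", lv)
        if sw.size != lv.size + 1:
            raise ValueError("switch_times must have len(levels)+1 entries")
        if sw[0] != 0.0:
            raise ValueError("switch_times must start at 0")
        if np.any(np.diff(sw) <= 0):
            raise ValueError("switch_times must be strictly increasing")
        lo, hi = self.eps_c - self.delta_eps, self.eps_c + self.delta_eps
        if lv.size and (lv.min() < lo - 1e-12 or lv.max() > hi + 1e-12):
            raise ValueError("levels outside [eps_c - delta_eps, "
                             "eps_c + delta_eps]")
        dur = np.diff(sw)
        if dur.size and (dur.min() < self.tau_min - 1e-9
                         or dur.max() > self.tau_max + 1e-9):
            raise ValueError("plateau durations outside [tau_min, tau_max]")

    @property
    def horizon(self) -> float:
        return float(self.switch_times[-1])

    def __call__(self, t: float) -> float:
        return coupling_at(self, t)


@dataclass
class EnsembleState:
    """Dynamical state of the population at time t."""

    t: float
    x: np.ndarray
    y: np.ndarray
    I: np.ndarray

    def __post_init__(self):
        self.x = np.ascontiguousarray(self.x, dtype=float)
        self.y = np.ascontiguousarray(self.y, dtype=float)
        self.I = np.ascontiguousarray(self.I, dtype=float)
        n = self.x.size
        if self.y.size != n or self.I.size != n:
            raise ValueError("x, y, I must have equal length")

    @property
    def X(self) -> float:
        """Instantaneous mean field."""
        return float(self.x.mean())

    def copy(self) -> "EnsembleState":
        return EnsembleState(self.t, self.x.copy(), self.y.copy(),
                             self.I.copy())


@dataclass(frozen=True)
class ObservationRecord:
    t: float
    X: float
    X_N: float


def sample_heterogeneity(params: EnsembleParams) -> np.ndarray:
    """Draw the currents I_k, reproducibly.

    "gaussian" (default): I_k ~ N(het_mean, het_std^2).  A unimodal
    current density gives a unimodal natural-frequency density and
    hence a sharp synchronization transition: full incoherence below
    the critical coupling (the collective envelope can truly vanish)
    and a fast-growing order parameter above it.
    "bimodal": equal mixture of N(het_mean -+ het_sep/2, het_std^2) --
    two oscillator classes with distinct typical frequencies, as in
    models with two cell types.
    "uniform": I_k ~ U[het_low, het_high].
    Gaussian-family draws are redrawn until inside
    [het_low, het_high], so every unit stays self-sustained.
    """
    rng = np.random.default_rng(params.seed)
    if params.het_dist == "uniform":
        return rng.uniform(params.het_low, params.het_high, params.N)

    def draw(n):
        I = params.het_mean + params.het_std * rng.standard_normal(n)
        if params.het_dist == "bimodal":
            I += params.het_sep * 0.5 * np.where(rng.random(n) < 0.5, -1., 1.)
        return I

    I = draw(params.N)
    while True:
        bad = (I < params.het_low) | (I > params.het_high)
        n_bad = int(bad.sum())
        if n_bad == 0:
            return I
        I[bad] = draw(n_bad)


def generate_coupling_schedule(eps_c: float, delta_eps: float,
                               tau_min: float, tau_max: float,
                               horizon: float, seed: int = 0,
                               ) -> CouplingSchedule:
    """Random piecewise-constant eps(t) tiling [0, horizon].

    Levels eps_n ~ U[eps_c - delta_eps, eps_c + delta_eps] and plateau
    durations tau_n ~ U[tau_min, tau_max]; the last plateau may overshoot
    the horizon.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if tau_min <= 0:
        raise ValueError("tau_min must be > 0")
    if tau_min > tau_max:
        raise ValueError("tau_min must be <= tau_max")
    if delta_eps < 0:
        raise ValueError("delta_eps must be >= 0")
    rng = np.random.default_rng(seed)
    times = [0.0]
    levels = []
    while times[-1] < horizon:
        levels.append(rng.uniform(eps_c - delta_eps, eps_c + delta_eps))
        times.append(times[-1] + rng.uniform(tau_min, tau_max))
    return CouplingSchedule(np.array(times), np.array(levels), eps_c,
                            delta_eps, tau_min, tau_max, seed)


def constant_schedule(eps: float, horizon: float) -> CouplingSchedule:
    """Degenerate schedule eps(t) = eps (the Delta-eps = 0 case)."""
    return CouplingSchedule(np.array([0.0, horizon]), np.array([eps]),
                            eps, 0.0, horizon, horizon)


def coupling_at(schedule: CouplingSchedule, t: float) -> float:
    """Level of the plateau containing t (left-closed / right-open)."""
    if t < 0 or t >= schedule.horizon:
        raise ValueError(f"t = {t} outside schedule horizon "
                         f"[0, {schedule.horizon})")
    lvl, _ = _k.sched_lookup(schedule.switch_times, schedule.levels, 0,
                             float(t))
    return float(lvl)


def ensemble_deriv(state: EnsembleState, eps: float, P: float,
                   psi: float, c1: float = 0.1, c2: float = 0.8,
                   c3: float = 0.7) -> tuple[np.ndarray, np.ndarray]:
    """Right-hand side of the population equations (pure function)."""
    dx = np.empty_like(state.x)
    dy = np.empty_like(state.y)
    _k.ensemble_deriv(state.x, state.y, state.I, eps, P, psi,
                      c1, c2, c3, dx, dy)
    return dx, dy


def rk4_step(state: EnsembleState, schedule: CouplingSchedule,
             stimulus_fn: Optional[Callable[[float], float]],
             params: EnsembleParams) -> EnsembleState:
    """One classical RK4 step of length params.dt.

    eps(t) and P(t) are evaluated at each stage time (t, t+dt/2, t+dt);
    a coupling switch inside the step is therefore seen by the stages on
    either side of it.
    """
    dt = params.dt
    t = state.t
    new = state.copy()

    def sched(tt):
        lvl, _ = _k.sched_lookup(schedule.switch_times, schedule.levels,
                                 0, tt)
        return lvl

    p = stimulus_fn if stimulus_fn is not None else (lambda tt: 0.0)
    work = np.empty((10, state.x.size))
    _k.rk4_ensemble_step(new.x, new.y, new.I, params.psi, dt,
                         sched(t), sched(t + 0.5 * dt), sched(t + dt),
                         p(t), p(t + 0.5 * dt), p(t + dt),
                         params.c1, params.c2, params.c3, work)
    new.t = t + dt
    if not (np.all(np.isfinite(new.x)) and np.all(np.isfinite(new.y))):
        raise FloatingPointError(
            f"ensemble state became non-finite at t = {new.t:.2f} "
            f"(eps = {sched(t):.4g}, P = {p(t):.4g})")
    return new


def observe(state: EnsembleState, sigma: float,
            rng: np.random.Generator) -> ObservationRecord:
    """Noisy observable X_N = X + sigma * xi, one Gaussian draw."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    X = state.X
    xi = rng.standard_normal() if sigma > 0 else 0.0
    return ObservationRecord(state.t, X, X + sigma * xi)


def initial_state(params: EnsembleParams, seed: int = 0) -> EnsembleState:
    """Random initial conditions in a box around the limit cycle.

    x in [-2, 2], y in [-1, 1], i.i.d. uniform; heterogeneity currents
    drawn from ``params``.  Statistics should only be collected after a
    burn-in (default 1000 time units in `simulate`).
    """
    rng = np.random.default_rng(seed)
    I = sample_heterogeneity(params)
    x = rng.uniform(-2.0, 2.0, params.N)
    y = rng.uniform(-1.0, 1.0, params.N)
    return EnsembleState(0.0, x, y, I)


def simulate(params: EnsembleParams, schedule: CouplingSchedule,
             duration: float, state: Optional[EnsembleState] = None,
             stimulus: Optional[np.ndarray] = None,
             noise_seed: int = 0, ic_seed: int = 0,
             ) -> tuple["np.ndarray", EnsembleState]:
    """Integrate for ``duration`` and record (t, X, X_N, eps, P) rows.

    ``stimulus``, if given, is the per-sample zero-order-hold P value.
    Returns a structured record array and the final state; the run is a
    pure function of its seeds.
    """
    import pandas as pd  # local: keep module import light

    dt = params.dt
    n = int(round(duration / dt))
    if state is None:
        state = initial_state(params, ic_seed)
    else:
        state = state.copy()
    P = np.zeros(n) if stimulus is None else np.asarray(stimulus, float)
    if P.size < n:
        raise ValueError("stimulus shorter than the number of steps")
    rng = np.random.default_rng(noise_seed)
    noise = rng.standard_normal(n)
    work = np.empty((10, params.N))
    out_t = np.empty(n)
    out_X = np.empty(n)
    out_eps = np.empty(n)
    idx = 0
    sw, lv = schedule.switch_times, schedule.levels
    for i in range(n):
        t = state.t
        out_t[i] = t
        out_X[i] = state.x.mean()
        e0, idx = _k.sched_lookup(sw, lv, idx, t)
        em, _ = _k.sched_lookup(sw, lv, idx, t + 0.5 * dt)
        e1, _ = _k.sched_lookup(sw, lv, idx, t + dt)
        out_eps[i] = e0
        _k.rk4_ensemble_step(state.x, state.y, state.I, params.psi, dt,
                             e0, em, e1, P[i], P[i], P[i],
                             params.c1, params.c2, params.c3, work)
        state.t = t + dt
    if not np.all(np.isfinite(state.x)):
        raise FloatingPointError("ensemble state became non-finite")
    table = pd.DataFrame({
        "t": out_t,
        "X": out_X,
        "X_N": out_X + params.sigma * noise,
        "eps": out_eps,
        "P": P[:n],
    })
    return table, state
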