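"""Adaptive tuning of the stimulation phase and feedback factor.

The controller does not know the vulnerable phase theta0 or a good
feedback factor eps_fb, so it learns them by trial and error in three
stages:

baseline   no stimulation; measure the autonomous mean amplitude a_aut
           and the collective frequency.
learning   stimulate for blocks of m oscillation periods while theta0
           sweeps from 0 to 2*pi*N_cycl.  After each block, with
           a_curr the block-averaged amplitude:
           (i)  a_curr < a_min: record the improvement (a_min = a_curr,
                theta_opt = theta0) and keep the parameters;
           (ii) a_curr above a_min but still decreasing: wait;
           (iii) otherwise advance theta0 by max(dtheta,
                dtheta*a_curr/a_aut) and strengthen the feedback,
                eps_fb -> eps_fb - g/(1 + c*eps_fb^2).
           The damped increment avoids runaway feedback strength; a
           hard floor on eps_fb is kept as a safety rail since the
           increment never reaches zero.  If no block ever beat the
           initial a_min = 0.3*a_aut, one extra full sweep is forced.
post       theta0 is frozen at theta_opt; eps_fb is strengthened by the
           same damped step whenever a_curr > 2*a_min (the rhythm is
           re-emerging), otherwise left alone.

Amplitude bursts of the uncontrolled system make naive gradient schemes
unstable here: the block bookkeeping against a_aut/a_min is what lets
the tuner tell stimulation-induced suppression from a quiescent epoch.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Stage",
    "TunerParams",
    "TunerState",
    "baseline_amplitude",
    "feedback_step",
    "block_update",
    "finish_learning",
    "post_adapt",
]


class Stage(str, Enum):
    BASELINE = "baseline"
    LEARNING = "learning"
    POST = "post"


@dataclass(frozen=True)
class TunerParams:
    """Protocol constants.

    N_cycl      full 2*pi sweeps of theta0 during learning
    m           oscillation periods per evaluation block
    d_theta     maximal phase step per block (radians)
    c, g        damping curvature and base step of the eps_fb update
    a_min_init_factor  initial a_min as a fraction of a_aut
    post_factor        re-adaptation threshold multiplier on a_min
    eps_fb_init        feedback factor at the start of learning
    eps_fb_floor_factor  hard floor on eps_fb, in units of A0/a_aut
    """

    N_cycl: int = 1
    m: int = 5
    d_theta: float = 2.0 * np.pi / 25.0
    c: float = 100.0
    g: float = 0.05
    a_min_init_factor: float = 0.3
    post_factor: float = 2.0
    eps_fb_init: float = -0.35
    eps_fb_floor_factor: float = 2.0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.d_theta <= 0 or self.c <= 0 or self.g <= 0:
            raise ValueError("d_theta, c, g must be > 0")
        if not 0.0 < self.a_min_init_factor < 1.0:
            raise ValueError("a_min_init_factor must be in (0, 1)")
        if self.post_factor <= 1.0:
            raise ValueError("post_factor must be > 1")
        if self.eps_fb_init > 0:
            raise ValueError("eps_fb_init must be <= 0")
        if self.N_cycl < 1:
            raise ValueError("N_cycl must be >= 1")


@dataclass
class TunerState:
    stage: Stage
    a_aut: float
    a_min: float
    a_prev: float
    theta0: float
    theta_opt: float
    eps_fb: float
    sweep_progress: float = 0.0
    sweep_target: float = 0.0
    forced_extra: bool = False
    improved: bool = False
    eps_fb_floor: float = -np.inf
    a_resolution: float = 0.0
    last_branch: str = ""

    @classmethod
    def start_learning(cls, a_aut: float, params: TunerParams,
                       A0: float = 1.0,
                       a_resolution: float = 0.0) -> "TunerState":
        """Enter the learning stage.

        ``a_resolution`` is the smallest block-averaged amplitude the
        estimator can distinguish from zero (set by the measurement
        noise left after filtering); a_min never drops below it, so the
        bookkeeping cannot chase meaningless sub-resolution minima.
        """
        if a_aut <= 0:
            raise ValueError("a_aut must be > 0")
        return cls(
            stage=Stage.LEARNING,
            a_aut=a_aut,
            a_min=params.a_min_init_factor * a_aut,
            a_prev=a_aut,
            theta0=0.0,
            theta_opt=0.0,
            eps_fb=params.eps_fb_init,
            sweep_target=2.0 * np.pi * params.N_cycl,
            eps_fb_floor=-params.eps_fb_floor_factor * A0 / a_aut,
            a_resolution=a_resolution,
        )


def baseline_amplitude(a_trace: np.ndarray, delta: float,
                       omega: float) -> float:
    """Time-averaged estimator amplitude over the unstimulated epoch.

    The trace must exclude the filter start-up; it must span at least
    10 oscillation periods of the collective rhythm.
    """
    a = np.asarray(a_trace, dtype=float)
    if a.size * delta < 10.0 * (2.0 * np.pi / omega):
        raise ValueError("baseline window shorter than 10 periods")
    return float(a.mean())


def feedback_step(eps_fb: float, params: TunerParams,
                  floor: float = -np.inf) -> float:
    """One damped strengthening step, eps_fb -> eps_fb - g/(1+c*eps_fb^2).

    Strictly more negative; the increment magnitude decreases with
    |eps_fb| so the feedback never jumps to a destabilizing strength.
    ``floor`` clips the result (safety rail; the bare update decreases
    forever, only ever more slowly).
    """
    new = eps_fb - params.g / (1.0 + params.c * eps_fb * eps_fb)
    return max(new, floor)


def block_update(state: TunerState, params: TunerParams,
                 a_curr: float) -> TunerState:
    """Trial-and-error decision after one m-period learning block."""
    if a_curr < 0:
        raise ValueError("a_curr must be >= 0")
    if state.stage is not Stage.LEARNING:
        raise ValueError("block_update only applies during learning")
    s = state
    if a_curr < s.a_min:
        s.a_min = a_curr
        s.theta_opt = s.theta0
        s.improved = True
        s.last_branch = "improve"
    elif a_curr < s.a_prev:
        s.last_branch = "wait"
    else:
        advance = max(params.d_theta,
                      params.d_theta * a_curr / s.a_aut)
        s.theta0 += advance
        s.sweep_progress += advance
        s.eps_fb = feedback_step(s.eps_fb, params, s.eps_fb_floor)
        s.last_branch = "advance"
    s.a_prev = a_curr
    return s


def finish_learning(state: TunerState, params: TunerParams) -> TunerState:
    """Close the learning epoch once the sweep target is reached.

    If no block ever improved on the initial a_min, one extra full 2*pi
    sweep is forced (once); otherwise theta0 is frozen at theta_opt and
    the state moves to the post stage.
    """
    s = state
    if s.sweep_progress < s.sweep_target:
        return s
    if not s.improved and not s.forced_extra:
        s.forced_extra = True
        s.sweep_target += 2.0 * np.pi
        return s
    s.stage = Stage.POST
    s.theta0 = s.theta_opt
    return s


def post_adapt(state: TunerState, params: TunerParams,
               a_curr: float) -> TunerState:
    """Post-learning maintenance: strengthen eps_fb if the rhythm returns.

    The trigger level is post_factor * a_min, but never below the
    amplitude-measurement resolution: a re-emergence must be
    distinguishable from the noise floor before the feedback reacts.
    """
    if state.stage is not Stage.POST:
        raise ValueError("post_adapt only applies in the post stage")
    if a_curr > params.post_factor * max(state.a_min, state.a_resolution):
        state.eps_fb = feedback_step(state.eps_fb, params,
                                     state.eps_fb_floor)
        state.last_branch = "post-adapt"
    else:
        state.last_branch = "post-hold"
    return state
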