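"""Closed-loop trials, suppression metrics, scans, and trial campaigns.

A trial wires the modules together:

    ensemble --X_N--> FIR --> device pair --> (theta_hat, a)
        ^                                         |
        |                                    phase gate
        +------- charge-balanced pulses <---------+

and runs the three protocol stages (baseline, learning sweep of theta0,
post-learning maintenance).  The suppression factor

    S = std(autonomous X) / std(stimulated X)

is computed on the noise-free mean field over the post-learning window,
against a matched autonomous run that shares the heterogeneity, the
initial conditions, the coupling realization eps(t), and the
measurement-noise stream, so amplitude changes caused by the wandering
coupling cancel out of the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels as _k
from .ensemble import (EnsembleParams, CouplingSchedule, constant_schedule,
                       generate_coupling_schedule, sample_heterogeneity)
from .signal_processing import (DeviceParams, FirSpec,
                                design_bandpass_fir, estimate_mean_frequency)
from .pulses import PulseShape, pulse_template
from .tuner import (Stage, TunerParams, TunerState, baseline_amplitude,
                    block_update, finish_learning, post_adapt)

__all__ = [
    "TrialConfig",
    "TrialResult",
    "run_trial",
    "matched_pair",
    "suppression_factor",
    "scan_coupling",
    "scan_filter",
    "batch_trials",
]

# provisional passband (cycles per time unit) used only to bootstrap the
# baseline frequency estimate before the real band is known
_PROV_BAND = (0.01, 0.06)


@dataclass(frozen=True)
class TrialConfig:
    """Everything one closed-loop trial needs; a pure function of `seed`."""

    ensemble: EnsembleParams = field(default_factory=EnsembleParams)
    # coupling schedule
    eps_c: float = 0.025
    delta_eps: float = 0.015
    tau_min: float = 200.0
    tau_max: float = 500.0
    # filter / estimator
    M: int = 350
    band_low_factor: float = 0.8
    band_high_factor: float = 1.2
    dev_factor: float = 8.0
    damp_amp_factor: float = 1.0
    damp_phase_factor: float = 0.1
    # gate / pulses
    alpha: float = 0.3
    min_interval_factor: float = 0.1   # Delta = factor * mean period
    pulse: PulseShape = field(default_factory=PulseShape)
    A0: float = 1.0
    # tuner
    tuner: TunerParams = field(default_factory=TunerParams)
    # timeline (time units)
    baseline_duration: float = 5000.0
    post_duration: float = 5000.0
    post_transient: float = 1000.0
    learning_max_blocks: int = 120
    # master seed; all sub-streams derive from it
    seed: int = 0

    def sub_seeds(self) -> dict:
        ss = np.random.SeedSequence(self.seed)
        het, ic, sched, noise = (int(s) for s in
                                 ss.generate_state(4, dtype=np.uint32) >> 1)
        return {"het": het, "ic": ic, "schedule": sched, "noise": noise}


@dataclass
class TrialResult:
    S: float
    S_prestim: float
    theta_opt: float
    eps_fb_final: float
    a_aut: float
    omega: float
    n_pulses: int
    mean_abs_height: float
    failed: bool
    failure_stage: str
    t_stim_on: float
    t_post_start: float
    t_end: float
    seed: int


class _Chain:
    """Estimator constants + warm state in kernel-ready form."""

    def __init__(self, fir: FirSpec, dev: DeviceParams, omega: float):
        from .signal_processing import LinearDevice
        self.fir = fir
        self.dev = dev
        self.omega = omega
        self.taps = fir.taps
        da = LinearDevice(dev.omega_dev, dev.gamma_amp, fir.delta)
        dp = LinearDevice(dev.omega_dev, dev.gamma_phase, fir.delta)
        self.Aa, self.Ba = da.A, da.B
        self.Ap, self.Bp = dp.A, dp.B
        self.nu = dev.nu
        self.amp_gain = dev.amp_gain()
        self.phase_lag = dev.phase_lag()
        self.comp = omega * fir.M * fir.delta
        self.startup = 2 * fir.taps.size
        # expected squared estimator amplitude on measurement noise
        # alone; set once the noise level has been estimated
        self.floor2 = 0.0

    def set_noise_floor(self, sigma_hat: float) -> None:
        """Calibrate the amplitude bias the chain reads on pure noise.

        White observation noise of std sigma passes the FIR with power
        gain sum(h^2); the devices read the envelope of that narrowband
        residue, whose mean square is twice its variance.
        """
        self.floor2 = 2.0 * sigma_hat ** 2 * float(np.sum(self.taps ** 2))

    @classmethod
    def provisional(cls, M: int, delta: float) -> "_Chain":
        fir = design_bandpass_fir(M, delta, *_PROV_BAND)
        omega = 2.0 * np.pi * np.sqrt(_PROV_BAND[0] * _PROV_BAND[1])
        dev = DeviceParams.from_signal_frequency(omega)
        return cls(fir, dev, omega)

    def process(self, xn: np.ndarray, fir_buf, fir_pos, ua, va, up, vp):
        return _k.estimate_stream(
            np.ascontiguousarray(xn, float), self.taps, fir_buf, fir_pos,
            ua, va, up, vp,
            self.Aa[0, 0], self.Aa[0, 1], self.Aa[1, 0], self.Aa[1, 1],
            self.Ba[0], self.Ba[1],
            self.Ap[0, 0], self.Ap[0, 1], self.Ap[1, 0], self.Ap[1, 1],
            self.Bp[0], self.Bp[1],
            self.nu, self.amp_gain, self.phase_lag, self.comp)


class _Loop:
    """Mutable closed-loop context around the compiled kernel."""

    def __init__(self, params: EnsembleParams, schedule: CouplingSchedule,
                 x0, y0, I, noise, n_total, chain: _Chain,
                 pulse_tpl, alpha, min_interval, A0):
        self.params = params
        self.schedule = schedule
        self.x = np.ascontiguousarray(x0, float).copy()
        self.y = np.ascontiguousarray(y0, float).copy()
        self.I = np.ascontiguousarray(I, float)
        self.noise = noise
        self.chain = chain
        self.pulse_tpl = pulse_tpl
        self.alpha = alpha
        self.min_interval = min_interval
        self.A0 = A0
        self.fs = np.zeros(_k.NF_STATE)
        self.fs[_k.F_LASTON] = -1e18
        self.istate = np.zeros(_k.NI_STATE, np.int64)
        self.fir_buf = np.zeros(chain.taps.size)
        self.work = np.empty((10, self.x.size))
        self.logs = {name: np.empty(n_total) for name in
                     ("t", "X", "X_N", "X_f", "theta_hat", "a", "P", "eps")}
        self.pulse_log = np.empty((max(64, n_total // 8), 4))

    @property
    def n_logged(self) -> int:
        return int(self.istate[_k.I_LOG])

    def run(self, max_steps, phase_target, gate_on, theta0, eps_fb):
        c = self.chain
        p = self.params
        return _k.run_closed_loop(
            int(max_steps), float(phase_target),
            self.x, self.y, self.I, p.psi, p.dt, p.c1, p.c2, p.c3,
            self.schedule.switch_times, self.schedule.levels,
            p.sigma, self.noise,
            c.taps, self.fir_buf,
            c.Aa[0, 0], c.Aa[0, 1], c.Aa[1, 0], c.Aa[1, 1],
            c.Ba[0], c.Ba[1],
            c.Ap[0, 0], c.Ap[0, 1], c.Ap[1, 0], c.Ap[1, 1],
            c.Bp[0], c.Bp[1],
            c.nu, c.amp_gain, c.phase_lag, c.comp,
            1 if gate_on else 0, float(theta0), self.alpha,
            self.min_interval, float(eps_fb), self.A0, self.pulse_tpl,
            c.floor2, c.startup,
            self.fs, self.istate, self.work,
            self.logs["t"], self.logs["X"], self.logs["X_N"],
            self.logs["X_f"], self.logs["theta_hat"], self.logs["a"],
            self.logs["P"], self.logs["eps"],
            self.pulse_log)

    def switch_chain(self, chain: _Chain, baseline_xn: np.ndarray,
                     warm_skip: int) -> np.ndarray:
        """Re-run the recorded baseline through a new chain.

        Replaces the estimator constants and warm state so the
        subsequent closed-loop segments continue seamlessly; returns the
        amplitude trace of the baseline under the new chain and fixes up
        the baseline rows of the estimator logs.
        """
        buf = np.zeros(chain.taps.size)
        xf, thd, th, a, pos, ua, va, up, vp = chain.process(
            baseline_xn, buf, 0, 0.0, 0.0, 0.0, 0.0)
        self.chain = chain
        self.fir_buf = buf
        self.istate[_k.I_FIRPOS] = pos
        self.fs[_k.F_UA], self.fs[_k.F_VA] = ua, va
        self.fs[_k.F_UP], self.fs[_k.F_VP] = up, vp
        self.fs[_k.F_PREVTH] = thd[-1]
        n = baseline_xn.size
        self.logs["X_f"][:n] = xf
        self.logs["theta_hat"][:n] = th
        self.logs["a"][:n] = a
        return a

    def tables(self) -> dict:
        n = self.n_logged
        series = pd.DataFrame({k: v[:n] for k, v in self.logs.items()})
        m = int(self.istate[_k.I_NPULSE])
        pulses = pd.DataFrame(self.pulse_log[:m],
                              columns=["t", "branch", "A_n", "theta_hat"])
        pulses["branch"] = pulses["branch"].astype(int)
        return {"series": series, "pulses": pulses}


def suppression_factor(autonomous: np.ndarray,
                       stimulated: np.ndarray) -> float:
    """S = std(autonomous X) / std(stimulated X) on matched windows."""
    aut = np.asarray(autonomous, float)
    stim = np.asarray(stimulated, float)
    if aut.size != stim.size:
        raise ValueError("series must cover matched durations")
    s = stim.std()
    if s == 0.0:
        return np.inf
    return float(aut.std() / s)


def _total_budget(config: TrialConfig, t_bar_max: float = 45.0) -> int:
    """Upper bound on the number of samples a stimulated run can take."""
    dt = config.ensemble.dt
    block_max = 2.0 * config.tuner.m * t_bar_max
    learn_max = (config.learning_max_blocks + 2) * block_max
    total = (config.baseline_duration + learn_max + config.post_duration
             + 10.0 * t_bar_max)
    return int(total / dt) + 16


def _prepare(config: TrialConfig):
    seeds = config.sub_seeds()
    p = replace(config.ensemble, seed=seeds["het"])
    I = sample_heterogeneity(p)
    rng_ic = np.random.default_rng(seeds["ic"])
    x0 = rng_ic.uniform(-2.0, 2.0, p.N)
    y0 = rng_ic.uniform(-1.0, 1.0, p.N)
    n_total = _total_budget(config)
    horizon = (n_total + 1) * p.dt + config.tau_max
    if config.delta_eps == 0.0:
        schedule = constant_schedule(config.eps_c, horizon)
    else:
        schedule = generate_coupling_schedule(
            config.eps_c, config.delta_eps, config.tau_min,
            config.tau_max, horizon, seeds["schedule"])
    noise = np.random.default_rng(seeds["noise"]).standard_normal(n_total)
    return p, I, x0, y0, schedule, noise, n_total


def _make_chain(omega: float, M: int, dt: float,
                config: TrialConfig) -> _Chain:
    f_bar = omega / (2.0 * np.pi)
    fir = design_bandpass_fir(M, dt, config.band_low_factor * f_bar,
                              config.band_high_factor * f_bar)
    dev = DeviceParams.from_signal_frequency(
        omega, config.dev_factor, config.damp_amp_factor,
        config.damp_phase_factor)
    return _Chain(fir, dev, omega)


def _calibrate_omega(xn: np.ndarray, xf_prov: np.ndarray,
                     config: TrialConfig, dt: float) -> float:
    """Mean collective frequency from the recorded baseline observable.

    A first guess comes from zero crossings of the provisionally
    filtered signal; residual broadband noise adds crossings and biases
    it high, so it is refined from the mean unwrapped-phase slope of
    the estimator chain built around the current guess (noise-induced
    phase jitter averages out of the slope).
    """
    omega = estimate_mean_frequency(xf_prov, dt)
    n_base = xn.size
    for _ in range(2):
        chain = _make_chain(omega, config.M, dt, config)
        buf = np.zeros(chain.taps.size)
        _, thd, _, amp, *_rest = chain.process(xn, buf, 0, 0., 0., 0., 0.)
        sk = max(chain.startup, n_base // 5)
        dphi = np.angle(np.exp(1j * np.diff(thd[sk:])))
        # weight by squared amplitude: the compensated phase matters
        # most during bursts, and the noise-dominated quiet stretches
        # would otherwise drag the estimate toward the band centre
        w = amp[sk:-1] ** 2
        omega_ref = float((dphi * w).sum() / max(w.sum(), 1e-300) / dt)
        if omega_ref <= 0:
            break
        omega = omega_ref
    return omega


def _baseline_and_chain(config: TrialConfig, loop: _Loop):
    """Run the unstimulated baseline, then calibrate the real chain.

    Returns (omega, t_bar, a_aut).  The collective frequency is
    estimated from the recorded baseline observable; the final chain
    (band 0.5..1.5 of the collective frequency, devices tied to it)
    then re-processes the recorded baseline so its warm state is
    exactly what a single continuous causal pass would give.
    """
    dt = config.ensemble.dt
    n_base = int(round(config.baseline_duration / dt))
    steps, _, _, status = loop.run(n_base, np.inf, False, 0.0, 0.0)
    if status == _k.ERR_BLOWUP:
        raise FloatingPointError("ensemble blow-up during baseline")
    xn = loop.logs["X_N"][:n_base]
    skip = max(loop.chain.startup, n_base // 5)
    omega = _calibrate_omega(xn, loop.logs["X_f"][skip:n_base], config, dt)
    chain = _make_chain(omega, config.M, dt, config)
    chain.set_noise_floor(_estimate_sigma(xn))
    a_base = loop.switch_chain(chain, xn, skip)
    skip2 = max(chain.startup, n_base // 5)
    a_corr = np.sqrt(np.maximum(a_base[skip2:] ** 2 - chain.floor2, 0.0))
    a_aut = baseline_amplitude(a_corr, dt, omega)
    t_bar = 2.0 * np.pi / omega
    loop.min_interval = config.min_interval_factor * t_bar
    return omega, t_bar, a_aut


def _amplitude_resolution(chain: _Chain, sigma_hat: float, block: int,
                          seed: int) -> float:
    """Smallest block-mean amplitude distinguishable from pure noise.

    Runs synthetic measurement noise at the estimated level through a
    copy of the chain and returns mean + 2 std of the noise-corrected
    block-averaged amplitudes; a_min is never allowed below this, so
    the tuner cannot chase sub-resolution minima.
    """
    rng = np.random.default_rng(seed)
    n_blocks = 24
    n = chain.startup + n_blocks * block
    xn = sigma_hat * rng.standard_normal(n)
    buf = np.zeros(chain.taps.size)
    _, _, _, a, *_rest = chain.process(xn, buf, 0, 0., 0., 0., 0.)
    a_c = np.sqrt(np.maximum(a[chain.startup:] ** 2 - chain.floor2, 0.0))
    means = a_c[:n_blocks * block].reshape(n_blocks, block).mean(axis=1)
    return float(means.mean() + 2.0 * means.std())


def _estimate_sigma(xn: np.ndarray) -> float:
    """Observation-noise std from first differences of the raw stream.

    The collective rhythm changes by O(a*omega*delta) per sample while
    the white noise contributes sigma*sqrt(2), so
    var(diff)/2 estimates sigma^2 with negligible signal leakage.
    """
    return float(np.sqrt(0.5 * np.var(np.diff(xn))))


def run_trial(config: TrialConfig, keep_logs: bool = True):
    """Execute baseline -> learning -> post and the matched autonomous run.

    Returns (TrialResult, logs) where logs is a dict with the stimulated
    and autonomous time-series tables, the pulse log and the per-block
    tuner log (empty frames when keep_logs=False).
    """
    p, I, x0, y0, schedule, noise, n_total = _prepare(config)
    dt = p.dt
    tpl = pulse_template(config.pulse, dt)
    prov = _Chain.provisional(config.M, dt)
    loop = _Loop(p, schedule, x0, y0, I, noise, n_total, prov, tpl,
                 config.alpha, 3.0, config.A0)
    failed, failure_stage = False, ""
    tuner_rows = []
    omega = np.nan
    a_aut = np.nan
    state = None
    try:
        omega, t_bar, a_aut = _baseline_and_chain(config, loop)
        t_stim_on = loop.fs[_k.F_T]
        block_cap = int(2.0 * config.tuner.m * t_bar / dt)
        phase_target = 2.0 * np.pi * config.tuner.m
        a_res = _amplitude_resolution(
            loop.chain, _estimate_sigma(loop.logs["X_N"][:loop.n_logged]),
            int(config.tuner.m * t_bar / dt),
            config.sub_seeds()["noise"] + 1)
        state = TunerState.start_learning(a_aut, config.tuner, config.A0,
                                          a_res)
        # settle-in block: stimulate but discard the first decision
        first = True
        blocks = 0
        while state.stage is Stage.LEARNING:
            if blocks >= config.learning_max_blocks:
                break
            steps, a_sum, a_cnt, status = loop.run(
                block_cap, phase_target, True,
                _k.wrap_phase(state.theta0), state.eps_fb)
            blocks += 1
            if status == _k.ERR_BLOWUP:
                raise FloatingPointError("blow-up during learning")
            a_curr = a_sum / max(a_cnt, 1)
            loop.fs[_k.F_PHACC] = 0.0
            if first:
                first = False
            else:
                state = block_update(state, config.tuner, a_curr)
                state = finish_learning(state, config.tuner)
            tuner_rows.append((blocks, _k.wrap_phase(state.theta0),
                               a_curr, state.a_min,
                               _k.wrap_phase(state.theta_opt),
                               state.eps_fb, state.last_branch))
        if state.stage is Stage.LEARNING:
            # sweep budget exhausted; freeze at the best phase seen
            state.stage = Stage.POST
            state.theta0 = state.theta_opt
        t_post_start = loop.fs[_k.F_T]
        n_post = int(round(config.post_duration / dt))
        theta_post = _k.wrap_phase(state.theta_opt)
        done = 0
        while done < n_post:
            cap = min(block_cap, n_post - done)
            steps, a_sum, a_cnt, status = loop.run(
                cap, phase_target, True, theta_post, state.eps_fb)
            if status == _k.ERR_BLOWUP:
                raise FloatingPointError("blow-up during post stage")
            done += steps
            loop.fs[_k.F_PHACC] = 0.0
            a_curr = a_sum / max(a_cnt, 1)
            state = post_adapt(state, config.tuner, a_curr)
    except FloatingPointError as exc:
        failed = True
        failure_stage = str(exc)
        t_stim_on = np.nan
        t_post_start = np.nan

    n_steps = loop.n_logged
    # matched autonomous run: same seeds, stimulation never enabled
    aut = _Loop(p, schedule, x0, y0, I, noise, n_total, prov, tpl,
                config.alpha, 3.0, config.A0)
    aut.run(n_steps, np.inf, False, 0.0, 0.0)

    if failed or state is None:
        result = TrialResult(np.nan, np.nan, np.nan, np.nan, a_aut, omega,
                             0, np.nan, True, failure_stage, np.nan,
                             np.nan, np.nan, config.seed)
        logs = _collect_logs(loop, aut, tuner_rows, keep_logs)
        return result, logs

    i_win = int(round((t_post_start + config.post_transient) / dt))
    i_win = min(i_win, n_steps - 2)
    X_stim = loop.logs["X"][i_win:n_steps]
    X_aut = aut.logs["X"][i_win:n_steps]
    S = suppression_factor(X_aut, X_stim)
    # alternative normalization: pre-stimulation epoch of the same run
    n_base = int(round(config.baseline_duration / dt))
    skip = max(loop.chain.startup, n_base // 5)
    S_pre = float(loop.logs["X"][skip:n_base].std() / X_stim.std())
    m_pulses = int(loop.istate[_k.I_NPULSE])
    heights = loop.pulse_log[:m_pulses, 2]
    result = TrialResult(
        S=S, S_prestim=S_pre,
        theta_opt=float(_k.wrap_phase(state.theta_opt)),
        eps_fb_final=float(state.eps_fb),
        a_aut=float(a_aut), omega=float(omega),
        n_pulses=m_pulses,
        mean_abs_height=float(np.abs(heights).mean()) if m_pulses else 0.0,
        failed=False, failure_stage="",
        t_stim_on=float(t_stim_on), t_post_start=float(t_post_start),
        t_end=float(loop.fs[_k.F_T]), seed=config.seed)
    logs = _collect_logs(loop, aut, tuner_rows, keep_logs)
    return result, logs


def _collect_logs(loop, aut, tuner_rows, keep_logs):
    if not keep_logs:
        return {}
    t = loop.tables()
    ta = aut.tables()
    tuner_log = pd.DataFrame(
        tuner_rows, columns=["block", "theta0", "a_curr", "a_min",
                             "theta_opt", "eps_fb", "branch"])
    return {"series": t["series"], "pulses": t["pulses"],
            "autonomous": ta["series"], "tuner": tuner_log}


def matched_pair(config: TrialConfig):
    """Stimulated and matched autonomous runs sharing every random draw.

    Returns (result, logs); logs["series"] and logs["autonomous"] are
    bit-identical before the stimulation onset.
    """
    return run_trial(config, keep_logs=True)


def scan_coupling(eps_grid: Sequence[float], delta_eps: float,
                  config: Optional[TrialConfig] = None,
                  duration: float = 4000.0, transient: float = 1000.0,
                  seed: int = 0) -> pd.DataFrame:
    """Synchronization-transition scan: <a>, envelope min/max per eps_c.

    Stimulation off; the envelope statistics use the causal estimator
    chain applied to the noise-free mean field.  With delta_eps = 0 this
    is the classical constant-coupling transition curve.
    """
    cfg = config if config is not None else TrialConfig()
    rows = []
    for i, eps_c in enumerate(eps_grid):
        c = replace(cfg, eps_c=float(eps_c), delta_eps=delta_eps,
                    seed=seed + 7919 * i,
                    ensemble=replace(cfg.ensemble, sigma=0.0))
        p, I, x0, y0, schedule, noise, _ = _prepare(
            replace(c, baseline_duration=duration, post_duration=0.0,
                    learning_max_blocks=0))
        n = int(round(duration / p.dt))
        prov = _Chain.provisional(cfg.M, p.dt)
        tpl = pulse_template(cfg.pulse, p.dt)
        loop = _Loop(p, schedule, x0, y0, I, noise, n + 8, prov, tpl,
                     cfg.alpha, 3.0, cfg.A0)
        _, _, _, status = loop.run(n, np.inf, False, 0.0, 0.0)
        if status == _k.ERR_BLOWUP:
            raise FloatingPointError(f"blow-up at eps_c = {eps_c}")
        X = loop.logs["X"][:n]
        skip = int(round(transient / p.dt))
        try:
            omega = estimate_mean_frequency(loop.logs["X_f"][skip:n], p.dt)
        except ValueError:
            omega = prov.omega
        f_bar = omega / (2.0 * np.pi)
        fir = design_bandpass_fir(cfg.M, p.dt,
                                  cfg.band_low_factor * f_bar,
                                  cfg.band_high_factor * f_bar)
        dev = DeviceParams.from_signal_frequency(omega)
        chain = _Chain(fir, dev, omega)
        buf = np.zeros(chain.taps.size)
        _, _, _, a, *_rest = chain.process(X, buf, 0, 0., 0., 0., 0.)
        a_use = a[max(skip, chain.startup):]
        rows.append({"eps_c": float(eps_c), "a_mean": float(a_use.mean()),
                     "env_min": float(a_use.min()),
                     "env_max": float(a_use.max())})
    return pd.DataFrame(rows)


def scan_filter(M_grid: Sequence[int], theta0_grid: Sequence[float],
                config: Optional[TrialConfig] = None,
                eps: float = 0.03, eps_fb: float = -0.2,
                baseline_duration: float = 2000.0,
                stim_duration: float = 3000.0,
                transient: float = 500.0,
                seed: int = 0, n_rep: int = 1) -> pd.DataFrame:
    """Suppression surface S(theta0, M) at constant coupling.

    Adaptation off: each cell stimulates at a fixed theta0 with a fixed
    feedback factor.  Within one replicate all cells share one system
    realization (same heterogeneity, initial conditions, and noise),
    and each cell's S is computed against the common matched autonomous
    run over the same window, isolating the effect of the filter
    semilength M and the stimulation phase.  With n_rep > 1 the cell S
    is averaged over that many independent realizations.
    """
    if n_rep > 1:
        frames = [_scan_filter_once(M_grid, theta0_grid, config, eps,
                                    eps_fb, baseline_duration,
                                    stim_duration, transient,
                                    seed + 104729 * r)
                  for r in range(n_rep)]
        out = frames[0][["M", "theta0"]].copy()
        out["S"] = np.mean([f["S"].to_numpy() for f in frames], axis=0)
        return out
    return _scan_filter_once(M_grid, theta0_grid, config, eps, eps_fb,
                             baseline_duration, stim_duration, transient,
                             seed)


def _scan_filter_once(M_grid, theta0_grid, config, eps, eps_fb,
                      baseline_duration, stim_duration, transient, seed):
    cfg = config if config is not None else TrialConfig()
    cfg = replace(cfg, eps_c=eps, delta_eps=0.0, seed=seed,
                  baseline_duration=baseline_duration)
    p, I, x0, y0, schedule, noise, _ = _prepare(
        replace(cfg, post_duration=stim_duration, learning_max_blocks=0))
    dt = p.dt
    n_base = int(round(baseline_duration / dt))
    n_stim = int(round(stim_duration / dt))
    n_total = n_base + n_stim + 8
    tpl = pulse_template(cfg.pulse, dt)

    # common baseline (ensemble dynamics do not depend on the estimator)
    prov = _Chain.provisional(cfg.M, dt)
    base = _Loop(p, schedule, x0, y0, I, noise, n_total, prov, tpl,
                 cfg.alpha, 3.0, cfg.A0)
    base.run(n_base, np.inf, False, 0.0, 0.0)
    xn_base = base.logs["X_N"][:n_base].copy()
    skip = max(prov.startup, n_base // 5)
    omega = _calibrate_omega(xn_base, base.logs["X_f"][skip:n_base],
                             cfg, dt)
    f_bar = omega / (2.0 * np.pi)
    t_bar = 2.0 * np.pi / omega
    min_interval = cfg.min_interval_factor * t_bar

    # matched autonomous continuation
    aut = _Loop(p, schedule, base.x.copy(), base.y.copy(), I,
                noise[n_base:], n_total, prov, tpl, cfg.alpha,
                min_interval, cfg.A0)
    aut.fs[_k.F_T] = base.fs[_k.F_T]
    aut.istate[_k.I_SCHED] = base.istate[_k.I_SCHED]
    aut.run(n_stim, np.inf, False, 0.0, 0.0)
    i_win = int(round(transient / dt))
    X_aut = aut.logs["X"][i_win:n_stim]

    sigma_hat = _estimate_sigma(xn_base)
    rows = []
    for M in M_grid:
        fir = design_bandpass_fir(int(M), dt, cfg.band_low_factor * f_bar,
                                  cfg.band_high_factor * f_bar)
        dev = DeviceParams.from_signal_frequency(
            omega, cfg.dev_factor, cfg.damp_amp_factor,
            cfg.damp_phase_factor)
        chain = _Chain(fir, dev, omega)
        chain.set_noise_floor(sigma_hat)
        for theta0 in theta0_grid:
            cell = _Loop(p, schedule, base.x.copy(), base.y.copy(), I,
                         noise[n_base:], n_total, chain, tpl, cfg.alpha,
                         min_interval, cfg.A0)
            cell.fs[_k.F_T] = base.fs[_k.F_T]
            cell.istate[_k.I_SCHED] = base.istate[_k.I_SCHED]
            # warm the chain on the recorded baseline
            cell.switch_chain(chain, xn_base, skip)
            cell.istate[_k.I_NSEEN] = n_base
            cell.istate[_k.I_LOG] = 0
            _, _, _, status = cell.run(n_stim, np.inf, True,
                                       float(theta0), eps_fb)
            if status == _k.ERR_BLOWUP:
                S = np.nan
            else:
                X_stim = cell.logs["X"][i_win:n_stim]
                S = suppression_factor(X_aut, X_stim)
            rows.append({"M": int(M), "theta0": float(theta0),
                         "S": float(S)})
    return pd.DataFrame(rows)


def batch_trials(config: TrialConfig, n_trials: int,
                 N_cycl: Optional[int] = None,
                 seed: int = 0) -> dict:
    """Monte-Carlo campaign over independent coupling realizations.

    Each trial gets an independent master seed derived from ``seed``.
    Returns the ascending-sorted suppression factors, the fractions of
    trials with S > 1 and S > 2, and the failed-trial count (failures
    are excluded from the fractions but reported).  S < 1 runs are kept:
    they are the algorithm's genuine failure mode, not outliers.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    cfg = config
    if N_cycl is not None:
        cfg = replace(config, tuner=replace(config.tuner, N_cycl=N_cycl))
    trial_seeds = [int(s) for s in
                   np.random.SeedSequence(seed).generate_state(
                       n_trials, dtype=np.uint32) >> 1]
    results = []
    failures = 0
    for ts in trial_seeds:
        res, _ = run_trial(replace(cfg, seed=ts), keep_logs=False)
        if res.failed or not np.isfinite(res.S):
            failures += 1
        results.append(res)
    S = np.sort([r.S for r in results if not r.failed
                 and np.isfinite(r.S)])
    n_ok = S.size
    return {
        "S_sorted": S,
        "results": results,
        "n_trials": n_trials,
        "n_failed": failures,
        "frac_S_gt_1": float((S > 1.0).mean()) if n_ok else np.nan,
        "frac_S_gt_2": float((S > 2.0).mean()) if n_ok else np.nan,
    }
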