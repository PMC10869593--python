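"""Compiled inner loops.

Everything here is scalar/loop code compiled with numba so that the
closed-loop simulation (ensemble RK4 + streaming filter + virtual
measuring devices + pulse gate) runs at a few microseconds per sample.
The Python-facing modules wrap these kernels; the small helpers
(`fir_push`, `device_push`, `gate_decide`, ...) are shared between the
streaming API and the fused loop so both paths execute identical logic.
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi

# --- indices into the mutable integer state vector -------------------------
I_NSEEN = 0      # samples processed since stream start
I_FIRPOS = 1     # circular-buffer write position
I_NOISE = 2      # next index into the pre-drawn noise stream
I_ARMED = 3      # 0: theta0 armed (negative branch), 1: theta0+pi armed
I_PLAYING = 4    # 1 while a pulse waveform is being played out
I_PLAYIDX = 5    # sample index into the pulse template
I_NPULSE = 6     # rows written to the pulse log
I_LOG = 7        # rows written to the sample logs
I_SCHED = 8      # current plateau index of the coupling schedule
I_INSIDE = 9     # 1 if previous sample was inside the armed alpha-window

# --- indices into the mutable float state vector ----------------------------
F_T = 0          # current time
F_LASTON = 1     # time of last pulse onset
F_PLAYAMP = 2    # height of the pulse being played
F_PREVTH = 3     # previous delayed phase (for unwrapping)
F_PHACC = 4      # unwrapped phase advance accumulated this segment
F_UA = 5         # strongly-damped device u
F_VA = 6         # strongly-damped device u'
F_UP = 7         # weakly-damped device u
F_VP = 8         # weakly-damped device u'

NI_STATE = 10
NF_STATE = 9

# status codes returned by run_closed_loop
OK_PHASE = 0     # stopped because the phase-advance target was reached
OK_STEPS = 1     # stopped because the step budget was exhausted
ERR_BLOWUP = 2   # non-finite ensemble state
ERR_NOISE = 3    # ran out of pre-drawn noise


@njit(cache=True, inline="always")
def wrap_phase(x):
    r = x % TWO_PI
    if r < 0.0:
        r += TWO_PI
    return r


@njit(cache=True, inline="always")
def circ_dist(a, b):
    d = (a - b + np.pi) % TWO_PI - np.pi
    return abs(d)


@njit(cache=True)
def sched_lookup(switch_times, levels, idx, t):
    """Level of the plateau containing t; plateaus are [t_n, t_{n+1}).

    Scans forward from `idx` (times are visited in order); times past the
    last switch clamp to the final level.
    """
    i = idx
    n = levels.size
    while i + 1 < n and t >= switch_times[i + 1]:
        i += 1
    return levels[i], i


@njit(cache=True)
def ensemble_deriv(x, y, I, eps, P, psi, c1, c2, c3, dx, dy):
    """Mean-field coupled Bonhoeffer-van der Pol right-hand side.

    dx_k = x_k - x_k^3/3 - y_k + I_k + eps*X + cos(psi)*P
    dy_k = c1*(x_k - c2*y_k + c3) + sin(psi)*P,   X = mean(x)
    """
    N = x.size
    X = 0.0
    for k in range(N):
        X += x[k]
    X /= N
    fx = np.cos(psi) * P
    fy = np.sin(psi) * P
    for k in range(N):
        xk = x[k]
        dx[k] = xk - xk * xk * xk / 3.0 - y[k] + I[k] + eps * X + fx
        dy[k] = c1 * (xk - c2 * y[k] + c3) + fy


@njit(cache=True)
def rk4_ensemble_step(x, y, I, psi, dt, e0, em, e1, P0, Pm, P1,
                      c1, c2, c3, work):
    """Classical RK4 update in place; coupling/stimulus given per stage.

    `work` is a (10, N) scratch array: k1x..k4y plus the trial state.
    """
    N = x.size
    k1x, k1y = work[0], work[1]
    k2x, k2y = work[2], work[3]
    k3x, k3y = work[4], work[5]
    k4x, k4y = work[6], work[7]
    tx, ty = work[8], work[9]
    ensemble_deriv(x, y, I, e0, P0, psi, c1, c2, c3, k1x, k1y)
    h = 0.5 * dt
    for k in range(N):
        tx[k] = x[k] + h * k1x[k]
        ty[k] = y[k] + h * k1y[k]
    ensemble_deriv(tx, ty, I, em, Pm, psi, c1, c2, c3, k2x, k2y)
    for k in range(N):
        tx[k] = x[k] + h * k2x[k]
        ty[k] = y[k] + h * k2y[k]
    ensemble_deriv(tx, ty, I, em, Pm, psi, c1, c2, c3, k3x, k3y)
    for k in range(N):
        tx[k] = x[k] + dt * k3x[k]
        ty[k] = y[k] + dt * k3y[k]
    ensemble_deriv(tx, ty, I, e1, P1, psi, c1, c2, c3, k4x, k4y)
    s = dt / 6.0
    for k in range(N):
        x[k] += s * (k1x[k] + 2.0 * (k2x[k] + k3x[k]) + k4x[k])
        y[k] += s * (k1y[k] + 2.0 * (k2y[k] + k3y[k]) + k4y[k])


@njit(cache=True, inline="always")
def fir_push(buf, pos, taps, sample):
    """Push one sample through the causal FIR; returns (output, new pos)."""
    L = taps.size
    pos += 1
    if pos == L:
        pos = 0
    buf[pos] = sample
    acc = 0.0
    j = pos
    for i in range(L):
        acc += taps[i] * buf[j]
        j -= 1
        if j < 0:
            j = L - 1
    return acc, pos


@njit(cache=True, inline="always")
def device_push(u, v, a00, a01, a10, a11, b0, b1, s):
    """Exact zero-order-hold update of u'' + 2*gamma*u' + w^2 u = s."""
    nu_ = a00 * u + a01 * v + b0 * s
    nv_ = a10 * u + a11 * v + b1 * s
    return nu_, nv_


@njit(cache=True, inline="always")
def gate_decide(theta_hat, t, theta0, alpha, min_interval,
                armed, was_inside, last_onset, playing):
    """Phase-gate state machine for one sample.

    Returns (emit, armed, inside).  `armed` selects the target
    (0 -> theta0, negative branch; 1 -> theta0+pi, positive branch) and
    flips when the phase leaves the alpha-window of the armed target.
    """
    target = theta0 if armed == 0 else wrap_phase(theta0 + np.pi)
    inside = circ_dist(theta_hat, target) < alpha
    emit = False
    if inside:
        if (playing == 0) and (t - last_onset >= min_interval):
            emit = True
    elif was_inside == 1:
        armed = 1 - armed
    return emit, armed, (1 if inside else 0)


@njit(cache=True)
def estimate_stream(xn, taps, buf, pos, ua, va, up, vp,
                    aa00, aa01, aa10, aa11, ba0, ba1,
                    ap00, ap01, ap10, ap11, bp0, bp1,
                    nu, amp_gain, phase_lag, comp):
    """Run the causal chain filter -> devices -> inversion over an array.

    Returns (x_f, theta_delayed, theta_hat, a, pos, ua, va, up, vp) so a
    warm state can be carried into a subsequent closed-loop segment.
    """
    n = xn.size
    xf = np.empty(n)
    thd = np.empty(n)
    th = np.empty(n)
    amp = np.empty(n)
    for i in range(n):
        s, pos = fir_push(buf, pos, taps, xn[i])
        ua, va = device_push(ua, va, aa00, aa01, aa10, aa11, ba0, ba1, s)
        up, vp = device_push(up, vp, ap00, ap01, ap10, ap11, bp0, bp1, s)
        ra = np.sqrt(ua * ua + (va / nu) ** 2)
        amp[i] = ra * amp_gain
        phi = np.arctan2(-vp / nu, up)
        thd[i] = wrap_phase(phi + phase_lag)
        th[i] = wrap_phase(thd[i] + comp)
        xf[i] = s
    return xf, thd, th, amp, pos, ua, va, up, vp


@njit(cache=True)
def run_closed_loop(max_steps, phase_target,
                    x, y, I, psi, dt, c1, c2, c3,
                    switch_times, levels,
                    sigma, noise,
                    taps, fir_buf,
                    aa00, aa01, aa10, aa11, ba0, ba1,
                    ap00, ap01, ap10, ap11, bp0, bp1,
                    nu, amp_gain, phase_lag, comp,
                    gate_on, theta0, alpha, min_interval,
                    eps_fb, A0, pulse_tpl,
                    floor2, startup,
                    fs, istate, work,
                    log_t, log_X, log_XN, log_Xf, log_th, log_a,
                    log_P, log_eps,
                    pulse_log):
    """Advance the closed loop sample by sample.

    Per sample: observe X and X_N, update the causal estimator, run the
    phase gate (if enabled), play out any active pulse (zero-order hold
    over the sampling interval), and advance the ensemble by one RK4
    step with the coupling evaluated at each stage time.

    Stops after `max_steps` samples or once the unwrapped delayed phase
    has advanced by `phase_target` radians, whichever comes first.
    Returns (steps_done, a_sum, a_count, status).

    `floor2` is the expected squared amplitude the estimator reads on
    measurement noise alone; the block statistic accumulated in a_sum
    uses the noise-corrected amplitude sqrt(max(a^2 - floor2, 0)) so
    the tuner's bookkeeping is unbiased, while the pulse amplitude law
    uses the raw estimator amplitude (stimulation declines to the
    noise level once the rhythm is suppressed).  Logs keep the raw
    amplitude.
    """
    N = x.size
    n_tpl = pulse_tpl.size
    a_sum = 0.0
    a_count = 0
    status = OK_STEPS
    for step in range(max_steps):
        t = fs[F_T]
        if istate[I_NOISE] >= noise.size:
            status = ERR_NOISE
            return step, a_sum, a_count, status
        # observe
        X = 0.0
        for k in range(N):
            X += x[k]
        X /= N
        xn = X + sigma * noise[istate[I_NOISE]]
        istate[I_NOISE] += 1
        # causal estimation chain
        s, pos = fir_push(fir_buf, istate[I_FIRPOS], taps, xn)
        istate[I_FIRPOS] = pos
        ua, va = device_push(fs[F_UA], fs[F_VA],
                             aa00, aa01, aa10, aa11, ba0, ba1, s)
        up, vp = device_push(fs[F_UP], fs[F_VP],
                             ap00, ap01, ap10, ap11, bp0, bp1, s)
        fs[F_UA], fs[F_VA], fs[F_UP], fs[F_VP] = ua, va, up, vp
        ra = np.sqrt(ua * ua + (va / nu) ** 2)
        a = ra * amp_gain
        phi = np.arctan2(-vp / nu, up)
        thd = wrap_phase(phi + phase_lag)
        th = wrap_phase(thd + comp)
        # unwrapped phase advance (block clock)
        d = (thd - fs[F_PREVTH] + np.pi) % TWO_PI - np.pi
        fs[F_PREVTH] = thd
        fs[F_PHACC] += d
        a_corr = np.sqrt(max(a * a - floor2, 0.0))
        a_sum += a_corr
        a_count += 1
        # phase gate
        if gate_on == 1 and istate[I_NSEEN] >= startup:
            emit, armed, inside = gate_decide(
                th, t, theta0, alpha, min_interval,
                istate[I_ARMED], istate[I_INSIDE],
                fs[F_LASTON], istate[I_PLAYING])
            istate[I_ARMED] = armed
            istate[I_INSIDE] = inside
            if emit:
                amp = max(eps_fb * a, -A0)
                if armed == 1:
                    amp = -amp
                if amp != 0.0:
                    istate[I_PLAYING] = 1
                    istate[I_PLAYIDX] = 0
                    fs[F_PLAYAMP] = amp
                    fs[F_LASTON] = t
                    np_row = istate[I_NPULSE]
                    if np_row < pulse_log.shape[0]:
                        pulse_log[np_row, 0] = t
                        pulse_log[np_row, 1] = armed
                        pulse_log[np_row, 2] = amp
                        pulse_log[np_row, 3] = th
                        istate[I_NPULSE] = np_row + 1
        # stimulus sample (ZOH over [t, t+dt))
        P = 0.0
        if istate[I_PLAYING] == 1:
            P = fs[F_PLAYAMP] * pulse_tpl[istate[I_PLAYIDX]]
            istate[I_PLAYIDX] += 1
            if istate[I_PLAYIDX] >= n_tpl:
                istate[I_PLAYING] = 0
        # coupling at the three distinct RK4 stage times
        e0, idx = sched_lookup(switch_times, levels, istate[I_SCHED], t)
        em, idx = sched_lookup(switch_times, levels, idx, t + 0.5 * dt)
        e1, idx2 = sched_lookup(switch_times, levels, idx, t + dt)
        istate[I_SCHED] = idx
        # log
        row = istate[I_LOG]
        log_t[row] = t
        log_X[row] = X
        log_XN[row] = xn
        log_Xf[row] = s
        log_th[row] = th
        log_a[row] = a
        log_P[row] = P
        log_eps[row] = e0
        istate[I_LOG] = row + 1
        # advance the ensemble
        rk4_ensemble_step(x, y, I, psi, dt, e0, em, e1, P, P, P,
                          c1, c2, c3, work)
        fs[F_T] = t + dt
        istate[I_NSEEN] += 1
        if not np.isfinite(x[0]):
            ok = True
            for k in range(N):
                if not np.isfinite(x[k]) or not np.isfinite(y[k]):
                    ok = False
                    break
            if not ok:
                status = ERR_BLOWUP
                return step + 1, a_sum, a_count, status
        if fs[F_PHACC] >= phase_target:
            status = OK_PHASE
            return step + 1, a_sum, a_count, status
    return max_steps, a_sum, a_count, status
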