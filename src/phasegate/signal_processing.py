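"""Causal real-time phase and amplitude estimation.

The measured signal X_N is dominated by broadband noise, so the rhythm
of interest is first isolated with a causal linear-phase FIR bandpass
filter of 2M+1 taps.  Symmetry of the taps makes the filter a pure
delay of M samples for in-band components; the phase read at time t
therefore refers to t - M*delta and is advanced by omega*M*delta, with
omega the (baseline-estimated) mean frequency of the collective rhythm.

Phase and amplitude themselves come from a pair of virtual "measuring
devices": driven damped linear oscillators u'' + 2*gamma*u' + w_dev^2*u
= s(t) with w_dev far above the signal band.  A strongly damped device
has a nearly flat amplitude response over the band and a weakly damped
one a nearly flat phase response; inverting the steady-state resonance
relations of each yields the driving signal's instantaneous amplitude
and phase using only arithmetic per sample.  The discrete update is the
exact zero-order-hold propagator of the linear system, so no extra
integration error is introduced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from . import _kernels as _k
from ._kernels import wrap_phase

__all__ = [
    "FirSpec",
    "FirFilter",
    "DeviceParams",
    "LinearDevice",
    "PhaseAmpEstimate",
    "PhaseAmplitudeEstimator",
    "design_bandpass_fir",
    "estimate_mean_frequency",
    "compensate_delay",
    "invert_resonance",
]


@dataclass(frozen=True)
class FirSpec:
    """Designed bandpass filter: 2M+1 symmetric taps."""

    M: int
    delta: float
    f_low: float
    f_high: float
    taps: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "taps",
                           np.ascontiguousarray(self.taps, dtype=float))
        if self.taps.size != 2 * self.M + 1:
            raise ValueError("taps must have 2M+1 entries")

    def gain_at(self, f: float) -> float:
        """Magnitude of the frequency response at f cycles/time-unit."""
        w = 2.0 * np.pi * f * self.delta
        n = np.arange(self.taps.size)
        return float(np.abs(np.sum(self.taps * np.exp(-1j * w * n))))

    def save_taps(self, path) -> None:
        np.savetxt(path, self.taps)

    @classmethod
    def load_taps(cls, path, delta: float, f_low: float,
                  f_high: float) -> "FirSpec":
        taps = np.loadtxt(path)
        return cls((taps.size - 1) // 2, delta, f_low, f_high, taps)


def design_bandpass_fir(M: int, delta: float, f_low: float,
                        f_high: float) -> FirSpec:
    """Windowed-sinc (Hamming) linear-phase bandpass filter.

    Gain is normalized to 1 at the geometric band centre
    sqrt(f_low*f_high); the symmetric taps give a group delay of exactly
    M samples.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    nyq = 0.5 / delta
    if not (0.0 < f_low < f_high < nyq):
        raise ValueError(
            f"band ({f_low}, {f_high}) must lie inside (0, {nyq})")
    n = np.arange(2 * M + 1) - M
    w1 = 2.0 * np.pi * f_low * delta
    w2 = 2.0 * np.pi * f_high * delta
    with np.errstate(invalid="ignore"):
        h = (np.sin(w2 * n) - np.sin(w1 * n)) / (np.pi * n)
    h[M] = (w2 - w1) / np.pi
    win = np.hamming(2 * M + 1)
    h *= win
    # remove the residual DC leakage of the windowed design exactly
    # (keeps the taps symmetric; negligible effect inside the band)
    h -= win * (h.sum() / win.sum())
    spec = FirSpec(M, delta, f_low, f_high, h)
    g = spec.gain_at(float(np.sqrt(f_low * f_high)))
    return FirSpec(M, delta, f_low, f_high, h / g)


class FirFilter:
    """Streaming causal FIR: one sample in, one sample out.

    Samples before the stream start are treated as zeros; the first
    2M+1 outputs are start-up transients and flagged via ``warmed_up``.
    """

    def __init__(self, spec: FirSpec):
        self.spec = spec
        self.buf = np.zeros(spec.taps.size)
        self.pos = 0
        self.n_seen = 0

    @property
    def warmed_up(self) -> bool:
        return self.n_seen >= self.spec.taps.size

    def push(self, sample: float) -> float:
        out, self.pos = _k.fir_push(self.buf, self.pos, self.spec.taps,
                                    float(sample))
        self.n_seen += 1
        return float(out)

    def process(self, samples: np.ndarray) -> np.ndarray:
        return np.array([self.push(s) for s in np.asarray(samples, float)])


@dataclass(frozen=True)
class DeviceParams:
    """Parameters of the non-resonant measuring-device pair.

    omega_dev sits far above the assumed input frequency nu, so the
    strongly damped oscillator (gamma_amp) has a flat amplitude response
    over the band and the weakly damped one (gamma_phase) a flat phase
    response.
    """

    omega_dev: float
    gamma_amp: float
    gamma_phase: float
    nu: float

    def __post_init__(self):
        if not self.omega_dev > self.nu > 0:
            raise ValueError("need omega_dev > nu > 0 (non-resonant regime)")
        if not self.gamma_amp > self.gamma_phase > 0:
            raise ValueError("need gamma_amp > gamma_phase > 0")

    @classmethod
    def from_signal_frequency(cls, omega: float, dev_factor: float = 8.0,
                              damp_amp_factor: float = 1.0,
                              damp_phase_factor: float = 0.1,
                              ) -> "DeviceParams":
        wd = dev_factor * omega
        return cls(wd, damp_amp_factor * wd, damp_phase_factor * wd, omega)

    def amp_gain(self) -> float:
        """|H|^-1 of the strongly damped device at the frequency nu."""
        return float(np.sqrt((self.omega_dev ** 2 - self.nu ** 2) ** 2
                             + 4.0 * self.gamma_amp ** 2 * self.nu ** 2))

    def phase_lag(self) -> float:
        """Response lag of the weakly damped device at nu."""
        return float(np.arctan2(2.0 * self.gamma_phase * self.nu,
                                self.omega_dev ** 2 - self.nu ** 2))


def _zoh_propagator(omega: float, gamma: float, delta: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Exact discrete update of u'' + 2*gamma*u' + omega^2 u = s.

    Returns (A, B) with [u, u']_{n+1} = A @ [u, u']_n + B * s_n for a
    zero-order-hold input; computed via the matrix exponential of the
    augmented system, so the only error is the ZOH assumption itself.
    """
    Ac = np.array([[0.0, 1.0], [-omega ** 2, -2.0 * gamma]])
    Bc = np.array([0.0, 1.0])
    aug = np.zeros((3, 3))
    aug[:2, :2] = Ac
    aug[:2, 2] = Bc
    M = expm(aug * delta)
    return M[:2, :2].copy(), M[:2, 2].copy()


class LinearDevice:
    """One driven damped linear oscillator advanced sample by sample."""

    def __init__(self, omega: float, gamma: float, delta: float):
        self.omega = omega
        self.gamma = gamma
        self.delta = delta
        self.A, self.B = _zoh_propagator(omega, gamma, delta)
        self.u = 0.0
        self.v = 0.0

    def push(self, sample: float) -> tuple[float, float]:
        self.u, self.v = _k.device_push(
            self.u, self.v, self.A[0, 0], self.A[0, 1], self.A[1, 0],
            self.A[1, 1], self.B[0], self.B[1], float(sample))
        return self.u, self.v

    def amplitude_phase(self, nu: float) -> tuple[float, float]:
        """Instantaneous amplitude/phase of the device oscillation at nu."""
        r = np.sqrt(self.u ** 2 + (self.v / nu) ** 2)
        phi = np.arctan2(-self.v / nu, self.u)
        return float(r), float(phi)


def invert_resonance(dev_amp: LinearDevice, dev_phase: LinearDevice,
                     params: DeviceParams) -> tuple[float, float]:
    """Read (theta_delayed, a) of the driving signal off the device pair.

    The strongly damped device's oscillation radius times the inverse
    resonance gain gives the input amplitude; the weakly damped device's
    oscillation phase plus its analytic response lag gives the input
    phase (still delayed by the FIR group delay).
    """
    r_amp, _ = dev_amp.amplitude_phase(params.nu)
    _, phi = dev_phase.amplitude_phase(params.nu)
    a = r_amp * params.amp_gain()
    theta_delayed = wrap_phase(phi + params.phase_lag())
    return float(theta_delayed), float(a)


def compensate_delay(theta_delayed: float, omega: float, M: int,
                     delta: float) -> float:
    """theta(t) ~ theta(t - M*delta) + omega*M*delta, wrapped to [0, 2pi)."""
    if omega <= 0:
        raise ValueError("omega must be > 0")
    return float(wrap_phase(theta_delayed + omega * M * delta))


def estimate_mean_frequency(signal: np.ndarray, delta: float) -> float:
    """Mean angular frequency from upward zero crossings.

    omega = 2*pi * (n_crossings - 1) / (time from first to last
    crossing), with crossing instants linearly interpolated.  The input
    should be the filtered, unstimulated signal spanning at least a few
    oscillation periods.
    """
    s = np.asarray(signal, dtype=float)
    s = s - s.mean()
    up = np.nonzero((s[:-1] < 0.0) & (s[1:] >= 0.0))[0]
    if up.size < 2:
        raise ValueError("fewer than 2 upward zero crossings; cannot "
                         "estimate the mean frequency")
    frac = -s[up] / (s[up + 1] - s[up])
    t_cross = (up + frac) * delta
    return float(2.0 * np.pi * (up.size - 1) / (t_cross[-1] - t_cross[0]))


@dataclass(frozen=True)
class PhaseAmpEstimate:
    t: float
    theta_delayed: float
    theta_hat: float
    a: float
    omega: float


class PhaseAmplitudeEstimator:
    """Full causal chain: FIR -> device pair -> inversion -> compensation.

    ``omega`` is the frozen baseline estimate of the collective
    frequency; it fixes the delay-compensation advance omega*M*delta and
    the assumed device input frequency nu.  Estimates during the first
    2*(2M+1) samples should be ignored (stream start-up).
    """

    def __init__(self, fir: FirSpec, devices: DeviceParams, omega: float):
        if omega <= 0:
            raise ValueError("omega must be > 0")
        self.fir_spec = fir
        self.device_params = devices
        self.omega = float(omega)
        self.filter = FirFilter(fir)
        self.dev_amp = LinearDevice(devices.omega_dev, devices.gamma_amp,
                                    fir.delta)
        self.dev_phase = LinearDevice(devices.omega_dev,
                                      devices.gamma_phase, fir.delta)
        self._n = 0

    @property
    def startup_samples(self) -> int:
        return 2 * self.fir_spec.taps.size

    @property
    def reliable(self) -> bool:
        return self._n >= self.startup_samples

    def update(self, sample: float) -> PhaseAmpEstimate:
        xf = self.filter.push(sample)
        self.dev_amp.push(xf)
        self.dev_phase.push(xf)
        thd, a = invert_resonance(self.dev_amp, self.dev_phase,
                                  self.device_params)
        th = compensate_delay(thd, self.omega, self.fir_spec.M,
                              self.fir_spec.delta)
        t = self._n * self.fir_spec.delta
        self._n += 1
        return PhaseAmpEstimate(t, thd, th, a, self.omega)

    def process(self, samples: np.ndarray):
        """Vectorized streaming over an array (compiled loop).

        Returns a dict of arrays (x_f, theta_delayed, theta_hat, a) and
        leaves the estimator state warm, exactly as if `update` had been
        called per sample.
        """
        xn = np.ascontiguousarray(samples, dtype=float)
        d = self.device_params
        xf, thd, th, a, pos, ua, va, up, vp = _k.estimate_stream(
            xn, self.fir_spec.taps, self.filter.buf, self.filter.pos,
            self.dev_amp.u, self.dev_amp.v, self.dev_phase.u,
            self.dev_phase.v,
            self.dev_amp.A[0, 0], self.dev_amp.A[0, 1],
            self.dev_amp.A[1, 0], self.dev_amp.A[1, 1],
            self.dev_amp.B[0], self.dev_amp.B[1],
            self.dev_phase.A[0, 0], self.dev_phase.A[0, 1],
            self.dev_phase.A[1, 0], self.dev_phase.A[1, 1],
            self.dev_phase.B[0], self.dev_phase.B[1],
            d.nu, d.amp_gain(), d.phase_lag(),
            self.omega * self.fir_spec.M * self.fir_spec.delta)
        self.filter.pos = int(pos)
        self.filter.n_seen += xn.size
        self.dev_amp.u, self.dev_amp.v = float(ua), float(va)
        self.dev_phase.u, self.dev_phase.v = float(up), float(vp)
        self._n += xn.size
        return {"x_f": xf, "theta_delayed": thd, "theta_hat": th, "a": a}
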