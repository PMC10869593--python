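"""Charge-balanced pulse shapes, phase gating, and the amplitude law.

Each stimulus is a bipolar pair of rectangles with opposite polarity and
equal area: a narrow, high pulse (the effective kick), a gap, then a
wide, low compensating pulse, so the integral over the stimulus is
exactly zero (no net charge into the tissue).

Pulses are delivered only when the estimated collective phase is within
a tolerance alpha of the vulnerable phase theta0 (negative kick) or of
theta0 + pi (positive kick), with a minimal interval Delta between
onsets.  The kick height follows the vanishing-stimulation feedback law
A_n = max(eps_fb * a(t_n), -A0) with eps_fb < 0: stimulation scales
with the collective amplitude and dies out once the rhythm is gone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as _k

__all__ = [
    "PulseShape",
    "GateParams",
    "GateState",
    "FeedbackLaw",
    "PulseGate",
    "build_pulse",
    "pulse_template",
    "stimulus_amplitude",
]

NEGATIVE_BRANCH = 0  # armed at theta0, narrow pulse has height A_n <= 0
POSITIVE_BRANCH = 1  # armed at theta0 + pi, narrow pulse height >= 0


@dataclass(frozen=True)
class PulseShape:
    """Bipolar rectangle pair: w1 (narrow) / gap / w2 (compensating)."""

    w1: float = 0.5
    gap: float = 0.5
    w2: float = 2.5

    def __post_init__(self):
        if self.w1 <= 0 or self.w2 <= 0 or self.gap < 0:
            raise ValueError("need w1 > 0, w2 > 0, gap >= 0")

    @property
    def T_s(self) -> float:
        """Total stimulus duration."""
        return self.w1 + self.gap + self.w2

    @property
    def height_ratio(self) -> float:
        """(narrow height) / (compensating height) enforcing equal areas."""
        return self.w2 / self.w1


def _n_samples(width: float, delta: float, name: str) -> int:
    n = width / delta
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"{name} = {width} is not an integer multiple of the sampling "
            f"interval {delta}; bit-exact charge balance requires it")
    return int(round(n))


def pulse_template(shape: PulseShape, delta: float) -> np.ndarray:
    """Unit-height sampled waveform; multiply by A_n to get the stimulus.

    Narrow samples are 1, gap samples 0, compensating samples -w1/w2, so
    the discrete integral is exactly zero for any height.
    """
    n1 = _n_samples(shape.w1, delta, "w1")
    ng = _n_samples(shape.gap, delta, "gap")
    n2 = _n_samples(shape.w2, delta, "w2")
    tpl = np.zeros(n1 + ng + n2)
    tpl[:n1] = 1.0
    tpl[n1 + ng:] = -shape.w1 / shape.w2
    return tpl


def build_pulse(shape: PulseShape, height: float,
                delta: float) -> np.ndarray:
    """Sampled stimulus waveform with narrow-pulse height ``height``."""
    return height * pulse_template(shape, delta)


@dataclass(frozen=True)
class GateParams:
    theta0: float
    alpha: float = 0.3
    min_interval: float = 3.0

    def __post_init__(self):
        if not 0.0 < self.alpha < np.pi / 2:
            raise ValueError("alpha must be in (0, pi/2)")
        if self.min_interval < 0:
            raise ValueError("min_interval must be >= 0")


@dataclass(frozen=True)
class FeedbackLaw:
    eps_fb: float = -0.2
    A0: float = 1.0

    def __post_init__(self):
        if self.eps_fb > 0:
            raise ValueError("eps_fb must be <= 0")
        if self.A0 <= 0:
            raise ValueError("A0 must be > 0")


def stimulus_amplitude(law: FeedbackLaw, a: float, branch: int) -> float:
    """Signed narrow-pulse height A_n.

    Negative branch (around theta0): A_n = max(eps_fb * a, -A0);
    positive branch (around theta0 + pi): the negative of that.
    |A_n| <= A0 always, and A_n = 0 when the amplitude has vanished.
    """
    if a < 0:
        raise ValueError("amplitude must be >= 0")
    amp = max(law.eps_fb * a, -law.A0)
    return amp if branch == NEGATIVE_BRANCH else -amp


@dataclass
class GateState:
    """Mutable gating state carried across samples."""

    armed: int = NEGATIVE_BRANCH
    was_inside: bool = False
    last_onset: float = -np.inf
    playing: bool = False
    play_index: int = 0
    play_amplitude: float = 0.0


class PulseGate:
    """Streaming phase gate + pulse player (reference implementation).

    The fused simulation loop runs the same logic in compiled form
    (sharing `gate_decide`); this class is the inspectable per-sample
    API and is cross-checked against the kernel in the test suite.
    """

    def __init__(self, params: GateParams, law: FeedbackLaw,
                 shape: PulseShape, delta: float):
        self.params = params
        self.law = law
        self.shape = shape
        self.delta = delta
        self.template = pulse_template(shape, delta)
        self.state = GateState()
        self.onsets: list[tuple[float, int, float, float]] = []

    def step(self, theta_hat: float, a: float, t: float) -> float:
        """Process one sample; returns the stimulus value P for [t, t+dt).

        Checks the gate, possibly starts a new pulse, and plays out the
        active waveform sample.
        """
        st = self.state
        emit, armed, inside = _k.gate_decide(
            float(theta_hat), float(t), self.params.theta0,
            self.params.alpha, self.params.min_interval,
            st.armed, 1 if st.was_inside else 0, st.last_onset,
            1 if st.playing else 0)
        st.armed = int(armed)
        st.was_inside = bool(inside)
        if emit:
            amp = stimulus_amplitude(self.law, a, st.armed)
            if amp != 0.0:
                st.playing = True
                st.play_index = 0
                st.play_amplitude = amp
                st.last_onset = t
                self.onsets.append((t, st.armed, amp, float(theta_hat)))
        P = 0.0
        if st.playing:
            P = st.play_amplitude * self.template[st.play_index]
            st.play_index += 1
            if st.play_index >= self.template.size:
                st.playing = False
        return P
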