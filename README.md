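# phasegate

Closed-loop, phase-gated pulsatile suppression of pathological collective
oscillations in a mean-field coupled oscillator population — a complete
in-silico testbed for feedback deep-brain-stimulation-like control.

`phasegate` is aimed at researchers in computational neuroscience and
network physiology who want to study how a *realistic* feedback
controller — one that only sees a noisy scalar measurement, must filter
causally, estimate phase and amplitude in real time, and stimulate with
charge-balanced pulses — performs against a collective rhythm whose
envelope waxes and wanes, as beta-band activity recorded from
Parkinsonian patients does.

## The model

The "tissue" is a population of `N` globally coupled, heterogeneous
Bonhoeffer–van der Pol (FitzHugh–Nagumo) relaxation oscillators:

    dx_k/dt = x_k − x_k³/3 − y_k + I_k + ε(t)·X + cos(ψ)·P(t)
    dy_k/dt = 0.1·(x_k − 0.8·y_k + 0.7) + sin(ψ)·P(t)

with the mean field `X = N⁻¹ Σ x_k`, heterogeneity currents `I_k`, a
common stimulus `P(t)` acting along the (unknown to the controller)
direction `ψ = π/4`, and — the model's key feature — a coupling strength
`ε(t)` that is piecewise constant and random: levels uniform in
`ε_c ± Δε`, plateau durations uniform in `[τ_min, τ_max]`. Near the
synchronization transition this produces bursts of collective activity
separated by quiescent epochs whose envelope almost vanishes.

The controller sees only `X_N = X + σξ` (strong white measurement
noise, `σ = 3`) and closes the loop with:

1. a causal linear-phase FIR bandpass filter (2M+1 symmetric taps; a
   pure delay of `M` samples, compensated as
   `θ(t) ≈ θ(t−Mδ) + ωMδ`);
2. a pair of driven damped linear "measuring device" oscillators far
   above the signal band — the strongly damped one has a flat amplitude
   response, the weakly damped one a flat phase response — whose
   resonance relations are inverted to read the signal's instantaneous
   amplitude `a(t)` and phase `θ(t)` using only arithmetic per sample;
3. charge-balanced bipolar pulses, gated to the moments when `θ` is
   within a tolerance `α` of the vulnerable phase `θ₀` (negative kick)
   or `θ₀ + π` (positive kick), with height
   `A_n = max(ε_fb·a, −A₀)`, `ε_fb < 0` — stimulation shrinks toward
   the noise level as the rhythm dies (vanishing stimulation);
4. a three-stage trial-and-error tuner: measure the autonomous mean
   amplitude `a_aut`; sweep `θ₀` over `2πN_cycl` in blocks of `m = 5`
   periods, keeping parameters while the block amplitude improves on
   the running minimum and otherwise advancing
   `θ₀ ← θ₀ + max(Δθ, Δθ·a_curr/a_aut)` while strengthening
   `ε_fb ← ε_fb − g/(1 + c·ε_fb²)`; then hold the best phase `θ_opt`
   and keep adapting `ε_fb` only if the rhythm re-emerges.

Performance is the suppression factor
`S = std(autonomous X) / std(stimulated X)`, computed on the noise-free
mean field against a *matched* autonomous run that shares the
heterogeneity, initial conditions, coupling realization, and noise
stream, so coupling-driven amplitude wandering cancels out of the
comparison.

## Worked example

One full closed-loop trial at the default study conditions (N = 1000,
ε_c = 0.025, Δε = 0.015, σ = 3, M = 350, one learning sweep):

```
$ phasegate run-trial --seed 13 --out-dir demo
S = 3.180, theta_opt = 3.066 rad, eps_fb = -0.414
```

`demo/result.json` holds the trial summary:

```
S                3.1797      # rhythm std reduced 3.2x vs matched autonomous run
theta_opt        3.0664      # learned vulnerable phase (rad)
eps_fb_final    -0.4144      # feedback factor after adaptation
a_aut            0.6909      # autonomous mean amplitude (noise-corrected)
omega            0.1919      # collective frequency estimate (rad/time)
n_pulses         772         # stimuli delivered
mean_abs_height  0.2218      # mean |A_n| of the narrow pulse
```

`demo/series.csv` contains the sampled time series (t, X, X_N, X_f,
theta_hat, a, P, eps), `demo/pulses.csv` the per-pulse log (onset time,
branch, height, gated phase), and `demo/tuner.csv` the per-block
learning decisions. Not every trial succeeds: the tuner judges
stimulation by the amplitude response of a signal that also waxes and
wanes on its own, so a minority of trials lock onto a wrong phase and
end with S < 1 — that failure rate is itself one of the quantities the
package measures.

Other entry points (`phasegate simulate`, `scan-coupling`,
`scan-filter`, `matched-pair`, `batch`) expose the building blocks: the
synchronization-transition scan, the joint (θ₀, M) suppression surface
at constant coupling, and Monte-Carlo campaigns over coupling
realizations. Every command writes a `config.yaml` snapshot next to its
outputs; `--config` replays one.

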