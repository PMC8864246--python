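"""Synthetic generators: AR2 control processes, HRV-like records, nonlinear control.

The two second-order autoregressive (AR2) processes serve as linear controls
for surrogate testing: a broadband, clearly stationary one (``a1=0.8,
a2=-0.25``) and a strongly peaked near-unit-root one (``a1=1.59, a2=-0.96``)
whose slow amplitude modulation makes short realizations fail a restricted
weak-stationarity test. Both are generated at 1800 samples with the first
1500 discarded, leaving 300 — the length of a typical 5-minute beat-interval
segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import TimeSeries

#: Coefficients of the stationary broadband AR2 control (x_t = 0.8 x_{t-1} - 0.25 x_{t-2} + e).
AR2S = (0.8, -0.25)
#: Coefficients of the nonstationary-looking peaked AR2 control (x_t = 1.59 x_{t-1} - 0.96 x_{t-2} + e).
AR2NS = (1.59, -0.96)


@dataclass(frozen=True)
class AR2Spec:
    """Specification of an AR2 recursion x_t = a1*x_{t-1} + a2*x_{t-2} + eps_t.

    ``a2`` is the signed coefficient (so the peaked control has a2=-0.96).
    ``n_burn`` leading samples are discarded to remove the transient from the
    zero initial conditions.
    """

    a1: float
    a2: float
    n_total: int = 1800
    n_burn: int = 1500
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_total > self.n_burn >= 0:
            raise ValueError("require n_total > n_burn >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be positive")


def gen_ar2(spec: AR2Spec) -> TimeSeries:
    """Generate an AR2 realization per ``spec``.

    Innovations are i.i.d. Gaussian(0, noise_sd^2); initial conditions are
    zero and the first ``n_burn`` samples are discarded. Identical spec and
    seed give bitwise-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.noise_sd, size=spec.n_total)
    x = np.empty(spec.n_total)
    xm1 = xm2 = 0.0
    for t in range(spec.n_total):
        xt = spec.a1 * xm1 + spec.a2 * xm2 + eps[t]
        x[t] = xt
        xm2, xm1 = xm1, xt
    if not np.all(np.isfinite(x)):
        raise OverflowError(
            f"AR2 recursion diverged for coefficients a1={spec.a1}, a2={spec.a2}; "
            "they lie outside the stationarity triangle"
        )
    return TimeSeries(
        x[spec.n_burn:],
        label=f"ar2(a1={spec.a1},a2={spec.a2})",
        meta={"generator": "gen_ar2", "spec": spec.__dict__ | {}, "seed": spec.seed},
    )


def gen_ar2s(seed: int = 0, n_total: int = 1800, n_burn: int = 1500) -> TimeSeries:
    """The stationary broadband AR2 control at the study's sample sizes."""
    ts = gen_ar2(AR2Spec(*AR2S, n_total=n_total, n_burn=n_burn, seed=seed))
    ts.label = "AR2s"
    return ts


def gen_ar2ns(seed: int = 0, n_total: int = 1800, n_burn: int = 1500) -> TimeSeries:
    """The peaked near-unit-root AR2 control at the study's sample sizes."""
    ts = gen_ar2(AR2Spec(*AR2NS, n_total=n_total, n_burn=n_burn, seed=seed))
    ts.label = "AR2ns"
    return ts


def gen_hrv_like(
    mean_nn: float = 0.8,
    sdnn: float = 0.04,
    lf_freq: float = 0.1,
    hf_freq: float = 0.25,
    trend_amp: float = 0.0,
    n_beats: int = 300,
    seed: int = 0,
) -> TimeSeries:
    """Generate an HRV-like beat-interval series (seconds).

    The series is ``mean_nn`` plus an LF sinusoid (Mayer-wave band,
    0.04-0.15 Hz), an HF sinusoid (respiratory band, 0.15-0.4 Hz), white
    Gaussian noise, and — when ``trend_amp > 0`` — a slow random-walk trend
    scaled to amplitude ``trend_amp`` that induces nonstationarity of the
    mean. Oscillation frequencies are in Hz of real time; beat times are
    approximated by multiples of ``mean_nn``.

    The three variability components split the target variance so the sample
    SD lands near ``sdnn``. All intervals are validated to stay above 0.2 s.
    """
    if mean_nn <= 0:
        raise ValueError("mean_nn must be positive")
    if sdnn < 0:
        raise ValueError("sdnn must be non-negative")
    if not 0.04 <= lf_freq <= 0.15:
        raise ValueError("lf_freq must lie in the LF band 0.04-0.15 Hz")
    if not 0.15 <= hf_freq <= 0.4:
        raise ValueError("hf_freq must lie in the HF band 0.15-0.4 Hz")
    rng = np.random.default_rng(seed)
    t = np.arange(n_beats) * mean_nn  # beat-time grid, seconds
    # variance thirds: LF, HF, broadband noise
    comp_sd = sdnn / np.sqrt(3.0)
    phase_lf, phase_hf = rng.uniform(0, 2 * np.pi, size=2)
    x = mean_nn + np.sqrt(2.0) * comp_sd * np.sin(2 * np.pi * lf_freq * t + phase_lf)
    x += np.sqrt(2.0) * comp_sd * np.sin(2 * np.pi * hf_freq * t + phase_hf)
    x += rng.normal(0.0, comp_sd, size=n_beats)
    if trend_amp > 0:
        walk = np.cumsum(rng.normal(0.0, 1.0, size=n_beats))
        walk -= walk.mean()
        span = np.abs(walk).max()
        if span > 0:
            x += trend_amp * walk / span
    if np.any(x <= 0.2):
        raise ValueError(
            "parameter combination produced intervals <= 0.2 s; "
            "reduce sdnn/trend_amp or raise mean_nn"
        )
    return TimeSeries(
        x,
        label="hrv_like",
        meta={
            "generator": "gen_hrv_like",
            "mean_nn": mean_nn,
            "sdnn": sdnn,
            "lf_freq": lf_freq,
            "hf_freq": hf_freq,
            "trend_amp": trend_amp,
            "seed": seed,
        },
    )


def gen_nonlinear_control(n_beats: int = 300, noise_sd: float = 0.0, seed: int = 0) -> TimeSeries:
    """Deterministically chaotic control with additive observational noise.

    Uses the Henon map (x' = 1 - 1.4 x^2 + 0.3 y, y' = x), a genuinely
    nonlinear system that no static invertible transform of a linear Gaussian
    process can mimic; it provides the true-positive control for the power of
    the surrogate test. Initial conditions are drawn near the attractor from
    ``seed`` and a 1000-step transient is discarded.
    """
    if n_beats < 100:
        raise ValueError("n_beats must be at least 100")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    x, y = 0.1 + 0.01 * rng.standard_normal(2)
    burn = 1000
    out = np.empty(n_beats)
    for i in range(burn + n_beats):
        x, y = 1.0 - 1.4 * x * x + 0.3 * y, x
        if i >= burn:
            out[i - burn] = x
    if noise_sd > 0:
        out = out + rng.normal(0.0, noise_sd, size=n_beats)
    return TimeSeries(
        out,
        label="henon",
        meta={"generator": "gen_nonlinear_control", "noise_sd": noise_sd, "seed": seed},
    )
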