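"""IAAFT and pinned-wavelet IAAFT (PWIAAFT) surrogate generators.

IAAFT surrogates realize the null hypothesis of a stationary linear Gaussian
process observed through a static invertible transform: they carry exactly
the original amplitude distribution and (to convergence) the original power
spectrum, but randomized Fourier phases. Any temporal localization of
variance — nonstationarity — is destroyed.

PWIAAFT surrogates relax exactly that: the series is taken to the wavelet
domain (MODWT), the largest detail coefficients carrying a fraction ``rho``
of the detail energy are *pinned* at their original time positions, the rest
are IAAFT-randomized scale by scale, and the deepest-level smooth
coefficients are kept fixed. Reconstruction plus a final rank remap returns a
series with the exact original value distribution whose large-scale,
large-amplitude features stay where they were — a linear null that tolerates
nonstationarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .series import TimeSeries
from .wavelets import DEFAULT_WAVELET, ModwtCoeffs, imodwt, modwt

N_SURROGATES = 99


@dataclass
class SurrogateSet:
    original: TimeSeries
    surrogates: list[TimeSeries]
    method: str  # "IAAFT" | "PWIAAFT"
    rho: float | None
    seed: int
    convergence: list[dict] = field(default_factory=list)

    @property
    def n_surr(self) -> int:
        return len(self.surrogates)


def _rank_remap(x: np.ndarray, sorted_amplitudes: np.ndarray) -> np.ndarray:
    """Replace values by the target amplitudes with the same ranks."""
    out = np.empty_like(sorted_amplitudes)
    out[np.argsort(x, kind="stable")] = sorted_amplitudes
    return out


def _iaaft_core(
    x: np.ndarray,
    rng: np.random.Generator,
    max_iter: int,
    pinned: np.ndarray | None = None,
    init: np.ndarray | None = None,
) -> tuple[np.ndarray, int, float]:
    """Shared IAAFT iteration, optionally holding ``pinned`` positions fixed.

    Returns (surrogate, iterations used, relative spectral discrepancy).
    The final step is always the amplitude (rank) adjustment, so the value
    multiset is exact; pinned positions are re-imposed after it.
    """
    n = x.size
    target_amp = np.abs(np.fft.rfft(x))
    sorted_vals = np.sort(x)
    y = rng.permutation(x) if init is None else init.copy()
    if pinned is not None:
        y[pinned] = x[pinned]
    prev_order = np.argsort(y, kind="stable")
    it = 0
    for it in range(1, max_iter + 1):
        spec = np.fft.rfft(y)
        mag = np.abs(spec)
        phase = np.where(mag > 0, spec / np.where(mag == 0, 1.0, mag), 1.0)
        y = np.fft.irfft(target_amp * phase, n=n)
        y = _rank_remap(y, sorted_vals)
        if pinned is not None:
            y[pinned] = x[pinned]
        order = np.argsort(y, kind="stable")
        if np.array_equal(order, prev_order):
            break
        prev_order = order
    amp = np.abs(np.fft.rfft(y))
    denom = float(np.linalg.norm(target_amp))
    discrepancy = float(np.linalg.norm(amp - target_amp) / denom) if denom > 0 else 0.0
    return y, it, discrepancy


def iaaft(
    series: TimeSeries | np.ndarray,
    max_iter: int = 1000,
    seed: int = 0,
) -> TimeSeries:
    """One IAAFT surrogate of ``series``.

    Iterates spectral substitution and rank remapping from a seeded random
    permutation until the rank ordering stops changing (or ``max_iter``);
    convergence metadata is attached to the result.
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    if x.size < 16:
        raise ValueError("IAAFT requires at least 16 samples")
    rng = np.random.default_rng(seed)
    if np.ptp(x) == 0:
        y, it, disc = x.copy(), 0, 0.0
    else:
        y, it, disc = _iaaft_core(x, rng, max_iter)
    meta = {
        "method": "IAAFT",
        "seed": seed,
        "iterations": it,
        "spectral_discrepancy": disc,
        "converged": it < max_iter,
    }
    label = series.label if isinstance(series, TimeSeries) else ""
    return TimeSeries(y, label=f"{label}|iaaft", meta=meta)


def _pin_mask(coeffs: ModwtCoeffs, rho: float, pin_rule: str) -> list[np.ndarray]:
    """Boolean pin masks per detail scale.

    ``energy`` rule (default): pin the globally largest-magnitude detail
    coefficients, fewest first, until they hold at least ``rho`` of the total
    detail energy — rho=0 pins nothing, rho=1 pins everything.
    ``per_scale`` rule: within each scale pin coefficients with
    |w| > (1-rho) * max|w| (strict, so rho=0 again pins nothing).
    ``amplitude`` rule (the opposite-direction reading found in parts of the
    wavelet-surrogate literature): within each scale pin coefficients with
    |w| >= rho * max|w|, so larger rho pins fewer and small rho leaves the
    surrogate close to the original.
    """
    if pin_rule == "energy":
        flat = np.concatenate(coeffs.details)
        masks = [np.zeros(d.size, dtype=bool) for d in coeffs.details]
        if rho <= 0:
            return masks
        e = flat**2
        total = e.sum()
        if total == 0:
            return masks
        order = np.argsort(e)[::-1]
        cum = np.cumsum(e[order])
        n_pin = int(np.searchsorted(cum, rho * total) + 1) if rho < 1 else flat.size
        n_pin = min(n_pin, flat.size)
        pinned_flat = np.zeros(flat.size, dtype=bool)
        pinned_flat[order[:n_pin]] = True
        offset = 0
        for j, d in enumerate(coeffs.details):
            masks[j] = pinned_flat[offset : offset + d.size]
            offset += d.size
        return masks
    if pin_rule == "per_scale":
        masks = []
        for d in coeffs.details:
            mx = np.abs(d).max()
            masks.append(np.abs(d) > (1.0 - rho) * mx if mx > 0 else np.zeros(d.size, bool))
        return masks
    if pin_rule == "amplitude":
        masks = []
        for d in coeffs.details:
            mx = np.abs(d).max()
            masks.append(np.abs(d) >= rho * mx if mx > 0 else np.zeros(d.size, bool))
        return masks
    raise ValueError(f"unknown pin_rule {pin_rule!r}; use 'energy', 'per_scale' or 'amplitude'")


def pwiaaft(
    series: TimeSeries | np.ndarray,
    rho: float = 0.01,
    max_iter: int = 100,
    outer_iter: int = 20,
    seed: int = 0,
    wavelet: str = DEFAULT_WAVELET,
    levels: int | None = None,
    pin_rule: str = "energy",
) -> TimeSeries:
    """One pinned-wavelet IAAFT surrogate of ``series``.

    Steps: MODWT; pin the detail coefficients selected by ``rho`` (see
    :func:`_pin_mask`); IAAFT-randomize each detail scale with the pinned
    positions re-imposed after every iteration; keep the smooth coefficients;
    inverse transform; then an outer loop of full-series IAAFT steps
    (original Fourier amplitudes, then exact value distribution) alternating
    with re-imposition of the pinned/smooth wavelet content, until the rank
    order converges (at most ``outer_iter`` rounds). The final step is the
    rank remap, so the value distribution is exact.
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if x.size < 64:
        raise ValueError("PWIAAFT requires at least 64 samples")
    rng = np.random.default_rng(seed)
    label = series.label if isinstance(series, TimeSeries) else ""
    if np.ptp(x) == 0:
        return TimeSeries(
            x.copy(), label=f"{label}|pwiaaft", meta={"method": "PWIAAFT", "rho": rho, "seed": seed}
        )
    coeffs = modwt(x, wavelet=wavelet, levels=levels)
    masks = _pin_mask(coeffs, rho, pin_rule)

    rand_details = []
    scale_iters = []
    for d, mask in zip(coeffs.details, masks):
        if mask.all():
            rand_details.append(d.copy())
            scale_iters.append(0)
            continue
        y, it, _ = _iaaft_core(d, rng, max_iter, pinned=mask)
        rand_details.append(y)
        scale_iters.append(it)
    work = ModwtCoeffs(details=rand_details, smooth=coeffs.smooth.copy(), wavelet=wavelet)
    y = imodwt(work)

    # Outer loop: the per-scale randomization above destroys cross-scale
    # coherence (MODWT bands overlap), which whitens the composite spectrum.
    # Alternate full-series IAAFT steps (restore the original's Fourier
    # amplitudes, then the exact value distribution) with re-imposition of the
    # pinned/smooth wavelet content, until the rank ordering settles.
    target_amp = np.abs(np.fft.rfft(x))
    sorted_vals = np.sort(x)
    n = x.size
    prev_order = None
    outer_used = 0
    for outer_used in range(1, outer_iter + 1):
        spec = np.fft.rfft(y)
        mag = np.abs(spec)
        phase = np.where(mag > 0, spec / np.where(mag == 0, 1.0, mag), 1.0)
        y = np.fft.irfft(target_amp * phase, n=n)
        y = _rank_remap(y, sorted_vals)
        order = np.argsort(y, kind="stable")
        if prev_order is not None and np.array_equal(order, prev_order):
            break
        prev_order = order
        c = modwt(y, wavelet=wavelet, levels=coeffs.levels)
        for d, d0, mask in zip(c.details, coeffs.details, masks):
            d[mask] = d0[mask]
        c.smooth[:] = coeffs.smooth
        y = imodwt(c)
    else:
        # loop exhausted without rank-order convergence: finish value-exact
        spec = np.fft.rfft(y)
        mag = np.abs(spec)
        phase = np.where(mag > 0, spec / np.where(mag == 0, 1.0, mag), 1.0)
        y = _rank_remap(np.fft.irfft(target_amp * phase, n=n), sorted_vals)
    meta = {
        "method": "PWIAAFT",
        "rho": rho,
        "pin_rule": pin_rule,
        "wavelet": wavelet,
        "levels": coeffs.levels,
        "seed": seed,
        "scale_iterations": scale_iters,
        "outer_iterations": outer_used,
        "converged": outer_used < outer_iter,
        "n_pinned": int(sum(m.sum() for m in masks)),
    }
    return TimeSeries(y, label=f"{label}|pwiaaft", meta=meta)


def generate_set(
    series: TimeSeries | np.ndarray,
    method: str = "IAAFT",
    n_surr: int = N_SURROGATES,
    rho: float = 0.01,
    seed: int = 0,
    **kwargs,
) -> SurrogateSet:
    """Generate ``n_surr`` independent surrogates with derived per-surrogate seeds."""
    if n_surr < 1:
        raise ValueError("n_surr must be at least 1")
    method = method.upper()
    if method not in ("IAAFT", "PWIAAFT"):
        raise ValueError("method must be 'IAAFT' or 'PWIAAFT'")
    ts = series if isinstance(series, TimeSeries) else TimeSeries(np.asarray(series, float))
    ss = np.random.SeedSequence(entropy=seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_surr)]
    surrogates = []
    convergence = []
    for s in child_seeds:
        if method == "IAAFT":
            surr = iaaft(ts, seed=s, **kwargs)
        else:
            surr = pwiaaft(ts, rho=rho, seed=s, **kwargs)
        surrogates.append(surr)
        convergence.append({k: surr.meta.get(k) for k in ("iterations", "outer_iterations",
                                                          "spectral_discrepancy", "converged")})
    return SurrogateSet(
        original=ts,
        surrogates=surrogates,
        method=method,
        rho=rho if method == "PWIAAFT" else None,
        seed=seed,
        convergence=convergence,
    )
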