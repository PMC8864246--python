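"""Time-delay embedding: delay from the autocorrelation function, dimension
from false nearest neighbors, and construction of the state matrix.

The delay tau is taken as the first zero crossing of the sample ACF (the lag
of the first local minimum is the fallback when the ACF never crosses zero
within ``max_lag``). The dimension m is the first at which the fraction of
Kennel false nearest neighbors drops to (effectively) zero. Surrogates are
analyzed with the (m, tau) estimated from their original series, never
re-estimated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .series import TimeSeries

#: Kennel criteria defaults: distance-increase ratio and absolute-increase factor.
R_TOL = 10.0
A_TOL = 2.0
FNN_ZERO_TOL = 0.01


@dataclass
class EmbeddingParams:
    m: int
    tau: int
    fnn_curve: np.ndarray = field(default_factory=lambda: np.empty(0))
    acf_curve: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if self.m < 1 or self.tau < 1:
            raise ValueError("m and tau must be positive integers")


def _as_array(series: TimeSeries | np.ndarray) -> np.ndarray:
    return series.values if isinstance(series, TimeSeries) else np.asarray(series, float)


def acf(series: TimeSeries | np.ndarray, max_lag: int) -> np.ndarray:
    """Biased sample autocorrelation for lags 0..max_lag (acf[0] == 1)."""
    x = _as_array(series)
    if max_lag >= x.size:
        raise ValueError("max_lag must be smaller than the series length")
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError("autocorrelation undefined: series has zero variance")
    full = np.correlate(x, x, mode="full")[x.size - 1 :]
    return full[: max_lag + 1] / denom


def select_tau(series: TimeSeries | np.ndarray, max_lag: int = 50) -> int:
    """Delay = smallest lag where the ACF first reaches zero.

    "Reaches zero" means falling below the 95% sampling band 1.96/sqrt(N) of
    a zero autocorrelation, so a lag whose true ACF is zero is recognized
    despite estimation noise. Falls back (with a warning) to the lag of the
    first local minimum when no such lag exists within ``max_lag``.
    """
    x = _as_array(series)
    max_lag = min(max_lag, x.size - 1)
    curve = acf(x, max_lag)
    band = 1.96 / np.sqrt(x.size)
    for k in range(1, max_lag + 1):
        if curve[k] <= band:
            return k
    # first local minimum fallback
    for k in range(1, max_lag):
        if curve[k] < curve[k - 1] and curve[k] <= curve[k + 1]:
            warnings.warn("ACF has no zero crossing within max_lag; using first local minimum")
            return k
    warnings.warn("ACF monotone over max_lag; using max_lag as delay")
    return max_lag


def delay_embed(series: TimeSeries | np.ndarray, m: int, tau: int) -> np.ndarray:
    """Delay-embedding state matrix with rows (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})."""
    x = _as_array(series)
    if m < 1 or tau < 1:
        raise ValueError("m and tau must be positive integers")
    n_states = x.size - (m - 1) * tau
    if n_states < 1:
        raise ValueError(
            f"series length {x.size} too short for m={m}, tau={tau}; "
            f"need at least {(m - 1) * tau + 1} samples"
        )
    return np.column_stack([x[j * tau : j * tau + n_states] for j in range(m)])


def fnn_fraction(
    series: TimeSeries | np.ndarray,
    tau: int,
    m_max: int = 10,
    r_tol: float = R_TOL,
    a_tol: float = A_TOL,
) -> np.ndarray:
    """Fraction of Kennel false nearest neighbors for each dimension 1..m_max.

    A neighbor pair in dimension m is false when the extra coordinate in
    dimension m+1 increases the distance by more than ``r_tol`` relative to
    the m-dimensional distance, or by more than ``a_tol`` series standard
    deviations absolutely.
    """
    x = _as_array(series)
    sd = x.std()
    if sd == 0:
        raise ValueError("false-nearest-neighbor analysis undefined for constant series")
    fractions = np.empty(m_max)
    for m in range(1, m_max + 1):
        # only points whose (m+1)-dim extension exists
        n_states = x.size - m * tau
        if n_states < 2:
            raise ValueError(f"series too short for FNN at m={m_max}, tau={tau}")
        emb = np.column_stack([x[j * tau : j * tau + n_states] for j in range(m)])
        d = cdist(emb, emb)
        np.fill_diagonal(d, np.inf)
        nn = np.argmin(d, axis=1)
        rd = d[np.arange(n_states), nn]
        extra = np.abs(x[m * tau : m * tau + n_states] - x[nn + m * tau])
        # floor the ratio denominator: numerically duplicate states (periodic
        # signals) would otherwise register as false neighbors by roundoff
        rd_safe = np.maximum(rd, 1e-6 * sd)
        false = (extra / rd_safe > r_tol) | (extra > a_tol * sd)
        fractions[m - 1] = false.mean()
    return fractions


def select_m(fnn_curve: np.ndarray, zero_tol: float = FNN_ZERO_TOL) -> int:
    """Dimension = first m with FNN fraction <= zero_tol; argmin fallback."""
    curve = np.asarray(fnn_curve, float)
    if curve.size == 0:
        raise ValueError("empty FNN curve")
    below = np.flatnonzero(curve <= zero_tol)
    if below.size:
        return int(below[0]) + 1
    warnings.warn("FNN fraction never reached zero tolerance; using its argmin")
    return int(np.argmin(curve)) + 1


def estimate_params(
    series: TimeSeries | np.ndarray,
    max_lag: int = 50,
    m_max: int = 10,
    r_tol: float = R_TOL,
    a_tol: float = A_TOL,
) -> EmbeddingParams:
    """Estimate (tau, m) for a series; the pair surrogates must reuse."""
    x = _as_array(series)
    tau = select_tau(x, max_lag=max_lag)
    curve = fnn_fraction(x, tau=tau, m_max=m_max, r_tol=r_tol, a_tol=a_tol)
    m = select_m(curve)
    return EmbeddingParams(m=m, tau=tau, fnn_curve=curve, acf_curve=acf(x, min(max_lag, x.size - 1)))
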