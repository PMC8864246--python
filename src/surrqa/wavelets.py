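"""Maximal-overlap discrete wavelet transform (MODWT) with circular boundary.

The MODWT is the undecimated, shift-invariant wavelet transform: every level
keeps all N coefficients, any number of levels up to floor(log2(N)) is
admissible for any N (no dyadic-length requirement), reconstruction is exact
and coefficient energies sum to the series energy. Filters come from
PyWavelets; the default family is the Daubechies least-asymmetric order-8
wavelet ("sym8").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from functools import lru_cache

DEFAULT_WAVELET = "sym8"


@lru_cache(maxsize=16)
def _filters(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        w = pywt.Wavelet(wavelet)
    except ValueError as exc:
        names = ", ".join(pywt.wavelist(kind="discrete")[:20])
        raise ValueError(
            f"unsupported wavelet {wavelet!r}; discrete families include: {names}, ..."
        ) from exc
    if not w.orthogonal:
        raise ValueError(f"wavelet {wavelet!r} is not orthogonal; MODWT requires a QMF pair")
    g = np.asarray(w.dec_lo, float) / np.sqrt(2.0)
    h = np.asarray(w.dec_hi, float) / np.sqrt(2.0)
    return g, h


@dataclass
class ModwtCoeffs:
    """MODWT coefficients: details[j] is level j+1 (N each), smooth is V_J."""

    details: list[np.ndarray]
    smooth: np.ndarray
    wavelet: str

    @property
    def levels(self) -> int:
        return len(self.details)

    @property
    def n(self) -> int:
        return self.smooth.size


def max_levels(n: int) -> int:
    return int(np.floor(np.log2(n)))


@lru_cache(maxsize=256)
def _circ_index(n: int, taps: int, step: int, sign: int) -> np.ndarray:
    idx = (np.arange(n)[:, None] + sign * step * np.arange(taps)[None, :]) % n
    idx.setflags(write=False)
    return idx


def _circ_filter(v: np.ndarray, filt: np.ndarray, step: int, sign: int) -> np.ndarray:
    return v[_circ_index(v.size, filt.size, step, sign)] @ filt


def modwt(x: np.ndarray, wavelet: str = DEFAULT_WAVELET, levels: int | None = None) -> ModwtCoeffs:
    """Forward MODWT via the pyramid algorithm (circular boundary)."""
    x = np.asarray(x, float)
    n = x.size
    if levels is None:
        levels = max(1, max_levels(n) - 2)
    if levels > max_levels(n):
        raise ValueError(f"levels={levels} exceeds floor(log2({n})) = {max_levels(n)}")
    g, h = _filters(wavelet)
    v = x
    details = []
    for j in range(1, levels + 1):
        step = 2 ** (j - 1)
        details.append(_circ_filter(v, h, step, sign=-1))
        v = _circ_filter(v, g, step, sign=-1)
    return ModwtCoeffs(details=details, smooth=v, wavelet=wavelet)


def imodwt(coeffs: ModwtCoeffs) -> np.ndarray:
    """Inverse MODWT; reconstructs the original series to ~1e-12."""
    g, h = _filters(coeffs.wavelet)
    v = coeffs.smooth
    for j in range(coeffs.levels, 0, -1):
        step = 2 ** (j - 1)
        v = _circ_filter(coeffs.details[j - 1], h, step, sign=+1) + _circ_filter(
            v, g, step, sign=+1
        )
    return v
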