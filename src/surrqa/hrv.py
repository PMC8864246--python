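"""Beat-interval record I/O, ectopic-interval replacement, and classical HRV indices.

Frequency-domain indices follow short-term HRV convention: the irregularly
sampled tachogram (interval value vs cumulative beat time) is linearly
resampled at 3 Hz, mean-removed, and its spectrum estimated by Welch
averaging of Hamming-windowed 300-sample segments with 50% overlap. LF power
integrates 0.04-0.15 Hz, HF 0.15-0.4 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .series import TimeSeries

RESAMPLE_HZ = 3.0
WELCH_NPERSEG = 300
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass
class HRVIndices:
    mean_nn: float
    sdnn: float
    lf_power: float
    hf_power: float
    lf_hf: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mean_nn": self.mean_nn,
            "sdnn": self.sdnn,
            "lf": self.lf_power,
            "hf": self.hf_power,
            "lf_hf": self.lf_hf,
        }


class RRParseError(ValueError):
    pass


def read_rr(path: str | Path, dialect: str = "auto") -> TimeSeries:
    """Read a beat-interval record from plain text (one value/line) or CSV.

    CSV files must carry a ``value`` column. Values whose median exceeds 10
    are taken to be milliseconds and converted to seconds with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = "csv" if path.suffix.lower() == ".csv" else "plain"
    if dialect == "csv":
        df = pd.read_csv(path)
        if "value" not in df.columns:
            raise RRParseError(f"{path}: CSV must contain a 'value' column")
        col = df["value"]
        bad = col[pd.to_numeric(col, errors="coerce").isna()]
        if len(bad):
            raise RRParseError(f"{path}: non-numeric value at data row {bad.index[0] + 1}")
        values = pd.to_numeric(col).to_numpy(float)
    elif dialect == "plain":
        values_list = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                token = line.strip()
                if not token:
                    continue
                try:
                    values_list.append(float(token))
                except ValueError as exc:
                    raise RRParseError(f"{path}: non-numeric value at line {lineno}") from exc
        values = np.asarray(values_list)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'plain', 'csv' or 'auto'")
    if values.size == 0:
        raise RRParseError(f"{path}: no numeric samples found")
    meta = {"source": str(path), "unit": "s"}
    if np.median(values) > 10:
        warnings.warn(f"{path}: median interval > 10, assuming milliseconds; converting to s")
        values = values / 1000.0
        meta["unit_converted_from"] = "ms"
    return TimeSeries(values, label=path.stem, meta=meta)


def write_rr(series: TimeSeries, path: str | Path) -> None:
    """Write a series as CSV with a single ``value`` column."""
    pd.DataFrame({"value": series.values}).to_csv(path, index=False)


def interpolate_ectopic(
    series: TimeSeries, z_thresh: float = 4.0
) -> tuple[TimeSeries, int]:
    """Replace outlier intervals (robust z vs median/MAD above ``z_thresh``)
    by linear interpolation between the nearest unflagged neighbors.

    Endpoint outliers take the nearest valid value. Returns the cleaned
    series and the replacement count; >20% flagged raises a quality warning,
    all flagged is an error.
    """
    x = series.values
    if x.size < 3:
        raise ValueError("need at least 3 intervals for ectopic interpolation")
    med = np.median(x)
    dev = np.abs(x - med)
    mad = np.median(dev)
    # MAD degenerates to 0 when most intervals are identical; fall back to the
    # mean absolute deviation, then the SD (consistency factors for normality)
    if mad > 0:
        scale = 1.4826 * mad
    elif dev.mean() > 0:
        scale = 1.2533 * dev.mean()
    else:
        scale = x.std()
    if scale == 0:
        return series.with_values(x.copy(), ectopic_replaced=0), 0
    flagged = np.abs(x - med) / scale > z_thresh
    n_flagged = int(flagged.sum())
    if n_flagged == x.size:
        raise ValueError("every interval flagged as ectopic; series unusable")
    if n_flagged > 0.2 * x.size:
        warnings.warn(f"{n_flagged}/{x.size} intervals flagged; record quality is poor")
    if n_flagged == 0:
        return series.with_values(x.copy(), ectopic_replaced=0), 0
    idx = np.arange(x.size)
    good = ~flagged
    cleaned = x.copy()
    cleaned[flagged] = np.interp(idx[flagged], idx[good], x[good])
    return series.with_values(cleaned, ectopic_replaced=n_flagged), n_flagged


def time_domain(series: TimeSeries | np.ndarray) -> tuple[float, float]:
    """meanNN and SDNN (sample standard deviation, ddof=1)."""
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    if x.size < 2:
        raise ValueError("need at least 2 intervals")
    return float(x.mean()), float(x.std(ddof=1))


def frequency_domain(series: TimeSeries | np.ndarray) -> HRVIndices:
    """LF/HF spectral indices of a beat-interval record (seconds).

    The record must span at least 150 s. LF/HF is +inf (with a warning) when
    HF power is exactly zero.
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    mean_nn, sdnn = time_domain(x)
    t = np.cumsum(x)
    duration = t[-1] - t[0]
    if duration < 150.0:
        raise ValueError(f"record spans {duration:.1f} s; need >= 150 s for spectral indices")
    grid = np.arange(t[0], t[-1], 1.0 / RESAMPLE_HZ)
    resampled = np.interp(grid, t, x)
    resampled = resampled - resampled.mean()
    nperseg = min(WELCH_NPERSEG, resampled.size)
    freqs, psd = signal.welch(
        resampled,
        fs=RESAMPLE_HZ,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend="constant",
    )
    lf = float(np.trapezoid(psd[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])],
                            freqs[(freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])]))
    hf = float(np.trapezoid(psd[(freqs >= HF_BAND[0]) & (freqs < HF_BAND[1])],
                            freqs[(freqs >= HF_BAND[0]) & (freqs < HF_BAND[1])]))
    if hf == 0.0:
        warnings.warn("HF power is zero; LF/HF reported as +inf")
        ratio = float("inf")
    else:
        ratio = lf / hf
    return HRVIndices(mean_nn=mean_nn, sdnn=sdnn, lf_power=lf, hf_power=hf, lf_hf=ratio)
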