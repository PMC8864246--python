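"""Core container for ordered beat-interval / process samples."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class TimeSeries:
    """An ordered, finite, real-valued sample sequence.

    Parameters
    ----------
    values
        The samples, in temporal order. Seconds for beat-interval (NN/RR)
        records; arbitrary units for synthetic processes.
    label
        Free-text identifier (record id, process name).
    meta
        Provenance: generator name, parameters, seed, warnings.
    """

    values: np.ndarray
    label: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("TimeSeries requires a 1-D array with at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("TimeSeries values must all be finite")

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values: np.ndarray, **meta_updates: Any) -> "TimeSeries":
        """Copy of this series with new samples and merged metadata."""
        meta = dict(self.meta)
        meta.update(meta_updates)
        return TimeSeries(values=np.asarray(values, dtype=float), label=self.label, meta=meta)
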