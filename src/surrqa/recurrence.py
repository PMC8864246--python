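"""FAN-norm recurrence plots and the 13 recurrence-quantification indices.

The recurrence criterion is the *fixed amount of nearest neighbors* (FAN):
for every column j, exactly the k = max(1, round(eps * N')) states nearest to
state j (the state itself included, distance 0) are marked recurrent. Every
column therefore has the same recurrence density k/N' regardless of trends in
the series, which is why FAN is the norm of choice for nonstationary
beat-interval data; the price is an asymmetric matrix.

Line-based indices (DET, ADL, LLDL, ENT) are computed from the diagonal
run-length histogram with the Theiler band |i-j| <= theiler excluded;
vertical-structure indices (LAM, TT, LLVL) from per-column run lengths;
recurrence-time indices (T1, T2, RPDE) from vertical gap statistics; network
indices (CC, TRANS) from the OR-symmetrized adjacency matrix with the
self-loops removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

#: FAN recurrence-density default.
EPS_FAN = 0.07

INDEX_NAMES = (
    "rr", "det", "adl", "lldl", "ent", "lam", "tt",
    "llvl", "t1", "t2", "rpde", "cc", "trans",
)


@dataclass
class RecurrencePlot:
    """Binary recurrence matrix plus the parameters that produced it."""

    matrix: np.ndarray
    k_neighbors: int
    eps: float
    theiler: int
    m: int = 1
    tau: int = 1

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]


@dataclass
class RQAProfile:
    rr: float
    det: float
    adl: float
    lldl: float
    ent: float
    lam: float
    tt: float
    llvl: float
    t1: float
    t2: float
    rpde: float
    cc: float
    trans: float
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in INDEX_NAMES}

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)


def recurrence_matrix(
    states: np.ndarray,
    eps: float = EPS_FAN,
    theiler: int = 0,
    m: int | None = None,
    tau: int = 1,
) -> RecurrencePlot:
    """Build a FAN recurrence plot from a state matrix.

    For each column j the k nearest states in Euclidean distance are marked,
    self included; ties at the k-th distance are broken toward the lower
    state index so the construction is deterministic. Column sums all equal
    k exactly.
    """
    states = np.asarray(states, float)
    if states.ndim == 1:
        states = states[:, None]
    n = states.shape[0]
    if n < 10:
        raise ValueError("need at least 10 states for a recurrence plot")
    k = max(1, int(round(eps * n)))
    if k >= n:
        raise ValueError(f"FAN neighbor count k={k} must be below the state count {n}")
    d = cdist(states, states)
    # stable sort: equal distances resolve to the lower row index
    order = np.argsort(d, axis=0, kind="stable")
    rows = order[:k, :]
    r = np.zeros((n, n), dtype=bool)
    r[rows, np.arange(n)[None, :]] = True
    return RecurrencePlot(
        matrix=r,
        k_neighbors=k,
        eps=eps,
        theiler=theiler,
        m=states.shape[1] if m is None else m,
        tau=tau,
    )


def _run_lengths(flat: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of ones in a 0/1 array (zero-separated)."""
    if flat.size == 0:
        return np.empty(0, dtype=int)
    padded = np.concatenate(([0], flat.view(np.int8) if flat.dtype == bool else flat, [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return ends - starts


def diagonal_histogram(rp: RecurrencePlot, theiler: int | None = None) -> np.ndarray:
    """Run-length counts of diagonal lines, Theiler band excluded.

    Returns ``counts`` where ``counts[l]`` is the number of maximal diagonal
    runs of exactly length l on diagonals with |i-j| > theiler. Runs cut by
    the matrix edge count at their observed length.
    """
    t = rp.theiler if theiler is None else theiler
    mat = rp.matrix
    n = mat.shape[0]
    pieces = []
    for off in range(t + 1, n):
        pieces.append(np.diagonal(mat, offset=off))
        pieces.append([0])
        pieces.append(np.diagonal(mat, offset=-off))
        pieces.append([0])
    if not pieces:
        return np.zeros(1, dtype=int)
    flat = np.concatenate([np.asarray(p, dtype=np.int8) for p in pieces])
    lengths = _run_lengths(flat)
    return np.bincount(lengths, minlength=2) if lengths.size else np.zeros(1, dtype=int)


def vertical_histogram(rp: RecurrencePlot) -> np.ndarray:
    """Run-length counts of vertical lines over all columns (LOI included)."""
    mat = rp.matrix
    n = mat.shape[0]
    padded = np.zeros((n + 1, n), dtype=np.int8)
    padded[:n, :] = mat
    flat = padded.T.ravel()
    lengths = _run_lengths(flat)
    return np.bincount(lengths, minlength=2) if lengths.size else np.zeros(1, dtype=int)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum()) if p.size else 0.0


def _column_gaps(mat: np.ndarray, first_only: bool) -> np.ndarray:
    """Vertical gaps between recurrence points (T1) or structure onsets (T2)."""
    n = mat.shape[0]
    if first_only:
        onset = mat.copy()
        onset[1:, :] &= ~mat[:-1, :]
        mat = onset
    ii, jj = np.nonzero(mat.T)  # ii = column index, jj = row index, row-sorted per column
    if jj.size < 2:
        return np.empty(0, dtype=int)
    gaps = np.diff(jj)
    same_col = np.diff(ii) == 0
    return gaps[same_col]


def rqa_profile(
    rp: RecurrencePlot,
    theiler: int | None = None,
    l_min: int = 2,
    v_min: int = 2,
    indices: Iterable[str] | None = None,
) -> RQAProfile:
    """Compute the 13 RQA indices of a recurrence plot.

    ``indices`` restricts computation to a subset (the rest are NaN), which
    matters when thousands of surrogate plots are profiled with a single
    discriminative statistic.
    """
    want = set(INDEX_NAMES if indices is None else indices)
    unknown = want - set(INDEX_NAMES)
    if unknown:
        raise ValueError(f"unknown RQA indices: {sorted(unknown)}")
    vals = {name: float("nan") for name in INDEX_NAMES}
    flags: dict[str, str] = {}
    mat = rp.matrix
    n = mat.shape[0]

    if "rr" in want:
        vals["rr"] = float(mat.mean())

    if want & {"det", "adl", "lldl", "ent"}:
        ph = diagonal_histogram(rp, theiler=theiler)
        ls = np.arange(ph.size)
        total_mass = float((ls * ph).sum())
        line_mass = float((ls[l_min:] * ph[l_min:]).sum()) if ph.size > l_min else 0.0
        n_lines = int(ph[l_min:].sum()) if ph.size > l_min else 0
        if total_mass > 0:
            vals["det"] = line_mass / total_mass
        else:
            vals["det"] = 0.0
            flags["det"] = "no diagonal recurrences off the Theiler band"
        if n_lines > 0:
            vals["adl"] = line_mass / n_lines
            vals["ent"] = _entropy(ph[l_min:] / n_lines)
        else:
            vals["adl"] = 0.0
            vals["ent"] = 0.0
            flags["adl"] = flags["ent"] = f"no diagonal lines of length >= {l_min}"
        vals["lldl"] = float(np.flatnonzero(ph)[-1]) if ph.any() else 0.0

    if want & {"lam", "tt", "llvl"}:
        pv = vertical_histogram(rp)
        vs = np.arange(pv.size)
        total_v = float((vs * pv).sum())
        v_mass = float((vs[v_min:] * pv[v_min:]).sum()) if pv.size > v_min else 0.0
        n_v = int(pv[v_min:].sum()) if pv.size > v_min else 0
        vals["lam"] = v_mass / total_v if total_v > 0 else 0.0
        if n_v > 0:
            vals["tt"] = v_mass / n_v
        else:
            vals["tt"] = 0.0
            flags["tt"] = f"no vertical lines of length >= {v_min}"
        vals["llvl"] = float(np.flatnonzero(pv)[-1]) if pv.any() else 0.0

    if "t1" in want:
        gaps = _column_gaps(mat, first_only=False)
        if gaps.size:
            vals["t1"] = float(gaps.mean())
        else:
            vals["t1"] = float("nan")
            flags["t1"] = "no column with two recurrence points"

    if want & {"t2", "rpde"}:
        gaps2 = _column_gaps(mat, first_only=True)
        if gaps2.size:
            vals["t2"] = float(gaps2.mean())
            t_max = int(gaps2.max())
            if t_max > 1:
                counts = np.bincount(gaps2)
                vals["rpde"] = _entropy(counts / counts.sum()) / np.log(t_max)
            else:
                vals["rpde"] = 0.0
                flags["rpde"] = "all recurrence times equal"
        else:
            vals["t2"] = float("nan")
            vals["rpde"] = float("nan")
            flags["t2"] = flags["rpde"] = "no column with two vertical structures"

    if want & {"cc", "trans"}:
        a = (mat | mat.T).astype(float)
        np.fill_diagonal(a, 0.0)
        deg = a.sum(axis=1)
        a3_diag = np.einsum("ij,jk,ki->i", a, a, a)
        denom = deg * (deg - 1)
        valid = denom > 0
        if valid.any():
            vals["cc"] = float((a3_diag[valid] / denom[valid]).mean())
        else:
            vals["cc"] = 0.0
            flags["cc"] = "no node with degree >= 2"
        triples = float(denom.sum())
        vals["trans"] = float(a3_diag.sum() / triples) if triples > 0 else 0.0

    return RQAProfile(**vals, flags=flags)


def series_profile(
    values: np.ndarray,
    m: int,
    tau: int,
    eps: float = EPS_FAN,
    theiler: int | None = None,
    l_min: int = 2,
    v_min: int = 2,
    indices: Sequence[str] | None = None,
) -> RQAProfile:
    """Embed a series, build its FAN recurrence plot, and profile it.

    The Theiler window defaults to the embedding delay ``tau``.
    """
    from .embedding import delay_embed

    states = delay_embed(values, m=m, tau=tau)
    theiler = tau if theiler is None else theiler
    rp = recurrence_matrix(states, eps=eps, theiler=theiler, m=m, tau=tau)
    return rqa_profile(rp, l_min=l_min, v_min=v_min, indices=indices)
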