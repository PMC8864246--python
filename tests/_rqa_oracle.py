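"""Independent brute-force implementations of the 13 RQA indices.

Everything here is written as direct, loop-based transcriptions of the
definitions — no shared code with the package, no vectorization tricks — so
it can serve as an oracle for the optimized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def diag_line_lengths(mat: np.ndarray, theiler: int) -> list[int]:
    n = mat.shape[0]
    lengths = []
    for off in range(-(n - 1), n):
        if abs(off) <= theiler:
            continue
        run = 0
        for i in range(n):
            j = i + off
            if 0 <= j < n and mat[i, j]:
                run += 1
            else:
                if run:
                    lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
    return lengths


def vert_line_lengths(mat: np.ndarray) -> list[int]:
    n = mat.shape[0]
    lengths = []
    for j in range(n):
        run = 0
        for i in range(n):
            if mat[i, j]:
                run += 1
            else:
                if run:
                    lengths.append(run)
                run = 0
        if run:
            lengths.append(run)
    return lengths


def brute_profile(mat: np.ndarray, theiler: int, l_min: int = 2, v_min: int = 2) -> dict:
    n = mat.shape[0]
    out = {}
    out["rr"] = mat.sum() / (n * n)

    dl = diag_line_lengths(mat, theiler)
    total = sum(dl)
    long = [l for l in dl if l >= l_min]
    out["det"] = (sum(long) / total) if total else 0.0
    out["adl"] = (sum(long) / len(long)) if long else 0.0
    out["lldl"] = max(dl) if dl else 0.0
    if long:
        ent = 0.0
        for l in sorted(set(long)):
            p = long.count(l) / len(long)
            ent -= p * math.log(p)
        out["ent"] = ent
    else:
        out["ent"] = 0.0

    vl = vert_line_lengths(mat)
    vtotal = sum(vl)
    vlong = [v for v in vl if v >= v_min]
    out["lam"] = (sum(vlong) / vtotal) if vtotal else 0.0
    out["tt"] = (sum(vlong) / len(vlong)) if vlong else 0.0
    out["llvl"] = max(vl) if vl else 0.0

    t1_gaps = []
    t2_gaps = []
    for j in range(n):
        rows = [i for i in range(n) if mat[i, j]]
        for a, b in zip(rows, rows[1:]):
            t1_gaps.append(b - a)
        firsts = [i for i in rows if i == 0 or not mat[i - 1, j]]
        for a, b in zip(firsts, firsts[1:]):
            t2_gaps.append(b - a)
    out["t1"] = sum(t1_gaps) / len(t1_gaps) if t1_gaps else float("nan")
    out["t2"] = sum(t2_gaps) / len(t2_gaps) if t2_gaps else float("nan")
    if t2_gaps:
        tmax = max(t2_gaps)
        if tmax > 1:
            ent = 0.0
            for t in sorted(set(t2_gaps)):
                p = t2_gaps.count(t) / len(t2_gaps)
                ent -= p * math.log(p)
            out["rpde"] = ent / math.log(tmax)
        else:
            out["rpde"] = 0.0
    else:
        out["rpde"] = float("nan")

    adj = [[bool(mat[i][j] or mat[j][i]) and i != j for j in range(n)] for i in range(n)]
    ccs = []
    tri_sum = 0
    triple_sum = 0
    for i in range(n):
        nb = [j for j in range(n) if adj[i][j]]
        k = len(nb)
        links = 0
        for a in range(k):
            for b in range(a + 1, k):
                if adj[nb[a]][nb[b]]:
                    links += 1
        if k >= 2:
            ccs.append(2 * links / (k * (k - 1)))
            tri_sum += 2 * links  # closed triples centred at i
            triple_sum += k * (k - 1)
    out["cc"] = sum(ccs) / len(ccs) if ccs else 0.0
    out["trans"] = tri_sum / triple_sum if triple_sum else 0.0
    return out


def brute_fan(states: np.ndarray, k: int) -> np.ndarray:
    """FAN matrix by full distance sort per column, lowest index wins ties."""
    n = states.shape[0]
    mat = np.zeros((n, n), dtype=bool)
    for j in range(n):
        d = [(float(np.linalg.norm(states[i] - states[j])), i) for i in range(n)]
        d.sort()
        for _, i in d[:k]:
            mat[i, j] = True
    return mat


def brute_mc_pvalue(orig: float, surr: list[float]) -> float:
    hi = sum(1 for s in surr if s >= orig)
    lo = sum(1 for s in surr if s <= orig)
    return (1 + min(hi, lo)) / (len(surr) + 1)
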