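"""Surrogate hypothesis testing and study-level comparison statistics.

The core test is a rank-based Monte-Carlo comparison: a discriminative
statistic (an RQA index) is computed on the original series and on each of
its n surrogates; the two-sided min-tail p-value is

    p = (1 + #{surrogates at least as extreme as the original,
               in the nearer tail}) / (n + 1)

so with 99 surrogates the attainable floor is 0.01, reached exactly when the
original lies strictly outside the surrogate range. The null (a linear
process compatible with the surrogate constraints) is rejected at p < 0.05.
Ties count as "at least as extreme" — the conservative direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import stats

from .recurrence import INDEX_NAMES, series_profile
from .series import TimeSeries
from .surrogates import SurrogateSet

ALPHA = 0.05


@dataclass
class TestResult:
    index_name: str
    original_value: float
    surrogate_values: np.ndarray
    p_value: float
    reject: bool
    tested: bool = True
    note: str = ""


@dataclass
class GroupSummary:
    group: str
    index_name: str
    n_series: int
    n_reject: int
    pct: float
    ci_low: float
    ci_high: float


def mc_pvalue(original: float, surrogate_values: np.ndarray) -> float:
    """Min-tail Monte-Carlo p-value with floor 1/(n+1)."""
    sv = np.asarray(surrogate_values, float)
    n = sv.size
    c_hi = int(np.sum(sv >= original))
    c_lo = int(np.sum(sv <= original))
    return (1 + min(c_hi, c_lo)) / (n + 1)


def surrogate_test(
    series: TimeSeries | np.ndarray,
    surrogate_set: SurrogateSet,
    m: int,
    tau: int,
    eps: float = 0.07,
    theiler: int | None = None,
    indices: Sequence[str] | None = None,
    alpha: float = ALPHA,
    profile_fn: Callable[[np.ndarray], dict[str, float]] | None = None,
) -> list[TestResult]:
    """Run the surrogate test for each RQA index.

    (m, tau) must come from the original series; surrogates reuse them. A
    custom ``profile_fn`` (values -> {index: value}) overrides the built-in
    RQA profiling, e.g. to test a non-RQA statistic.
    """
    x = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    names = list(INDEX_NAMES if indices is None else indices)
    if profile_fn is None:
        def profile_fn(values: np.ndarray) -> dict[str, float]:
            return series_profile(values, m=m, tau=tau, eps=eps, theiler=theiler,
                                  indices=names).as_dict()

    orig = profile_fn(x)
    surr = [profile_fn(s.values) for s in surrogate_set.surrogates]
    results = []
    for name in names:
        ov = orig[name]
        sv = np.array([p[name] for p in surr])
        if not np.isfinite(ov) or not np.all(np.isfinite(sv)):
            results.append(TestResult(name, ov, sv, float("nan"), False, tested=False,
                                      note="sentinel/undefined statistic; excluded"))
            continue
        p = mc_pvalue(ov, sv)
        results.append(TestResult(name, float(ov), sv, p, p < alpha))
    return results


def rejection_rates(
    grouped_results: dict[str, list[list[TestResult]]],
    ci_method: str = "jeffreys",
) -> list[GroupSummary]:
    """Per-(group, index) rejection percentages with 95% binomial CIs.

    ``grouped_results`` maps a group label to a list of per-series result
    lists. Untested (sentinel) indices are excluded from both numerator and
    denominator.
    """
    summaries = []
    for group, series_results in grouped_results.items():
        if not series_results:
            import warnings

            warnings.warn(f"group {group!r} is empty; skipped")
            continue
        by_index: dict[str, list[bool]] = {}
        for res_list in series_results:
            for r in res_list:
                if r.tested:
                    by_index.setdefault(r.index_name, []).append(r.reject)
        for name, rejects in by_index.items():
            n = len(rejects)
            k = int(sum(rejects))
            lo, hi = proportion_ci(k, n, method=ci_method)
            summaries.append(GroupSummary(group, name, n, k, 100.0 * k / n,
                                          100.0 * lo, 100.0 * hi))
    return summaries


def proportion_ci(k: int, n: int, conf: float = 0.95, method: str = "jeffreys") -> tuple[float, float]:
    """Binomial proportion CI.

    The default is the Jeffreys interval (quantiles of Beta(k+1/2, n-k+1/2)),
    which reproduces the rejection-rate intervals of the kind printed in
    short-term HRV surrogate studies to the decimal; Clopper-Pearson (exact)
    and Wilson are available alternatives.
    """
    if not 0 <= k <= n or n == 0:
        raise ValueError("require 0 <= k <= n, n > 0")
    alpha_half = (1 - conf) / 2
    if method == "jeffreys":
        lo = 0.0 if k == 0 else stats.beta.ppf(alpha_half, k + 0.5, n - k + 0.5)
        hi = 1.0 if k == n else stats.beta.ppf(1 - alpha_half, k + 0.5, n - k + 0.5)
        return float(lo), float(hi)
    if method == "clopper-pearson":
        alpha = 1 - conf
        lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
        hi = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
        return float(lo), float(hi)
    if method == "wilson":
        z = stats.norm.ppf(0.5 + conf / 2)
        phat = k / n
        denom = 1 + z**2 / n
        center = (phat + z**2 / (2 * n)) / denom
        half = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2)) / denom
        return float(max(0.0, center - half)), float(min(1.0, center + half))
    raise ValueError(f"unknown CI method {method!r}")


def compare_proportions(k_a: int, n_a: int, k_b: int, n_b: int, n_comparisons: int = 1) -> float:
    """Two-sided Fisher exact test on the 2x2 rejection table, Bonferroni-adjusted."""
    table = [[k_a, n_a - k_a], [k_b, n_b - k_b]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(min(1.0, p * n_comparisons))


def correlate_meanNN(
    mean_nn: Sequence[float],
    profiles: Sequence[dict[str, float]],
    indices: Iterable[str] = INDEX_NAMES,
) -> dict[str, tuple[float, float]]:
    """Spearman rho (and p) of each RQA index against meanNN across records.

    For surrogate tables, each record's index value should be the mean over
    that record's surrogates. Constant columns yield a NaN sentinel.
    """
    mean_nn = np.asarray(mean_nn, float)
    if mean_nn.size < 5:
        raise ValueError("need at least 5 paired records")
    if len(profiles) != mean_nn.size:
        raise ValueError("mean_nn and profiles must pair up")
    out = {}
    for name in indices:
        vals = np.array([p[name] for p in profiles], float)
        if np.ptp(vals) == 0 or np.ptp(mean_nn) == 0:
            out[name] = (float("nan"), float("nan"))
            continue
        rho, p = stats.spearmanr(mean_nn, vals)
        out[name] = (float(rho), float(p))
    return out


def compare_distributions(a: Sequence[float], b: Sequence[float]) -> dict:
    """Two-sided Mann-Whitney U with medians and order-statistic 95% CIs."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (no_ties and max(a.size, b.size) <= 25) else "asymptotic"
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "u": float(u),
        "p": float(p),
        "median_a": float(np.median(a)),
        "ci_a": median_ci(a),
        "median_b": float(np.median(b)),
        "ci_b": median_ci(b),
    }


def median_ci(x: np.ndarray, conf: float = 0.95) -> tuple[float, float]:
    """Distribution-free median CI from binomial order statistics."""
    x = np.sort(np.asarray(x, float))
    n = x.size
    alpha = 1 - conf
    lo_idx = int(stats.binom.ppf(alpha / 2, n, 0.5))
    hi_idx = int(stats.binom.isf(alpha / 2, n, 0.5))
    lo_idx = max(0, min(lo_idx, n - 1))
    hi_idx = max(0, min(hi_idx, n - 1))
    return float(x[lo_idx]), float(x[hi_idx])
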