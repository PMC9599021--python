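"""Genotype-level descriptive statistics and multiple comparisons.

Provides the classical toolkit for a germplasm screening table: per-genotype
mean +/- SE summaries, one-way ANOVA, Duncan's multiple range test with a
compact-letter display, Pearson correlation matrices across genotype means,
and the fold-range / grand-mean summaries usually quoted in the text of a
screening study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "DuncanResult",
    "summarize_groups",
    "one_way_anova",
    "duncan_mrt",
    "pairwise_significance",
    "letters_consistent",
    "pearson_matrix",
    "range_ratio",
    "grand_mean",
]


@dataclass(frozen=True)
class GroupSummary:
    genotype: str
    variable: str
    mean: float
    se: float | None
    n: int


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    mse: float
    p: float


@dataclass(frozen=True)
class DuncanResult:
    """Duncan's multiple range test outcome.

    ``order`` ranks group indices by descending mean; ``letters`` maps each
    input group index to its letter string; ``significant`` is the boolean
    matrix of pairwise significance in input order.
    """

    alpha: float
    means: tuple[float, ...]
    order: tuple[int, ...]
    letters: tuple[str, ...]
    significant: np.ndarray
    mse: float
    df_error: int
    critical_ranges: dict[int, float]


def summarize_groups(replicates: pd.DataFrame) -> list[GroupSummary]:
    """Mean and SE (= sd/sqrt(n), ddof=1) per genotype per variable.

    Expects a long table with columns ``genotype``, ``variable``, ``value``.
    Groups with a single replicate get ``se=None``.
    """
    out: list[GroupSummary] = []
    for (g, v), sub in replicates.groupby(["genotype", "variable"], sort=False):
        vals = sub["value"].to_numpy(dtype=float)
        n = len(vals)
        se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else None
        out.append(GroupSummary(str(g), str(v), float(np.mean(vals)), se, n))
    return out


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Fixed-effects one-way ANOVA from replicate vectors."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(len(a) < 2 for a in arrs):
        raise ValueError("every group needs at least two replicates")
    grand = np.mean(np.concatenate(arrs))
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrs)
    ssw = sum(np.sum((a - a.mean()) ** 2) for a in arrs)
    df_b = len(arrs) - 1
    df_w = sum(len(a) for a in arrs) - len(arrs)
    msb = ssb / df_b
    mse = ssw / df_w
    if mse == 0.0:
        f = 0.0 if msb == 0.0 else np.inf
    else:
        f = msb / mse
    p = float(_st.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    return AnovaResult(float(f), df_b, df_w, float(mse), p)


@lru_cache(maxsize=4096)
def _studentized_range_q(upper_tail: float, span: int, df_error: int) -> float:
    # scipy's studentized-range quantile is expensive (~0.1 s per call); the
    # same (alpha, span, df) triples recur constantly across groups and seeds
    return float(_st.studentized_range.ppf(upper_tail, span, df_error))


def _duncan_critical_range(span: int, alpha: float, df_error: int, mse: float, n: float) -> float:
    # Duncan's protection level: alpha_p = 1 - (1-alpha)^(p-1)
    alpha_p = 1.0 - (1.0 - alpha) ** (span - 1)
    q = _studentized_range_q(1.0 - alpha_p, span, df_error)
    return float(q * np.sqrt(mse / n))


def pairwise_significance(
    means: Sequence[float], ns: Sequence[int], mse: float, df_error: int, alpha: float = 0.05
) -> np.ndarray:
    """Duncan's stepwise pairwise significance matrix (input order).

    Means are ranked; ranges are examined from the widest span downwards and
    a range whose endpoints differ by less than its critical range is declared
    homogeneous together with everything inside it (Duncan's protection rule).
    """
    m = np.asarray(means, dtype=float)
    k = len(m)
    ns = np.asarray(ns, dtype=float)
    if np.ptp(ns) > 0:
        warnings.warn(
            "unequal group sizes: using the harmonic mean of n in Duncan's "
            "critical ranges",
            UserWarning,
            stacklevel=2,
        )
    n_eff = len(ns) / np.sum(1.0 / ns)
    # stable sort, descending mean, ties broken by input order
    order = sorted(range(k), key=lambda i: (-m[i], i))
    sorted_means = m[order]
    ns_interval: list[tuple[int, int]] = []  # homogeneous intervals in sorted positions
    sig_sorted = np.zeros((k, k), dtype=bool)
    for span in range(k, 1, -1):
        r_p = _duncan_critical_range(span, alpha, df_error, mse, n_eff)
        for i in range(0, k - span + 1):
            j = i + span - 1
            if any(a <= i and j <= b for a, b in ns_interval):
                continue
            if sorted_means[i] - sorted_means[j] <= r_p:
                ns_interval.append((i, j))
            else:
                sig_sorted[i, j] = sig_sorted[j, i] = True
    # pairs inside a homogeneous interval are not significant
    for a, b in ns_interval:
        sig_sorted[a : b + 1, a : b + 1] = False
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(k):
            sig[order[i], order[j]] = sig_sorted[i, j]
    return sig


def _insert_absorb(k: int, sig: np.ndarray, order: Sequence[int]) -> list[str]:
    """Compact-letter display by the insert-and-absorb algorithm."""
    cols: list[set[int]] = [set(range(k))]
    for a in range(k):
        for b in range(a + 1, k):
            if not sig[a, b]:
                continue
            for col in [c for c in cols if a in c and b in c]:
                cols.remove(col)
                cols.append(col - {a})
                cols.append(col - {b})
            # absorb: drop empty, duplicate, and strictly contained columns
            kept: list[set[int]] = []
            for c in cols:
                if c and c not in kept and not any(c < d for d in cols):
                    kept.append(c)
            cols = kept
    # order letters so 'a' goes with the highest mean
    rank = {g: pos for pos, g in enumerate(order)}
    cols.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for li, col in enumerate(cols):
        lab = alphabet[li] if li < 26 else f"({li})"
        for g in col:
            letters[g] += lab
    return ["".join(sorted(s)) for s in letters]


def duncan_mrt(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> DuncanResult:
    """Duncan's multiple range test with a compact-letter display.

    Groups sharing any letter are not significantly different at the chosen
    protection level; groups sharing no letter are.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    anova = one_way_anova(groups)
    means = [float(np.mean(np.asarray(g, dtype=float))) for g in groups]
    ns = [len(g) for g in groups]
    k = len(means)
    sig = pairwise_significance(means, ns, anova.mse, anova.df_within, alpha)
    order = tuple(sorted(range(k), key=lambda i: (-means[i], i)))
    letters = _insert_absorb(k, sig, order)
    n_eff = k / sum(1.0 / n for n in ns)
    crit = {
        p: _duncan_critical_range(p, alpha, anova.df_within, anova.mse, n_eff)
        for p in range(2, k + 1)
    }
    return DuncanResult(
        alpha=alpha,
        means=tuple(means),
        order=order,
        letters=tuple(letters),
        significant=sig,
        mse=anova.mse,
        df_error=anova.df_within,
        critical_ranges=crit,
    )


def letters_consistent(letters: Sequence[str], sig: np.ndarray) -> bool:
    """Check a compact-letter display against a pairwise significance matrix.

    Valid iff every significant pair shares no letter and every
    non-significant pair shares at least one.
    """
    k = len(letters)
    for i in range(k):
        for j in range(i + 1, k):
            shared = set(letters[i]) & set(letters[j])
            if sig[i, j] and shared:
                return False
            if not sig[i, j] and not shared:
                return False
    return True


def pearson_matrix(
    means: pd.DataFrame, variables: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pearson correlations between variables across genotype means.

    Pairwise-complete observations; a zero-variance variable yields NaN
    against everything (its diagonal stays 1).
    """
    cols = list(variables) if variables is not None else list(means.columns)
    sub = means[cols].astype(float)
    if len(sub) < 3:
        raise ValueError("need at least 3 genotypes for a correlation matrix")
    corr = sub.corr(method="pearson", min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def range_ratio(values: Sequence[float]) -> float:
    """Fold range max/min across genotype means; requires strictly positive values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    if v.min() <= 0:
        raise ValueError("range ratio undefined for non-positive values")
    return float(v.max() / v.min())


def grand_mean(values: Sequence[float]) -> float:
    """Arithmetic mean over genotypes."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty vector")
    return float(v.mean())
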