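"""Statistical procedures used by the enrichment analyses.

Self-contained implementations (distribution tail areas come from scipy):
Yates-corrected chi-square in both goodness-of-fit and 2x2 contingency form,
Mann-Whitney U with an exact small-sample path, Spearman rank correlation,
Kruskal-Wallis, Dunn's pairwise z tests with Bonferroni family adjustment,
and a Monte-Carlo (Lilliefors-style) Kolmogorov-Smirnov normality test.

The goodness-of-fit Yates form treats the expected counts as fixed; it is the
right tool when the expected values are (near-)deterministic, e.g. derived
from proteome-wide residue fractions or from the median of several control
repetitions.  When both samples are single random draws of comparable size,
use the 2x2 contingency form, which accounts for the variance of both.
"""
from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2
from scipy.stats import norm as _norm
from scipy.stats import rankdata

from .types import TestResult

__all__ = [
    "yates_chi_square",
    "yates_chi_square_2x2",
    "mann_whitney_u",
    "spearman_rho",
    "kruskal_wallis",
    "dunn_pairwise",
    "bonferroni_threshold",
    "ks_normality",
]


def _as_float_array(x: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(list(x), dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


def yates_chi_square(observed: Sequence[float], expected: Sequence[float]) -> TestResult:
    """Yates continuity-corrected chi-square goodness-of-fit test.

    chi2 = sum over cells of max(|O - E| - 0.5, 0)^2 / E with df = k - 1.
    The correction is clamped at zero, so O == E gives chi2 = 0, p = 1.
    """
    obs = _as_float_array(observed, "observed")
    exp = _as_float_array(expected, "expected")
    if obs.size != exp.size or obs.size < 2:
        raise ValueError("observed and expected must have equal length k >= 2")
    if np.any(exp <= 0):
        raise ValueError("expected counts must all be positive")
    notes = ""
    tot_o, tot_e = obs.sum(), exp.sum()
    if abs(tot_o - tot_e) > 1e-6 * max(abs(tot_e), 1.0):
        notes = f"totals differ: observed {tot_o:g} vs expected {tot_e:g}"
    corrected = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    stat = float(np.sum(corrected**2 / exp))
    df = obs.size - 1
    p = float(_chi2.sf(stat, df))
    return TestResult("yates_chi_square", stat, p, df=df, notes=notes)


def yates_chi_square_2x2(
    assigned_a: int, n_a: int, assigned_b: int, n_b: int
) -> TestResult:
    """Yates-corrected chi-square test of independence on a 2x2 table.

    Compares two proportions (``assigned_a/n_a`` vs ``assigned_b/n_b``)
    accounting for the sampling variance of both groups.
    """
    table = np.array(
        [
            [assigned_a, n_a - assigned_a],
            [assigned_b, n_b - assigned_b],
        ],
        dtype=float,
    )
    if np.any(table < 0):
        raise ValueError("negative cell count")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    if n <= 0 or np.any(row <= 0):
        raise ValueError("empty group")
    if np.any(col == 0):
        # degenerate: one column empty, proportions identical by construction
        return TestResult(
            "yates_chi_square_2x2", 0.0, 1.0, df=1, notes="degenerate margin"
        )
    expected = np.outer(row, col) / n
    corrected = np.maximum(np.abs(table - expected) - 0.5, 0.0)
    stat = float(np.sum(corrected**2 / expected))
    p = float(_chi2.sf(stat, 1))
    return TestResult("yates_chi_square_2x2", stat, p, df=1)


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], method: str = "auto"
) -> TestResult:
    """Two-sided Mann-Whitney U test; U = min(U_x, U_y) is reported.

    ``method='auto'`` uses exact enumeration when n <= 8, m <= 8 and there
    are no ties, otherwise a normal approximation with tie-corrected variance
    and a 0.5 continuity correction; ``'exact'``/``'normal'`` force a path.
    """
    if method not in ("auto", "exact", "normal"):
        raise ValueError("method must be 'auto', 'exact' or 'normal'")
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    n, m = xa.size, ya.size
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([xa, ya])
    if np.all(pooled == pooled[0]):
        return TestResult(
            "mann_whitney_u", n * m / 2.0, 1.0, notes="all values identical"
        )
    ranks = rankdata(pooled)
    r_x = float(ranks[:n].sum())
    u_x = r_x - n * (n + 1) / 2.0
    u_y = n * m - u_x
    u_min = min(u_x, u_y)
    has_ties = np.unique(pooled).size < pooled.size
    use_exact = (
        method == "exact"
        or (method == "auto" and n <= 8 and m <= 8 and not has_ties)
    )
    if use_exact:
        if has_ties or n > 12 or m > 12:
            raise ValueError("exact path requires small tie-free samples")
        # P(U <= u_min) by enumeration of C(n+m, n) labelings of the x ranks
        total = comb(n + m, n)
        count = 0
        base = n * (n + 1) / 2.0
        for picked in combinations(range(1, n + m + 1), n):
            ux = sum(picked) - base
            if min(ux, n * m - ux) <= u_min + 1e-9:
                count += 1
        # min() folds both tails into one count, so no doubling is needed:
        # x=(1,2), y=(3,4) gives 2 of C(4,2)=6 labelings, p = 1/3
        p = min(1.0, count / total)
        return TestResult("mann_whitney_u", u_min, p, notes="exact")
    # normal approximation, tie-corrected variance
    N = n + m
    _, t = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(t**3 - t)) / (N * (N - 1))
    var_u = n * m / 12.0 * ((N + 1) - tie_term)
    if var_u <= 0:
        return TestResult("mann_whitney_u", u_min, 1.0, notes="zero variance")
    mu = n * m / 2.0
    z = (abs(u_min - mu) - 0.5) / np.sqrt(var_u)
    z = max(z, 0.0)
    p = min(1.0, 2.0 * float(_norm.sf(z)))
    return TestResult("mann_whitney_u", u_min, p, notes="normal approximation")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of midranks."""
    xa = _as_float_array(x, "x")
    ya = _as_float_array(y, "y")
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        raise ValueError("rank correlation undefined for a constant vector")
    rx = rankdata(xa)
    ry = rankdata(ya)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def _rank_groups(groups: Sequence[Sequence[float]]):
    arrs = [_as_float_array(g, "group") for g in groups]
    if len(arrs) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 1 for a in arrs):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate(arrs)
    ranks = rankdata(pooled)
    out = []
    pos = 0
    for a in arrs:
        out.append(ranks[pos : pos + a.size])
        pos += a.size
    return arrs, pooled, out


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H test across >= 2 groups."""
    arrs, pooled, group_ranks = _rank_groups(groups)
    N = pooled.size
    if np.all(pooled == pooled[0]):
        return TestResult(
            "kruskal_wallis", 0.0, 1.0, df=len(arrs) - 1, notes="all values tied"
        )
    h = 12.0 / (N * (N + 1)) * sum(
        r.size * (r.mean() ** 2) for r in group_ranks
    ) - 3.0 * (N + 1)
    _, t = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(t**3 - t)) / (N**3 - N)
    if correction > 0:
        h /= correction
    h = max(h, 0.0)
    df = len(arrs) - 1
    return TestResult("kruskal_wallis", float(h), float(_chi2.sf(h, df)), df=df)


def dunn_pairwise(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    adjust: bool = True,
) -> list[TestResult]:
    """Dunn's post-hoc pairwise comparisons after Kruskal-Wallis.

    z_ij = (meanrank_i - meanrank_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))
    with tie correction T = sum(t^3 - t) / (12 (N - 1)).  Two-sided p-values
    are Bonferroni-multiplied by the number of pairs when ``adjust``.
    """
    arrs, pooled, group_ranks = _rank_groups(groups)
    g = len(arrs)
    if labels is None:
        labels = [f"group{i}" for i in range(g)]
    N = pooled.size
    _, t = np.unique(pooled, return_counts=True)
    tie_corr = float(np.sum(t**3 - t)) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_corr
    n_pairs = g * (g - 1) // 2
    results = []
    for i, j in combinations(range(g), 2):
        ni, nj = arrs[i].size, arrs[j].size
        var = base_var * (1.0 / ni + 1.0 / nj)
        diff = group_ranks[i].mean() - group_ranks[j].mean()
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = diff / np.sqrt(var)
            p = 2.0 * float(_norm.sf(abs(z)))
            if adjust:
                p = min(1.0, p * n_pairs)
        results.append(
            TestResult(
                "dunn",
                float(z),
                p,
                notes=f"{labels[i]} vs {labels[j]}"
                + ("" if adjust else "; unadjusted"),
            )
        )
    return results


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def ks_normality(
    x: Sequence[float], mc_reps: int = 500, seed: int = 0
) -> TestResult:
    """Kolmogorov-Smirnov test of normality with estimated mean/SD.

    The p-value is Monte-Carlo (Lilliefors-style): ``mc_reps`` normal samples
    of the same size are drawn, parameters re-estimated for each, and the
    exceedance fraction of the D statistic reported (add-one estimator).
    """
    xa = np.sort(_as_float_array(x, "x"))
    n = xa.size
    if n < 5:
        raise ValueError("need at least 5 observations")

    def _d(sorted_vals: np.ndarray) -> float:
        mu = sorted_vals.mean()
        sd = sorted_vals.std(ddof=1)
        if sd == 0:
            return 1.0
        cdf = _norm.cdf((sorted_vals - mu) / sd)
        i = np.arange(1, sorted_vals.size + 1)
        d_plus = np.max(i / sorted_vals.size - cdf)
        d_minus = np.max(cdf - (i - 1) / sorted_vals.size)
        return float(max(d_plus, d_minus))

    d_obs = _d(xa)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(mc_reps):
        sim = np.sort(rng.standard_normal(n))
        if _d(sim) >= d_obs:
            exceed += 1
    p = (1 + exceed) / (mc_reps + 1)
    return TestResult(
        "ks_normality", d_obs, float(p), notes=f"monte-carlo, {mc_reps} reps"
    )
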