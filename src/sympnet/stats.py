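"""Association and comparison statistics for group-level strength series.

Covers the analyses linking global connectivity strength to clinical change
across the change-magnitude groups: Spearman rank correlations (exact
permutation p for small tie-free samples, asymptotic otherwise), the
Fisher r-to-z comparison of two correlation coefficients, a one-way
repeated-measures ANOVA of strength over the three phases with the eight
groups as the repeated unit, and Bonferroni-corrected paired t-tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsError",
    "CorrelationResult",
    "spearman_test",
    "fisher_z_compare",
    "rm_anova_time",
    "paired_t_bonferroni",
    "phase_correlation_suite",
]


class StatsError(ValueError):
    """Statistical input is degenerate or undefined."""


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str  # "exact" | "asymptotic"


def _exact_spearman_p(rho_obs: float, n: int) -> float:
    """Two-sided exact p by enumeration of all n! rank permutations."""
    total = math.factorial(n)
    denom = n * (n * n - 1)
    base = np.arange(n)
    count = 0
    perms = itertools.permutations(range(n))
    while True:
        chunk = list(itertools.islice(perms, 200_000))
        if not chunk:
            break
        P = np.asarray(chunk)
        d2 = ((P - base) ** 2).sum(axis=1)
        rho = 1.0 - 6.0 * d2 / denom
        count += int(np.count_nonzero(np.abs(rho) >= abs(rho_obs) - 1e-12))
    return count / total


def spearman_test(x, y) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    The p-value is exact (full enumeration over rank permutations) when
    n <= 10 and neither vector has ties; otherwise the asymptotic
    t-approximation is used.  Constant input is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("x and y must be 1-d and of equal length")
    n = len(x)
    if n < 4:
        raise StatsError(f"n={n} too small (need >= 4)")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise StatsError("correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    no_ties = np.unique(x).size == n and np.unique(y).size == n
    if n <= 10 and no_ties:
        return CorrelationResult(rho, _exact_spearman_p(rho, n), n, "exact")
    # asymptotic t-approximation on rho
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho, p, n, "asymptotic")


def fisher_z_compare(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided p
    from the standard normal.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if abs(r) >= 1.0:
            raise StatsError("|r| = 1 has an infinite Fisher transform")
        if n <= 3:
            raise StatsError(f"n={n} too small for the Fisher comparison")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = float(2.0 * sps.norm.sf(abs(z)))
    return float(z), p


def rm_anova_time(series: np.ndarray) -> tuple[float, int, int, float]:
    """One-way repeated-measures ANOVA: rows are the repeated units (groups),
    columns are timepoints.  Returns (F, df1, df2, p) with df1 = t-1 and
    df2 = (t-1)(g-1); for 8 groups x 3 phases this is df = (2, 14).
    """
    X = np.asarray(series, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise StatsError("need a complete groups x timepoints matrix (>= 2 each)")
    if np.isnan(X).any():
        raise StatsError("missing cells are not supported (no imputation)")
    g, t = X.shape
    grand = X.mean()
    m_time = X.mean(axis=0)
    m_subj = X.mean(axis=1)
    ss_time = g * float(((m_time - grand) ** 2).sum())
    resid = X - m_time[None, :] - m_subj[:, None] + grand
    ss_err = float((resid**2).sum())
    df1, df2 = t - 1, (t - 1) * (g - 1)
    ms_time = ss_time / df1
    ms_err = ss_err / df2
    if ms_err == 0:
        raise StatsError("zero error variance; F undefined")
    F = ms_time / ms_err
    p = float(sps.f.sf(F, df1, df2))
    return float(F), df1, df2, p


def paired_t_bonferroni(series: np.ndarray, labels=None) -> pd.DataFrame:
    """Two-tailed paired t-tests for every timepoint pair, Bonferroni-adjusted.

    Adjusted p = min(1, m * p_raw) with m the number of pairs.  A pair with
    zero within-pair variance has an undefined t; by policy identical
    columns report t = 0 with adjusted p = 1, and an exact nonzero shift
    reports the limiting signed-infinite t with p = 0.
    """
    X = np.asarray(series, dtype=float)
    if np.isnan(X).any():
        raise StatsError("missing cells are not supported")
    g, t = X.shape
    labels = labels or [f"t{j}" for j in range(t)]
    pairs = list(itertools.combinations(range(t), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        d = X[:, j] - X[:, i]
        if np.allclose(d.std(ddof=1), 0.0):
            if np.allclose(d.mean(), 0.0):
                tval, praw = 0.0, 1.0
            else:
                tval, praw = math.copysign(math.inf, d.mean()), 0.0
        else:
            tval, praw = sps.ttest_rel(X[:, j], X[:, i])
        rows.append(
            {
                "a": labels[i],
                "b": labels[j],
                "t": float(tval),
                "df": g - 1,
                "p_raw": float(praw),
                "p_adj": float(min(1.0, m * praw)),
            }
        )
    return pd.DataFrame(rows)


def _corr_row(name: str, x, y, stratum: str = "all") -> dict:
    try:
        res = spearman_test(x, y)
        return {
            "name": name,
            "stratum": stratum,
            "rho": res.rho,
            "p_value": res.p_value,
            "n": res.n,
            "method": res.method,
            "note": "",
        }
    except StatsError as e:
        return {
            "name": name,
            "stratum": stratum,
            "rho": np.nan,
            "p_value": np.nan,
            "n": len(np.asarray(x)),
            "method": "NA",
            "note": str(e),
        }


def phase_correlation_suite(series: pd.DataFrame) -> pd.DataFrame:
    """The headline group-level correlations, one group per data point.

    ``series`` needs one row per group with columns ``strength_baseline``,
    ``strength_change``, ``strength_postchange``, ``mean_delta``,
    ``severity_baseline``, ``severity_change``, ``severity_postchange`` and
    optionally ``week12_delta`` (plus ``week12_delta_good`` /
    ``week12_delta_poor`` for the context-stratified variants).  Computes:

    - baseline strength vs mean maximum change (plasticity gradient);
    - baseline strength vs week-12 change, overall and per context class;
    - strength change (change - baseline) vs mean maximum change;
    - baseline strength vs mean severity at each of the three phases.
    """
    s = series
    rows = [
        _corr_row("baseline_strength_vs_max_change", s["strength_baseline"], s["mean_delta"]),
        _corr_row(
            "strength_change_vs_max_change",
            s["strength_change"] - s["strength_baseline"],
            s["mean_delta"],
        ),
    ]
    if "week12_delta" in s:
        rows.append(
            _corr_row("baseline_strength_vs_week12_change", s["strength_baseline"], s["week12_delta"])
        )
    for cls in ("good", "poor"):
        col = f"week12_delta_{cls}"
        if col in s:
            rows.append(
                _corr_row(
                    "baseline_strength_vs_week12_change",
                    s["strength_baseline"],
                    s[col],
                    stratum=cls,
                )
            )
    for phase in ("baseline", "change", "postchange"):
        rows.append(
            _corr_row(
                f"baseline_strength_vs_severity_{phase}",
                s["strength_baseline"],
                s[f"severity_{phase}"],
            )
        )
    return pd.DataFrame(rows)
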