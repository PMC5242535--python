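"""Cohort-level statistics: Grubbs outlier screening, factorial
between-subject ANOVA, Bonferroni-corrected Pearson correlation matrices
and Bonferroni post-hoc pairwise tests.

The screening convention follows the study workflow: Grubbs' test is
applied once per genotype x sex x age x measure cell (single most-extreme
value per pass), flagged values are excluded, and longitudinal data are
analysed with age as a between-subject factor (a repeated-measures layout
is impossible with missing sessions).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .types import InsufficientDataError


@dataclass
class GrubbsResult:
    g: float
    critical: float
    outlier_index: int | None
    alpha: float
    z_ratios: np.ndarray = field(default=None)

    @property
    def is_outlier(self) -> bool:
        return self.outlier_index is not None


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile:
    ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with
    t = t_{1 - alpha/(2n), n-2}."""
    if n < 3:
        raise InsufficientDataError("Grubbs' test needs at least 3 values")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    if not np.isfinite(t):  # alpha -> 0: the criterion tends to its supremum
        return (n - 1) / math.sqrt(n)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


def grubbs_screen(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided single-pass Grubbs screen.

    The z ratio of each value is |x - mean| / sd; the most extreme value
    is flagged when its ratio exceeds the critical value at ``alpha``.
    Zero-variance data yield a no-outlier result.
    """
    x = np.asarray(values, float)
    if x.size < 3:
        raise InsufficientDataError("Grubbs' test needs at least 3 values")
    sd = x.std(ddof=1)
    if sd == 0:
        return GrubbsResult(0.0, grubbs_critical(x.size, alpha), None, alpha,
                            np.zeros(x.size))
    z = np.abs(x - x.mean()) / sd
    idx = int(np.argmax(z))
    g = float(z[idx])
    crit = grubbs_critical(x.size, alpha)
    return GrubbsResult(g, crit, idx if g > crit else None, alpha, z)


def grubbs_iterative(values, alpha: float = 0.05, max_pass: int = 10):
    """Repeated Grubbs passes, removing one value per pass; returns the
    indices (into the original array) of all flagged values."""
    x = np.asarray(values, float)
    keep = np.arange(x.size)
    flagged = []
    for _ in range(max_pass):
        if keep.size < 3:
            break
        res = grubbs_screen(x[keep], alpha)
        if not res.is_outlier:
            break
        flagged.append(int(keep[res.outlier_index]))
        keep = np.delete(keep, res.outlier_index)
    return flagged


def screen_cohort(
    table: pd.DataFrame,
    alpha: float = 0.05,
    cell_keys=("genotype", "sex", "age_weeks", "measure"),
    value_col: str = "value",
) -> pd.DataFrame:
    """Apply the per-cell Grubbs screen to a long-format cohort table;
    returns a copy with an ``outlier`` flag column."""
    out = table.copy()
    out["outlier"] = False
    for _, idx in out.groupby(list(cell_keys)).groups.items():
        vals = out.loc[idx, value_col]
        ok = vals.notna()
        if ok.sum() < 3:
            continue
        res = grubbs_screen(vals[ok].to_numpy(), alpha)
        if res.is_outlier:
            out.loc[vals[ok].index[res.outlier_index], "outlier"] = True
    return out


@dataclass
class AnovaResult:
    table: pd.DataFrame  # per-term F, df, p
    factors: tuple[str, ...]

    def f(self, term: str) -> float:
        return float(self.table.loc[term, "F"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "PR(>F)"])

    def dof(self, term: str) -> tuple[float, float]:
        return (float(self.table.loc[term, "df"]),
                float(self.table.loc[term, "df_resid"]))


def factorial_anova(table: pd.DataFrame, factors, response: str = "value") -> AnovaResult:
    """Between-subject factorial ANOVA with all interactions.

    Least-squares fit with sum-to-zero factor coding and Type III sums of
    squares (robust to the unbalanced cells that missing data create).
    Raises ``InsufficientDataError`` naming any factor level left empty
    after missing-data removal.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    factors = list(factors)
    data = table.dropna(subset=[response]).copy()
    if "missing" in data.columns:
        data = data[~data["missing"].astype(bool)]
    if "outlier" in data.columns:
        data = data[~data["outlier"].astype(bool)]
    for f in factors:
        counts = data[f].value_counts()
        empty = [lvl for lvl in table[f].dropna().unique() if counts.get(lvl, 0) == 0]
        if empty:
            raise InsufficientDataError(f"factor {f!r} level {empty[0]!r} is empty")
        if counts.size < 2:
            raise InsufficientDataError(f"factor {f!r} needs at least 2 levels")
    rhs = " * ".join(f"C({f}, Sum)" for f in factors)
    if np.isclose(data[response].var(), 0.0):
        # constant response: every effect is exactly null
        terms = [":".join(c) for k in range(1, len(factors) + 1)
                 for c in combinations(factors, k)]
        aov = pd.DataFrame(
            {"sum_sq": 0.0, "df": 1.0, "F": 0.0, "PR(>F)": 1.0}, index=terms)
        aov["df_resid"] = float(len(data) - len(terms) - 1)
        return AnovaResult(aov, tuple(factors))
    model = smf.ols(f"{response} ~ {rhs}", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=3)
    aov = aov.rename(index=lambda s: s.replace("C(", "").replace(", Sum)", ""))
    aov["df_resid"] = model.df_resid
    return AnovaResult(aov, tuple(factors))


@dataclass
class CorrelationPlan:
    measures: tuple[str, ...]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    n_comparisons: int
    adjusted_alpha: float
    significant: pd.DataFrame


def bonferroni_alpha(n_measures: int, alpha: float = 0.05) -> float:
    """Adjusted alpha = alpha / C(k, 2) comparisons among k measures."""
    m = math.comb(n_measures, 2)
    return alpha / m if m else alpha


def bonferroni_correlations(
    wide: pd.DataFrame, measures=None, alpha: float = 0.05, min_pairs: int = 3
) -> CorrelationPlan:
    """Pairwise-complete Pearson correlation matrix with Bonferroni gate.

    ``wide`` holds one column per measure (rows = subjects or
    subject-sessions). Pairs with fewer than ``min_pairs`` complete
    observations are omitted (NaN) with a warning.
    """
    import warnings

    measures = tuple(measures if measures is not None else wide.columns)
    k = len(measures)
    m = math.comb(k, 2)
    adj = bonferroni_alpha(k, alpha)
    r = pd.DataFrame(np.eye(k), index=measures, columns=measures)
    p = pd.DataFrame(np.full((k, k), np.nan), index=measures, columns=measures)
    n = pd.DataFrame(np.zeros((k, k), int), index=measures, columns=measures)
    for a, b in combinations(measures, 2):
        pair = wide[[a, b]].dropna()
        n.loc[a, b] = n.loc[b, a] = len(pair)
        if len(pair) < min_pairs:
            warnings.warn(f"pair ({a}, {b}) has <{min_pairs} complete rows; omitted",
                          RuntimeWarning)
            r.loc[a, b] = r.loc[b, a] = np.nan
            continue
        rr, pp = stats.pearsonr(pair[a], pair[b])
        r.loc[a, b] = r.loc[b, a] = rr
        p.loc[a, b] = p.loc[b, a] = pp
    sig = p < adj
    np.fill_diagonal(sig.values, False)
    return CorrelationPlan(measures, r, p, n, m, adj, sig)


def posthoc_bonferroni(
    table: pd.DataFrame, grouping: str, response: str = "value"
) -> pd.DataFrame:
    """Pairwise Welch t tests between group levels with Bonferroni-adjusted
    p (raw p x number of comparisons, capped at 1)."""
    data = table.dropna(subset=[response])
    levels = list(pd.unique(data[grouping]))
    if len(levels) < 2:
        raise InsufficientDataError("post-hoc tests need at least 2 groups")
    pairs = list(combinations(levels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        xa = data.loc[data[grouping] == a, response]
        xb = data.loc[data[grouping] == b, response]
        t, praw = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append({"group_a": a, "group_b": b, "t": float(t),
                     "p_raw": float(praw), "p_adjusted": min(1.0, float(praw) * m),
                     "n_comparisons": m})
    return pd.DataFrame(rows)
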