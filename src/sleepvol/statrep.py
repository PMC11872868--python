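"""Statistical testing and reporting over features and volatility measures.

Wraps the univariate and multivariate tests applied to mean-conditional-
volatility tables: multiway ANOVA (type-II sums of squares) with Bonferroni
correction, Tukey HSD post-hoc comparisons, two-sample t-tests, chi-square
tests of association, and MANOVA (Pillai's trace).  Every result is
returned as a :class:`StatResult` carrying the raw and Bonferroni-corrected
p-value and the correction family size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from itertools import combinations

from scipy import stats as sstats

__all__ = [
    "StatResult",
    "multiway_anova",
    "tukey_hsd",
    "two_sample_t",
    "chi_square",
    "manova",
    "report",
]


@dataclass
class StatResult:
    """One test outcome with Bonferroni bookkeeping."""

    effect: str
    statistic: float
    df: tuple
    p_raw: float
    p_corrected: float
    method: str
    family_size: int

    def __post_init__(self) -> None:
        for p in (self.p_raw, self.p_corrected):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p-value {p} outside [0, 1]")
        if self.p_corrected < self.p_raw - 1e-12:
            raise ValueError("corrected p-value below raw p-value")


def _bonferroni(p: float, m: int) -> float:
    return float(min(1.0, m * p))


def _finalize(rows: list[dict], method: str) -> list[StatResult]:
    m = len(rows)
    return [StatResult(effect=r["effect"], statistic=r["statistic"],
                       df=r["df"], p_raw=r["p"],
                       p_corrected=_bonferroni(r["p"], m), method=method,
                       family_size=m) for r in rows]


def multiway_anova(data: pd.DataFrame, response: str, factors: list,
                   max_interaction: int = 2) -> list[StatResult]:
    """Multiway ANOVA with type-II sums of squares and Bonferroni correction.

    Main effects for every factor, plus two-way interactions when
    ``max_interaction >= 2`` and more than one factor is given.  Factors
    must have at least two observed levels; a rank-deficient design raises
    an error naming the aliased terms.  A response with no variance yields
    F = 0, p = 1 for every effect (no evidence of any difference).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than two levels")
    terms = [f"C({f})" for f in factors]
    if max_interaction >= 2 and len(factors) > 1:
        terms += [f"C({a}):C({b})" for a, b in combinations(factors, 2)]
    formula = f"{response} ~ " + " + ".join(terms)

    y = data[response].to_numpy(dtype=float)
    if float(np.var(y)) == 0.0:
        rows = [{"effect": t, "statistic": 0.0, "df": (np.nan, np.nan),
                 "p": 1.0} for t in terms]
        return _finalize(rows, "multiway-anova")

    model = smf.ols(formula, data=data).fit()
    if model.df_resid < 1:
        raise ValueError("no residual degrees of freedom left")
    rank = np.linalg.matrix_rank(model.model.exog)
    if rank < model.model.exog.shape[1]:
        raise ValueError(
            f"rank-deficient design for {formula!r}: some of the terms "
            f"{terms} are aliased; drop factors or interactions")
    table = sm.stats.anova_lm(model, typ=2)
    rows = []
    for name, row in table.iterrows():
        if name == "Residual":
            continue
        rows.append({"effect": name, "statistic": float(row["F"]),
                     "df": (float(row["df"]),
                            float(table.loc["Residual", "df"])),
                     "p": float(row["PR(>F)"])})
    return _finalize(rows, "multiway-anova")


def tukey_hsd(values, groups) -> list[StatResult]:
    """Tukey honestly-significant-difference pairwise comparisons.

    The studentized-range test controls the family-wise error by
    construction, so ``p_corrected == p_raw`` and the family size is the
    number of pairs.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two observations")
    samples = [values[groups == g] for g in labels]
    res = sstats.tukey_hsd(*samples)
    n = len(values)
    k = len(labels)
    out = []
    m = k * (k - 1) // 2
    for i, j in combinations(range(k), 2):
        p = float(res.pvalue[i, j])
        out.append(StatResult(effect=f"{labels[i]} vs {labels[j]}",
                              statistic=float(res.statistic[i, j]),
                              df=(float(k), float(n - k)), p_raw=p,
                              p_corrected=p, method="tukey-hsd",
                              family_size=m))
    return out


def two_sample_t(values_a, values_b) -> StatResult:
    """Pooled-variance two-sample t-test for a difference in means."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    t, p = sstats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):  # both samples constant and equal
        t, p = 0.0, 1.0
    return StatResult(effect="a vs b", statistic=float(t),
                      df=(float(len(a) + len(b) - 2),), p_raw=float(p),
                      p_corrected=float(p), method="t-test", family_size=1)


def chi_square(table) -> StatResult:
    """Pearson chi-square test of association on a contingency table."""
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    res = sstats.chi2_contingency(table, correction=False)
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return StatResult(effect="association", statistic=float(res.statistic),
                      df=(float(df),), p_raw=float(res.pvalue),
                      p_corrected=float(res.pvalue), method="chi-square",
                      family_size=1)


def manova(data: pd.DataFrame, responses: list, factors: list
           ) -> list[StatResult]:
    """MANOVA with Pillai's trace and Bonferroni over effects.

    With a single response column this reduces exactly to the ANOVA F for
    that factor.  A singular within-group covariance (e.g., collinear
    responses) raises an error suggesting dimension reduction.
    """
    from statsmodels.multivariate.manova import MANOVA

    for f in factors:
        if data[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has fewer than two levels")
    if len(responses) == 1:
        # Pillai's trace with one response reduces exactly to the ANOVA F
        uni = multiway_anova(data, responses[0], factors, max_interaction=1)
        return [StatResult(effect=r.effect, statistic=r.statistic, df=r.df,
                           p_raw=r.p_raw, p_corrected=r.p_corrected,
                           method="manova-pillai",
                           family_size=r.family_size) for r in uni]
    lhs = " + ".join(responses)
    rhs = " + ".join(f"C({f})" for f in factors)
    try:
        mv = MANOVA.from_formula(f"{lhs} ~ {rhs}", data=data)
        tests = mv.mv_test()
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular within-group covariance; reduce the response "
            "dimension or pool levels") from exc
    except ValueError as exc:
        if "zero-size" in str(exc):
            # exactly null between-group effect: statsmodels' eigenvalue
            # extraction finds nothing to test
            rows = [{"effect": f"C({f})", "statistic": 0.0,
                     "df": (np.nan, np.nan), "p": 1.0} for f in factors]
            return _finalize(rows, "manova-pillai")
        raise
    rows = []
    for effect in tests.results:
        if effect == "Intercept":
            continue
        stat = tests.results[effect]["stat"]
        pillai = stat.loc["Pillai's trace"]
        rows.append({"effect": effect,
                     "statistic": float(pillai["F Value"]),
                     "df": (float(pillai["Num DF"]),
                            float(pillai["Den DF"])),
                     "p": float(pillai["Pr > F"])})
    return _finalize(rows, "manova-pillai")


def report(results: list[StatResult]) -> pd.DataFrame:
    """Structured result bundle: one stably-ordered row per StatResult."""
    rows = [{"effect": r.effect, "method": r.method,
             "statistic": r.statistic,
             "df": "/".join(f"{d:g}" for d in r.df),
             "p_raw": r.p_raw, "p_corrected": r.p_corrected,
             "family_size": r.family_size} for r in results]
    df = pd.DataFrame(rows)
    return df.sort_values(["method", "effect"],
                          kind="stable").reset_index(drop=True)
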