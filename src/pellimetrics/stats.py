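"""Group comparisons used across the pellicle measurements.

One-way and two-way ANOVA (strain × washing method), Bonferroni-corrected
pairwise post-hoc t-tests gated on a significant omnibus result, and Pearson
correlation for the density–mechanics relationships. The post-hoc t statistic
uses the pooled ANOVA residual mean square (classical protected pairwise
comparison).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

STAR_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Figure-legend convention: * p<0.05, ** p<0.01, *** p<0.001."""
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return "ns"


@dataclass(frozen=True)
class EffectResult:
    """One ANOVA effect: sum of squares, degrees of freedom, F and p."""

    name: str
    ss: float
    df: float
    F: float
    p: float


def _check_table(table: pd.DataFrame, factors: list[str]) -> None:
    if "value" not in table.columns:
        raise ValueError("table must have a 'value' column")
    for f in factors:
        if f not in table.columns:
            raise ValueError(f"missing factor column {f!r}")
        if table[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs at least 2 levels")
    if len(factors) == 2:
        counts = table.groupby(factors, observed=True).size()
        full = list(itertools.product(*(table[f].unique() for f in factors)))
        for cell in full:
            if cell not in counts.index or counts.loc[cell] < 2:
                raise ValueError(
                    f"two-way design cell {cell} has fewer than 2 observations"
                )
        if counts.nunique() > 1:
            warnings.warn(
                "unbalanced two-way design; Type II sums of squares used",
                stacklevel=3,
            )


def anova(table: pd.DataFrame, factors: str | list[str]) -> dict[str, EffectResult]:
    """One- or two-way fixed-effects ANOVA.

    Parameters
    ----------
    table
        Long-format observations with a ``value`` column and one categorical
        column per factor (e.g. ``strain``, ``wash``).
    factors
        One factor name, or two for a crossed design with interaction.

    Returns a mapping from effect name (factor, ``factor_a:factor_b`` for the
    interaction, and ``Residual``) to its sums of squares, df, F and p. A
    degenerate table in which every observation is identical returns F=0,
    p=1 for all effects.
    """
    if isinstance(factors, str):
        factors = [factors]
    if len(factors) not in (1, 2):
        raise ValueError("one or two factors supported")
    _check_table(table, factors)

    values = table["value"].to_numpy(dtype=float)
    if np.ptp(values) == 0:  # no variance anywhere: F = 0/0 in the formula
        out = {}
        for name in factors + ([f"{factors[0]}:{factors[1]}"] if len(factors) == 2 else []):
            out[name] = EffectResult(name, 0.0, np.nan, 0.0, 1.0)
        out["Residual"] = EffectResult("Residual", 0.0, np.nan, np.nan, np.nan)
        return out

    terms = " * ".join(f"C({f})" for f in factors)
    model = smf.ols(f"value ~ {terms}", data=table).fit()
    typ = 2 if len(factors) == 2 else 1
    tab = anova_lm(model, typ=typ)

    out: dict[str, EffectResult] = {}
    for row_name, row in tab.iterrows():
        name = (
            row_name.replace("C(", "").replace(")", "") if row_name != "Residual" else "Residual"
        )
        out[name] = EffectResult(
            name=name,
            ss=float(row["sum_sq"]),
            df=float(row["df"]),
            F=float(row["F"]) if np.isfinite(row.get("F", np.nan)) else np.nan,
            p=float(row["PR(>F)"]) if np.isfinite(row.get("PR(>F)", np.nan)) else np.nan,
        )
    return out


def bonferroni_pairwise(
    table: pd.DataFrame, factor: str, alpha: float = 0.05
) -> pd.DataFrame | None:
    """Protected pairwise comparisons between the levels of one factor.

    Runs the one-way omnibus ANOVA first; if its p-value is ≥ `alpha` the
    post-hoc is not performed (returns None), matching the gatekeeping
    convention. Otherwise every level pair is compared with a pooled-variance
    t-test using the ANOVA residual mean square, and raw p-values are
    Bonferroni-adjusted: p_adj = min(1, p·m) with m the number of pairs.
    """
    counts = table.groupby(factor, observed=True)["value"].count()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"groups with n<2 excluded from post-hoc: {small}", stacklevel=2)
        table = table[~table[factor].isin(small)]

    omnibus = anova(table, factor)
    if not (omnibus[factor].p < alpha):
        return None

    groups = {lvl: g["value"].to_numpy(dtype=float) for lvl, g in table.groupby(factor, observed=True)}
    mse = omnibus["Residual"].ss / omnibus["Residual"].df
    df_resid = omnibus["Residual"].df
    pairs = list(itertools.combinations(sorted(groups), 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        xa, xb = groups[a], groups[b]
        se = np.sqrt(mse * (1.0 / len(xa) + 1.0 / len(xb)))
        t = (xa.mean() - xb.mean()) / se
        p = 2.0 * scipy.stats.t.sf(abs(t), df_resid)
        p_adj = min(1.0, p * m)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_diff": xa.mean() - xb.mean(),
                "t": t,
                "p_raw": p,
                "p_adj": p_adj,
                "stars": significance_stars(p_adj),
            }
        )
    return pd.DataFrame(rows)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be matching 1D arrays of length ≥ 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(scipy.stats.pearsonr(x, y).statistic)
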