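"""Trait computation and comparative statistics.

Implements the downstream analysis stage: leaf-trait arithmetic (LMA, water
content), two-factor ANOVA with normality screening and optional
transformation, Tukey HSD with compact letter displays, nested OLS models of
the refixation percentage, and per-group summaries.

ANOVA uses Type-II sums of squares by default because the study design is
unbalanced once inadmissible fits drop out; the decomposition is switchable.
"""

from __future__ import annotations

import logging
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps
from statsmodels.stats.libqsturng import psturng

__all__ = [
    "AnovaResult",
    "OlsResult",
    "TukeyResult",
    "compute_lma",
    "compute_water_content",
    "two_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "nested_ols",
    "simple_regressions",
    "group_summary",
    "NESTED_MODEL_TERMS",
]

logger = logging.getLogger(__name__)

#: predictor sets of the three nested models of the refixation percentage
NESTED_MODEL_TERMS: tuple[tuple[str, ...], ...] = (
    ("rm",),
    ("rm", "rs"),
    ("rm", "rs", "LMA"),
)


def compute_lma(dry_mass: float, area_cm2: float) -> float:
    """Leaf mass per area in g m-2 from dry mass (g) and one-sided area (cm2)."""
    if not area_cm2 > 0:
        raise ValueError("leaf area must be strictly positive")
    if dry_mass < 0:
        raise ValueError("dry mass must be non-negative")
    return dry_mass / (area_cm2 * 1e-4)


def compute_water_content(fresh: float, dry: float) -> float:
    """Leaf water content in percent of fresh mass."""
    if not fresh > 0:
        raise ValueError("fresh mass must be strictly positive")
    if dry < 0:
        raise ValueError("dry mass must be non-negative")
    if dry > fresh:
        raise ValueError("dry mass cannot exceed fresh mass")
    return 100.0 * (fresh - dry) / fresh


@dataclass
class AnovaResult:
    """Main-effects ANOVA of one response on two factors."""

    response: str
    factors: tuple[str, str]
    F: dict[str, float]
    p: dict[str, float]
    df: dict[str, int]
    df_resid: int
    transformation: str  # "none", "log" or "rank"
    shapiro_p: float


def _apply_transform(y: pd.Series, how: str) -> pd.Series:
    if how == "none":
        return y
    if how == "log":
        return np.log(y)
    if how == "rank":
        return pd.Series(sps.rankdata(y), index=y.index)
    raise ValueError(f"unknown transformation {how!r}")


def two_way_anova(
    table: pd.DataFrame,
    response: str,
    factors: tuple[str, str] = ("species", "season"),
    typ: int = 2,
    transform: str = "auto",
    alpha_normality: float = 0.05,
) -> AnovaResult:
    """Main-effects (no interaction) ANOVA of ``response`` on two factors.

    With ``transform='auto'`` a Shapiro-Wilk test screens the residuals; on
    rejection the response is log-transformed when strictly positive and
    rank-transformed otherwise, then the model is refit.
    """
    fa, fb = factors
    data = table[[response, fa, fb]].dropna()
    for f in factors:
        levels = data[f].nunique()
        if levels < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels, found {levels}")

    if float(data[response].std()) < 1e-12:
        # constant response: every decomposition is 0/0; report null effects
        df_resid = len(data) - 1 - (data[fa].nunique() - 1) - (data[fb].nunique() - 1)
        return AnovaResult(
            response=response, factors=factors,
            F={f: 0.0 for f in factors}, p={f: 1.0 for f in factors},
            df={f: int(data[f].nunique() - 1) for f in factors},
            df_resid=df_resid, transformation="none", shapiro_p=float("nan"),
        )

    def fit(y: pd.Series):
        d = data.assign(_y=y)
        model = smf.ols(f"_y ~ C({fa}) + C({fb})", data=d).fit()
        return model

    model = fit(data[response])
    resid = np.asarray(model.resid)
    # Shapiro-Wilk is defined for 3 <= n <= 5000
    shapiro_p = float(sps.shapiro(resid).pvalue) if 3 <= resid.size <= 5000 else float("nan")

    applied = "none"
    if transform == "auto":
        if np.isfinite(shapiro_p) and shapiro_p < alpha_normality:
            applied = "log" if (data[response] > 0).all() else "rank"
    elif transform in ("log", "rank"):
        applied = transform
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if applied != "none":
        model = fit(_apply_transform(data[response], applied))

    if model.df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tab = sm.stats.anova_lm(model, typ=typ)

    def row(f: str) -> str:
        return f"C({f})"

    F = {f: float(tab.loc[row(f), "F"]) for f in factors}
    p = {f: float(tab.loc[row(f), "PR(>F)"]) for f in factors}
    df = {f: int(tab.loc[row(f), "df"]) for f in factors}
    # a perfectly explained response yields 0/0; report F=0, p=1
    for f in factors:
        if not np.isfinite(F[f]):
            ss = float(tab.loc[row(f), "sum_sq"])
            F[f] = 0.0 if ss <= 1e-300 else float("inf")
            p[f] = 1.0 if ss <= 1e-300 else 0.0
    return AnovaResult(
        response=response,
        factors=factors,
        F=F,
        p=p,
        df=df,
        df_resid=int(model.df_resid),
        transformation=applied,
        shapiro_p=shapiro_p,
    )


@dataclass
class TukeyResult:
    """Pairwise studentized-range tests plus a compact letter display."""

    response: str
    grouping: str
    groups: list[str]  # ordered by descending mean
    means: dict[str, float]
    pvalues: dict[tuple[str, str], float]
    letters: dict[str, str]
    alpha: float


def tukey_hsd(
    table: pd.DataFrame,
    response: str,
    grouping: str,
    alpha: float = 0.05,
) -> TukeyResult:
    """Tukey HSD over all group pairs with a compact letter display."""
    data = table[[response, grouping]].dropna()
    counts = data.groupby(grouping, observed=True)[response].count()
    if len(counts) < 2:
        raise ValueError("need >= 2 groups")
    singles = counts[counts < 2]
    if len(singles):
        raise ValueError(f"singleton group(s): {list(singles.index)}")

    means = data.groupby(grouping, observed=True)[response].mean()
    ns = counts.astype(float)
    k = len(means)
    n_total = int(ns.sum())
    df_err = n_total - k
    ss_err = float(
        ((data[response] - data[grouping].map(means)) ** 2).sum()
    )
    mse = ss_err / df_err

    groups = list(means.sort_values(ascending=False).index)
    pvals: dict[tuple[str, str], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[gi] + 1.0 / ns[gj]))
            if se == 0.0:
                p = 1.0 if means[gi] == means[gj] else 0.0
            else:
                q = abs(means[gi] - means[gj]) / se
                p = float(np.atleast_1d(psturng(q, k, df_err))[0])
            pvals[(gi, gj)] = pvals[(gj, gi)] = p

    letters = compact_letter_display(groups, pvals, alpha)
    return TukeyResult(
        response=response,
        grouping=grouping,
        groups=groups,
        means={g: float(means[g]) for g in groups},
        pvalues=pvals,
        letters=letters,
        alpha=alpha,
    )


def compact_letter_display(
    groups_desc: list[str],
    pvalues: dict[tuple[str, str], float],
    alpha: float = 0.05,
) -> dict[str, str]:
    """Letter display by insert-and-absorb over the significant pairs.

    Guarantees a valid clique cover: two groups share a letter iff they are
    connected through sets of mutually non-significant groups; any
    significantly different pair never shares a letter, and any
    non-significant pair shares at least one.  Groups must be supplied in
    descending-mean order; letters are assigned alphabetically in that order
    so the display is deterministic and insertion-order independent.
    """
    sets: list[set[str]] = [set(groups_desc)]
    for i, gi in enumerate(groups_desc):
        for gj in groups_desc[i + 1:]:
            if pvalues[(gi, gj)] >= alpha:
                continue
            new_sets: list[set[str]] = []
            for s in sets:
                if gi in s and gj in s:
                    new_sets.extend((s - {gi}, s - {gj}))
                else:
                    new_sets.append(s)
            # absorb: drop empty sets, duplicates and proper subsets
            new_sets = [s for s in new_sets if s]
            kept: list[set[str]] = []
            for s in new_sets:
                if s in kept or any(s < t for t in new_sets):
                    continue
                kept.append(s)
            sets = kept

    # order letter sets by the best (highest-mean) group they contain
    rank = {g: i for i, g in enumerate(groups_desc)}
    sets.sort(key=lambda s: min(rank[g] for g in s))
    alphabet = string.ascii_lowercase
    letters: dict[str, str] = {g: "" for g in groups_desc}
    for idx, s in enumerate(sets):
        symbol = alphabet[idx % 26] * (idx // 26 + 1)
        for g in groups_desc:
            if g in s:
                letters[g] += symbol
    return letters


@dataclass
class OlsResult:
    """One fitted OLS model in the layout of the nested-model table."""

    response: str
    terms: dict[str, tuple[float, float, float]]  # name -> (estimate, t, p)
    intercept: tuple[float, float, float]
    df_resid: int
    adj_r2: float
    f_stat: float
    f_p: float
    n: int
    dropped: tuple[str, ...] = ()


def _fit_ols(data: pd.DataFrame, response: str, terms: tuple[str, ...]) -> OlsResult:
    sub = data[[response, *terms]].dropna()
    kept = list(terms)
    X = sub[kept].to_numpy(float)
    dropped: list[str] = []
    # rank check: drop trailing collinear terms with a warning
    while kept and np.linalg.matrix_rank(np.column_stack([np.ones(len(sub)), X])) < len(kept) + 1:
        bad = kept.pop()
        dropped.append(bad)
        warnings.warn(f"dropping rank-deficient term {bad!r}", RuntimeWarning, stacklevel=3)
        X = sub[kept].to_numpy(float)
    if len(sub) <= len(kept) + 1:
        raise ValueError(f"need n > terms + 1, got n={len(sub)} for terms {kept}")

    model = sm.OLS(sub[response].to_numpy(float), sm.add_constant(X)).fit()
    names = ["const", *kept]
    out = {
        name: (float(model.params[i]), float(model.tvalues[i]), float(model.pvalues[i]))
        for i, name in enumerate(names)
    }
    return OlsResult(
        response=response,
        terms={k: out[k] for k in kept},
        intercept=out["const"],
        df_resid=int(model.df_resid),
        adj_r2=float(model.rsquared_adj),
        f_stat=float(model.fvalue),
        f_p=float(model.f_pvalue),
        n=int(model.nobs),
        dropped=tuple(dropped),
    )


def nested_ols(
    table: pd.DataFrame,
    response: str = "Pr",
    model_terms: tuple[tuple[str, ...], ...] = NESTED_MODEL_TERMS,
) -> list[OlsResult]:
    """The nested OLS models of the refixation percentage (rm; +rs; +LMA)."""
    return [_fit_ols(table, response, terms) for terms in model_terms]


def simple_regressions(
    table: pd.DataFrame,
    response: str = "Pr",
    predictors: tuple[str, ...] = ("rm", "rs", "LMA"),
    by_species: bool = True,
) -> pd.DataFrame:
    """Single-predictor regressions, all species pooled and per species.

    Returns a long table with columns: predictor, species ("all" for the
    pooled fit), slope, intercept, t, p, adj_r2, n.
    """
    rows: list[dict] = []

    def one(d: pd.DataFrame, predictor: str, label: str) -> None:
        sub = d[[response, predictor]].dropna()
        if len(sub) < 3:
            return
        res = _fit_ols(sub, response, (predictor,))
        est, t, p = res.terms[predictor]
        rows.append(
            dict(predictor=predictor, species=label, slope=est,
                 intercept=res.intercept[0], t=t, p=p, adj_r2=res.adj_r2, n=res.n)
        )

    for predictor in predictors:
        one(table, predictor, "all")
        if by_species and "species" in table.columns:
            for sp, d in table.groupby("species", sort=True):
                one(d, predictor, str(sp))
    return pd.DataFrame(rows)


def group_summary(
    table: pd.DataFrame,
    response: str,
    grouping: str | list[str],
) -> pd.DataFrame:
    """Per-group n, mean and sample SD (n-1 denominator; SD missing for n=1)."""
    g = table.groupby(grouping, observed=True)[response]
    out = g.agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
    return out.reset_index()
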