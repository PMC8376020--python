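"""Comparison layer: factorial ANOVA, Tukey HSD, and AICc best-subset OLS.

Concentration contrasts across seasons and land-use categories use Type-II
ANOVA with Tukey honest-significant-difference post hocs. Links between land
cover and chemistry use all-subsets ordinary least squares: every subset of
the candidate predictors is fit, ranked by the small-sample Akaike criterion

    AICc = -2*logL + 2k + 2k(k+1) / (n - k - 1),

and the minimum-AICc subset is the final model. OLS is the identity-structure
special case of generalized least squares; no correlation or variance
structure is modelled (none is identifiable from a single synoptic table).
Season enters as a categorical predictor (two dummy columns, counted in k).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .data_io import LAND_COVER, SiteTable

DEFAULT_CANDIDATES = ("Season",) + LAND_COVER

_FACTOR_COLUMNS = {"season": "season", "category": "category", "network": "network"}


def aicc(log_likelihood: float, k: int, n: int) -> float:
    """Second-order (small-sample) Akaike information criterion."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * log_likelihood + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _term(name: str) -> str:
    key = name.lower()
    if key in _FACTOR_COLUMNS:
        return f"C({_FACTOR_COLUMNS[key]})"
    return name


def _check_factor_levels(df: pd.DataFrame, factors: Sequence[str]) -> None:
    for f in factors:
        key = f.lower()
        if key in _FACTOR_COLUMNS:
            counts = df[_FACTOR_COLUMNS[key]].value_counts()
            if len(counts) < 2:
                raise ValueError(f"factor {f!r} has a single level")
            thin = counts[counts < 2]
            if not thin.empty:
                raise ValueError(
                    f"factor {f!r}: level(s) {list(thin.index)} have < 2 observations"
                )


def anova(
    table: SiteTable,
    response: str,
    factors: Sequence[str],
    interaction: bool = False,
) -> pd.DataFrame:
    """Type-II fixed-effects ANOVA; returns term, f_stat, df, p_value.

    ``df`` is the (term, residual) degree-of-freedom pair. ``interaction=True``
    adds the pairwise interaction of the first two factors (used for the
    season-by-category contrast); it requires every cell to be occupied.
    """
    if response not in table.df.columns:
        raise ValueError(f"unknown response {response!r}")
    cols = [_FACTOR_COLUMNS.get(f.lower(), f) for f in factors]
    df = table.df[[response] + cols].dropna()
    _check_factor_levels(df, factors)
    terms = [_term(f) for f in factors]
    if interaction:
        if len(factors) < 2:
            raise ValueError("interaction requires at least two factors")
        a, b = cols[0], cols[1]
        cells = df.groupby([a, b]).size().unstack(fill_value=0)
        empty = [(i, j) for i in cells.index for j in cells.columns if cells.at[i, j] == 0]
        if empty:
            raise ValueError(f"empty cell(s) for interaction: {empty}")
        terms.append(f"{_term(factors[0])}:{_term(factors[1])}")
    formula = f"Q('{response}') ~ " + " + ".join(terms)
    fit = ols(formula, data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    resid_df = int(tab.loc["Residual", "df"])
    rows = []
    for term in tab.index:
        if term == "Residual":
            continue
        rows.append(
            {
                "term": term,
                "f_stat": float(tab.loc[term, "F"]),
                "df": (int(tab.loc[term, "df"]), resid_df),
                "p_value": float(tab.loc[term, "PR(>F)"]),
            }
        )
    return pd.DataFrame(rows)


def tukey_hsd(table: SiteTable, response: str, factor: str) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (studentized-range adjusted p)."""
    col = _FACTOR_COLUMNS.get(factor.lower(), factor)
    df = table.df[[response, col]].dropna()
    _check_factor_levels(df, [factor])
    res = pairwise_tukeyhsd(df[response], df[col])
    pairs = list(itertools.combinations(res.groupsunique, 2))
    return pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "mean_diff": res.meandiffs.astype(float),
            "p_adj": res.pvalues.astype(float),
            "lower": res.confint[:, 0].astype(float),
            "upper": res.confint[:, 1].astype(float),
            "reject": res.reject.astype(bool),
        }
    )


@dataclass
class ModelFit:
    """A selected regression model in the land-use table shape."""

    response: str
    predictors: tuple[str, ...]
    coefficients: dict[str, float]
    r_squared: float
    aicc: float
    n: int
    signs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.signs:
            self.signs = {
                name: ("+" if coef > 0 else "-" if coef < 0 else "0")
                for name, coef in self.coefficients.items()
                if name != "Intercept"
            }


def _design(df: pd.DataFrame, predictors: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(df))]
    names = ["Intercept"]
    for p in predictors:
        if p.lower() == "season":
            dummies = pd.get_dummies(
                pd.Categorical(df["season"], categories=sorted(set(df["season"]))),
                drop_first=True,
            )
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(f"Season[{c}]")
        else:
            cols.append(df[p].to_numpy(dtype=float))
            names.append(p)
    return np.column_stack(cols), names


def best_subset(
    table: SiteTable,
    response: str,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
    return_all: bool = False,
) -> ModelFit | tuple[ModelFit, pd.DataFrame]:
    """Exhaustive all-subsets OLS selected by minimum AICc.

    Every subset of ``candidates`` (including the intercept-only model) is fit
    on the complete cases of the response and all candidate columns, so every
    subset sees the same rows and the AICc values are comparable. Ties break
    toward fewer predictors, then lexicographically, so selection is
    deterministic and invariant to candidate order. Rank-deficient subsets are
    skipped with a warning. ``k`` counts the mean parameters (intercept plus
    one per design column).
    """
    candidates = tuple(sorted(set(candidates), key=str.lower))
    if len(candidates) > 10:
        raise ValueError("at most 10 candidates (exhaustive 2^p enumeration)")
    if response not in table.df.columns:
        raise ValueError(f"unknown response {response!r}")
    needed = [response] + [
        "season" if c.lower() == "season" else c for c in candidates
    ]
    df = table.df[needed].dropna()
    if len(df) < 10:
        raise ValueError(f"need >= 10 complete cases, got {len(df)}")
    y = df[response].to_numpy(dtype=float)
    n = len(y)

    audit_rows = []
    fits: list[tuple[int, tuple[str, ...], ModelFit]] = []
    subsets = sorted(
        (
            tuple(sub)
            for r in range(len(candidates) + 1)
            for sub in itertools.combinations(candidates, r)
        ),
        key=lambda s: (len(s), s),
    )
    for sub in subsets:
        X, names = _design(df, sub)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn(f"subset {sub}: collinear design, skipped")
            audit_rows.append(
                {"predictors": "+".join(sub) or "(intercept)", "k": X.shape[1],
                 "aicc": np.nan, "r_squared": np.nan, "skipped": True}
            )
            continue
        res = sm.OLS(y, X).fit()
        k = X.shape[1]
        score = aicc(res.llf, k, n)
        r2 = float(res.rsquared) if X.shape[1] > 1 else 0.0
        fit = ModelFit(
            response=response,
            predictors=sub,
            coefficients=dict(zip(names, (float(b) for b in res.params))),
            r_squared=r2,
            aicc=float(score),
            n=n,
        )
        fits.append((len(sub), sub, fit))
        audit_rows.append(
            {"predictors": "+".join(sub) or "(intercept)", "k": k,
             "aicc": float(score), "r_squared": r2, "skipped": False}
        )
    if not fits:
        raise ValueError("no estimable subset model")
    # subsets are pre-sorted by (size, name); first strict minimum wins,
    # so AICc ties resolve toward parsimony deterministically
    best = min(fits, key=lambda t: (t[2].aicc, t[0], t[1]))[2]
    audit = pd.DataFrame(audit_rows).sort_values("aicc").reset_index(drop=True)
    return (best, audit) if return_all else best


def model_table(
    table: SiteTable,
    responses: Sequence[str] | None = None,
    candidates: Sequence[str] = DEFAULT_CANDIDATES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Selected model per solute (term signs and R^2) plus the full audit."""
    responses = list(responses) if responses is not None else list(table.solutes)
    rows, audits = [], []
    for resp in responses:
        try:
            fit, audit = best_subset(table, resp, candidates, return_all=True)
        except ValueError as exc:
            warnings.warn(f"{resp}: {exc}")
            continue
        rows.append(
            {
                "solute": resp,
                "model": " + ".join(
                    f"{'' if s == '+' else s}{t}" for t, s in fit.signs.items()
                )
                or "(intercept)",
                "predictors": "+".join(fit.predictors) or "(intercept)",
                "r_squared": fit.r_squared,
                "aicc": fit.aicc,
                "n": fit.n,
            }
        )
        audit = audit.copy()
        audit.insert(0, "solute", resp)
        audits.append(audit)
    return (
        pd.DataFrame(rows),
        pd.concat(audits, ignore_index=True) if audits else pd.DataFrame(),
    )
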