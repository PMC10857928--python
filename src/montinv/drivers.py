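"""Regression analyses linking alien richness to natives, climate and
disturbance.

Analysis units are 200 m elevational belts below 4000 m (belts above carry
too few aliens to be informative) or landscape grid cells.  Models are
ordinary least squares with normal errors; predictors are z-standardised
before interaction fits so coefficients are comparable; collinearity is
screened with variance inflation factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import LandscapeGrid

__all__ = [
    "drivers_from_grid",
    "drivers_from_bands",
    "LinearFit",
    "fit_linear",
    "proportion_vs_native",
    "collinearity_check",
    "subsample_refit",
]


def drivers_from_grid(grid: LandscapeGrid) -> pd.DataFrame:
    """One analysis row per grid cell (requires richness columns from
    :func:`montinv.richness.assign_grid`)."""
    df = grid.df
    for col in ("native_richness", "alien_richness"):
        if col not in df.columns:
            raise ValueError("grid lacks richness columns; run assign_grid first")
    out = pd.DataFrame(
        {
            "alien_richness": df["alien_richness"].astype(float),
            "native_richness": df["native_richness"].astype(float),
            "bio6": df["bio6"],
            "bio12": df["bio12"],
            "footprint": df["footprint"],
            "elevation": df["mean_elev"],
            "region": df["region"],
        }
    )
    denom = out["alien_richness"] + out["native_richness"]
    out["alien_proportion"] = np.where(denom > 0, out["alien_richness"] / denom.where(denom > 0), np.nan)
    return out


def drivers_from_bands(
    band_table: pd.DataFrame,
    grid: LandscapeGrid,
    region: str | None = None,
    max_elevation: float = 4000.0,
) -> pd.DataFrame:
    """One analysis row per 200 m belt below ``max_elevation``.

    Belt climate/disturbance covariates are the means over the (optionally
    region-restricted) grid cells whose mean elevation falls in the belt;
    belts without any matching cell are dropped.  The 4000-5000 m belts are
    excluded by default because almost no aliens reach them.
    """
    cells = grid.df if region is None else grid.cells_in_region(region)
    rows = []
    for label, row in band_table.iterrows():
        lo = row["band_low"]
        mid = row["band_mid"]
        hi = 2 * mid - lo
        if mid >= max_elevation:
            continue
        sel = cells[(cells["mean_elev"] >= lo) & (cells["mean_elev"] < hi)]
        if sel.empty:
            continue
        rows.append(
            {
                "band": label,
                "elevation": mid,
                "alien_richness": float(row["alien"]),
                "native_richness": float(row["native"]),
                "alien_proportion": row.get("alien_proportion", np.nan),
                "bio6": float(sel["bio6"].mean()),
                "bio12": float(sel["bio12"].mean()),
                "footprint": float(sel["footprint"].mean()),
                "region": region if region is not None else "all",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class LinearFit:
    """OLS summary: coefficient table, fit statistics and residual export."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    rsquared: float
    rsquared_adj: float
    nobs: int
    residual_table: pd.DataFrame
    result: object  # the underlying statsmodels results, for power users

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "t": self.tvalues, "p": self.pvalues}
        )


def _design(
    table: pd.DataFrame,
    terms: Sequence[str],
    interactions: bool,
    standardize: bool,
) -> pd.DataFrame:
    X = table.loc[:, list(terms)].astype(float).copy()
    if standardize:
        for t in terms:
            sd = X[t].std(ddof=0)
            X[t] = (X[t] - X[t].mean()) / sd if sd > 0 else 0.0
    if interactions:
        for a, b in combinations(terms, 2):
            X[f"{a}:{b}"] = X[a] * X[b]
    return X


def fit_linear(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    interactions: bool = False,
    standardize: bool = True,
) -> LinearFit:
    """OLS of ``response`` on ``terms`` (plus all pairwise interactions if
    requested), assuming normal errors.

    Predictors are z-standardised by default (recommended whenever
    interactions are fitted).  Rows with missing values are dropped.  A
    rank-deficient design raises ``ValueError`` naming the aliased terms.
    The residual table (fitted vs. residual) supports the usual visual
    diagnostics for normality/homoscedasticity.
    """
    data = table.dropna(subset=[response, *terms])
    X = _design(data, terms, interactions, standardize)
    y = data[response].astype(float)
    if len(data) <= X.shape[1] + 2:
        raise ValueError("too few rows for the number of parameters")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        aliased = _aliased_terms(Xc)
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")
    res = sm.OLS(y, Xc).fit()
    return LinearFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        rsquared=float(res.rsquared),
        rsquared_adj=float(res.rsquared_adj),
        nobs=int(res.nobs),
        residual_table=pd.DataFrame(
            {"fitted": res.fittedvalues, "residual": res.resid}
        ),
        result=res,
    )


def _aliased_terms(X: pd.DataFrame) -> list[str]:
    """Columns whose removal restores full rank (greedy scan)."""
    aliased = []
    cols = list(X.columns)
    M = X.to_numpy()
    base_rank = np.linalg.matrix_rank(M)
    for i, c in enumerate(cols):
        sub = np.delete(M, i, axis=1)
        if np.linalg.matrix_rank(sub) == base_rank:
            aliased.append(c)
    return aliased


@dataclass(frozen=True)
class SlopeResult:
    slope: float
    se: float
    p: float
    rsquared: float
    nobs: int


def proportion_vs_native(table: pd.DataFrame) -> SlopeResult:
    """OLS of the alien proportion of a belt on its native richness.

    A negative slope would be consistent with natives inhibiting alien
    establishment; a linear (not logistic) response is used deliberately.
    Predictor left on its natural scale so the slope is per native species.
    Accepts either a drivers table (``native_richness``) or a band richness
    table (``native``) directly.
    """
    if "native_richness" not in table.columns and "native" in table.columns:
        table = table.rename(columns={"native": "native_richness"})
    fit = fit_linear(
        table, "alien_proportion", ["native_richness"],
        interactions=False, standardize=False,
    )
    return SlopeResult(
        slope=float(fit.params["native_richness"]),
        se=float(fit.bse["native_richness"]),
        p=float(fit.pvalues["native_richness"]),
        rsquared=fit.rsquared,
        nobs=fit.nobs,
    )


def collinearity_check(table: pd.DataFrame, terms: Sequence[str]) -> dict[str, float]:
    """Variance inflation factors from auxiliary regressions.

    ``VIF_j = 1 / (1 - R^2_j)`` where ``R^2_j`` regresses predictor j on the
    others; perfect collinearity reports ``inf``."""
    if len(terms) < 2:
        raise ValueError("need at least 2 predictors")
    data = table.dropna(subset=list(terms)).astype({t: float for t in terms})
    out: dict[str, float] = {}
    for t in terms:
        others = [u for u in terms if u != t]
        X = sm.add_constant(data[others], has_constant="add")
        r2 = sm.OLS(data[t], X).fit().rsquared
        out[t] = float("inf") if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def subsample_refit(
    table: pd.DataFrame,
    response: str,
    terms: Sequence[str],
    n: int,
    repeats: int = 20,
    seed: int | None = None,
    **fit_kwargs,
) -> pd.DataFrame:
    """Robustness utility: refit on random row subsets of size ``n`` and
    collect the coefficient paths (one row per repeat per term)."""
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        idx = rng.choice(len(table), size=n, replace=False)
        fit = fit_linear(table.iloc[idx], response, terms, **fit_kwargs)
        for t, v in fit.params.items():
            rows.append({"repeat": rep, "term": t, "coef": float(v)})
    return pd.DataFrame(rows)
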