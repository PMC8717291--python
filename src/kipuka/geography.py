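"""Regression of community-assembly model support on island geography.

Each community's posterior model probabilities (neutral / filtering /
competition) are regressed on the biogeographic covariates of its island:
species richness, area (m²), isolation — distance to the surrounding lava
edge (m) — and elevation (m).  Ordinary least squares is fit for every single
predictor, every pairwise interaction, and the full additive combination, per
response.  Area and isolation span orders of magnitude and are log-transformed
by default.  No multiple-testing correction is applied across the battery;
the report carries the number of tests run so readers can judge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from ._errors import ValidationError

__all__ = ["RegressionResult", "fit_support_regressions", "default_formulae"]

RESPONSES = ("p_neutral", "p_filtering", "p_competition")
COVARIATES = ("richness", "area", "isolation", "elevation")


@dataclass
class RegressionResult:
    """One fitted OLS model of model support on geography."""

    response: str
    formula: str
    coefficients: pd.Series
    std_errors: pd.Series
    p_values: pd.Series
    r_squared: float
    f_pvalue: float
    n: int

    def to_rows(self) -> list[dict]:
        return [
            {
                "response": self.response,
                "formula": self.formula,
                "term": term,
                "estimate": self.coefficients[term],
                "se": self.std_errors[term],
                "p": self.p_values[term],
                "r_squared": self.r_squared,
                "f_pvalue": self.f_pvalue,
                "n": self.n,
            }
            for term in self.coefficients.index
        ]


def default_formulae(covariates=COVARIATES) -> list[str]:
    """Single predictors, all pairwise interactions, and the full additive model."""
    singles = list(covariates)
    pairs = [
        f"{a} * {b}"
        for i, a in enumerate(covariates)
        for b in covariates[i + 1 :]
    ]
    full = " + ".join(covariates)
    return singles + pairs + [full]


def fit_support_regressions(
    support: pd.DataFrame,
    geography: pd.DataFrame,
    formulae: list[str] | None = None,
    responses=RESPONSES,
    log_area: bool = True,
    log_isolation: bool = True,
    alpha: float = 0.05,
    skip_infeasible: bool = False,
) -> tuple[list[RegressionResult], pd.DataFrame]:
    """Fit the OLS battery of support ~ geography models.

    ``support`` carries ``community_id`` and the response columns;
    ``geography`` carries ``community_id``, ``area_m2``, ``isolation_m``,
    ``elevation_m`` and optionally ``richness``.  Returns the fitted models
    and a tidy frame (one row per term) with ``significant`` flagged at
    ``alpha``; ``frame.attrs["n_tests"]`` counts the models fitted.
    """
    sup = support.copy()
    if "richness" in sup.columns and "richness" in geography.columns:
        sup = sup.drop(columns="richness")  # geography's richness is authoritative
    df = sup.merge(geography, on="community_id", how="inner")
    if df.empty:
        raise ValidationError("support and geography share no community ids")
    data = pd.DataFrame({"community_id": df["community_id"]})
    for r in responses:
        if r not in df.columns:
            raise ValidationError(f"support table missing response {r!r}")
        data[r] = df[r].astype(float)
    if "richness" not in df.columns:
        raise ValidationError("geography/support must provide a richness column")
    data["richness"] = df["richness"].astype(float)
    data["area"] = np.log(df["area_m2"].astype(float)) if log_area else df["area_m2"]
    data["isolation"] = (
        np.log(df["isolation_m"].astype(float)) if log_isolation else df["isolation_m"]
    )
    data["elevation"] = df["elevation_m"].astype(float)

    if formulae is None:
        formulae = default_formulae()

    results: list[RegressionResult] = []
    rows: list[dict] = []
    n_skipped = 0
    for resp in responses:
        for rhs in formulae:
            formula = f"{resp} ~ {rhs}"
            n_params = len(smf.ols(formula, data=data).exog_names)
            if len(data) <= n_params:
                if skip_infeasible:
                    n_skipped += 1
                    continue
                raise ValidationError(
                    f"{formula!r}: {len(data)} observations for {n_params} parameters"
                )
            fit = smf.ols(formula, data=data).fit()
            res = RegressionResult(
                response=resp,
                formula=rhs,
                coefficients=fit.params,
                std_errors=fit.bse,
                p_values=fit.pvalues,
                r_squared=float(fit.rsquared),
                f_pvalue=float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else float("nan"),
                n=int(fit.nobs),
            )
            results.append(res)
            rows.extend(res.to_rows())
    if not results:
        raise ValidationError("no formula had enough observations to fit")
    frame = pd.DataFrame(rows)
    frame["significant"] = frame["p"] < alpha
    frame.attrs["n_tests"] = len(results)
    frame.attrs["n_skipped"] = n_skipped
    frame.attrs["alpha"] = alpha
    return results, frame
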