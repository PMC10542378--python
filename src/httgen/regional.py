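"""Per-region multiple linear regressions and genotype percent differences.

Each regional binding potential is regressed on the five carrier indicators
plus age (mean-centered), sex, and both scanner indicators (ordinary least
squares via statsmodels). Percent differences between a carrier group and the
homozygote reference are reported relative to the covariate-adjusted
reference-group mean: the fitted value with all genotype indicators at 0,
continuous covariates at their sample means and categorical covariates at
their sample proportions — a denominator that is invariant to covariate
imbalance between genotype groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .simulate import COVARIATES, REGIONS, VARIANTS

__all__ = ["RegionalFit", "RegionalEffects", "fit_region", "percent_difference"]

_CATEGORICAL = ("sex", "pet_scanner", "mri_scanner")


@dataclass
class RegionalFit:
    """OLS coefficient table for one region plus percent-difference summary."""

    region: str
    table: pd.DataFrame  # estimate, se, ci_lower, ci_upper, p per term
    reference_mean: float
    pct_diff: dict = field(default_factory=dict)
    n_obs: int = 0
    dropped_terms: tuple = ()


def _design(cohort: pd.DataFrame) -> pd.DataFrame:
    df = cohort.copy()
    if "age_c" not in df.columns:
        df["age_c"] = df["age"] - df["age"].mean()
    X = df.loc[:, list(COVARIATES)].astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_region(cohort: pd.DataFrame, region: str) -> RegionalFit:
    """OLS of one region's BP_ND on all genotypes and covariates."""
    if region not in cohort.columns:
        raise ValueError(f"region column {region!r} not in the cohort table")
    X = _design(cohort)
    y = cohort[region].astype(float)

    # constant (zero-variance) genotype indicators are inestimable: drop them
    # from the design and report NaN rows rather than an arbitrary pinv split
    dropped = tuple(
        c for c in COVARIATES if X[c].nunique() <= 1
    )
    Xfit = X.drop(columns=list(dropped))
    if np.linalg.matrix_rank(Xfit.to_numpy()) < Xfit.shape[1]:
        raise ValueError(f"rank-deficient design for region {region!r}")
    res = sm.OLS(y, Xfit).fit()

    ci = res.conf_int()
    table = pd.DataFrame(
        {
            "estimate": res.params,
            "se": res.bse,
            "ci_lower": ci[0],
            "ci_upper": ci[1],
            "p": res.pvalues,
        }
    ).reindex(["const", *COVARIATES])

    ref_mean = float(res.params["const"])
    for c in _CATEGORICAL:
        if c in res.params:
            ref_mean += float(res.params[c]) * float(X[c].mean())

    fit = RegionalFit(
        region=region,
        table=table,
        reference_mean=ref_mean,
        n_obs=int(res.nobs),
        dropped_terms=dropped,
    )
    fit.pct_diff = {
        v: percent_difference(fit, v) if v not in dropped else float("nan")
        for v in VARIANTS
    }
    return fit


def percent_difference(fit: RegionalFit, genotype: str) -> float:
    """100 * beta_genotype / covariate-adjusted reference-group mean."""
    if genotype not in VARIANTS:
        raise ValueError(f"{genotype!r} is not a genotype term")
    if not fit.reference_mean > 0:
        raise ValueError(
            f"reference mean for {fit.region} is {fit.reference_mean:.4g}; "
            "percent difference is undefined"
        )
    beta = fit.table.loc[genotype, "estimate"]
    return float(100.0 * beta / fit.reference_mean)


class RegionalEffects(BaseEstimator):
    """Per-region OLS effect estimates over all seven regions.

    Attributes (after ``fit``): ``fits_`` dict of :class:`RegionalFit`;
    ``pct_diff_`` DataFrame (regions x genotypes) of percent differences.
    """

    def __init__(self, regions=REGIONS):
        self.regions = regions

    def fit(self, cohort: pd.DataFrame, y=None):
        self.fits_ = {r: fit_region(cohort, r) for r in self.regions}
        self.pct_diff_ = pd.DataFrame(
            {r: f.pct_diff for r, f in self.fits_.items()}
        ).T.loc[list(self.regions), list(VARIANTS)]
        return self
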