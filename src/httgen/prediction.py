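"""Permutation-calibrated cross-validated genotype prediction of binding.

Per region: (1) residualize BP_ND against the nuisance covariates (age, sex,
PET scanner, MRI scanner) by OLS; (2) evaluate how well the five carrier
indicators predict those residuals with a random forest under five-fold
cross-validation repeated over ``n_resamples`` fold assignments (squared
errors pooled across folds before the root, one RMSE per assignment, mean
over assignments); (3) calibrate significance against an empirical null built
by permuting the residual vector and re-running the *entire* repeated-CV
procedure for each permutation. The test is one-sided (improvement = lower
RMSE) and uses the add-one convention

    p_unc = (1 + #{null RMSE <= observed RMSE}) / (n_permutations + 1).

Model improvement is summarized as
``delta_rmse = 100 * (rmse_residual - rmse_genotype) / rmse_residual``
(positive when genotype helps), and the seven regional p-values are Holm
adjusted into family-wise ``p_fwe``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .multitest import holm_adjust
from .rf import forest_predict
from .simulate import REGIONS, VARIANTS

__all__ = [
    "PredictionConfig",
    "PredictionResult",
    "residualize",
    "rmse_residual",
    "rf_cv_rmse",
    "permutation_test",
    "delta_rmse",
    "predict_all_regions",
]

NUISANCE = ("age_c", "sex", "pet_scanner", "mri_scanner")


@dataclass(frozen=True)
class PredictionConfig:
    """Settings of the prediction harness (defaults = study conditions)."""

    k_folds: int = 5
    n_resamples: int = 10
    n_trees: int = 500
    mtry: int | None = None  # None -> max(1, floor(p/3))
    min_node: int = 5
    n_permutations: int = 10_000
    pooling: str = "pooled"  # or "per_fold": mean of per-fold RMSEs
    seed: int = 0

    def __post_init__(self):
        if self.k_folds < 2:
            raise ValueError("k_folds must be at least 2")
        if self.n_trees < 1 or self.n_resamples < 1:
            raise ValueError("n_trees and n_resamples must be positive")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if self.pooling not in ("pooled", "per_fold"):
            raise ValueError("pooling must be 'pooled' or 'per_fold'")


def residualize(cohort: pd.DataFrame, region: str) -> np.ndarray:
    """OLS residuals of one region's BP_ND on the nuisance covariates."""
    if region not in cohort.columns:
        raise ValueError(f"region column {region!r} not in the cohort table")
    df = cohort.copy()
    if "age_c" not in df.columns:
        df["age_c"] = df["age"] - df["age"].mean()
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in NUISANCE]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient nuisance design for region {region!r}")
    y = df[region].to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def rmse_residual(residuals) -> float:
    """Root mean squared residual: the covariate-only null model's RMSE."""
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("empty residual vector")
    return float(np.sqrt(np.mean(r**2)))


def _fold_bounds(n: int, k: int):
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    return np.concatenate([[0], np.cumsum(sizes)])


def rf_cv_rmse(X, y, config: PredictionConfig, seed: int | None = None) -> float:
    """Mean cross-validated forest RMSE over repeated fold assignments."""
    X = np.asarray(X)
    y = np.asarray(y, dtype=float)
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X and y sizes differ")
    if n < config.k_folds:
        raise ValueError("fewer observations than folds")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    bounds = _fold_bounds(n, config.k_folds)
    out = np.empty(config.n_resamples)
    for r in range(config.n_resamples):
        perm = rng.permutation(n)
        fold_rmses = np.empty(config.k_folds)
        sq_sum = 0.0
        for f in range(config.k_folds):
            test = perm[bounds[f] : bounds[f + 1]]
            train = np.concatenate([perm[: bounds[f]], perm[bounds[f + 1] :]])
            pred = forest_predict(
                X[train],
                y[train],
                X[test],
                n_trees=config.n_trees,
                mtry=config.mtry,
                min_node=config.min_node,
                seed=int(rng.integers(2**31)),
            )
            err2 = (y[test] - pred) ** 2
            sq_sum += float(err2.sum())
            fold_rmses[f] = np.sqrt(err2.mean())
        out[r] = np.sqrt(sq_sum / n) if config.pooling == "pooled" else fold_rmses.mean()
    return float(out.mean())


def permutation_test(X, y, config: PredictionConfig, seed: int | None = None, observed=None):
    """One-sided permutation test of cross-validated prediction skill.

    Each permutation shuffles the outcome vector and re-runs the full
    repeated-CV RMSE procedure. Returns ``(p_unc, summary)`` where summary
    holds the observed RMSE and null-distribution statistics.
    """
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if observed is None:
        observed = rf_cv_rmse(X, y, config, seed=int(rng.integers(2**31)))
    else:
        rng.integers(2**31)  # keep the stream aligned
    null = np.empty(config.n_permutations)
    for b in range(config.n_permutations):
        y_perm = rng.permutation(y)
        null[b] = rf_cv_rmse(X, y_perm, config, seed=int(rng.integers(2**31)))
    p_unc = float((1 + np.sum(null <= observed)) / (config.n_permutations + 1))
    summary = {
        "observed": float(observed),
        "n_permutations": int(config.n_permutations),
        "null_mean": float(null.mean()),
        "null_sd": float(null.std(ddof=1)) if null.size > 1 else 0.0,
        "null_quantiles": {
            q: float(np.quantile(null, q)) for q in (0.025, 0.05, 0.25, 0.5, 0.75, 0.95)
        },
    }
    return p_unc, summary


def delta_rmse(rmse_resid: float, rmse_genotype: float) -> float:
    """Percent RMSE improvement of the genotype model over the covariate-only
    null; positive when genotype predicts better."""
    if not rmse_resid > 0:
        raise ValueError("rmse_residual must be positive")
    return float(100.0 * (rmse_resid - rmse_genotype) / rmse_resid)


@dataclass
class PredictionResult:
    """Per-region prediction summary (unrounded values)."""

    region: str
    rmse_residual: float
    rmse_genotype: float
    delta_rmse_pct: float
    p_unc: float
    p_fwe: float = float("nan")
    null_summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "region": self.region,
            "rmse_residual": self.rmse_residual,
            "rmse_genotype": self.rmse_genotype,
            "delta_rmse_pct": self.delta_rmse_pct,
            "p_unc": self.p_unc,
            "p_fwe": self.p_fwe,
            "null_summary": self.null_summary,
        }


def predict_all_regions(
    cohort: pd.DataFrame, config: PredictionConfig | None = None, regions=REGIONS
) -> list[PredictionResult]:
    """Run the residualize -> repeated-CV forest -> permutation pipeline per
    region and Holm-adjust the uncorrected p-values across the family."""
    config = config or PredictionConfig()
    X = cohort.loc[:, list(VARIANTS)].to_numpy(dtype=int)
    seeds = np.random.SeedSequence(config.seed).generate_state(2 * len(regions))
    results = []
    for i, region in enumerate(regions):
        resid = residualize(cohort, region)
        null_rmse = rmse_residual(resid)
        observed = rf_cv_rmse(X, resid, config, seed=int(seeds[2 * i] % 2**31))
        p_unc, summary = permutation_test(
            X, resid, config, seed=int(seeds[2 * i + 1] % 2**31), observed=observed
        )
        results.append(
            PredictionResult(
                region=region,
                rmse_residual=null_rmse,
                rmse_genotype=observed,
                delta_rmse_pct=delta_rmse(null_rmse, observed),
                p_unc=p_unc,
                null_summary=summary,
            )
        )
    fwe = holm_adjust([r.p_unc for r in results])
    for r, p in zip(results, fwe):
        r.p_fwe = float(p)
    return results
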