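"""Maximum-likelihood Gaussian latent-variable (structural equation) model.

The seven regional binding potentials load on a single latent factor; genotype
and nuisance covariates act on the factor, with optional direct
covariate->region paths and residual covariance links between region pairs.
For subject i with covariate row x_i:

    y_i = nu + lambda * (gamma' x_i) + D x_i + eps_i + lambda * zeta_i
    eps_i ~ N(0, Psi),  zeta_i ~ N(0, tau^2)

so the implied moments are

    mean_i = nu + lambda (gamma' x_i) + D x_i
    Sigma  = tau^2 lambda lambda' + Psi        (shared across subjects)

Identification fixes the reference-region loading at 1 (caudate by default)
and the latent intercept at 0, so latent-scale effects read as effects on
caudate BP_ND. The latent residual variance is estimable only with at least
three regions; a one-region specification degenerates to ordinary least
squares (tau^2 = 0) and two-region specifications are rejected as
unidentified.

Estimation maximizes the exact multivariate-normal likelihood with the mean
parameters (intercepts, latent effects, direct effects) concentrated out by
generalized least squares at each covariance evaluation; the outer
quasi-Newton search runs on log variances. Standard errors come from the
inverse of the numerically differentiated observed information.

Model search scores every absent direct path and residual covariance with a
Rao (score) test at the fitted null (one extra parameter, 1 df), adjusting
p-values by Benjamini-Hochberg across the full candidate set; a slower
refit-and-Wald confirmation mode is also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from sklearn.base import BaseEstimator
from statsmodels.tools import numdiff

from .multitest import bh_adjust
from .simulate import COVARIATES, REGIONS, VARIANTS

__all__ = [
    "LvmSpec",
    "LatentVariableSEM",
    "PathSearchResult",
    "implied_moments",
    "fit_lvm",
    "path_search",
    "lrt_genotypes",
    "DEFAULT_DIRECT_PATHS",
    "DEFAULT_COV_PAIRS",
]

DEFAULT_DIRECT_PATHS = (("sex", "caudate"), ("rs6265", "neocortex"))
DEFAULT_COV_PAIRS = (
    ("caudate", "putamen"),
    ("amygdala", "hippocampus"),
    ("thalamus", "midbrain"),
)

_Z95 = float(stats.norm.ppf(0.975))


@dataclass(frozen=True)
class LvmSpec:
    """Model graph: regions, covariates, identification and extra edges."""

    regions: tuple = REGIONS
    covariates: tuple = COVARIATES
    reference_region: str = "caudate"
    direct_paths: tuple = DEFAULT_DIRECT_PATHS
    residual_cov_pairs: tuple = DEFAULT_COV_PAIRS

    def __post_init__(self):
        object.__setattr__(self, "regions", tuple(self.regions))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "direct_paths", tuple(map(tuple, self.direct_paths)))
        object.__setattr__(
            self, "residual_cov_pairs", tuple(map(tuple, self.residual_cov_pairs))
        )
        if self.reference_region not in self.regions:
            raise ValueError(
                f"reference region {self.reference_region!r} not among regions"
            )
        if len(set(self.regions)) != len(self.regions):
            raise ValueError("duplicate regions")
        for c, r in self.direct_paths:
            if c not in self.covariates or r not in self.regions:
                raise ValueError(f"direct path ({c}, {r}) references unknown node")
        seen = set()
        for r, s in self.residual_cov_pairs:
            if r not in self.regions or s not in self.regions or r == s:
                raise ValueError(f"invalid residual covariance pair ({r}, {s})")
            key = frozenset((r, s))
            if key in seen:
                raise ValueError(f"duplicate residual covariance pair ({r}, {s})")
            seen.add(key)
        if len(self.regions) == 2:
            raise ValueError(
                "a two-region latent specification is not identified; "
                "use one region (OLS) or three or more"
            )
        for c in self.covariates:
            targets = {r for cc, r in self.direct_paths if cc == c}
            if len(self.regions) > 1 and targets >= set(self.regions):
                raise ValueError(
                    f"covariate {c!r} has direct paths to every region in "
                    "addition to its latent effect: unidentified"
                )

    @property
    def latent_variance_free(self) -> bool:
        return len(self.regions) >= 3


class _ParamLayout:
    """Index bookkeeping for the free natural-scale parameter vector:
    [nu | lambda(non-ref) | gamma | delta | tau2 | psi | psi_pairs]."""

    def __init__(self, spec: LvmSpec):
        self.spec = spec
        R, C, D, P = (
            len(spec.regions),
            len(spec.covariates),
            len(spec.direct_paths),
            len(spec.residual_cov_pairs),
        )
        self.R, self.C, self.D, self.P = R, C, D, P
        self.ref = spec.regions.index(spec.reference_region)
        self.free_lam = [i for i in range(R) if i != self.ref] if R > 1 else []
        self.tau_free = spec.latent_variance_free
        names = [f"nu[{r}]" for r in spec.regions]
        names += [f"lambda[{spec.regions[i]}]" for i in self.free_lam]
        names += [f"gamma[{c}]" for c in spec.covariates]
        names += [f"delta[{c}->{r}]" for c, r in spec.direct_paths]
        if self.tau_free:
            names += ["tau2"]
        names += [f"psi[{r}]" for r in spec.regions]
        names += [f"psi[{r},{s}]" for r, s in spec.residual_cov_pairs]
        self.names = names
        self.n_mean = R + C + D
        self.n_params = len(names)
        i = R + len(self.free_lam)
        self.sl_nu = slice(0, R)
        self.sl_lam = slice(R, i)
        self.sl_gamma = slice(i, i + C)
        self.sl_delta = slice(i + C, i + C + D)
        j = i + C + D
        self.i_tau = j if self.tau_free else None
        j += int(self.tau_free)
        self.sl_psi = slice(j, j + R)
        self.sl_pairs = slice(j + R, j + R + P)
        self.pair_idx = [
            (spec.regions.index(r), spec.regions.index(s))
            for r, s in spec.residual_cov_pairs
        ]
        self.direct_idx = [
            (spec.covariates.index(c), spec.regions.index(r))
            for c, r in spec.direct_paths
        ]

    def unpack(self, theta):
        theta = np.asarray(theta, dtype=float)
        lam = np.ones(self.R)
        lam[self.free_lam] = theta[self.sl_lam]
        tau2 = theta[self.i_tau] if self.tau_free else 0.0
        return {
            "nu": theta[self.sl_nu],
            "lam": lam,
            "gamma": theta[self.sl_gamma],
            "delta": theta[self.sl_delta],
            "tau2": tau2,
            "psi": theta[self.sl_psi],
            "pairs": theta[self.sl_pairs],
        }

    def to_unconstrained(self, theta):
        """Map the natural parameter vector to an unconstrained scale
        (log variances, atanh residual correlations)."""
        phi = np.asarray(theta, dtype=float).copy()
        psi = np.maximum(phi[self.sl_psi], 1e-12)
        if self.tau_free:
            phi[self.i_tau] = np.log(max(phi[self.i_tau], 1e-12))
        pairs = phi[self.sl_pairs].copy()
        for m, (i, j) in enumerate(self.pair_idx):
            rho = pairs[m] / np.sqrt(psi[i] * psi[j])
            pairs[m] = np.arctanh(np.clip(rho, -1 + 1e-9, 1 - 1e-9))
        phi[self.sl_pairs] = pairs
        phi[self.sl_psi] = np.log(psi)
        return phi

    def from_unconstrained(self, phi):
        theta = np.asarray(phi, dtype=float).copy()
        psi = np.exp(theta[self.sl_psi])
        if self.tau_free:
            theta[self.i_tau] = np.exp(theta[self.i_tau])
        pairs = theta[self.sl_pairs].copy()
        for m, (i, j) in enumerate(self.pair_idx):
            pairs[m] = np.tanh(pairs[m]) * np.sqrt(psi[i] * psi[j])
        theta[self.sl_pairs] = pairs
        theta[self.sl_psi] = psi
        return theta

    def sigma(self, lam, tau2, psi, pairs):
        S = tau2 * np.outer(lam, lam) + np.diag(psi)
        for k, (i, j) in enumerate(self.pair_idx):
            S[i, j] += pairs[k]
            S[j, i] += pairs[k]
        return S


def _implied_means(layout, p, X):
    M = p["nu"][None, :] + np.outer(X @ p["gamma"], p["lam"])
    for k, (ci, ri) in enumerate(layout.direct_idx):
        M[:, ri] += p["delta"][k] * X[:, ci]
    return M


def implied_moments(spec: LvmSpec, theta, x):
    """Implied mean vector(s) and shared covariance for covariate row(s) x.

    ``theta`` is the free natural-scale parameter vector in the layout order
    (see :attr:`LatentVariableSEM.param_names_`). Pure model algebra — no
    positive-definiteness requirement.
    """
    layout = _ParamLayout(spec)
    p = layout.unpack(theta)
    X = np.atleast_2d(np.asarray(x, dtype=float))
    means = _implied_means(layout, p, X)
    cov = layout.sigma(p["lam"], p["tau2"], p["psi"], p["pairs"])
    if np.asarray(x).ndim == 1:
        means = means[0]
    return means, cov


def _loglik(layout, theta, X, Y):
    """Exact multivariate-normal log-likelihood at a full parameter vector."""
    p = layout.unpack(theta)
    S = layout.sigma(p["lam"], p["tau2"], p["psi"], p["pairs"])
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        return -np.inf
    resid = Y - _implied_means(layout, p, X)
    z = linalg.solve_triangular(L, resid.T, lower=True)
    n, R = Y.shape
    return -0.5 * (
        n * R * np.log(2 * np.pi) + 2 * n * np.log(np.diag(L)).sum() + float((z**2).sum())
    )


def _mean_design(layout, lam, X):
    """Per-subject mean design tensor B (n, R, n_mean) for GLS concentration."""
    n = X.shape[0]
    R, C, D = layout.R, layout.C, layout.D
    B = np.zeros((n, R, layout.n_mean))
    B[:, np.arange(R), np.arange(R)] = 1.0  # intercepts
    B[:, :, R : R + C] = lam[None, :, None] * X[:, None, :]
    for k, (ci, ri) in enumerate(layout.direct_idx):
        B[:, ri, R + C + k] = X[:, ci]
    return B


def _profile(layout, phi, X, Y, return_theta=False):
    """Profile log-likelihood over covariance parameters phi =
    [lambda_free, log tau2 (if free), log psi, atanh residual correlations];
    the mean parameters are concentrated out by GLS. The bounded correlation
    parameterization keeps the search path positive definite (the default
    covariance pairs form disjoint 2x2 blocks)."""
    nfl = len(layout.free_lam)
    lam = np.ones(layout.R)
    lam[layout.free_lam] = phi[:nfl]
    k = nfl
    if layout.tau_free:
        tau2 = np.exp(phi[k])
        k += 1
    else:
        tau2 = 0.0
    psi = np.exp(phi[k : k + layout.R])
    rho = np.tanh(phi[k + layout.R :])
    pairs = np.array(
        [rho[m] * np.sqrt(psi[i] * psi[j]) for m, (i, j) in enumerate(layout.pair_idx)]
    )
    S = layout.sigma(lam, tau2, psi, pairs)
    try:
        L = np.linalg.cholesky(S)
    except np.linalg.LinAlgError:
        return (-np.inf, None) if return_theta else -np.inf

    n = X.shape[0]
    B = _mean_design(layout, lam, X)
    # whiten region axis: L^{-1} applied to B_i and y_i
    U = linalg.solve_triangular(
        L, B.transpose(1, 0, 2).reshape(layout.R, -1), lower=True
    ).reshape(layout.R, n, layout.n_mean)
    Yt = linalg.solve_triangular(L, Y.T, lower=True)
    A = np.einsum("rim,riq->mq", U, U, optimize=True)
    b = np.einsum("rim,ri->m", U, Yt)
    try:
        theta_mean = linalg.solve(A, b, assume_a="pos")
    except linalg.LinAlgError:
        return (-np.inf, None) if return_theta else -np.inf
    quad = float((Yt**2).sum() - b @ theta_mean)
    ll = -0.5 * (
        n * layout.R * np.log(2 * np.pi) + 2 * n * np.log(np.diag(L)).sum() + quad
    )
    if not return_theta:
        return ll
    full = np.empty(layout.n_params)
    full[layout.sl_nu] = theta_mean[: layout.R]
    full[layout.sl_gamma] = theta_mean[layout.R : layout.R + layout.C]
    full[layout.sl_delta] = theta_mean[layout.R + layout.C :]
    full[layout.sl_lam] = lam[layout.free_lam]
    if layout.tau_free:
        full[layout.i_tau] = tau2
    full[layout.sl_psi] = psi
    full[layout.sl_pairs] = pairs
    return ll, full


def _start_values(layout, X, Y):
    """Principal-axis heuristic on the covariate-adjusted region covariance."""
    n = X.shape[0]
    Xc = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Xc, Y, rcond=None)
    resid = Y - Xc @ beta
    S = np.cov(resid.T) if n > 1 else np.eye(layout.R)
    S = np.atleast_2d(S)
    w, v = np.linalg.eigh(S)
    f = np.sqrt(max(w[-1], 1e-8)) * v[:, -1]
    if f[layout.ref] < 0:
        f = -f
    f_ref = max(abs(f[layout.ref]), 1e-4)
    lam = f / f_ref
    tau2 = max(f_ref**2, 1e-6)
    psi = np.maximum(np.diag(S) - lam**2 * tau2, 0.05 * np.maximum(np.diag(S), 1e-6))
    nfl = len(layout.free_lam)
    phi = np.empty(nfl + int(layout.tau_free) + layout.R + layout.P)
    phi[:nfl] = lam[layout.free_lam]
    k = nfl
    if layout.tau_free:
        phi[k] = np.log(tau2)
        k += 1
    phi[k : k + layout.R] = np.log(psi)
    for m, (i, j) in enumerate(layout.pair_idx):
        rho = (S[i, j] - lam[i] * lam[j] * tau2) / np.sqrt(psi[i] * psi[j])
        phi[k + layout.R + m] = np.arctanh(np.clip(rho, -0.9, 0.9))
    return phi


class LatentVariableSEM(BaseEstimator):
    """Single-factor structural equation model for regional binding.

    Parameters
    ----------
    regions, covariates, reference_region, direct_paths, residual_cov_pairs
        Model graph (see :class:`LvmSpec`).
    max_restarts : int
        Jittered restarts if the quasi-Newton search fails to converge.
    compute_se : bool
        Invert the observed information for SEs/CIs/p-values after fitting.
    random_state : int
        Seed for restart jitter.

    Attributes
    ----------
    params_ : pd.Series
        Named ML estimates (natural scale).
    se_, pvalues_ : pd.Series
    conf_int_ : pd.DataFrame with columns ``lower``/``upper`` (Wald 95%).
    loglik_ : float
    converged_ : bool
    n_obs_ : int
    """

    def __init__(
        self,
        regions=REGIONS,
        covariates=COVARIATES,
        reference_region="caudate",
        direct_paths=DEFAULT_DIRECT_PATHS,
        residual_cov_pairs=DEFAULT_COV_PAIRS,
        max_restarts=5,
        compute_se=True,
        random_state=0,
    ):
        self.regions = regions
        self.covariates = covariates
        self.reference_region = reference_region
        self.direct_paths = direct_paths
        self.residual_cov_pairs = residual_cov_pairs
        self.max_restarts = max_restarts
        self.compute_se = compute_se
        self.random_state = random_state

    # ------------------------------------------------------------------ #

    def _spec(self) -> LvmSpec:
        return LvmSpec(
            regions=self.regions,
            covariates=self.covariates,
            reference_region=self.reference_region,
            direct_paths=self.direct_paths,
            residual_cov_pairs=self.residual_cov_pairs,
        )

    @staticmethod
    def _validate_xy(spec, X, Y):
        if isinstance(X, pd.DataFrame):
            X = X.loc[:, list(spec.covariates)].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        if isinstance(Y, pd.DataFrame):
            Y = Y.loc[:, list(spec.regions)].to_numpy(dtype=float)
        else:
            Y = np.asarray(Y, dtype=float)
        Y = Y.reshape(len(Y), -1)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y have different numbers of rows")
        if X.shape[1] != len(spec.covariates) or Y.shape[1] != len(spec.regions):
            raise ValueError("X/Y column counts do not match the specification")
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("non-finite values in the input")
        return X, Y

    def fit(self, X, Y):
        spec = self._spec()
        X, Y = self._validate_xy(spec, X, Y)
        layout = _ParamLayout(spec)
        if X.shape[0] <= layout.n_params:
            raise ValueError(
                f"n = {X.shape[0]} observations for {layout.n_params} parameters"
            )
        rng = np.random.default_rng(self.random_state)
        phi0 = _start_values(layout, X, Y)

        def objective(phi):
            ll = _profile(layout, phi, X, Y)
            return np.inf if not np.isfinite(ll) else -ll

        best = None
        converged = False
        phi_try = phi0.copy()
        for attempt in range(self.max_restarts + 1):
            res = optimize.minimize(
                objective, phi_try, method="L-BFGS-B", options={"maxiter": 2000}
            )
            if best is None or res.fun < best.fun:
                best = res
            if res.success and np.isfinite(res.fun):
                converged = True
                break
            phi_try = phi0 + rng.normal(0, 0.1 + 0.1 * attempt, size=phi0.size)
        ll, theta = _profile(layout, best.x, X, Y, return_theta=True)

        self.spec_ = spec
        self.layout_ = layout
        self.param_names_ = list(layout.names)
        self.params_ = pd.Series(theta, index=self.param_names_)
        self.loglik_ = float(ll)
        self.n_obs_ = int(X.shape[0])
        self.converged_ = bool(converged)
        self._X, self._Y = X, Y

        if self.compute_se:
            H = numdiff.approx_hess(theta, lambda t: _loglik(layout, t, X, Y))
            info = -H
            try:
                cov = np.linalg.inv(info)
                diag = np.diag(cov)
                if np.any(diag <= 0):
                    raise np.linalg.LinAlgError
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(info)
                diag = np.abs(np.diag(cov))
                self.converged_ = False
            se = np.sqrt(diag)
            self.se_ = pd.Series(se, index=self.param_names_)
            self.pvalues_ = pd.Series(
                2 * stats.norm.sf(np.abs(theta) / np.where(se > 0, se, np.inf)),
                index=self.param_names_,
            )
            self.conf_int_ = pd.DataFrame(
                {"lower": theta - _Z95 * se, "upper": theta + _Z95 * se},
                index=self.param_names_,
            )
        return self

    # ------------------------------------------------------------------ #

    def loglik(self, X=None, Y=None, theta=None) -> float:
        """Log-likelihood at the fitted (or supplied) parameters."""
        if X is None:
            X, Y = self._X, self._Y
        else:
            X, Y = self._validate_xy(self.spec_, X, Y)
        theta = self.params_.to_numpy() if theta is None else np.asarray(theta)
        return _loglik(self.layout_, theta, X, Y)

    def score(self, X, Y) -> float:
        """Mean per-observation log-likelihood (sklearn scoring convention)."""
        X, Y = self._validate_xy(self.spec_, X, Y)
        return self.loglik(X, Y) / max(len(X), 1)

    def implied_moments(self, x):
        return implied_moments(self.spec_, self.params_.to_numpy(), x)

    def summary(self) -> pd.DataFrame:
        cols = {"estimate": self.params_}
        if hasattr(self, "se_"):
            cols.update(
                {
                    "se": self.se_,
                    "ci_lower": self.conf_int_["lower"],
                    "ci_upper": self.conf_int_["upper"],
                    "p": self.pvalues_,
                }
            )
        return pd.DataFrame(cols)

    # ------------------------------------------------------------------ #
    # model search

    def candidate_paths(self):
        """All absent direct paths and absent residual covariances."""
        spec = self.spec_
        existing = set(map(tuple, spec.direct_paths))
        cands = [
            ("direct", c, r)
            for c in spec.covariates
            for r in spec.regions
            if (c, r) not in existing
        ]
        have = {frozenset(p) for p in spec.residual_cov_pairs}
        for i, r in enumerate(spec.regions):
            for s in spec.regions[i + 1 :]:
                if frozenset((r, s)) not in have:
                    cands.append(("cov", r, s))
        return cands

    def _extended_loglik_fn(self, kind, a, b):
        spec, layout = self.spec_, self.layout_
        X, Y = self._X, self._Y
        if kind == "direct":
            ext_spec = replace(spec, direct_paths=spec.direct_paths + ((a, b),))
        else:
            ext_spec = replace(
                spec, residual_cov_pairs=spec.residual_cov_pairs + ((a, b),)
            )
        ext_layout = _ParamLayout(ext_spec)

        def embed(theta_ext):
            return _loglik(ext_layout, theta_ext, X, Y)

        def lift(theta, beta):
            """Embed (theta, beta) of the base+1 model into the extended layout."""
            t = np.empty(ext_layout.n_params)
            t[ext_layout.sl_nu] = theta[layout.sl_nu]
            t[ext_layout.sl_lam] = theta[layout.sl_lam]
            t[ext_layout.sl_gamma] = theta[layout.sl_gamma]
            if kind == "direct":
                t[ext_layout.sl_delta] = np.append(theta[layout.sl_delta], beta)
                t[ext_layout.sl_pairs] = theta[layout.sl_pairs]
            else:
                t[ext_layout.sl_delta] = theta[layout.sl_delta]
                t[ext_layout.sl_pairs] = np.append(theta[layout.sl_pairs], beta)
            if layout.tau_free:
                t[ext_layout.i_tau] = theta[layout.i_tau]
            t[ext_layout.sl_psi] = theta[layout.sl_psi]
            return t

        return ext_spec, ext_layout, (lambda v: embed(lift(v[:-1], v[-1])))

    def path_search(self, method="score", alpha=0.05) -> "PathSearchResult":
        """Score every candidate edge; BH-adjust across the candidate set."""
        if not self.converged_:
            raise RuntimeError("path search requires a converged fit")
        cands = self.candidate_paths()
        if not cands:
            return PathSearchResult(
                candidates=pd.DataFrame(
                    columns=["path", "statistic", "p", "p_fdr"]
                ),
                added=[],
                method=method,
            )
        theta = self.params_.to_numpy()
        rows = []
        if method == "score":
            # work on the unconstrained scale (log variances, atanh residual
            # correlations) where every finite-difference step stays inside
            # the positive-definite region; the Rao statistic is invariant to
            # smooth reparameterization of the nuisance parameters.
            # gradient and information of the base model are shared by every
            # candidate; each candidate only adds one new row/column.
            layout = self.layout_
            phi0 = layout.to_unconstrained(theta)
            base_ll = lambda ph: _loglik(
                layout, layout.from_unconstrained(ph), self._X, self._Y
            )
            g0 = numdiff.approx_fprime(phi0, base_ll, centered=True)
            H0 = numdiff.approx_hess(phi0, base_ll)
        for kind, a, b in cands:
            label = f"{a}->{b}" if kind == "direct" else f"{a}~{b}"
            if method == "score":
                _, _, ll_ext = self._extended_loglik_fn(kind, a, b)
                ll_ext_t = lambda v: ll_ext(
                    np.append(layout.from_unconstrained(v[:-1]), v[-1])
                )
                stat = _score_statistic(ll_ext_t, phi0, g0, H0)
                if not np.isfinite(stat):
                    warnings.warn(
                        f"score statistic for candidate {label} was not "
                        "finite; reporting no evidence (p = 1)"
                    )
                    stat = 0.0
                p = float(stats.chi2.sf(stat, df=1))
            elif method == "wald":
                ext_spec, _, _ = self._extended_loglik_fn(kind, a, b)
                est = LatentVariableSEM(
                    regions=ext_spec.regions,
                    covariates=ext_spec.covariates,
                    reference_region=ext_spec.reference_region,
                    direct_paths=ext_spec.direct_paths,
                    residual_cov_pairs=ext_spec.residual_cov_pairs,
                    max_restarts=self.max_restarts,
                    random_state=self.random_state,
                ).fit(self._X, self._Y)
                name = (
                    f"delta[{a}->{b}]" if kind == "direct" else f"psi[{a},{b}]"
                )
                z = est.params_[name] / est.se_[name]
                stat = float(z**2)
                p = float(est.pvalues_[name])
            else:
                raise ValueError("method must be 'score' or 'wald'")
            rows.append({"path": label, "statistic": stat, "p": p})
        table = pd.DataFrame(rows)
        table["p_fdr"] = bh_adjust(table["p"].to_numpy())
        added = table.loc[table["p_fdr"] < alpha, "path"].tolist()
        return PathSearchResult(candidates=table, added=added, method=method)


def _score_statistic(ll_ext, theta, g0, H0, eps=1e-3):
    """Rao score statistic for one extra parameter fixed at zero.

    ``ll_ext`` maps the (k+1)-vector [theta, beta] to the extended model's
    log-likelihood; ``g0``/``H0`` are the base model's gradient and Hessian at
    ``theta``. The new gradient entry and the new information row/column are
    obtained by central finite differences in beta; the log-likelihood is
    close to quadratic near the optimum, so moderately large steps keep the
    roundoff error of the second differences well below the curvature.
    """
    k = theta.size

    def f(beta, t=None):
        v = np.append(theta if t is None else t, beta)
        return ll_ext(v)

    f0 = f(0.0)
    u_new = (f(eps) - f(-eps)) / (2 * eps)
    h_nn = (f(eps) - 2 * f0 + f(-eps)) / eps**2
    h = np.empty(k)
    for j in range(k):
        step = 1e-4 * (1.0 + abs(theta[j]))
        tp = theta.copy()
        tp[j] += step
        tm = theta.copy()
        tm[j] -= step
        h[j] = (f(eps, tp) - f(-eps, tp) - f(eps, tm) + f(-eps, tm)) / (4 * step * eps)
    H = np.empty((k + 1, k + 1))
    H[:k, :k] = H0
    H[:k, k] = H[k, :k] = h
    H[k, k] = h_nn
    U = np.append(g0, u_new)
    if not (np.all(np.isfinite(U)) and np.all(np.isfinite(H))):
        return np.nan
    try:
        stat = float(U @ np.linalg.solve(-H, U))
    except np.linalg.LinAlgError:
        stat = float(U @ np.linalg.pinv(-H) @ U)
    return max(stat, 0.0) if np.isfinite(stat) else np.nan


@dataclass
class PathSearchResult:
    """Candidate edges with score statistics, raw and BH-adjusted p-values."""

    candidates: pd.DataFrame
    added: list = field(default_factory=list)
    method: str = "score"


# ---------------------------------------------------------------------- #
# functional wrappers operating on a cohort table


def _split_cohort(cohort: pd.DataFrame, spec: LvmSpec):
    df = cohort.copy()
    if "age_c" not in df.columns and "age" in df.columns:
        df["age_c"] = df["age"] - df["age"].mean()
    X = df.loc[:, list(spec.covariates)]
    Y = df.loc[:, list(spec.regions)]
    return X, Y


def fit_lvm(cohort: pd.DataFrame, spec: LvmSpec | None = None, **kwargs) -> LatentVariableSEM:
    """Fit the latent-variable model to a cohort table."""
    spec = spec or LvmSpec()
    X, Y = _split_cohort(cohort, spec)
    est = LatentVariableSEM(
        regions=spec.regions,
        covariates=spec.covariates,
        reference_region=spec.reference_region,
        direct_paths=spec.direct_paths,
        residual_cov_pairs=spec.residual_cov_pairs,
        **kwargs,
    )
    return est.fit(X, Y)


def path_search(fit: LatentVariableSEM, method="score", alpha=0.05) -> PathSearchResult:
    return fit.path_search(method=method, alpha=alpha)


def reduced_spec(spec: LvmSpec) -> LvmSpec:
    """The specification with every genotype-bearing parameter removed."""
    return replace(
        spec,
        covariates=tuple(c for c in spec.covariates if c not in VARIANTS),
        direct_paths=tuple(p for p in spec.direct_paths if p[0] not in VARIANTS),
    )


def lrt_genotypes(cohort: pd.DataFrame, spec: LvmSpec | None = None, **kwargs):
    """Genotype-block likelihood-ratio test: full model vs. all genotype
    parameters removed. Returns ``(statistic, df, p)``."""
    spec = spec or LvmSpec()
    full = fit_lvm(cohort, spec, compute_se=False, **kwargs)
    red = fit_lvm(cohort, reduced_spec(spec), compute_se=False, **kwargs)
    df = full.layout_.n_params - red.layout_.n_params
    stat = 2.0 * (full.loglik_ - red.loglik_)
    if df == 0:  # nothing removed: the models are identical
        return max(stat, 0.0), 0, 1.0
    if stat < -1e-6:
        retry = {**kwargs, "max_restarts": 10}
        full = fit_lvm(cohort, spec, compute_se=False, **retry)
        stat = 2.0 * (full.loglik_ - red.loglik_)
        if stat < -1e-6:
            raise RuntimeError(
                f"negative LRT statistic ({stat:.3g}) after restarts: "
                "the full model did not reach its optimum"
            )
    stat = max(stat, 0.0)
    return stat, df, float(stats.chi2.sf(stat, df=df))
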