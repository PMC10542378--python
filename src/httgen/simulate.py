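"""Seeded synthetic cohorts with the generative structure the analysis assumes.

The generator emulates a healthy-volunteer [11C]DASB PET cohort: fixed
demographic and genotype marginals (n = 140; 84 F / 56 M; GE-Advance vs. HRRT
PET scanners 42/98; Trio vs. Verio MRI 81/59; per-variant carrier counts),
ages from a truncated normal calibrated so the *realized* mean/SD match
26.7 +/- 7.2 years on 18-51, and regional binding potentials generated from a
single-factor latent model:

    eta_i   = sum_c gamma_c x_ic + zeta_i,        zeta ~ N(0, tau^2)
    BP_ir   = mu_r + lambda_r eta_i + delta_r x_i(direct) + eps_ir,
    eps_i ~ N(0, Psi)   with three residual covariance links.

Calibration closure: the caudate loading is fixed at 1 (reference scale), and
the planted MAOA carrier effect gamma = 0.07 together with the target caudate
percent difference (11%) pins the covariate-adjusted reference-group caudate
mean at 0.07/0.11 ~= 0.636; since the direct sex->caudate path (0.14)
contributes to that adjusted mean at the male sample proportion, the caudate
intercept is mu_cau = 0.07/0.11 - 0.14 * p_male. Loadings of the remaining
regions are derived so latent-mediated effects reproduce the planted regional
percent-difference profile, and region residual variances are derived by
subtracting the latent contribution from the target covariate-adjusted SDs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .genotypes import CARRIER_ALLELE

__all__ = [
    "REGIONS",
    "VARIANTS",
    "COVARIATES",
    "GeneratorConfig",
    "generate_covariates",
    "generate_genotypes",
    "generate_binding",
    "generate_cohort",
]

REGIONS = (
    "caudate",
    "putamen",
    "midbrain",
    "thalamus",
    "hippocampus",
    "amygdala",
    "neocortex",
)
VARIANTS = ("httlpr", "rs6295", "rs7333412", "rs1137070", "rs6265")
#: covariate order used throughout the package (models and generator)
COVARIATES = VARIANTS + ("age_c", "sex", "pet_scanner", "mri_scanner")


def _truncnorm_shape(mean: float, sd: float, lo: float, hi: float):
    """Underlying (loc, scale) such that the truncated distribution on
    [lo, hi] has the requested mean and SD."""

    def moments(params):
        loc, log_scale = params
        scale = np.exp(log_scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - mean, np.sqrt(v) - sd]

    loc, log_scale = optimize.fsolve(moments, [mean, np.log(sd)], full_output=False)
    return float(loc), float(np.exp(log_scale))


def _default_carrier_counts():
    return {"httlpr": 99, "rs6295": 107, "rs7333412": 53, "rs1137070": 65, "rs6265": 50}


def _default_latent_effects():
    return {
        "httlpr": 0.0,
        "rs6295": 0.0,
        "rs7333412": 0.0,
        "rs1137070": 0.07,
        "rs6265": -0.06,
        "age_c": -0.009,
        "sex": 0.0,
        "pet_scanner": 0.0,
        "mri_scanner": 0.0,
    }


def _default_regional_pct():
    return {
        "caudate": 11.0,
        "putamen": 9.0,
        "midbrain": 6.0,
        "thalamus": 6.0,
        "hippocampus": 6.0,
        "amygdala": 2.0,
        "neocortex": 6.0,
    }


def _default_regional_means():
    # plausible healthy-adult regional BP_ND levels relative to caudate;
    # the caudate mean itself is derived by the calibration closure
    return {
        "putamen": 0.75,
        "midbrain": 0.85,
        "thalamus": 0.65,
        "hippocampus": 0.35,
        "amygdala": 0.55,
        "neocortex": 0.25,
    }


def _default_adjusted_sd():
    # per-region total covariate-adjusted SD targets
    return {
        "caudate": 0.266,
        "putamen": 0.301,
        "midbrain": 0.251,
        "thalamus": 0.305,
        "hippocampus": 0.121,
        "amygdala": 0.272,
        "neocortex": 0.056,
    }


def _default_residual_corr():
    return {
        ("caudate", "putamen"): 0.4,
        ("amygdala", "hippocampus"): 0.3,
        ("thalamus", "midbrain"): 0.3,
    }


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic-cohort generator.

    Defaults are the study conditions: fixed marginal counts, planted latent
    effects (MAOA carrier +0.07, rs6265 met carrier -0.06, age -0.009/y on the
    caudate reference scale), the direct sex->caudate path (+0.14) and an
    rs6265->neocortex direct path that nullifies the neocortical total effect,
    regional percent-difference targets, covariate-adjusted SD targets per
    region, latent residual SD ``latent_sd``, and residual correlations for
    the three covariance links.
    """

    n: int = 140
    sex_counts: tuple[int, int] = (84, 56)  # (female, male)
    age_mean: float = 26.7
    age_sd: float = 7.2
    age_range: tuple[float, float] = (18.0, 51.0)
    pet_counts: tuple[int, int] = (42, 98)  # (GE-Advance "A", HRRT "H")
    mri_counts: tuple[int, int] = (81, 59)  # (Trio "T", Verio "V")
    carrier_counts: dict = field(default_factory=_default_carrier_counts)
    latent_effects: dict = field(default_factory=_default_latent_effects)
    sex_caudate_effect: float = 0.14
    #: rs6265 -> neocortex direct effect; None derives -gamma_rs6265 * lambda_neo
    #: (total neocortical rs6265 effect of zero)
    rs6265_neocortex_effect: float | None = None
    regional_pct: dict = field(default_factory=_default_regional_pct)
    regional_means: dict = field(default_factory=_default_regional_means)
    adjusted_sd: dict = field(default_factory=_default_adjusted_sd)
    latent_sd: float = 0.15
    residual_corr: dict = field(default_factory=_default_residual_corr)
    #: explicit loadings override; None derives them from the pct closure
    loadings: dict | None = None
    #: also emit raw genotype strings consistent with the carrier indicators
    emit_raw: bool = False
    #: fraction of S' alleles that are L_G rather than S (raw emission only)
    lg_fraction: float = 0.15
    seed: int = 0

    # ------------------------------------------------------------------ #
    # derived quantities

    def male_proportion(self) -> float:
        return self.sex_counts[1] / self.n if self.n else 0.0

    def region_means(self) -> dict:
        """Regional intercepts mu_r (reference genotype group, covariate means)."""
        mu = dict(self.regional_means)
        if "caudate" not in mu:
            gamma = self.latent_effects["rs1137070"]
            pct = self.regional_pct["caudate"]
            if gamma == 0 or pct == 0:
                raise ValueError(
                    "caudate mean cannot be derived from the percent closure when "
                    "the MAOA latent effect or target percent is zero; supply "
                    "regional_means['caudate'] explicitly"
                )
            mu["caudate"] = gamma / (pct / 100.0) - self.sex_caudate_effect * self.male_proportion()
        return mu

    def region_loadings(self) -> dict:
        """Loadings lambda_r; caudate fixed at 1 (reference scale)."""
        if self.loadings is not None:
            lam = dict(self.loadings)
            lam["caudate"] = 1.0
            return lam
        gamma = self.latent_effects["rs1137070"]
        if gamma == 0:
            raise ValueError(
                "loadings cannot be derived from the percent closure when the "
                "MAOA latent effect is zero; supply `loadings` explicitly"
            )
        mu = self.region_means()
        lam = {"caudate": 1.0}
        for r in REGIONS:
            if r == "caudate":
                continue
            lam[r] = (self.regional_pct[r] / 100.0) * mu[r] / gamma
        return lam

    def residual_variances(self) -> dict:
        """psi_r = adjusted_sd_r^2 - lambda_r^2 tau^2 (must be positive)."""
        lam = self.region_loadings()
        tau2 = self.latent_sd**2
        psi = {}
        for r in REGIONS:
            v = self.adjusted_sd[r] ** 2 - lam[r] ** 2 * tau2
            if v <= 0:
                raise ValueError(
                    f"derived residual variance for {r} is non-positive "
                    f"({v:.4g}); lower latent_sd or raise adjusted_sd[{r}]"
                )
            psi[r] = v
        return psi

    def residual_cov_matrix(self) -> np.ndarray:
        psi = self.residual_variances()
        cov = np.diag([psi[r] for r in REGIONS])
        idx = {r: i for i, r in enumerate(REGIONS)}
        for (r, s), rho in self.residual_corr.items():
            c = rho * np.sqrt(psi[r] * psi[s])
            cov[idx[r], idx[s]] = cov[idx[s], idx[r]] = c
        # positive definiteness check
        np.linalg.cholesky(cov)
        return cov

    def direct_effects(self) -> dict:
        """Direct (covariate, region) -> effect paths planted by the generator."""
        neo = self.rs6265_neocortex_effect
        if neo is None:
            neo = -self.latent_effects["rs6265"] * self.region_loadings()["neocortex"]
        return {("sex", "caudate"): self.sex_caudate_effect, ("rs6265", "neocortex"): neo}

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name, counts in [
            ("sex_counts", self.sex_counts),
            ("pet_counts", self.pet_counts),
            ("mri_counts", self.mri_counts),
        ]:
            if sum(counts) != self.n or min(counts) < 0:
                raise ValueError(f"{name} {counts} inconsistent with n={self.n}")
        for v, k in self.carrier_counts.items():
            if not 0 <= k <= self.n:
                raise ValueError(f"carrier count for {v} ({k}) outside [0, n]")
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be non-negative")
        if not self.age_range[0] < self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if self.n > 0:
            self.residual_cov_matrix()  # raises on invalid dispersion config

    # ------------------------------------------------------------------ #

    @classmethod
    def null(cls, **overrides) -> "GeneratorConfig":
        """A no-genetic-effect configuration with the default dispersion
        structure (loadings/means frozen at their default derived values)."""
        base = cls()
        cfg = cls(
            latent_effects={
                **_default_latent_effects(),
                "httlpr": 0.0,
                "rs6295": 0.0,
                "rs7333412": 0.0,
                "rs1137070": 0.0,
                "rs6265": 0.0,
            },
            rs6265_neocortex_effect=0.0,
            loadings=base.region_loadings(),
            regional_means={**base.region_means()},
        )
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown generator config key: {key}")
            current = getattr(cfg, key)
            if isinstance(current, tuple) and isinstance(value, (list, tuple)):
                value = tuple(value)
            if key == "residual_corr" and isinstance(value, dict):
                value = {tuple(k.split("~")): float(v) for k, v in value.items()}
            setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["residual_corr"] = {"~".join(k): v for k, v in self.residual_corr.items()}
        d["sex_counts"] = list(self.sex_counts)
        d["pet_counts"] = list(self.pet_counts)
        d["mri_counts"] = list(self.mri_counts)
        d["age_range"] = list(self.age_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------- #
# generation


def _fixed_count_indicator(n: int, n_ones: int, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros(n, dtype=int)
    out[:n_ones] = 1
    rng.shuffle(out)
    return out


def generate_covariates(config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Ids, ages, sex and scanner assignments with exact marginal counts."""
    config.validate()
    rng = np.random.default_rng(config.seed if rng is None else rng)
    n = config.n
    if n == 0:
        return pd.DataFrame(
            columns=["id", "age", "sex", "pet_scanner", "mri_scanner"]
        ).astype({"id": str, "age": float, "sex": int, "pet_scanner": int, "mri_scanner": int})
    loc, scale = _truncnorm_shape(config.age_mean, config.age_sd, *config.age_range)
    a = (config.age_range[0] - loc) / scale
    b = (config.age_range[1] - loc) / scale
    age = stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    return pd.DataFrame(
        {
            "id": [f"sub-{i + 1:04d}" for i in range(n)],
            "age": np.round(age, 2),
            "sex": _fixed_count_indicator(n, config.sex_counts[1], rng),  # 1 = male
            "pet_scanner": _fixed_count_indicator(n, config.pet_counts[1], rng),  # 1 = HRRT
            "mri_scanner": _fixed_count_indicator(n, config.mri_counts[1], rng),  # 1 = Verio
        }
    )


def _raw_from_carrier(variant, carrier, sex, rng, lg_fraction):
    """Raw genotype strings consistent with a carrier indicator vector.

    Within carriers the heterozygote/homozygote split follows Hardy-Weinberg
    proportions at the allele frequency implied by the carrier fraction.
    """
    n = carrier.size
    frac = max(min(carrier.mean() if n else 0.0, 1.0 - 1e-9), 0.0)
    q = 1.0 - np.sqrt(1.0 - frac)  # P(carrier) = 1 - (1-q)^2
    p_hom = q**2 / (q**2 + 2 * q * (1 - q)) if q > 0 else 0.0

    if variant == "httlpr":
        lpr, snp = [], []
        for c in carrier:
            if not c:
                lpr.append("L/L")
                snp.append("A/A")
                continue
            k = 2 if rng.random() < p_hom else 1
            alleles = []  # (lpr allele, snp allele)
            for _ in range(k):
                if rng.random() < lg_fraction:
                    alleles.append(("L", "G"))
                else:
                    alleles.append(("S", "A"))
            while len(alleles) < 2:
                alleles.append(("L", "A"))
            rng.shuffle(alleles)
            lpr.append("/".join(a[0] for a in alleles))
            snp.append("/".join(a[1] for a in alleles))
        return {"httlpr": lpr, "httlpr_snp": snp}

    alt = CARRIER_ALLELE[variant]
    ref = {"rs6265": "G", "rs6295": "C", "rs7333412": "A", "rs1137070": "C"}[variant]
    out = []
    for i, c in enumerate(carrier):
        if variant == "rs1137070" and sex[i] == 1:  # hemizygous male
            out.append(alt if c else ref)
        elif not c:
            out.append(f"{ref}/{ref}")
        elif rng.random() < p_hom:
            out.append(f"{alt}/{alt}")
        else:
            out.append(f"{ref}/{alt}" if rng.random() < 0.5 else f"{alt}/{ref}")
    return {variant: out}


def generate_genotypes(config: GeneratorConfig, rng=None, sex=None) -> pd.DataFrame:
    """Carrier indicators with exact per-variant counts, independent across
    variants; optionally also raw genotype strings (``config.emit_raw``)."""
    config.validate()
    rng = np.random.default_rng(config.seed if rng is None else rng)
    data = {}
    for variant in VARIANTS:
        data[variant] = _fixed_count_indicator(config.n, config.carrier_counts[variant], rng)
    df = pd.DataFrame(data, columns=list(VARIANTS), index=range(config.n))
    if config.emit_raw:
        if sex is None:
            raise ValueError("raw genotype emission requires the sex vector")
        raw_cols = {}
        for variant in VARIANTS:
            raw_cols.update(
                _raw_from_carrier(
                    variant, df[variant].to_numpy(), np.asarray(sex), rng, config.lg_fraction
                )
            )
        for name, col in raw_cols.items():
            df[f"raw_{name}"] = col
    return df


def generate_binding(cohort: pd.DataFrame, config: GeneratorConfig, rng=None) -> pd.DataFrame:
    """Append the seven regional BP_ND columns generated from the latent model."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    n = len(cohort)
    out = cohort.copy()
    if n == 0:
        for r in REGIONS:
            out[r] = pd.Series(dtype=float)
        return out
    mu = config.region_means()
    lam = config.region_loadings()
    psi_cov = config.residual_cov_matrix()
    direct = config.direct_effects()

    x = np.column_stack(
        [
            cohort[c].to_numpy(dtype=float)
            if c != "age_c"
            else cohort["age"].to_numpy(dtype=float) - cohort["age"].mean()
            for c in COVARIATES
        ]
    )
    gamma = np.array([config.latent_effects[c] for c in COVARIATES])
    eta = x @ gamma + rng.normal(0.0, config.latent_sd, size=n)
    chol = np.linalg.cholesky(psi_cov)
    eps = rng.standard_normal((n, len(REGIONS))) @ chol.T

    cov_idx = {c: j for j, c in enumerate(COVARIATES)}
    for i, r in enumerate(REGIONS):
        y = mu[r] + lam[r] * eta + eps[:, i]
        for (c, rr), d in direct.items():
            if rr == r:
                y = y + d * x[:, cov_idx[c]]
        out[r] = y
    return out


def generate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Full cohort table: covariates + genotypes + regional binding."""
    config = GeneratorConfig() if config is None else config
    if seed is not None:
        config = dataclasses.replace(config, seed=seed)
    rng = np.random.default_rng(config.seed)
    cov = generate_covariates(config, rng)
    geno = generate_genotypes(config, rng, sex=cov["sex"] if len(cov) else [])
    cohort = pd.concat([cov.reset_index(drop=True), geno.reset_index(drop=True)], axis=1)
    return generate_binding(cohort, config, rng)
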