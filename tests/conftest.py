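import dataclasses

import pytest

from httgen.simulate import GeneratorConfig, generate_cohort


def scaled_config(n: int, base: GeneratorConfig | None = None, **overrides) -> GeneratorConfig:
    """Default generator configuration rescaled to cohort size n, keeping the
    marginal proportions of the default study conditions."""
    base = base or GeneratorConfig()
    f = n / base.n
    cfg = dataclasses.replace(
        base,
        n=n,
        sex_counts=(n - int(base.sex_counts[1] * f), int(base.sex_counts[1] * f)),
        pet_counts=(n - int(base.pet_counts[1] * f), int(base.pet_counts[1] * f)),
        mri_counts=(n - int(base.mri_counts[1] * f), int(base.mri_counts[1] * f)),
        carrier_counts={k: int(v * f) for k, v in base.carrier_counts.items()},
        **overrides,
    )
    return cfg


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (n = 140, planted study effects)."""
    return generate_cohort(GeneratorConfig(), seed=1)


@pytest.fixture(scope="session")
def big_cohort():
    """A large cohort (n = 10,000) for asymptotic recovery checks."""
    return generate_cohort(scaled_config(10_000), seed=11)


@pytest.fixture(scope="session")
def big_fit(big_cohort):
    from httgen.lvm import fit_lvm

    return fit_lvm(big_cohort, compute_se=False)
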