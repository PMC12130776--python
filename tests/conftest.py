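"""Shared fixtures: small synthetic bundles with closed-form ground truth.

Bundles are generated once per session into tmp directories; the noise-free
untruncated one is the oracle for exact pipeline equivalence, the noisy one
exercises censoring, disruption and recovery behaviour.
"""

import pytest
from hypothesis import HealthCheck, settings

from pharmtrends import Dataset, generate
from pharmtrends.synthetic import (
    CpiConfig,
    DisruptionConfig,
    EligibilityConfig,
    EntityConfig,
    StepChange,
    SyntheticConfig,
)

settings.register_profile(
    "ci", derandomize=True, database=None,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("ci")


def _entities():
    return [
        EntityConfig(atc="A02BC02", name="pantoprazole", baseline=50000,
                     monthly_trend=1.004, unit_cost=12.0),
        EntityConfig(atc="A02BC05", name="esomeprazole", baseline=80000,
                     monthly_trend=1.005, unit_cost=10.0),
        EntityConfig(
            atc="N03AX16", name="pregabalin", baseline=40000, unit_cost=32.49,
            step_changes=[StepChange(month="2018-01", multiplier=0.3,
                                     applies_to="unit_cost")],
        ),
        EntityConfig(atc="J01CA04", name="amoxicillin", baseline=60000,
                     seasonal_amplitude=0.5, seasonal_peak_month=12, unit_cost=8.0),
        EntityConfig(
            atc="N01BB02", name="lidocaine", baseline=20000, unit_cost=60.0,
            step_changes=[StepChange(month="2016-07", multiplier=0.1,
                                     applies_to="frequency")],
        ),
    ]


def base_config(**overrides) -> SyntheticConfig:
    """Four years, five entities, censoring off, noise off."""
    kwargs = dict(
        start="2016-01",
        end="2019-12",
        entities=_entities(),
        tail_total=500_000,
        tail_unit_cost=10.0,
        top_n=5,
        eligibility=EligibilityConfig(baseline=1_500_000, monthly_drift=0.0),
        cpi=CpiConfig(baseline=100.0, monthly_inflation=0.002),
        noise_cv=0.0,
        seed=11,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


@pytest.fixture(scope="session")
def clean_bundle(tmp_path_factory):
    """Noise-free, untruncated, no disruption: the exact oracle bundle."""
    out = tmp_path_factory.mktemp("clean_bundle")
    truth = generate(base_config(), out)
    return out, truth


@pytest.fixture(scope="session")
def clean_dataset(clean_bundle):
    out, truth = clean_bundle
    return Dataset.load(out), truth


@pytest.fixture(scope="session")
def noisy_bundle(tmp_path_factory):
    """noise_cv=0.05, top-3 censoring, May/June-style disruption."""
    out = tmp_path_factory.mktemp("noisy_bundle")
    config = base_config(
        noise_cv=0.05,
        top_n=3,
        disruption=DisruptionConfig(month_a="2018-05", month_b="2018-06",
                                    carryover_fraction=0.8),
        seed=11,
    )
    truth = generate(config, out)
    return out, truth


@pytest.fixture(scope="session")
def noisy_dataset(noisy_bundle):
    out, truth = noisy_bundle
    return Dataset.load(out), truth
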