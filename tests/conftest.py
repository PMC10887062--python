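import numpy as np
import pytest

from isdkit.synthetic import (
    BaselineHazard,
    SyntheticConfig,
    constant_effect,
    default_config,
    generate_cohort,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def ph_config(n: int, seed: int, effects: dict[str, float] | None = None) -> SyntheticConfig:
    """Proportional-hazards configuration: constant effects only.

    The baseline rates are doubled relative to the default config because
    the constant-effect sets used in tests have a lower average hazard
    multiplier than the full default effect set; this keeps the censoring
    fraction in the 30-50% band the recovery experiments assume.
    """
    if effects is None:
        effects = {"treatment=Yes": -0.7, "stage=IV": 0.9, "lauren=Diffuse": 0.5}
    return default_config(
        n=n, seed=seed,
        effects={k: constant_effect(v) for k, v in effects.items()},
        baseline=BaselineHazard((0.0, 12.0, 36.0, 72.0), (0.036, 0.044, 0.024, 0.012)),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-condition cohort shared across read-only tests."""
    cohort, truth = generate_cohort(default_config(n=250, seed=11))
    return cohort, truth
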