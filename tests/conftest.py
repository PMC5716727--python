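import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study_cohort():
    """A study-scale synthetic matched cohort (818 cases / 935 controls)."""
    from gxepi import SimulationConfig, simulate_cohort

    sample, _ = simulate_cohort(SimulationConfig(seed=3))
    return sample


@pytest.fixture(scope="session")
def additive_null_replicates():
    """200 matched case-control replicates simulated with no additive
    interaction (joint OR = genotype OR + adiposity OR - 1), population
    2x10^5 per replicate."""
    from gxepi.validation import additive_null_config, replicate_interaction

    return replicate_interaction(additive_null_config(200_000), 200, seed=0)


def expand_2x2(a, b, c, d):
    """Subject-level frame for a 2x2 table (a=exp cases, b=exp controls,
    c=unexp cases, d=unexp controls)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "case_status": [1] * a + [0] * b + [1] * c + [0] * d,
            "exposed": [1] * (a + b) + [0] * (c + d),
        }
    )
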