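import numpy as np
import pytest

from thermoniche.briere import CanonicalBriereParams, NaturalBriereParams
from thermoniche.simulate import control_curve, generate_condition


@pytest.fixture(scope="session")
def control_params() -> CanonicalBriereParams:
    """Unstressed truth curve: optimum 37.7 degC, niche ~15 degC, peak 0.5."""
    return control_curve()


@pytest.fixture(scope="session")
def control_data(control_params):
    """One study-scale synthetic dataset (7 temperatures x 4 replicates)."""
    df = generate_condition(control_params, seed=42)
    return df["temperature_c"].to_numpy(), df["od600_24h"].to_numpy()


def random_natural_params(rng: np.random.Generator) -> NaturalBriereParams:
    t_min = rng.uniform(-5.0, 20.0)
    t_max = t_min + rng.uniform(15.0, 40.0)
    return NaturalBriereParams(
        c=10.0 ** rng.uniform(-5, -1),
        t_min=t_min,
        t_max=t_max,
        a=rng.uniform(0.2, 5.0),
        b=rng.uniform(0.2, 5.0),
    )
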