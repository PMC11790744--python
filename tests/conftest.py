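import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mixdoc import (
    ClassLabel,
    MixingProportions,
    ModelSpec,
    PathParameters,
    ScenarioConfig,
    Variant,
    simulate,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


#: spec defaults of the generating model, shared by many tests
DEFAULT_PATHS = PathParameters(
    a_x=np.sqrt(0.5), c_x=np.sqrt(0.2), e_x=np.sqrt(0.3),
    a_y=np.sqrt(0.2), c_y=np.sqrt(0.3), e_y=np.sqrt(0.5),
    b_yx=0.5, b_xy=0.5,
)


def concordant_xy_config(**kw) -> ScenarioConfig:
    """Homogeneous X->Y scenario: all pairs in the concordant X->Y class."""
    props = MixingProportions(
        labels=ClassLabel.causal_classes(), mz=(1, 0, 0, 0), dz=(1, 0, 0, 0)
    )
    kw.setdefault("delta_x", 0.0)
    kw.setdefault("delta_y", 0.0)
    return ScenarioConfig(proportions=props, **kw)


@pytest.fixture(scope="session")
def tiny_dataset():
    """60 MZ + 60 DZ pairs under the default heterogeneous scenario."""
    return simulate(ScenarioConfig(n_mz=60, n_dz=60, seed=42))


@pytest.fixture(scope="session")
def separated_dataset():
    """Well-separated 4-class data (delta 1.5/1.5), 400 pairs."""
    return simulate(ScenarioConfig(n_mz=200, n_dz=200,
                                   delta_x=1.5, delta_y=1.5, seed=7))


@pytest.fixture(scope="session")
def separated_mix4_fit(separated_dataset):
    from mixdoc import fit

    return fit(separated_dataset, ModelSpec(variant=Variant.MIX4),
               n_starts=1, seed=3)
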