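import pytest

import dcvax
from dcvax import datasets as dsets


@pytest.fixture(scope="session")
def ref_params():
    return dcvax.reference_parameters()


@pytest.fixture(scope="session")
def constants():
    return dcvax.DesignConstants()


@pytest.fixture(scope="session")
def scenarios():
    return dcvax.builtin_scenarios()


@pytest.fixture(scope="session")
def noiseless_datasets(ref_params):
    cfg = dsets.GeneratorConfig(params=ref_params, lognormal_sigma=0.0,
                                gaussian_sd=0.0, seed=0)
    return {kind: dsets.generate_dataset(kind, cfg) for kind in dsets.KINDS}


@pytest.fixture(scope="session")
def ref_trajectory(ref_params, constants, scenarios):
    """Reference normal-DC trajectory over 300 h on a dense grid."""
    return dcvax.simulate(scenarios["normal_dc"], ref_params, constants,
                          t_end=300.0)


@pytest.fixture(scope="session")
def arm_trajectories(ref_params, constants, scenarios):
    out = {}
    for arm in ("normal_dc", "caikk_dc"):
        out[arm] = dcvax.simulate(scenarios[arm], ref_params, constants,
                                  t_end=300.0)
    return out
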