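import numpy as np
import pandas as pd
import pytest

from msapop import (
    FragmentProfilePair,
    SyntheticConfig,
    encode_binary,
    generate_study,
    make_toy_fixture,
    partition_loci,
    score_methylation_states,
)


@pytest.fixture(scope="session")
def toy_study():
    return make_toy_fixture()


@pytest.fixture(scope="session")
def default_study():
    """One default-size synthetic study shared across tests."""
    return generate_study(SyntheticConfig(seed=2023))


@pytest.fixture(scope="session")
def default_matrices(default_study):
    """(epi, gen, populations) binary matrices from the default study."""
    states = score_methylation_states(default_study.pair)
    partition = partition_loci(states)
    epi, gen = encode_binary(states, partition)
    return epi, gen, default_study.samples["population"]


def random_pair(rng, n_ind=6, n_frag=5, p_missing=0.0):
    """Small random fragment pair for property tests."""
    def mat():
        m = (rng.uniform(size=(n_ind, n_frag)) < 0.5).astype(float)
        if p_missing:
            m[rng.uniform(size=m.shape) < p_missing] = np.nan
        return pd.DataFrame(
            m,
            index=[f"ind{i}" for i in range(n_ind)],
            columns=[f"frag{j}" for j in range(n_frag)],
        )

    return FragmentProfilePair(mat(), mat())
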