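import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from crossmeth import synth

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def mixed_cohort():
    """47-pair cohort with a little of every planted signal class."""
    cfg = synth.SimConfig(
        n_probes=4000,
        n_individuals=47,
        seed=11,
        class_fractions={
            "snp_bimodal": 0.02,
            "snp_trimodal": 0.02,
            "negative_correlated": 0.005,
            "outlier_driven": 0.02,
            "imprinted": 0.01,
        },
    )
    return synth.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def toy_beta(values, samples=None):
    """Probe x sample DataFrame from a nested list/array."""
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return pd.DataFrame(arr, index=[f"p{i}" for i in range(arr.shape[0])],
                        columns=samples)
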