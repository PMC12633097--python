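import numpy as np
import pandas as pd
import pytest

import vascnet as v


@pytest.fixture(scope="session")
def default_dataset():
    """One seeded dataset at the generator's default study conditions."""
    return v.generate_dataset(v.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def corrected(default_dataset):
    """Default dataset taken through scaling, filtering, TAMPOR and
    bootstrap regression."""
    X, manifest, truth = default_dataset
    Xl = v.log2_transform(v.filter_missing(v.sum_scale(X)))
    Xc, state = v.tampor_correct(Xl, manifest)
    Xr = v.bootstrap_regress(Xc, manifest,
                             v.RegressionSpec(n_bootstrap=200, seed=3))
    return Xr, manifest, truth, state


@pytest.fixture(scope="session")
def network_model(corrected):
    Xr, manifest, truth, _ = corrected
    return v.build_network(Xr)


def make_matrix(values, scale_tag="log2", prefix="P"):
    """Small AbundanceMatrix helper for hand-built examples."""
    arr = np.asarray(values, dtype=float)
    df = pd.DataFrame(arr,
                      index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                      columns=[f"S{j}" for j in range(arr.shape[1])])
    return v.AbundanceMatrix(values=df, scale_tag=scale_tag)
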