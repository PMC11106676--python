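import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ifptml.operators import FeatureDef, FeatureSpec
from ifptml.synthetic import SignalSpec, SynthConfig, generate_study

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Compact study: enough rows for group structure, fast to pair."""
    return SynthConfig(
        n_ndd_assays=300, n_np_assays=80,
        n_unique_compounds=150, n_unique_nps=12,
        cardinalities={"c_d0": 8, "c_d1": 5, "c_n0": 4, "c_n1": 10},
        signal_spec=SignalSpec(
            linear_weights={"ndd:logp": 1.0, "ndd:psa": -1.0}),
        seed=11)


@pytest.fixture(scope="session")
def small_study(small_config):
    """(ndd_df, np_df, desirability, truth) with a planted linear signal."""
    return generate_study(small_config)


@pytest.fixture(scope="session")
def small_feature_spec():
    """Feature set matched to the planted signal's conditioning (c_d0/c_n0)."""
    return FeatureSpec((
        FeatureDef("reference", "f_ref"),
        FeatureDef("ma", "dD_logp", "logp", ("c_d0",)),
        FeatureDef("ma", "dD_psa", "psa", ("c_d0",)),
        FeatureDef("ma", "dD_lnp", "d_n02", ("c_n0",)),
    ))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def random_paired_frame(rng):
    """A paired-style frame with labels and descriptors for oracle checks."""
    n = 1000
    return pd.DataFrame({
        "ndd_assay_id": [f"A{i:04d}" for i in range(n)],
        "np_assay_id": [f"B{i:04d}" for i in range(n)],
        "c_d0": rng.choice(["IC50 (nM)", "EC50 (nM)", "Ki (nM)"], n),
        "c_d1": rng.choice(["T1", "T2"], n),
        "c_n0": rng.choice(["CC50 (nM)", "LC50 (nM)"], n),
        "c_n1": rng.choice(["L1", "L2", "L3"], n),
        "logp": rng.normal(2.0, 1.0, n),
        "psa": rng.normal(80.0, 20.0, n),
        "d_n02": rng.normal(50.0, 10.0, n),
        "d_n10": rng.normal(60.0, 20.0, n),
        "d_n11": rng.normal(70.0, 25.0, n),
        "f_obs": rng.integers(0, 2, n),
    })
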