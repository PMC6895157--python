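import numpy as np
import pandas as pd
import pytest

from herdvoice import SynthConfig, generate_feature_table


@pytest.fixture(scope="session")
def study_table() -> pd.DataFrame:
    """Study-scale synthetic feature table: 13 individuals, 170 + 163 calls."""
    return generate_feature_table(SynthConfig(seed=0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def null_table(seed: int, n_groups: int = 13, per_group: int = 24,
               n_vars: int = 5) -> pd.DataFrame:
    """Pure-noise table: no between-individual signal at all."""
    r = np.random.default_rng(seed)
    ids = np.repeat([f"h{i:02d}" for i in range(n_groups)], per_group)
    df = pd.DataFrame(r.standard_normal((len(ids), n_vars)),
                      columns=[f"v{j}" for j in range(n_vars)])
    df["individual_id"] = ids
    return df
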