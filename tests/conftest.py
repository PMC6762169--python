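import numpy as np
import pandas as pd
import pytest

from lvsig.io import ExpressionMatrix
from lvsig.simulate import SimulationConfig, generate_dataset


def make_matrix(values, mask=None, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    vdf = pd.DataFrame(values, index=genes, columns=samples)
    mdf = (pd.DataFrame(np.asarray(mask, dtype=bool), index=genes, columns=samples)
           if mask is not None else None)
    return ExpressionMatrix(vdf, mdf)


@pytest.fixture(scope="session")
def paper_size_dataset():
    """One seeded draw at the study conditions: 26/62 samples, 55 of 1000
    genes planted at effect 1.5, noise SD 0.5, 5% dropout."""
    return generate_dataset(SimulationConfig(seed=11))


@pytest.fixture()
def labels_3v3():
    return pd.Series([True, True, True, False, False, False],
                     index=[f"s{j}" for j in range(6)])
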