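import numpy as np
import pandas as pd
import pytest

from momicnet.preprocess import AnnotationTable, OmicsLayer


def make_layer(values, name="layer", samples=None, features=None, **kwargs):
    values = np.asarray(values, dtype=float)
    samples = samples or [f"S{i+1}" for i in range(values.shape[0])]
    features = features or [f"f{j+1}" for j in range(values.shape[1])]
    return OmicsLayer(
        name=name,
        data=pd.DataFrame(values, index=samples, columns=features),
        **kwargs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_layer(rng):
    return make_layer(rng.normal(size=(12, 6)))


@pytest.fixture
def annotation():
    idx = [f"S{i+1}" for i in range(12)]
    return AnnotationTable(
        pd.DataFrame(
            {
                "depth": np.linspace(0.0, 11.0, 12),
                "site": ["north"] * 6 + ["south"] * 6,
            },
            index=idx,
        )
    )
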