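import numpy as np
import pandas as pd
import pytest

from multiplexbrain import LayerMatrix, MultiplexNetwork


@pytest.fixture
def toy_atlas_file(tmp_path):
    path = tmp_path / "atlas4.tsv"
    path.write_text(
        "roi_id\tname\themisphere\n"
        "0\tlh_alpha\tleft\n"
        "1\tlh_beta\tleft\n"
        "2\trh_alpha\tright\n"
        "3\trh_beta\tright\n"
    )
    return path


@pytest.fixture
def small_manifest():
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(6)],
            "group": ["patient"] * 3 + ["control"] * 3,
            "age": [25.0, 31.0, 28.0, 40.0, 22.0, 35.0],
            "sex": ["female", "male", "female", "female", "male", "female"],
        }
    )


def random_multiplex(rng, n, density=0.7, n_layers=2):
    """Random non-negative weighted multiplex with weights in [0, 1]."""
    layers = []
    for _ in range(n_layers):
        upper = np.triu(rng.random((n, n)) * (rng.random((n, n)) < density), k=1)
        if upper.sum() == 0:
            upper[0, 1] = 0.5
        layers.append(LayerMatrix(upper + upper.T))
    return MultiplexNetwork(layers)
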