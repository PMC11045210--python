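import numpy as np
import pandas as pd
import pytest

from dosig.io import ExpressionDataset


def make_dataset(values, genes, samples, labels, scale="linear"):
    frame = pd.DataFrame(np.asarray(values, dtype=float), index=genes, columns=samples)
    return ExpressionDataset(frame, pd.Series(labels, index=samples), scale)


@pytest.fixture
def tiny_dataset():
    """3 genes x 4 samples (2 tumor, 2 normal), linear scale."""
    return make_dataset(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0], [2.5, 2.5, 2.5, 2.5]],
        ["G1", "G2", "G3"],
        ["S1", "S2", "S3", "S4"],
        ["tumor", "tumor", "normal", "normal"],
    )


def two_class_gaussian(rng, n_per_class=20, n_features=4, shift=0.0):
    """Random two-class Gaussian matrix (samples x features) + labels."""
    X = rng.normal(size=(2 * n_per_class, n_features))
    X[:n_per_class] += shift
    y = np.array(["tumor"] * n_per_class + ["normal"] * n_per_class)
    cols = [f"F{i}" for i in range(n_features)]
    return pd.DataFrame(X, columns=cols), y
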