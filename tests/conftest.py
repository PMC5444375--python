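import numpy as np
import pytest

from varpath.matrix import ExpressionMatrix


@pytest.fixture
def small_matrix():
    """6 genes x 6 samples, two labeled groups of 3."""
    rng = np.random.default_rng(11)
    genes = [f"G{i}" for i in range(6)]
    samples = [f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)]
    values = rng.normal(10, 2, size=(6, 6))
    labels = {s: ("g1" if s.startswith("A") else "g2") for s in samples}
    return ExpressionMatrix(genes, samples, values, group_labels=labels)


def make_matrix(values, group_labels=None):
    values = np.asarray(values, dtype=float)
    genes = [f"G{i}" for i in range(values.shape[0])]
    samples = [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values, group_labels=group_labels)
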