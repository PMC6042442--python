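import numpy as np
import pandas as pd
import pytest

from coexkit.deg import CountMatrix, RpkmMatrix


def make_count_matrix(counts, lengths=None, n_control=None):
    """Build a CountMatrix from a genes-by-samples array.

    Samples are split half control / half treated unless ``n_control``
    says otherwise; lengths default to 1000 bp.
    """
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    if n_control is None:
        n_control = n_samples // 2
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"c{i}" for i in range(n_control)] + [
        f"t{i}" for i in range(n_samples - n_control)
    ]
    design = pd.Series(
        ["control"] * n_control + ["treated"] * (n_samples - n_control),
        index=samples,
    )
    if lengths is None:
        lengths = [1000] * n_genes
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        lengths=pd.Series(lengths, index=genes),
        design=design,
    )


def make_rpkm(values, n_control=None):
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    if n_control is None:
        n_control = n_samples // 2
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"c{i}" for i in range(n_control)] + [
        f"t{i}" for i in range(n_samples - n_control)
    ]
    rpkm = RpkmMatrix(
        values=pd.DataFrame(values, index=genes, columns=samples),
        total_reads=pd.Series(1e6, index=samples),
    )
    design = pd.Series(
        ["control"] * n_control + ["treated"] * (n_samples - n_control),
        index=samples,
    )
    return rpkm, design


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
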