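import numpy as np
import pandas as pd
import pytest

from bloodmark.io import SCALE_LOG2, SCALE_RAW, ExpressionMatrix


def make_matrix(values, gene_symbols=None, is_control=None,
                scale=SCALE_LOG2, probe_prefix="P", sample_prefix="S"):
    """Build an ExpressionMatrix from a plain 2-D array."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probes = [f"{probe_prefix}{i + 1:04d}" for i in range(n_probes)]
    samples = [f"{sample_prefix}{j + 1:03d}" for j in range(n_samples)]
    if gene_symbols is None:
        gene_symbols = [f"G{i + 1:04d}" for i in range(n_probes)]
    if is_control is None:
        is_control = [False] * n_probes
    df = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"),
                      columns=pd.Index(samples, name="sample_id"))
    return ExpressionMatrix(df, pd.Series(gene_symbols, index=df.index),
                            pd.Series(is_control, index=df.index), scale)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_log2_matrix(rng):
    return make_matrix(rng.normal(8.0, 1.0, size=(30, 12)))


@pytest.fixture
def raw_matrix_with_controls(rng):
    """Raw-scale 40-probe matrix whose first 5 probes are controls near 100."""
    signal = 100.0 + np.exp2(rng.normal(8.0, 1.0, size=(35, 10)))
    controls = rng.normal(100.0, 5.0, size=(5, 10))
    values = np.vstack([controls, signal])
    flags = [True] * 5 + [False] * 35
    symbols = [""] * 5 + [f"G{i:04d}" for i in range(35)]
    return make_matrix(values, gene_symbols=symbols, is_control=flags,
                       scale=SCALE_RAW)
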