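import numpy as np
import pandas as pd
import pytest

from monomap.containers import ExpressionDataset, SampleDesign


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_dataset(values, samples=None, genes=None, scale="log2", **kw):
    """Build an ExpressionDataset from a plain array."""
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i:03d}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionDataset(pd.DataFrame(arr, index=genes, columns=samples), scale=scale, **kw)


def make_design(condition, donor=None, batch=None):
    """Build a SampleDesign from parallel label lists keyed s0, s1, ..."""
    samples = [f"s{i}" for i in range(len(condition))]
    tab = pd.DataFrame({"condition": condition}, index=pd.Index(samples, name="sample"))
    if donor is not None:
        tab["donor"] = donor
    if batch is not None:
        tab["batch"] = batch
    return SampleDesign(tab)


@pytest.fixture
def two_group_ds(rng):
    """12-sample, 100-gene random log2 dataset over two conditions."""
    ds = make_dataset(rng.normal(8, 1, size=(100, 12)))
    design = make_design(["A"] * 6 + ["B"] * 6, donor=[f"d{i % 3}" for i in range(12)])
    return ds, design
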