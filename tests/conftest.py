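import numpy as np
import pandas as pd
import pytest

from rhythmscan.dataset_io import ExpressionDataset


def make_dataset(values, times=None, condition="white", genotype="WT",
                 agi=None, compartment=None):
    """Build a small ExpressionDataset from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    if times is None:
        times = 24.0 + 4.0 * np.arange(n_samples)
    sample_ids = [f"S{i}" for i in range(n_samples)]
    probe_ids = [f"P{i}" for i in range(n_probes)]
    design = pd.DataFrame({
        "sample_id": sample_ids,
        "condition": condition if isinstance(condition, str) else list(condition),
        "genotype": genotype if isinstance(genotype, str) else list(genotype),
        "time_h": np.asarray(times, dtype=float),
    })
    annotation = pd.DataFrame({
        "probe_id": probe_ids,
        "agi_code": agi if agi is not None else [f"AT1G{i:05d}" for i in range(n_probes)],
        "compartment": compartment if compartment is not None else ["nuclear"] * n_probes,
    })
    frame = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    frame.index.name = "probe_id"
    return ExpressionDataset(values=frame, design=design, annotation=annotation)


@pytest.fixture
def small_dataset():
    rng = np.random.default_rng(7)
    return make_dataset(rng.uniform(10, 200, size=(20, 12)))


def cosine_series(times, phase, mean, ratio, period=24.0):
    """Noiseless cosine time course with the given peak/trough ratio."""
    times = np.asarray(times, dtype=float)
    amp = mean * (ratio - 1.0) / (ratio + 1.0)
    return mean + amp * np.cos(2 * np.pi * (times - phase) / period)
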