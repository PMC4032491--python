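import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from coexmod import ExpressionDataset

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable


def make_dataset(values: np.ndarray, probe_ids=None, sample_ids=None) -> ExpressionDataset:
    """Wrap a raw matrix in an ExpressionDataset with generic metadata."""
    n_probes, n_samples = values.shape
    probe_ids = probe_ids or [f"p{i:04d}" for i in range(n_probes)]
    sample_ids = sample_ids or [f"s{j:02d}" for j in range(n_samples)]
    meta = pd.DataFrame(
        {
            "genotype": ["control"] * n_samples,
            "day": list(range(n_samples)),
            "replicate": [1] * n_samples,
            "batch": ["b1"] * n_samples,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return ExpressionDataset(
        pd.DataFrame(values, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids),
        meta,
    )


def correlated_profiles(gram: np.ndarray, n_samples: int, rng) -> np.ndarray:
    """Zero-mean profiles whose empirical correlations equal `gram` exactly."""
    k = len(gram)
    raw = rng.normal(size=(k, n_samples))
    raw -= raw.mean(axis=1, keepdims=True)
    # orthonormalize rows, then color by the Cholesky factor of the target
    q, _ = np.linalg.qr(raw.T)
    basis = q.T[:k]
    # eigen square root; clipping guards targets that are only nearly PSD
    w, V = np.linalg.eigh(gram)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    prof = L @ basis
    return prof / prof.std(axis=1, ddof=1, keepdims=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
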