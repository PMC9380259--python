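import numpy as np
import pandas as pd
import pytest

from pafskit.phospho_stats import PhosphoSiteTable


def make_table(values, conditions, batches=None, log2=True, loc_prob=None, fractions=None):
    """Small hand-built PhosphoSiteTable for unit tests."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_sites, n_samples = values.shape
    idx = pd.Index([f"PR{i:03d}:S{i + 1}" for i in range(n_sites)], name="site_id")
    cols = pd.Index([f"s{j}" for j in range(n_samples)], name="sample_id")
    sites = pd.DataFrame(
        {
            "protein": [f"PR{i:03d}" for i in range(n_sites)],
            "position": np.arange(1, n_sites + 1),
            "residue": ["S"] * n_sites,
            "localization_prob": loc_prob if loc_prob is not None else [1.0] * n_sites,
        },
        index=idx,
    )
    samples = pd.DataFrame(
        {
            "batch": batches if batches is not None else ["B1"] * n_samples,
            "condition": conditions,
        },
        index=cols,
    )
    if fractions is not None:
        samples["fraction"] = fractions
    return PhosphoSiteTable(
        values=pd.DataFrame(values, index=idx, columns=cols),
        sites=sites,
        samples=samples,
        log2=log2,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
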