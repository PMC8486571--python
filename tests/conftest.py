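import numpy as np
import pandas as pd
import pytest

from tepimage import panel as panel_mod
from tepimage.preprocess import CountMatrix


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """4 features x 3 samples with distinct totals."""
    df = pd.DataFrame(
        {
            "s1": [10, 20, 30, 40],
            "s2": [5, 10, 15, 20],
            "s3": [20, 40, 60, 80],
        },
        index=["f1", "f2", "f3", "f4"],
    )
    return CountMatrix(df)


@pytest.fixture
def tiny_annotation() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "source_id": ["f1", "f2", "f3", "f4"],
            "gene_name": ["GA", "GB", "GC", "GD"],
            "status": ["known", "known", "known", "known"],
            "level": [1, 1, 1, 1],
        }
    )


@pytest.fixture
def two_pathway_panel() -> panel_mod.PathwayPanel:
    """The hand-computable 2-pathway panel: P1=[g1,g2,g3], P2=[g2]."""
    return panel_mod.PathwayPanel(
        [
            panel_mod.PathwayEntry("P1", "P1", "cancer", ("g1", "g2", "g3")),
            panel_mod.PathwayEntry("P2", "P2", "signaling", ("g2",)),
        ]
    )


@pytest.fixture
def nb_cohort():
    """A moderate NB cohort with a known dispersion trend, for VST checks."""
    rng = np.random.default_rng(42)
    n_genes, n_samples = 800, 60
    mu = rng.lognormal(np.log(50), 1.0, n_genes)
    a0, a1 = 0.05, 2.0
    alpha = a0 + a1 / mu
    sf = rng.lognormal(0, 0.2, n_samples)
    mean = mu[:, None] * sf[None, :]
    r = 1.0 / alpha[:, None]
    counts = rng.negative_binomial(np.broadcast_to(r, mean.shape), r / (r + mean))
    df = pd.DataFrame(
        counts,
        index=[f"g{i:04d}" for i in range(n_genes)],
        columns=[f"s{j:02d}" for j in range(n_samples)],
    )
    return CountMatrix(df), (a0, a1)
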