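import numpy as np
import pandas as pd
import pytest

from quadindex.covariance import TraitPanel


def make_panel(G0, E0, n_geno, n_reps, seed, trait_names=None):
    """Replicated panel simulated from genotype effects ~ N(0, G0) and
    replicate errors ~ N(0, E0)."""
    rng = np.random.default_rng(seed)
    t = np.asarray(G0).shape[0]
    names = trait_names or [f"T{i + 1}" for i in range(t)]
    g = rng.multivariate_normal(np.zeros(t), G0, size=n_geno)
    frames = []
    for rep in range(1, n_reps + 1):
        e = rng.multivariate_normal(np.zeros(t), E0, size=n_geno)
        df = pd.DataFrame(g + e, columns=names)
        df.insert(0, "rep", rep)
        df.insert(0, "genotype", np.arange(n_geno))
        frames.append(df)
    return TraitPanel(pd.concat(frames, ignore_index=True)), g


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_markers(rng):
    """30 genotypes x 50 polymorphic markers of {0,1,2} codes."""
    from quadindex.gebv import standardize_markers

    codes = rng.integers(0, 3, size=(30, 50)).astype(float)
    return standardize_markers(codes)


@pytest.fixture
def two_trait_covs():
    from quadindex.covariance import CovarianceSet

    return CovarianceSet(
        P=np.array([[2.0, 0.0], [0.0, 2.0]]),
        G=np.array([[1.0, 0.5], [0.5, 1.0]]),
        Gamma=np.array([[0.8, 0.3], [0.3, 0.8]]),
        h2=np.array([0.5, 0.5]),
        n_reps=4.0,
        traits=["T1", "T2"],
    )
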