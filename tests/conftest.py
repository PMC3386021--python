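import numpy as np
import pytest

import pangenesis as pg


@pytest.fixture(scope="session")
def moran_spectrum():
    """One stationary sampled spectrum at theta = 0.3 (shared across tests).

    N = 150, M = 50, sigma = 0.1 so theta = N*sigma/(M*rho) = 0.3; G = 15
    genomes sampled at 150 well-spaced epochs.
    """
    cfg = pg.SimConfig(N0=150, M=50, rho=1.0, sigma=0.1, seed=11)
    return pg.stationary_spectrum_mc(cfg, G=15, n_epochs=150, spacing=1.0)


@pytest.fixture()
def tiny_matrix():
    """3 genes x 2 genomes: one shared-by-both gene row, two singletons."""
    return pg.PresenceAbsenceMatrix(
        np.array([[1, 1], [1, 0], [0, 1]]),
        gene_names=["gA", "gB", "gC"],
        genome_names=["s1", "s2"],
    )
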