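import warnings

import numpy as np
import pytest

from atrace import qc, simulate


@pytest.fixture(scope="session")
def default_sim():
    """One full-size synthetic capture shared across tests."""
    cfg = simulate.SimConfig(seed=7)
    bundle, truth = simulate.simulate_counts(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def small_sim():
    cfg = simulate.SimConfig(
        seed=11,
        n_cells_per_type={"cDC2": 120, "LEC": 120, "Tcell": 40, "Bcell": 40},
        n_genes=400,
    )
    bundle, truth = simulate.simulate_counts(cfg)
    return cfg, bundle, truth


@pytest.fixture(scope="session")
def processed(default_sim):
    """QC'd, normalized, PCA'd default capture."""
    cfg, bundle, truth = default_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filt, _ = qc.qc_filter(bundle)
        norm = qc.lognormalize(filt)
        hvg = qc.select_hvg(filt, 2000)
        n_pcs = min(40, len(hvg), filt.n_cells - 1)
        norm = qc.run_pca(norm, hvg, n_pcs=n_pcs, seed=cfg.seed)
    return cfg, filt, truth, norm


def rng(seed=0):
    return np.random.default_rng(seed)
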