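import numpy as np
import pytest

from lcimpute.panel_store import GeneticMap, annotate_cm, build_sparse_panel
from lcimpute.simdata import SimConfig, simulate_panel


def random_dense_panel(rng, n_hap, n_site, rare_fraction=0.0):
    """Dense 0/1 matrix (n_site, n_hap) with a controllable share of
    low-count columns."""
    dense = np.zeros((n_site, n_hap), dtype=np.uint8)
    for s in range(n_site):
        if rng.random() < rare_fraction:
            c = int(rng.integers(0, 3))  # 0..2 carriers
        else:
            c = int(rng.integers(1, n_hap))
        carriers = rng.choice(n_hap, size=c, replace=False)
        dense[s, carriers] = 1
    return dense


def panel_from_dense(dense, maf_threshold=0.1, region_bp=1_000_000):
    panel = build_sparse_panel(dense, maf_threshold)
    n_site = dense.shape[0]
    gmap = GeneticMap.uniform(region_bp)
    for i, site in enumerate(panel.sites):
        site.pos_bp = int((i + 1) * region_bp / (n_site + 1))
    annotate_cm(panel, gmap)
    return panel, gmap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """Shared small synthetic dataset: 60 haplotypes x 300 sites, 0.3 cM."""
    cfg = SimConfig(seed=7, n_hap=60, n_site=300, region_bp=300_000, coverage=1.0)
    panel, gmap = simulate_panel(cfg)
    return cfg, panel, gmap
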