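import numpy as np
import pandas as pd
import pytest

from gliastat.simulate import (
    ClusterSpec,
    SceneConfig,
    SimCountsConfig,
    SpikedSet,
    render_coculture_scene,
    simulate_sn_counts,
)


@pytest.fixture(scope="session")
def small_null_sim():
    """Null simulation (no spiked effects), small but fittable."""
    return simulate_sn_counts(SimCountsConfig(n_genes=400, n_cells_per_group=80, seed=5))


@pytest.fixture(scope="session")
def spiked_sim():
    """Simulation with one up-spiked 20-gene set (log2FC 1)."""
    cfg = SimCountsConfig(
        n_genes=500,
        n_cells_per_group=100,
        seed=1,
        spiked_sets=(SpikedSet("up", 20, 1.0, 0.2),),
    )
    return simulate_sn_counts(cfg)


@pytest.fixture(scope="session")
def spiked_de(spiked_sim):
    from gliastat.de import NegativeBinomialDE

    return NegativeBinomialDE.from_simulation(spiked_sim).fit()


@pytest.fixture(scope="session")
def cluster_scene():
    """Scene with one 6-cell, 5000-um^2 damaged cluster and 5 singles."""
    cfg = SceneConfig(
        seed=2,
        clusters=(ClusterSpec(6, 5000.0, damaged=True),),
        damage_fraction_in_clusters=0.6,
        n_single_cells=5,
    )
    return render_coculture_scene(cfg)


@pytest.fixture
def tiny_tscores():
    return pd.Series([3.0, 1.0, 0.0, -1.0, -2.0], index=list("abcde"), name="t_score")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
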