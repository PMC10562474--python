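import warnings

import numpy as np
import pandas as pd
import pytest

from daesc.data import GeneASECounts
from daesc.simulate import ParamDraw, SimScenario, simulate_one_eqtl


@pytest.fixture(autouse=True)
def _silence_small_n_warning():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def toy_single_donor():
    """Five printed rows for one donor (overdispersed, interior MLE)."""
    return GeneASECounts(
        gene_id="toy",
        donor_id=np.repeat("d1", 5),
        y=np.array([1, 9, 2, 14, 0]),
        n=np.array([10, 12, 6, 15, 4]),
        x=np.array([0.1, 0.3, 0.5, 0.7, 0.9]),
    )


@pytest.fixture
def small_gene():
    """A modest simulated gene with haplotype switching (N=20)."""
    sc = SimScenario(n_donors=20, cells_per_donor=(12, 2.0),
                     depth=(15, 0.8), r2=0.0, maf_eqtl=0.5, maf_tsnp=0.5,
                     seed=11)
    rng = np.random.default_rng(11)
    return simulate_one_eqtl(sc, ParamDraw(1.0, -1.5, 0.3, 0.1), rng,
                             gene_id="small")


@pytest.fixture
def counts_frame_3genes():
    """Long-format frame with three small genes (shared donors)."""
    frames = []
    for k in range(3):
        sc = SimScenario(n_donors=8, cells_per_donor=(8, 2.0),
                         depth=(12, 0.8), r2=0.9, seed=40 + k)
        rng = np.random.default_rng(40 + k)
        g = simulate_one_eqtl(sc, ParamDraw(0.6, 1.2 if k else 0.0,
                                            0.3, 0.1), rng,
                              gene_id=f"g{k}")
        frames.append(g.data.to_dataframe())
    return pd.concat(frames, ignore_index=True)
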