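import numpy as np
import pandas as pd
import pytest

from encoop.activity import ActivityMatrix, parse_design
from encoop.simulate import SimConfig, simulate

SMALL = SimConfig(seed=7, n_genes=20, n_enhancers=60, n_decoys=10,
                  chrom_length=4_000_000)


@pytest.fixture(scope="session")
def small_sim():
    """A 20-gene synthetic study shared across tests (read-only)."""
    return simulate(SMALL)


@pytest.fixture(scope="session")
def noiseless_sim():
    return simulate(SimConfig(seed=9, n_genes=20, n_enhancers=60, n_decoys=0,
                              chrom_length=4_000_000, noise_cv=0.0))


def make_activity(trajectories: dict, n_replicates: int = 2,
                  time_points=(0, 12, 24, 30, 36, 72, 96),
                  lengths=None) -> ActivityMatrix:
    """ActivityMatrix from noiseless per-unit trajectories (helper)."""
    samples = [f"TTseq_{t:g}_{r + 1}" for t in time_points
               for r in range(n_replicates)]
    rows = {u: np.repeat(np.asarray(v, dtype=float), n_replicates)
            for u, v in trajectories.items()}
    values = pd.DataFrame(rows, index=samples).T
    units = list(trajectories)
    lengths = pd.Series(1000.0, index=units) if lengths is None else lengths
    return ActivityMatrix(values, parse_design(samples), lengths,
                          pd.Series(1.0, index=pd.Index(samples)))
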