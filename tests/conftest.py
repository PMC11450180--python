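import numpy as np
import pandas as pd
import pytest

from landgea.datatypes import GenotypeMatrix
from landgea.simulate import SimConfig, simulate_landscape


def build_gm(G, pops=None, chrom="chr1", pos=None) -> GenotypeMatrix:
    """Assemble a GenotypeMatrix from a raw dosage array."""
    G = np.asarray(G, dtype=np.int8)
    n, m = G.shape
    pos = np.arange(1, m + 1) if pos is None else np.asarray(pos)
    chroms = [chrom] * m if isinstance(chrom, str) else list(chrom)
    variants = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": "A", "alt": "T",
                             "id": [f"{c}:{p}" for c, p in zip(chroms, pos)]})
    pops = ["pop1"] * n if pops is None else list(pops)
    individuals = pd.DataFrame({"ind_id": [f"i{k}" for k in range(n)],
                                "pop_id": pops})
    return GenotypeMatrix(G, variants, individuals)


@pytest.fixture(scope="session")
def make_gm():
    return build_gm


@pytest.fixture(scope="session")
def default_sim():
    """One default-condition landscape shared across tests."""
    return simulate_landscape(SimConfig(seed=7))


@pytest.fixture(scope="session")
def small_sim():
    """A light landscape for quick structural checks."""
    return simulate_landscape(SimConfig(seed=3, n_pops=20, inds_per_pop=6,
                                        n_neutral=400, n_adaptive=10,
                                        n_deleterious=40, n_synonymous=40))


def env_current(ds, var):
    """Population-level current values of one env variable, pop order of pop_freqs."""
    e = ds.env[(ds.env["scenario"] == "current") & (ds.env["var"] == var)]
    return e.set_index("pop_id")["value"]
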