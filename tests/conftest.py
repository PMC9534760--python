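import numpy as np
import pandas as pd
import pytest

from thermocline import GenotypeDataset, SimulationConfig

# A hand-sized genotype panel: 3 populations x 4 individuals, 3 loci with
# multiple alleles and missing calls — the workbench for parser and
# estimator checks.
GENEPOP_FIXTURE = """three ponds, three loci
locA
locB
locC
POP
up-01 , 001001 002003 001002
up-02 , 001002 002002 001001
up-03 , 001001 003003 002002
up-04 , 002002 002003 000000
upstream , 001001 002002 001001
POP
mid-01 , 001002 001003 001001
mid-02 , 002002 001001 001002
mid-03 , 001002 000000 002002
midstream , 002003 001003 001001
POP
down-01 , 003003 001002 002002
down-02 , 002003 002002 001002
downstream , 003003 001001 002002
"""


@pytest.fixture()
def genepop_file(tmp_path):
    path = tmp_path / "fixture.gen"
    path.write_text(GENEPOP_FIXTURE)
    return path


@pytest.fixture()
def fixture_dataset(genepop_file):
    from thermocline import read_genepop

    return read_genepop(genepop_file)


def make_trait_table(
    seed: int,
    n_pops: int = 20,
    n_per_pop: int = 50,
    sigma_b2: float = 1.0,
    sigma_w2: float = 1.0,
    mean: float = 0.0,
) -> pd.DataFrame:
    """Balanced one-way random-effects draws with known components."""
    rng = np.random.default_rng(seed)
    pops = np.repeat([f"p{i:02d}" for i in range(n_pops)], n_per_pop)
    y = (
        mean
        + np.repeat(rng.normal(0, np.sqrt(sigma_b2), n_pops), n_per_pop)
        + rng.normal(0, np.sqrt(sigma_w2), n_pops * n_per_pop)
    )
    return pd.DataFrame({"population": pops, "trait": "T", "value_c": y})


@pytest.fixture()
def small_config():
    return SimulationConfig(
        n_populations=5, n_per_pop=12, n_loci=4, alleles_per_locus=4, seed=11
    )


def fixed_two_pop_dataset(n: int = 10) -> GenotypeDataset:
    """Two populations fixed for alternative alleles at one locus."""
    calls = np.zeros((2 * n, 1, 2), dtype=np.int64)
    calls[:n] = 1
    calls[n:] = 2
    return GenotypeDataset(
        populations=["A", "B"],
        loci=["L1"],
        individual_ids=[f"i{k}" for k in range(2 * n)],
        pop_index=np.repeat([0, 1], n),
        calls=calls,
    )
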