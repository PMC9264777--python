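import numpy as np
import pandas as pd
import pytest

from ssgblup.mme import TraitDataset
from ssgblup.pedigree import UNKNOWN, Pedigree
from ssgblup.simulate import SimulationConfig, simulate_population


@pytest.fixture
def trio() -> Pedigree:
    return Pedigree.from_records([("S", "0", "0"), ("D", "0", "0"), ("O", "S", "D")])


def make_random_pedigree(rng: np.random.Generator, n: int,
                         founder_fraction: float = 0.2) -> Pedigree:
    """Sorted random pedigree: founders first, later animals draw parents
    from strictly earlier animals (occasionally unknown)."""
    n_found = max(2, int(founder_fraction * n))
    sire = np.full(n, UNKNOWN, dtype=np.int64)
    dam = np.full(n, UNKNOWN, dtype=np.int64)
    for i in range(n_found, n):
        s = int(rng.integers(0, i))
        d = int(rng.integers(0, i))
        if rng.random() < 0.05:
            s = UNKNOWN
        if rng.random() < 0.05 or d == s:
            d = UNKNOWN
        sire[i], dam[i] = s, d
    return Pedigree([f"a{i+1}" for i in range(n)], sire, dam)


@pytest.fixture
def random_pedigree():
    return make_random_pedigree


@pytest.fixture(scope="session")
def small_population():
    """Modest population reused by read-only tests (600 animals, genotyped tail)."""
    cfg = SimulationConfig(n_founders=120, n_generations=5, offspring_per_mating=2,
                           n_snps=300, n_qtl=30, heritability=0.4,
                           qtl_effect_distribution="gamma-signed", seed=42)
    return simulate_population(cfg)


def unrelated_dataset(rng: np.random.Generator, n: int) -> tuple[Pedigree, TraitDataset]:
    ped = Pedigree([f"x{i}" for i in range(n)],
                   np.full(n, UNKNOWN, dtype=np.int64),
                   np.full(n, UNKNOWN, dtype=np.int64))
    df = pd.DataFrame({"id": ped.ids, "trait": rng.standard_normal(n)})
    return ped, TraitDataset(df)
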