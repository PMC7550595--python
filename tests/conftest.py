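import numpy as np
import pytest

from matearray.genodata import Family, Locus, PopulationSample, StudyDataset
from matearray.simulate import (
    SimulationConfig,
    generate_study_like_dataset,
    simulate_progeny_arrays,
)


@pytest.fixture
def toy_dataset() -> StudyDataset:
    """Two hand-written families at two null-free loci."""
    loci = [
        Locus("L1", "GA", (100, 120), [100, 102, 104]),
        Locus("L2", "CT", (200, 220), [200, 202]),
    ]
    fam1 = Family(
        "f1",
        [(100, 102), (200, 202)],
        [[(100, 100), (200, 200)], [(100, 104), (200, 202)]],
    )
    fam2 = Family(
        "f2",
        [(102, 102), (200, 200)],
        [[(102, 104), (200, 202)], [(100, 102), (200, 200)], [(102, 102), (200, 200)]],
    )
    pop = PopulationSample("popA", 25.0, 100.0, 800.0, [fam1, fam2])
    return StudyDataset(loci, [pop])


def single_pop_config(seed: int, **kw) -> SimulationConfig:
    """Study-scale single-population design: 30 families × 10 seeds, 8 loci."""
    defaults = dict(
        seed=seed,
        n_populations=1,
        families_per_population=30,
        offspring_per_family=(10, 10),
        n_loci=8,
        alleles_per_locus=8,
        s=0.15,
        migration_rate=0.3,
        generations=5,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)


@pytest.fixture
def small_sim():
    """Error-free simulated single population (quick fixture)."""
    cfg = single_pop_config(11, families_per_population=10,
                            offspring_per_family=(5, 5))
    ds, truth = simulate_progeny_arrays(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def study_dataset():
    return generate_study_like_dataset(7)


def draw_hwe_phenotypes(
    rng: np.random.Generator,
    n: int,
    alleles: np.ndarray,
    freqs: np.ndarray | None = None,
    null_freq: float = 0.0,
) -> list[tuple[int, int]]:
    """Random-mating phenotypes, with optional null-allele masking."""
    p = freqs if freqs is not None else np.ones(alleles.size) / alleles.size
    if null_freq > 0:
        codes = np.concatenate(([-1], alleles))
        p = np.concatenate(([null_freq], p * (1 - null_freq)))
    else:
        codes = alleles
    a = rng.choice(codes, size=n, p=p)
    b = rng.choice(codes, size=n, p=p)
    obs = []
    for x, y in zip(a, b):
        x, y = sorted((int(x), int(y)))
        if x == -1 and y == -1:
            continue
        obs.append((y, y) if x == -1 else (x, y))
    return obs
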