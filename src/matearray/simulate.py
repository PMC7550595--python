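"""Synthetic progeny-array generator.

Produces :class:`~matearray.genodata.StudyDataset` objects with the
statistical structure the downstream analyses assume, so every estimator
can be validated by parameter recovery without the original field data:

* population allele frequencies drawn from a symmetric Dirichlet and
  evolved forward by drift + migration (island or stepping-stone), giving
  tunable differentiation and isolation by distance;
* open-pollinated families under the mixed-mating model: mothers drawn
  with inbreeding coefficient F, selfing with rate ``s`` correlated
  within families (``r_s``), outcross fathers shared within a family with
  probability ``r_p`` (correlated paternity), and optional biparental
  inbreeding in which a father is a half-relative of the mother (one of
  his gametes is drawn from the maternal genotype);
* genotyping errors applied to the true genotypes: null-allele masking,
  stutter mis-scoring of one-repeat heterozygotes, and size-dependent
  large-allele dropout.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so any sub-stage is independently
reproducible.  The ``generate_study_like_dataset`` preset reproduces the
sampled design of the six-population *Toona ciliata* field study (family
counts, seeds per family, locus allele counts and population
coordinates), with mating parameters in the empirically reported ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genodata import (
    MISSING,
    NULL,
    Family,
    Genotype,
    Locus,
    PopulationSample,
    StudyDataset,
    genotype,
    observe_phenotype,
)
from .popstruct import FrequencyTable


def _as_list(x, n: int) -> list:
    if isinstance(x, (list, tuple, np.ndarray)):
        if len(x) != n:
            raise ValueError(f"expected {n} per-locus values, got {len(x)}")
        return list(x)
    return [x] * n


@dataclass
class SimulationConfig:
    """Full generative specification for one synthetic study.

    Rates are probabilities in [0, 1]; ``offspring_per_family`` is an
    inclusive range sampled uniformly per family.  ``null_freq``,
    ``stutter_rate`` and ``dropout_rate`` may be scalars (broadcast) or
    per-locus sequences.  ``seed`` is mandatory.
    """

    seed: int
    n_populations: int = 6
    families_per_population: int | Sequence[int] = 20
    offspring_per_family: tuple[int, int] = (4, 10)
    n_loci: int = 8
    alleles_per_locus: int | Sequence[int] = 10
    allele_freq_concentration: float = 1.0
    s: float | Sequence[float] = 0.1
    r_p: float | Sequence[float] = 0.0
    r_s: float | Sequence[float] = 0.0
    F: float | Sequence[float] = 0.0
    biparental_rate: float | Sequence[float] = 0.0
    null_freq: float | Sequence[float] = 0.0
    stutter_rate: float | Sequence[float] = 0.0
    dropout_rate: float | Sequence[float] = 0.0
    migration_model: str = "island"  # or "stepping_stone"
    migration_rate: float = 0.1
    effective_size: int = 100
    generations: int = 20
    coordinates: list[tuple[float, float, float]] | None = None  # lat, lon, alt
    population_names: list[str] | None = None
    locus_names: list[str] | None = None
    repeat_unit: int = 2

    def __post_init__(self) -> None:
        for name in ("s", "r_p", "r_s", "biparental_rate", "null_freq",
                     "stutter_rate", "dropout_rate", "migration_rate"):
            vals = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if np.any((vals < 0) | (vals > 1)):
                raise ValueError(f"{name} outside [0, 1]")

    # -- derived helpers -----------------------------------------------------

    def pop_names(self) -> list[str]:
        if self.population_names:
            return list(self.population_names)
        return [f"pop{i + 1}" for i in range(self.n_populations)]

    def per_pop(self, attr: str) -> list[float]:
        return _as_list(getattr(self, attr), self.n_populations)

    def per_locus(self, attr: str) -> list[float]:
        return _as_list(getattr(self, attr), self.n_loci)


def build_loci(config: SimulationConfig) -> list[Locus]:
    """Locus registry with evenly spaced allele sizes (one repeat apart)."""
    counts = _as_list(config.alleles_per_locus, config.n_loci)
    names = config.locus_names or [f"L{j + 1}" for j in range(config.n_loci)]
    nulls = config.per_locus("null_freq")
    loci = []
    for j, (name, k) in enumerate(zip(names, counts)):
        start = 100 + 60 * j
        alleles = [start + config.repeat_unit * i for i in range(int(k))]
        loci.append(
            Locus(
                name=name,
                repeat_motif="GA",
                size_range=(alleles[0], alleles[-1]),
                alleles=alleles,
                has_null=nulls[j] > 0,
            )
        )
    return loci


def simulate_population_frequencies(
    config: SimulationConfig, loci: list[Locus] | None = None
) -> FrequencyTable:
    """Ancestral Dirichlet frequencies evolved by drift + migration.

    Each generation every population's frequency vector is mixed with the
    migrant pool (island: the unweighted mean over populations;
    stepping-stone: the mean of the linear-chain neighbours) and then
    resampled multinomially with 2·``effective_size`` gene copies.
    """
    loci = loci or build_loci(config)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    n_pop = config.n_populations
    m = config.migration_rate
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    names = config.pop_names()
    for locus in loci:
        k = len(locus.alleles)
        conc = np.full(k, config.allele_freq_concentration)
        ancestral = rng.dirichlet(conc)
        p = np.tile(ancestral, (n_pop, 1))
        two_ne = 2 * config.effective_size
        for _ in range(config.generations):
            if config.migration_model == "island":
                pool = p.mean(axis=0)
                p_mig = (1 - m) * p + m * pool
            elif config.migration_model == "stepping_stone":
                p_mig = p.copy()
                for i in range(n_pop):
                    nb = [x for x in (i - 1, i + 1) if 0 <= x < n_pop]
                    p_mig[i] = (1 - m) * p[i] + m * p[nb].mean(axis=0)
            else:
                raise ValueError(config.migration_model)
            for i in range(n_pop):
                draws = rng.multinomial(two_ne, p_mig[i] / p_mig[i].sum())
                p[i] = draws / two_ne
        for i, name in enumerate(names):
            vec = {a: float(f) for a, f in zip(locus.alleles, p[i]) if f > 0}
            total = sum(vec.values())
            freqs[(name, locus.name)] = {a: f / total for a, f in vec.items()}
    table = FrequencyTable(names, [l.name for l in loci], freqs, {})
    return table


@dataclass
class SimulationTruth:
    """Hidden generative truth recorded alongside a simulated dataset."""

    offspring: pd.DataFrame  # population, family, seed, selfed, father_id
    params: pd.DataFrame     # per-population s, r_p, r_s, F, biparental_rate

    def to_tsv(self, path) -> None:
        self.offspring.to_csv(path, sep="\t", index=False)


def _genotype_sampler(alleles: np.ndarray, p: np.ndarray, f_coef: float,
                      rng: np.random.Generator):
    """Sampler for diploid genotypes with inbreeding coefficient F.

    Genotype probabilities are p_k² + F p_k(1−p_k) for homozygotes and
    2 p_j p_k (1−F) for heterozygotes; tiny negative entries produced by
    strongly negative F at common alleles are clipped and the matrix
    renormalized.
    """
    k = alleles.size
    mat = np.outer(p, p) * (1.0 - f_coef)
    mat[np.diag_indices(k)] = p**2 + f_coef * p * (1.0 - p)
    mat = np.clip(mat, 0.0, None)
    mat /= mat.sum()
    flat = mat.ravel()

    def draw() -> Genotype:
        idx = rng.choice(k * k, p=flat)
        return genotype(int(alleles[idx // k]), int(alleles[idx % k]))

    return draw


def _freq_arrays(
    freqs: FrequencyTable, pop: str, loci: list[Locus], null_by_locus: list[float]
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-locus (alleles, probs) gamete pools with the null class folded in."""
    pools = []
    for locus, nu in zip(loci, null_by_locus):
        vec = freqs.freqs[(pop, locus.name)]
        alleles = np.array(sorted(a for a in vec if a != NULL))
        p = np.array([vec[a] for a in alleles])
        p = p / p.sum()
        if nu > 0:
            alleles = np.concatenate(([NULL], alleles))
            p = np.concatenate(([nu], p * (1.0 - nu)))
        pools.append((alleles, p))
    return pools


def simulate_progeny_arrays(
    config: SimulationConfig, freqs: FrequencyTable | None = None
) -> tuple[StudyDataset, SimulationTruth]:
    """Error-free progeny arrays under the correlated mixed-mating model.

    Selfing statuses within a family are either one shared Bernoulli(s)
    draw (probability ``r_s``) or independent draws, which gives the
    selfing statuses of two sibs exactly correlation ``r_s``.  Similarly
    all outcrossed sibs of a family share one father with probability
    ``r_p``.  Null alleles (when configured) enter the gamete pools here,
    as real alleles; masking happens in :func:`apply_genotyping_errors`.
    """
    loci = build_loci(config)
    if freqs is None:
        freqs = simulate_population_frequencies(config, loci)
    seq = np.random.SeedSequence(config.seed).spawn(2)[1]
    rng = np.random.default_rng(seq)
    nulls = config.per_locus("null_freq")
    names = config.pop_names()
    coords = config.coordinates or [(0.0, 0.0, 0.0)] * config.n_populations
    fam_counts = _as_list(config.families_per_population, config.n_populations)
    pops: list[PopulationSample] = []
    truth_rows = []
    params_rows = []
    lo, hi = config.offspring_per_family
    for i, name in enumerate(names):
        s = config.per_pop("s")[i]
        r_p = config.per_pop("r_p")[i]
        r_s = config.per_pop("r_s")[i]
        f_coef = config.per_pop("F")[i]
        bip = config.per_pop("biparental_rate")[i]
        params_rows.append(
            {"population": name, "s": s, "r_p": r_p, "r_s": r_s, "F": f_coef,
             "biparental_rate": bip}
        )
        pools = _freq_arrays(freqs, name, loci, nulls)
        mother_samplers = [
            _genotype_sampler(a, p, f_coef, rng) for a, p in pools
        ]
        lat, lon, alt = coords[i]
        pop = PopulationSample(name, lat, lon, alt)
        father_counter = 0

        def draw_father(mother: list[Genotype]) -> list[Genotype]:
            related = rng.random() < bip
            gt = []
            for j, (alleles, p) in enumerate(pools):
                pollen = int(alleles[rng.choice(alleles.size, p=p)])
                if related:
                    mat = mother[j][rng.integers(2)]
                    gt.append(genotype(mat, pollen))
                else:
                    pollen2 = int(alleles[rng.choice(alleles.size, p=p)])
                    gt.append(genotype(pollen, pollen2))
            return gt

        for fi in range(int(fam_counts[i])):
            fam_id = f"{name}-F{fi + 1:03d}"
            mother = [draw() for draw in mother_samplers]
            n_off = int(rng.integers(lo, hi + 1))
            shared_self = rng.random() < r_s
            family_self_status = rng.random() < s
            shared_father_flag = rng.random() < r_p
            shared_father = None
            fam = Family(fam_id, list(mother), [])
            for k in range(n_off):
                selfed = family_self_status if shared_self else (rng.random() < s)
                gt = []
                father_id = ""
                if selfed:
                    for j in range(config.n_loci):
                        a = mother[j][rng.integers(2)]
                        b = mother[j][rng.integers(2)]
                        gt.append(genotype(a, b))
                else:
                    if shared_father_flag:
                        if shared_father is None:
                            father_counter += 1
                            shared_father = (
                                f"{fam_id}-P{father_counter}",
                                draw_father(mother),
                            )
                        father_id, father = shared_father
                    else:
                        father_counter += 1
                        father_id = f"{fam_id}-P{father_counter}"
                        father = draw_father(mother)
                    for j in range(config.n_loci):
                        a = mother[j][rng.integers(2)]
                        b = father[j][rng.integers(2)]
                        gt.append(genotype(a, b))
                fam.offspring.append(gt)
                truth_rows.append(
                    {"population": name, "family": fam_id, "seed_index": k,
                     "selfed": bool(selfed), "father_id": father_id}
                )
            pop.families.append(fam)
        pops.append(pop)
    dataset = StudyDataset([replace(l) for l in loci], pops)
    truth = SimulationTruth(pd.DataFrame(truth_rows), pd.DataFrame(params_rows))
    return dataset, truth


def apply_genotyping_errors(
    dataset: StudyDataset, config: SimulationConfig, seed: int | None = None
) -> StudyDataset:
    """Mask true genotypes into scored phenotypes.

    Null alleles are masked deterministically (``(k, NULL) → (k, k)``,
    ``(NULL, NULL) →`` untyped).  Stutter rescoring hits one-repeat
    heterozygotes with probability ``stutter_rate`` (scored as the larger
    homozygote).  Dropout hits heterozygotes with probability
    ``dropout_rate`` scaled by the larger allele's size rank (scored as
    the smaller homozygote).  With all rates zero and no null loci the
    dataset is returned unchanged in content.
    """
    seq = np.random.SeedSequence(config.seed if seed is None else seed).spawn(3)[2]
    rng = np.random.default_rng(seq)
    stut = config.per_locus("stutter_rate")
    drop = config.per_locus("dropout_rate")
    unit = config.repeat_unit

    def mask(g: Genotype, j: int, locus: Locus) -> Genotype:
        g = observe_phenotype(g, locus.has_null)
        a, b = g
        if a == b or a in (NULL, MISSING):
            return g
        if stut[j] > 0 and b - a == unit and rng.random() < stut[j]:
            return (b, b)
        if drop[j] > 0:
            ranks = locus.alleles
            rank = (ranks.index(b) + 1) / len(ranks) if b in ranks else 1.0
            if rng.random() < drop[j] * rank:
                return (a, a)
        return g

    new_pops = []
    for pop in dataset.populations:
        fams = []
        for fam in pop.families:
            maternal = [
                None if g is None else mask(g, j, dataset.loci[j])
                for j, g in enumerate(fam.maternal)
            ]
            offspring = [
                [mask(g, j, dataset.loci[j]) for j, g in enumerate(off)]
                for off in fam.offspring
            ]
            fams.append(Family(fam.family_id, maternal, offspring))
        new_pops.append(
            PopulationSample(pop.name, pop.latitude, pop.longitude, pop.altitude, fams)
        )
    return StudyDataset([replace(l) for l in dataset.loci], new_pops)


# ---------------------------------------------------------------------------
# study-like preset
# ---------------------------------------------------------------------------

# six-population field design: name, latitude, longitude, altitude (m),
# number of families, total seeds, seeds-per-family range
STUDY_POPULATIONS = [
    ("Baoshan", 24.9833, 99.0167, 1401.0, 23, 132, (4, 6)),
    ("Simao", 22.7667, 100.9667, 600.0, 12, 64, (4, 6)),
    ("Yongren", 26.0167, 101.6667, 1580.0, 16, 90, (4, 6)),
    ("Tianlin", 24.2833, 106.2167, 1200.0, 20, 119, (4, 6)),
    ("Guanshan", 28.5333, 114.5500, 330.0, 24, 138, (4, 6)),
    ("Nanping", 26.6333, 118.1667, 800.0, 30, 300, (10, 10)),
]

# eight SSR loci: name, motif, annealing-independent size range, allele count
STUDY_LOCI = [
    ("TCR17", "GA", (140, 205), 14),
    ("TCR18", "AG", (107, 210), 44),
    ("TCR20", "GA", (152, 327), 30),
    ("TCR26", "TC", (233, 271), 30),
    ("TCR51", "GA", (108, 140), 5),
    ("TCR78", "GA", (163, 255), 24),
    ("TCR83", "CT", (183, 287), 47),
    ("TCR122", "CA", (158, 298), 14),
]

# loci screened as carrying null alleles, per population
STUDY_NULL_LOCI = {
    "Baoshan": ["TCR20"],
    "Simao": ["TCR17", "TCR20", "TCR83"],
    "Yongren": ["TCR17", "TCR20", "TCR83"],
    "Tianlin": ["TCR17", "TCR20", "TCR51"],
    "Guanshan": ["TCR18", "TCR20", "TCR26"],
    "Nanping": ["TCR18", "TCR20", "TCR51", "TCR78"],
}

# per-population mating parameters in the empirically reported ranges:
# selfing 0–0.16, paternity correlation 0–0.45, maternal F slightly negative
STUDY_MATING = {
    "Baoshan": dict(s=0.00, r_p=0.11, r_s=0.0, F=-0.15, biparental_rate=0.25),
    "Simao": dict(s=0.01, r_p=0.00, r_s=0.0, F=-0.15, biparental_rate=0.25),
    "Yongren": dict(s=0.00, r_p=0.08, r_s=0.0, F=-0.12, biparental_rate=0.25),
    "Tianlin": dict(s=0.00, r_p=0.21, r_s=0.0, F=-0.15, biparental_rate=0.25),
    "Guanshan": dict(s=0.02, r_p=0.30, r_s=0.0, F=-0.03, biparental_rate=0.25),
    "Nanping": dict(s=0.16, r_p=0.31, r_s=0.05, F=-0.18, biparental_rate=0.30),
}

STUDY_NULL_FREQ = 0.15


def _family_sizes(n_families: int, total: int, lo: int, hi: int) -> list[int]:
    """Deterministic per-family seed counts in [lo, hi] summing to total."""
    base = [lo] * n_families
    remaining = total - lo * n_families
    if remaining < 0 or remaining > (hi - lo) * n_families:
        raise ValueError("total seeds incompatible with family-size range")
    i = 0
    while remaining > 0:
        add = min(hi - base[i], remaining)
        base[i] += add
        remaining -= add
        i += 1
    return base


def study_like_config(seed: int) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_populations=len(STUDY_POPULATIONS),
        families_per_population=[p[4] for p in STUDY_POPULATIONS],
        offspring_per_family=(4, 10),  # superseded by explicit sizes below
        n_loci=len(STUDY_LOCI),
        alleles_per_locus=[l[3] for l in STUDY_LOCI],
        allele_freq_concentration=0.5,
        s=[STUDY_MATING[p[0]]["s"] for p in STUDY_POPULATIONS],
        r_p=[STUDY_MATING[p[0]]["r_p"] for p in STUDY_POPULATIONS],
        r_s=[STUDY_MATING[p[0]]["r_s"] for p in STUDY_POPULATIONS],
        F=[STUDY_MATING[p[0]]["F"] for p in STUDY_POPULATIONS],
        biparental_rate=[
            STUDY_MATING[p[0]]["biparental_rate"] for p in STUDY_POPULATIONS
        ],
        migration_model="stepping_stone",
        migration_rate=0.05,
        effective_size=50,
        generations=100,
        coordinates=[(p[1], p[2], p[3]) for p in STUDY_POPULATIONS],
        population_names=[p[0] for p in STUDY_POPULATIONS],
        locus_names=[l[0] for l in STUDY_LOCI],
    )


def generate_study_like_dataset(
    seed: int, with_errors: bool = True
) -> tuple[StudyDataset, SimulationTruth]:
    """One-call preset reproducing the six-population study design.

    Populations are ordered west to east (stepping-stone chain matching
    the geography); family counts, seeds per family, locus identities,
    allele counts and coordinates follow the published sampling design.
    Null alleles are placed at the loci flagged per population in the
    published screening, at frequency 0.15, and masked in the returned
    phenotypes when ``with_errors`` is True.
    """
    config = study_like_config(seed)
    loci = [
        Locus(name=n, repeat_motif=m, size_range=rng_, has_null=False,
              alleles=[rng_[0] + 2 * i for i in range(count)])
        for (n, m, rng_, count) in STUDY_LOCI
    ]
    # allele counts must fit the printed size ranges at a 2 bp repeat
    for loc in loci:
        if loc.alleles[-1] > loc.size_range[1]:
            loc.size_range = (loc.size_range[0], loc.alleles[-1])
    freqs = simulate_population_frequencies(config, loci)
    # explicit per-family seed counts reproducing the published totals
    dataset, truth = _simulate_study_arrays(config, freqs, loci)
    if with_errors:
        dataset = apply_genotyping_errors(dataset, config)
    return dataset, truth


def _simulate_study_arrays(
    config: SimulationConfig, freqs: FrequencyTable, loci: list[Locus]
) -> tuple[StudyDataset, SimulationTruth]:
    """Like :func:`simulate_progeny_arrays` but with fixed family sizes and
    per-(population, locus) null-allele placement."""
    seq = np.random.SeedSequence(config.seed).spawn(2)[1]
    rng = np.random.default_rng(seq)
    pops: list[PopulationSample] = []
    truth_rows = []
    params_rows = []
    for i, (name, lat, lon, alt, n_fam, total, (lo, hi)) in enumerate(
        STUDY_POPULATIONS
    ):
        sizes = _family_sizes(n_fam, total, lo, hi)
        mp = STUDY_MATING[name]
        params_rows.append({"population": name, **mp})
        null_set = set(STUDY_NULL_LOCI.get(name, []))
        nulls = [STUDY_NULL_FREQ if l.name in null_set else 0.0 for l in loci]
        pools = _freq_arrays(freqs, name, loci, nulls)
        mother_samplers = [_genotype_sampler(a, p, mp["F"], rng) for a, p in pools]
        pop = PopulationSample(name, lat, lon, alt)
        father_counter = 0
        for fi, n_off in enumerate(sizes):
            fam_id = f"{name}-F{fi + 1:03d}"
            mother = [draw() for draw in mother_samplers]
            shared_self = rng.random() < mp["r_s"]
            family_self_status = rng.random() < mp["s"]
            shared_father_flag = rng.random() < mp["r_p"]
            shared_father = None
            fam = Family(fam_id, list(mother), [])

            def draw_father() -> list[Genotype]:
                related = rng.random() < mp["biparental_rate"]
                gt = []
                for j, (alleles, p) in enumerate(pools):
                    pollen = int(alleles[rng.choice(alleles.size, p=p)])
                    if related:
                        gt.append(genotype(mother[j][rng.integers(2)], pollen))
                    else:
                        p2 = int(alleles[rng.choice(alleles.size, p=p)])
                        gt.append(genotype(pollen, p2))
                return gt

            for k in range(n_off):
                selfed = family_self_status if shared_self else (
                    rng.random() < mp["s"]
                )
                gt = []
                father_id = ""
                if selfed:
                    for j in range(len(loci)):
                        gt.append(
                            genotype(
                                mother[j][rng.integers(2)],
                                mother[j][rng.integers(2)],
                            )
                        )
                else:
                    if shared_father_flag:
                        if shared_father is None:
                            father_counter += 1
                            shared_father = (
                                f"{fam_id}-P{father_counter}", draw_father()
                            )
                        father_id, father = shared_father
                    else:
                        father_counter += 1
                        father_id = f"{fam_id}-P{father_counter}"
                        father = draw_father()
                    for j in range(len(loci)):
                        gt.append(
                            genotype(mother[j][rng.integers(2)],
                                     father[j][rng.integers(2)])
                        )
                fam.offspring.append(gt)
                truth_rows.append(
                    {"population": name, "family": fam_id, "seed_index": k,
                     "selfed": bool(selfed), "father_id": father_id}
                )
            pop.families.append(fam)
        pops.append(pop)
    # a locus carries the null flag if any population hosts a null allele
    flagged = {l for ls in STUDY_NULL_LOCI.values() for l in ls}
    out_loci = []
    for l in loci:
        new = replace(l, alleles=list(l.alleles))
        new.has_null = l.name in flagged
        out_loci.append(new)
    dataset = StudyDataset(out_loci, pops)
    truth = SimulationTruth(pd.DataFrame(truth_rows), pd.DataFrame(params_rows))
    return dataset, truth
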