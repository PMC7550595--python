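"""Genotyping-error diagnosis for microsatellite data.

Implements the three classic electropherogram-error screens used for SSR
loci, in the style of Micro-Checker:

* **null alleles** — overall excess of homozygotes, spread evenly across
  allele-size classes (every class gains apparent homozygotes when a null
  allele hides heterozygotes);
* **stuttering** — deficit of heterozygotes whose alleles differ by a
  single repeat unit, with a compensating homozygote excess (adjacent
  peaks merged by PCR stutter);
* **large-allele dropout** (short allele dominance) — homozygote excess
  biased toward one extreme of the allele-size distribution.

Expectations come from Monte-Carlo randomization: the observed allele pool
is repeatedly re-paired at random (random union of gametes), giving the
null distribution of per-class homozygote counts.  Family structure is
ignored (all individuals pooled as if unrelated); the resulting
Hardy-Weinberg approximation is a known, documented bias of this style of
screening on progeny arrays.

Null-allele frequency is estimated by an iterative adjustment of the
visible-allele frequencies ("oosterhout"): given a candidate null
frequency ν the visible frequencies are the apparent ones rescaled by
(1 − ν), and ν is adjusted until the expected apparent homozygosity among
typed individuals matches the observed one.  The closed forms of
Brookfield (r = (He − Ho)/(1 + He)) and Chakraborty
(r = (He − Ho)/(He + Ho)) are kept as cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .genodata import MISSING, Genotype, StudyDataset, is_untyped


class NotScreenableError(ValueError):
    """Locus cannot be screened (monomorphic or too few allele classes)."""


@dataclass
class ExpectedCounts:
    """Monte-Carlo expectations for homozygote counts under random mating."""

    alleles: np.ndarray            # sorted allele-size classes
    observed_hom: np.ndarray       # observed homozygote count per class
    expected_hom: np.ndarray       # MC mean per class
    hom_lower: np.ndarray          # MC lower bound per class (2.5%)
    hom_upper: np.ndarray          # MC upper bound per class (97.5%)
    total_hom_observed: int
    total_hom_expected: float
    p_excess: float                # MC upper-tail p for total homozygotes
    p_deficit: float               # MC lower-tail p


@dataclass
class LocusScreenResult:
    locus: str
    population: str
    null_allele_flag: bool = False
    stutter_flag: bool = False
    dropout_flag: bool = False
    homozygote_excess_by_class: dict[int, float] = field(default_factory=dict)
    null_frequency_estimate: float = 0.0
    monte_carlo_p: float = 1.0


def _typed(observations: list[Genotype]) -> np.ndarray:
    arr = [g for g in observations if not is_untyped(g) and MISSING not in g]
    return np.asarray(arr, dtype=np.int64)


def _mc_pairings(
    pool: np.ndarray, n_reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Randomly re-pair the allele pool ``n_reps`` times -> (a, b) arrays."""
    tiled = np.tile(pool, (n_reps, 1))
    perm = rng.permuted(tiled, axis=1)
    return perm[:, 0::2], perm[:, 1::2]


def expected_genotype_counts(
    observations: list[Genotype], n_reps: int = 1000, seed: int = 0
) -> ExpectedCounts:
    """Observed vs randomization-expected homozygote counts per size class.

    Untyped individuals are excluded; raises :class:`NotScreenableError`
    for a monomorphic locus (no heterozygosity to randomize).
    """
    g = _typed(observations)
    if g.size == 0:
        raise NotScreenableError("no typed individuals")
    alleles = np.unique(g)
    if alleles.size < 2:
        raise NotScreenableError("monomorphic locus is not screenable")
    rng = np.random.default_rng(seed)
    pool = g.ravel()
    a, b = _mc_pairings(pool, n_reps, rng)
    hom_mc = np.zeros((n_reps, alleles.size))
    for i, al in enumerate(alleles):
        hom_mc[:, i] = ((a == al) & (b == al)).sum(axis=1)
    obs_hom = np.array([(g[:, 0] == al) & (g[:, 1] == al) for al in alleles]).sum(axis=1)
    tot_mc = hom_mc.sum(axis=1)
    tot_obs = int(obs_hom.sum())
    p_excess = (1.0 + np.count_nonzero(tot_mc >= tot_obs)) / (n_reps + 1.0)
    p_deficit = (1.0 + np.count_nonzero(tot_mc <= tot_obs)) / (n_reps + 1.0)
    return ExpectedCounts(
        alleles=alleles,
        observed_hom=obs_hom.astype(float),
        expected_hom=hom_mc.mean(axis=0),
        hom_lower=np.quantile(hom_mc, 0.025, axis=0),
        hom_upper=np.quantile(hom_mc, 0.975, axis=0),
        total_hom_observed=tot_obs,
        total_hom_expected=float(tot_mc.mean()),
        p_excess=float(p_excess),
        p_deficit=float(p_deficit),
    )


def detect_null_alleles(
    observations: list[Genotype],
    alpha: float = 0.05,
    seed: int = 0,
    n_reps: int = 1000,
    locus: str = "",
    population: str = "",
) -> LocusScreenResult:
    """Flag a locus for null alleles.

    Requires (i) a significant overall homozygote excess under the
    Monte-Carlo null and (ii) the excess to be spread across size classes:
    at least half of the classes show positive excess and no single class
    contributes more than half of the total excess.
    """
    exp = expected_genotype_counts(observations, n_reps=n_reps, seed=seed)
    excess = exp.observed_hom - exp.expected_hom
    total_excess = float(excess.sum())
    even = False
    if total_excess > 0:
        pos_frac = np.count_nonzero(excess > 0) / excess.size
        max_share = float(excess.max()) / total_excess
        even = pos_frac >= 0.5 and max_share <= 0.5
    flag = exp.p_excess <= alpha and even
    res = LocusScreenResult(
        locus=locus,
        population=population,
        null_allele_flag=bool(flag),
        homozygote_excess_by_class={
            int(al): float(e) for al, e in zip(exp.alleles, excess)
        },
        monte_carlo_p=exp.p_excess,
    )
    if flag:
        res.null_frequency_estimate = estimate_null_frequency(observations)
    return res


def detect_stuttering(
    observations: list[Genotype],
    repeat_unit: int,
    alpha: float = 0.05,
    seed: int = 0,
    n_reps: int = 1000,
    locus: str = "",
    population: str = "",
) -> LocusScreenResult:
    """Flag stutter mis-scoring.

    Tests whether heterozygotes whose alleles differ by exactly one repeat
    unit are significantly rarer than the random-pairing expectation while
    homozygotes are in overall excess (the merged peak is scored as the
    larger homozygote, so a deficit of adjacent-allele heterozygotes must
    be paid for by extra homozygotes).
    """
    if repeat_unit <= 0:
        raise ValueError("repeat unit must be positive")
    g = _typed(observations)
    if g.size == 0 or np.unique(g).size < 2:
        raise NotScreenableError("monomorphic locus is not screenable")
    diffs = np.abs(g[:, 0] - g[:, 1])
    # vacuous when no allele pair in the data is one repeat apart
    alleles = np.unique(g)
    pairs_one = any(
        abs(int(x) - int(y)) == repeat_unit for x in alleles for y in alleles if x < y
    )
    res = LocusScreenResult(locus=locus, population=population)
    if not pairs_one:
        return res
    rng = np.random.default_rng(seed)
    a, b = _mc_pairings(g.ravel(), n_reps, rng)
    one_rep_mc = (np.abs(a - b) == repeat_unit).sum(axis=1)
    one_rep_obs = int(np.count_nonzero(diffs == repeat_unit))
    p_deficit = (1.0 + np.count_nonzero(one_rep_mc <= one_rep_obs)) / (n_reps + 1.0)
    hom_obs = int(np.count_nonzero(diffs == 0))
    hom_mc = (a == b).sum(axis=1)
    hom_excess = hom_obs - float(hom_mc.mean())
    res.stutter_flag = bool(p_deficit <= alpha and hom_excess > 0)
    res.monte_carlo_p = float(p_deficit)
    return res


def detect_large_allele_dropout(
    observations: list[Genotype],
    alpha: float = 0.05,
    seed: int = 0,
    n_reps: int = 1000,
    locus: str = "",
    population: str = "",
) -> LocusScreenResult:
    """Flag short allele dominance (large-allele dropout).

    Dropout skews apparent homozygotes toward one extreme of the size
    distribution, so the per-class homozygote excess correlates with
    allele size.  The Spearman rank correlation of excess vs size is
    tested two-sided by permuting the excesses across classes.
    """
    exp = expected_genotype_counts(observations, n_reps=n_reps, seed=seed)
    if exp.alleles.size < 3:
        raise NotScreenableError("need >= 3 allele-size classes")
    excess = exp.observed_hom - exp.expected_hom
    rho = stats.spearmanr(exp.alleles.astype(float), excess).statistic
    res = LocusScreenResult(
        locus=locus,
        population=population,
        homozygote_excess_by_class={
            int(al): float(e) for al, e in zip(exp.alleles, excess)
        },
    )
    if not np.isfinite(rho):
        return res
    rng = np.random.default_rng(seed + 1)
    count = 0
    for _ in range(n_reps):
        r = stats.spearmanr(exp.alleles.astype(float), rng.permutation(excess)).statistic
        if np.isfinite(r) and abs(r) >= abs(rho) - 1e-12:
            count += 1
    p = (1.0 + count) / (n_reps + 1.0)
    res.dropout_flag = bool(p <= alpha)
    res.monte_carlo_p = float(p)
    return res


def _apparent_stats(observations: list[Genotype]) -> tuple[np.ndarray, float, float]:
    """Apparent allele freqs, observed het fraction and expected het."""
    g = _typed(observations)
    if g.size == 0:
        raise NotScreenableError("no typed individuals")
    alleles, counts = np.unique(g.ravel(), return_counts=True)
    freqs = counts / counts.sum()
    ho = float(np.mean(g[:, 0] != g[:, 1]))
    he = float(1.0 - np.sum(freqs**2))
    return freqs, ho, he


def estimate_null_frequency(
    observations: list[Genotype], method: str = "oosterhout"
) -> float:
    """Estimate the null-allele frequency at one locus.

    ``oosterhout``: iteratively rescales the visible-allele frequencies by
    (1 − ν) and solves for the ν whose expected apparent homozygosity
    among typed individuals matches the observed one (tolerance 1e-6).
    ``brookfield1`` and ``chakraborty`` are the closed-form moment
    estimators.  Returns 0 when there is no homozygote excess to explain.
    """
    freqs, ho, he = _apparent_stats(observations)
    if method == "brookfield1":
        return max(0.0, (he - ho) / (1.0 + he))
    if method == "chakraborty":
        if he + ho == 0:
            return 0.0
        return max(0.0, (he - ho) / (he + ho))
    if method != "oosterhout":
        raise ValueError(f"unknown method {method!r}")
    h_obs = 1.0 - ho  # observed apparent homozygosity
    sum_sq = float(np.sum(freqs**2))
    if h_obs <= sum_sq:
        return 0.0  # no excess to explain

    def expected_hom(nu: float) -> float:
        # visible freqs q_k = a_k (1-nu); apparent homozygosity among typed:
        # [sum q^2 + 2 nu sum q] / (1 - nu^2)
        return ((1.0 - nu) * sum_sq + 2.0 * nu) / (1.0 + nu)

    lo, hi = 0.0, 0.999999
    if expected_hom(hi) < h_obs:
        return hi
    return float(
        optimize.brentq(lambda nu: expected_hom(nu) - h_obs, lo, hi, xtol=1e-9)
    )


# ---------------------------------------------------------------------------
# dataset-level screening (one pooled sample per population)
# ---------------------------------------------------------------------------


def pooled_observations(dataset: StudyDataset, pop_name: str, locus_j: int) -> list[Genotype]:
    """All scored phenotypes (mothers + offspring) at one locus in one population."""
    pop = dataset.population(pop_name)
    obs: list[Genotype] = []
    for fam in pop.families:
        if fam.maternal[locus_j] is not None:
            obs.append(fam.maternal[locus_j])
        for off in fam.offspring:
            obs.append(off[locus_j])
    return [g for g in obs if not is_untyped(g)]


def screen_dataset(
    dataset: StudyDataset,
    alpha: float = 0.05,
    n_reps: int = 1000,
    seed: int = 0,
) -> list[LocusScreenResult]:
    """Run all three screens per locus × population on the pooled sample."""
    results: list[LocusScreenResult] = []
    for pop in dataset.populations:
        for j, locus in enumerate(dataset.loci):
            obs = pooled_observations(dataset, pop.name, j)
            sub = seed + 7919 * j + 104729 * dataset.populations.index(pop)
            try:
                null_res = detect_null_alleles(
                    obs, alpha=alpha, seed=sub, n_reps=n_reps,
                    locus=locus.name, population=pop.name,
                )
            except NotScreenableError:
                results.append(LocusScreenResult(locus.name, pop.name))
                continue
            try:
                stut = detect_stuttering(
                    obs, locus.repeat_unit, alpha=alpha, seed=sub + 1,
                    n_reps=n_reps, locus=locus.name, population=pop.name,
                )
                null_res.stutter_flag = stut.stutter_flag
            except NotScreenableError:
                pass
            try:
                drop = detect_large_allele_dropout(
                    obs, alpha=alpha, seed=sub + 2, n_reps=n_reps,
                    locus=locus.name, population=pop.name,
                )
                null_res.dropout_flag = drop.dropout_flag
            except NotScreenableError:
                pass
            results.append(null_res)
    return results
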