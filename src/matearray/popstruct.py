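"""Allele frequencies, diversity, F_st estimators, and isolation by distance.

The differentiation estimator is the frequency-based one used throughout
this analysis: for locus *j* over *r* populations with per-population
sample sizes ``n_i`` (individuals) and allele frequencies ``p_ijk``,

    F_st(s) = [ Σ_i Σ_k n_i (p_ijk − p̄_jk)² / ((r−1) n̄) ]
              / Σ_k p̄_jk (1 − p̄_jk),

where ``p̄_jk`` is the **unweighted** mean frequency over populations and
``n̄ = Σ n_i / r``.  The multilocus value is the ratio of the summed
numerators to the summed denominators over loci.  The null hypothesis
F_st = 0 is tested with χ² = (r−1) n̄ F_st(s) on r−1 degrees of freedom.

Two properties of this printed estimator are deliberate and covered by
tests: the numerator is a sum of squares, so F_st ≥ 0 always; and because
the among-population variance is divided by (r−1), the estimator can
exceed 1 (two populations fixed for different alleles give exactly 2.0).
A variant weighting p̄ by sample size is available for comparison.

Isolation by distance follows the Rousset regression
``F_st/(1−F_st) = a + b ln(distance)`` over all unordered population
pairs, with OLS coefficient tests and an optional Mantel permutation test
for the slope (pairwise F_st values are not independent).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import MISSING, NULL, StudyDataset, is_untyped

EARTH_RADIUS_KM = 6371.0088


@dataclass
class FrequencyTable:
    """Per-population, per-locus allele frequencies (null class allowed).

    ``freqs[(pop, locus)]`` maps allele code → frequency and sums to 1;
    the reserved ``NULL`` code (−1) carries the estimated null-allele
    frequency where one was supplied.  ``n[pop]`` is the population sample
    size in individuals.
    """

    populations: list[str]
    loci: list[str]
    freqs: dict[tuple[str, str], dict[int, float]]
    n: dict[str, float]

    def validate(self) -> None:
        for key, f in self.freqs.items():
            s = sum(f.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {key} sum to {s}")

    def restrict(self, pops: list[str]) -> "FrequencyTable":
        return FrequencyTable(
            populations=list(pops),
            loci=list(self.loci),
            freqs={k: v for k, v in self.freqs.items() if k[0] in pops},
            n={p: self.n[p] for p in pops},
        )


@dataclass
class DifferentiationResult:
    fst_by_locus: dict[str, float]
    chi2_by_locus: dict[str, tuple[float, int, float]]  # chi2, df, p
    fst_multilocus: float
    r: int


@dataclass
class IBDResult:
    a: float
    b: float
    r_squared: float
    p_a: float
    p_b: float
    n_pairs: int
    mantel_p: float | None = None


def allele_frequencies(
    dataset: StudyDataset,
    null_estimates: dict[tuple[str, str], float] | None = None,
) -> FrequencyTable:
    """Count-based allele frequencies per population and locus.

    All scored individuals (mothers and offspring) contribute.  For a
    (population, locus) with an entry in ``null_estimates`` the visible
    frequencies are rescaled by (1 − ν) and a null class of frequency ν
    is appended, so each vector still sums to 1.
    """
    null_estimates = null_estimates or {}
    pops = [p.name for p in dataset.populations]
    loci = [l.name for l in dataset.loci]
    freqs: dict[tuple[str, str], dict[int, float]] = {}
    n: dict[str, float] = {}
    for pop in dataset.populations:
        n[pop.name] = float(
            sum(1 for fam in pop.families for _ in fam.offspring)
            + sum(1 for fam in pop.families if any(g is not None for g in fam.maternal))
        )
        for j, locus in enumerate(dataset.loci):
            counts: dict[int, int] = {}
            for fam in pop.families:
                cells = [fam.maternal[j]] + [off[j] for off in fam.offspring]
                for g in cells:
                    if g is None or is_untyped(g):
                        continue
                    for a in g:
                        if a in (NULL, MISSING):
                            continue
                        counts[a] = counts.get(a, 0) + 1
            total = sum(counts.values())
            if total == 0:
                warnings.warn(
                    f"locus {locus.name} untyped in {pop.name}; cell left missing",
                    stacklevel=2,
                )
                continue
            vec = {a: c / total for a, c in counts.items()}
            nu = null_estimates.get((pop.name, locus.name))
            if nu:
                vec = {a: f * (1.0 - nu) for a, f in vec.items()}
                vec[NULL] = nu
            freqs[(pop.name, locus.name)] = vec
    table = FrequencyTable(pops, loci, freqs, n)
    table.validate()
    return table


@dataclass
class DiversityResult:
    per_locus: pd.DataFrame   # population, locus, Ho, He, n_alleles
    summary: pd.DataFrame     # population, mean/sd Ho, He, mean alleles


def heterozygosities(dataset: StudyDataset, freqs: FrequencyTable) -> DiversityResult:
    """Observed and expected heterozygosity per locus and population.

    Ho is the heterozygote fraction among scored phenotypes (null-masked
    apparent homozygotes count as homozygotes); He = 1 − Σ p² with the
    null class included where estimated.
    """
    rows = []
    for pop in dataset.populations:
        for j, locus in enumerate(dataset.loci):
            key = (pop.name, locus.name)
            obs = []
            for fam in pop.families:
                cells = [fam.maternal[j]] + [off[j] for off in fam.offspring]
                obs.extend(g for g in cells if g is not None and not is_untyped(g))
            ho = float(np.mean([g[0] != g[1] for g in obs])) if obs else math.nan
            vec = freqs.freqs.get(key)
            he = (
                float(1.0 - sum(f * f for f in vec.values())) if vec else math.nan
            )
            n_all = len({a for g in obs for a in g if a not in (NULL, MISSING)})
            rows.append(
                {"population": pop.name, "locus": locus.name, "Ho": ho, "He": he,
                 "n_alleles": n_all}
            )
    per_locus = pd.DataFrame(rows)
    summary = (
        per_locus.groupby("population", sort=False)
        .agg(
            Ho_mean=("Ho", "mean"), Ho_sd=("Ho", "std"),
            He_mean=("He", "mean"), He_sd=("He", "std"),
            alleles_mean=("n_alleles", "mean"), alleles_sd=("n_alleles", "std"),
        )
        .reset_index()
    )
    return DiversityResult(per_locus, summary)


# ---------------------------------------------------------------------------
# F_st
# ---------------------------------------------------------------------------


def _locus_terms(
    freqs: FrequencyTable, locus: str, weighted_mean: bool = False
) -> tuple[float, float] | None:
    """(numerator, denominator) of the single-locus estimator, or None."""
    pops = [p for p in freqs.populations if (p, locus) in freqs.freqs]
    r = len(pops)
    if r < 2:
        return None
    alleles = sorted({a for p in pops for a in freqs.freqs[(p, locus)]})
    p_mat = np.array(
        [[freqs.freqs[(p, locus)].get(a, 0.0) for a in alleles] for p in pops]
    )
    n_i = np.array([freqs.n[p] for p in pops])
    n_bar = n_i.mean()
    if weighted_mean:
        p_bar = (n_i[:, None] * p_mat).sum(axis=0) / n_i.sum()
    else:
        p_bar = p_mat.mean(axis=0)
    num = float((n_i[:, None] * (p_mat - p_bar) ** 2).sum() / ((r - 1) * n_bar))
    den = float((p_bar * (1.0 - p_bar)).sum())
    if den == 0.0:
        return None
    return num, den


def fst_single_locus(
    freqs: FrequencyTable, locus: str, weighted_mean: bool = False
) -> tuple[float, float, int, float]:
    """Single-locus F_st with its chi-square test.

    Returns ``(F_st, chi2, df, p)``.  Raises ``ValueError`` when the locus
    is monomorphic across populations (denominator zero) or present in
    fewer than two populations.
    """
    terms = _locus_terms(freqs, locus, weighted_mean)
    if terms is None:
        raise ValueError(f"F_st undefined at locus {locus}")
    num, den = terms
    pops = [p for p in freqs.populations if (p, locus) in freqs.freqs]
    r = len(pops)
    n_bar = float(np.mean([freqs.n[p] for p in pops]))
    fst = num / den
    chi2 = (r - 1) * n_bar * fst
    df = r - 1
    p = float(stats.chi2.sf(chi2, df))
    return fst, chi2, df, p


def fst_multilocus(
    freqs: FrequencyTable,
    loci: list[str] | None = None,
    weighted_mean: bool = False,
) -> float:
    """Multilocus F_st: summed numerators over summed denominators."""
    loci = loci if loci is not None else freqs.loci
    num = den = 0.0
    any_defined = False
    for locus in loci:
        terms = _locus_terms(freqs, locus, weighted_mean)
        if terms is None:
            continue
        any_defined = True
        num += terms[0]
        den += terms[1]
    if not any_defined or den == 0.0:
        raise ValueError("F_st undefined: no polymorphic locus")
    return num / den


def differentiation(freqs: FrequencyTable, weighted_mean: bool = False) -> DifferentiationResult:
    """Per-locus and multilocus differentiation with chi-square tests."""
    fst_by: dict[str, float] = {}
    chi_by: dict[str, tuple[float, int, float]] = {}
    for locus in freqs.loci:
        try:
            fst, chi2, df, p = fst_single_locus(freqs, locus, weighted_mean)
        except ValueError:
            continue
        fst_by[locus] = fst
        chi_by[locus] = (chi2, df, p)
    return DifferentiationResult(
        fst_by_locus=fst_by,
        chi2_by_locus=chi_by,
        fst_multilocus=fst_multilocus(freqs, weighted_mean=weighted_mean),
        r=len(freqs.populations),
    )


def pairwise_fst(
    freqs: FrequencyTable, loci: list[str] | None = None
) -> pd.DataFrame:
    """Symmetric matrix of multilocus F_st for every population pair (r = 2)."""
    pops = freqs.populations
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1:]:
            sub = freqs.restrict([p1, p2])
            try:
                val = fst_multilocus(sub, loci)
            except ValueError:
                val = math.nan
            mat.loc[p1, p2] = mat.loc[p2, p1] = val
    return mat


# ---------------------------------------------------------------------------
# geography, IBD, altitude
# ---------------------------------------------------------------------------


def geographic_distance(
    coord1: tuple[float, float], coord2: tuple[float, float]
) -> float:
    """Great-circle (haversine) distance in km between (lat, lon) points."""
    lat1, lon1 = (math.radians(c) for c in coord1)
    lat2, lon2 = (math.radians(c) for c in coord2)
    dlat, dlon = lat2 - lat1, lon2 - lon1
    h = math.sin(dlat / 2) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(h))


def distance_matrix(dataset: StudyDataset) -> pd.DataFrame:
    """Pairwise great-circle distances (km) between the populations."""
    pops = dataset.populations
    names = [p.name for p in pops]
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1:]:
            d = geographic_distance(
                (p1.latitude, p1.longitude), (p2.latitude, p2.longitude)
            )
            mat.loc[p1.name, p2.name] = mat.loc[p2.name, p1.name] = d
    return mat


def altitude_difference_matrix(dataset: StudyDataset) -> pd.DataFrame:
    names = [p.name for p in dataset.populations]
    mat = pd.DataFrame(0.0, index=names, columns=names)
    for p1 in dataset.populations:
        for p2 in dataset.populations:
            mat.loc[p1.name, p2.name] = abs(p1.altitude - p2.altitude)
    return mat


def _pair_vectors(
    fst_matrix: pd.DataFrame, other: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    pops = list(fst_matrix.index)
    xs, ys = [], []
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1:]:
            ys.append(float(fst_matrix.loc[p1, p2]))
            xs.append(float(other.loc[p1, p2]))
    return np.asarray(xs), np.asarray(ys)


def _ibd_fit(log_d: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    import statsmodels.api as sm

    X = sm.add_constant(log_d)
    fit = sm.OLS(y, X).fit()
    a, b = fit.params
    p_a, p_b = fit.pvalues
    return float(a), float(b), float(fit.rsquared), float(p_a), float(p_b)


def ibd_regression(
    fst_matrix: pd.DataFrame,
    dist_matrix: pd.DataFrame,
    method: str = "ols",
    mantel_reps: int = 999,
    seed: int = 0,
) -> IBDResult:
    """Rousset regression of F_st/(1−F_st) on ln(distance) over pairs.

    ``method="ols"`` reports coefficient t-test p-values; ``"mantel"``
    additionally permutes population labels and reports the one-sided
    permutation p for a positive slope (appropriate because pairwise
    F_st values share populations and are not independent).
    Pairs with F_st = 1 (infinite transform) are excluded with a warning;
    all distances must be positive.
    """
    d, f = _pair_vectors(fst_matrix, dist_matrix)
    # _pair_vectors returns (other, fst); unpack accordingly
    dist_v, fst_v = d, f
    if np.any(dist_v <= 0):
        raise ValueError("all pairwise distances must be positive")
    keep = fst_v < 1.0
    if not np.all(keep):
        warnings.warn("excluding pair(s) with F_st = 1 (infinite transform)",
                      stacklevel=2)
    x = np.log(dist_v[keep])
    y = fst_v[keep] / (1.0 - fst_v[keep])
    if x.size < 3:
        raise ValueError("need at least 3 population pairs")
    a, b, r2, p_a, p_b = _ibd_fit(x, y)
    result = IBDResult(a, b, r2, p_a, p_b, n_pairs=int(x.size))
    if method == "mantel":
        rng = np.random.default_rng(seed)
        pops = list(fst_matrix.index)
        count = 0
        for _ in range(mantel_reps):
            perm = rng.permutation(len(pops))
            shuffled = fst_matrix.iloc[perm, perm]
            shuffled.index = pops
            shuffled.columns = pops
            dv, fv = _pair_vectors(shuffled, dist_matrix)
            k = fv < 1.0
            if k.sum() < 3:
                continue
            _, b_perm, _, _, _ = _ibd_fit(np.log(dv[k]), fv[k] / (1.0 - fv[k]))
            if b_perm >= b:
                count += 1
        result.mantel_p = (1.0 + count) / (mantel_reps + 1.0)
    elif method != "ols":
        raise ValueError(f"unknown method {method!r}")
    return result


def altitude_correlation(
    fst_matrix: pd.DataFrame, alt_diff_matrix: pd.DataFrame
) -> tuple[float, float]:
    """Pearson correlation between pairwise F_st and |Δaltitude|."""
    alt_v, fst_v = _pair_vectors(fst_matrix, alt_diff_matrix)
    if alt_v.size < 3:
        raise ValueError("need at least 3 population pairs")
    if np.std(alt_v) == 0 or np.std(fst_v) == 0:
        return math.nan, math.nan
    r, p = stats.pearsonr(fst_v, alt_v)
    return float(r), float(p)
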