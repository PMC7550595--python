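"""Mixed-mating model with correlated paternity for progeny arrays.

Each seed in an open-pollinated family is either selfed (probability
``1 − t``) or outcrossed (probability ``t``), with the outcross paternal
allele drawn from a population pollen pool.  The model is fitted per
population by an expectation-maximization scheme over the composite
likelihood of the progeny arrays, yielding the classic parameter set:

``t_m``
    multilocus outcrossing rate, from the joint multilocus likelihood in
    which the selfing status is shared across loci;
``t_s``
    mean of the single-locus outcrossing rates (``t_s_by_locus``);
    ``t_m − t_s > 0`` indicates biparental inbreeding, because mating
    with relatives mimics selfing locus by locus but rarely at all loci
    jointly;
``F``
    inbreeding coefficient of the maternal parents, entering the
    maternal-genotype prior (homozygote probability ``p² + Fp(1−p)``);
``r_p(m)``, ``r_p(s)``
    correlation of paternity — the probability that two outcrossed sibs
    share a father — from multilocus and single-locus pairwise composite
    likelihoods; ``1/r_p(m)`` approximates the effective number of pollen
    donors, and ``r_p(s) > r_p(m)`` signals pollen-pool substructure;
``r_s``, ``r_loci``
    correlations of selfing among families (correlated-Bernoulli pair
    model) and among loci (correlation of per-locus posterior selfing
    indicators).

Null alleles are handled in the likelihood itself: a scored phenotype is
matched against every true genotype that masks to it (an apparent
homozygote ``(k,k)`` may be ``(k,k)`` or ``(k,NULL)``), with the null
class carried as an extra allele in the pollen and ovule frequency
vectors.  Pollen and ovule frequencies are estimated separately by
default (they may be pooled via :class:`EMOptions`).

Following the behaviour of classic mating-system software, ``t`` is not
constrained to [0, 1] unless requested: excess heterozygosity in the
progeny can push the maximum-likelihood outcrossing rate past 1, and the
estimator is allowed to follow it (the mixture stays a proper likelihood
as long as every per-offspring term remains positive, which bounds the
search from above).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import optimize

from .genodata import (
    MISSING,
    NULL,
    Family,
    Genotype,
    PopulationSample,
    StudyDataset,
    genotype,
    is_untyped,
    _maternal_candidates,
)

_FLOOR = 1e-300


class EstimationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mendelian transition probabilities
# ---------------------------------------------------------------------------


def self_transition_prob(mother: Genotype, offspring: Genotype) -> float:
    """P(offspring genotype | self-fertilization of the mother).

    Random union of two maternal gametes; an offspring allele absent from
    the mother simply gives probability 0.
    """
    m1, m2 = mother
    off = genotype(*offspring)
    p = 0.0
    for a in (m1, m2):
        for b in (m1, m2):
            if genotype(a, b) == off:
                p += 0.25
    return p


def outcross_transition_prob(
    mother: Genotype, offspring: Genotype, pollen_freqs: dict[int, float]
) -> float:
    """P(offspring genotype | outcross): maternal gamete × pollen draw."""
    off = genotype(*offspring)
    p = 0.0
    for m in mother:
        for a, f in pollen_freqs.items():
            if genotype(m, a) == off:
                p += 0.5 * f
    return p


def _compatible_true_genotypes(phen: Genotype, has_null: bool) -> list[Genotype]:
    a, b = genotype(*phen)
    if is_untyped(phen) or MISSING in (a, b):
        return [(NULL, NULL)] if has_null else []
    if has_null and a == b:
        return [(a, a), (NULL, a)]
    return [(a, b)]


def _fold_null(pollen_freqs: dict[int, float], null_freq: float) -> dict[int, float]:
    if null_freq <= 0.0:
        return dict(pollen_freqs)
    folded = {a: f * (1.0 - null_freq) for a, f in pollen_freqs.items() if a != NULL}
    folded[NULL] = folded.get(NULL, 0.0) + null_freq
    return folded


def phenotype_likelihood(
    phenotype: Genotype,
    mother: Genotype,
    t: float,
    pollen_freqs: dict[int, float],
    null_freq: float = 0.0,
) -> float:
    """Mixture likelihood of a scored phenotype given the true mother.

    Sums ``t · P_outcross + (1 − t) · P_self`` over every true genotype
    that masks to the observed phenotype under the null-allele map.  With
    ``null_freq = 0`` at a null-free locus this reduces to the mixture on
    the literal genotype.
    """
    if not 0.0 <= null_freq < 1.0:
        raise ValueError("null_freq outside [0, 1)")
    folded = _fold_null(pollen_freqs, null_freq)
    has_null = null_freq > 0.0 or NULL in pollen_freqs or NULL in mother
    total = 0.0
    for g in _compatible_true_genotypes(phenotype, has_null):
        total += t * outcross_transition_prob(mother, g, folded)
        total += (1.0 - t) * self_transition_prob(mother, g)
    return total


def genotype_prior(g: Genotype, freqs: dict[int, float], f_coef: float) -> float:
    """Inbreeding-adjusted genotype prior: p²+Fp(1−p) / 2pq(1−F), floored at 0."""
    x, y = genotype(*g)
    px = freqs.get(x, 0.0)
    if x == y:
        return max(0.0, px * px + f_coef * px * (1.0 - px))
    return max(0.0, 2.0 * px * freqs.get(y, 0.0) * (1.0 - f_coef))


def infer_maternal_genotypes(
    family: Family,
    ovule_freqs: list[dict[int, float]],
    f_coef: float,
    has_null: list[bool],
    pollen_freqs: list[dict[int, float]] | None = None,
    t: float = 0.9,
) -> list[dict[Genotype, float]]:
    """Per-locus posterior over the true maternal genotype.

    A recorded unambiguous maternal phenotype gives a point mass (an
    apparent homozygote at a null locus keeps both null-consistent
    candidates); an unrecorded mother is integrated over every genotype
    assembled from the family's allele support, with prior
    ``prior(g | ovule_freqs, F)`` and likelihood the product of offspring
    phenotype likelihoods.  Raises :class:`EstimationError` when no
    candidate has positive posterior.
    """
    if family.n_offspring < 1:
        raise EstimationError(f"family {family.family_id} has no offspring")
    pollen_freqs = pollen_freqs or ovule_freqs
    n_loci = len(family.maternal)
    out: list[dict[Genotype, float]] = []
    for j in range(n_loci):
        cands = _maternal_candidates(family.maternal[j], has_null[j])
        if not cands:
            support = sorted(
                {a for off in family.offspring for a in off[j]
                 if a not in (NULL, MISSING)}
            )
            if has_null[j]:
                support = [NULL] + support
            if not support:
                support = sorted(ovule_freqs[j])
            cands = [
                genotype(support[i], support[k])
                for i in range(len(support))
                for k in range(i, len(support))
            ]
        weights = []
        for m in cands:
            w = genotype_prior(m, ovule_freqs[j], f_coef)
            for off in family.offspring:
                if is_untyped(off[j]) and not has_null[j]:
                    continue  # missing data carries no information
                w *= phenotype_likelihood(off[j], m, t, pollen_freqs[j])
            weights.append(w)
        total = sum(weights)
        if total <= 0.0:
            raise EstimationError(
                f"no maternal genotype has positive likelihood for family "
                f"{family.family_id}, locus index {j}"
            )
        out.append({m: w / total for m, w in zip(cands, weights)})
    return out


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------


@dataclass
class EMOptions:
    tol: float = 1e-6
    max_iter: int = 300
    pool_pollen_ovule: bool = False
    constrain_t_to_unit: bool = False
    seed: int = 0
    t_init: float = 0.9
    f_init: float = 0.0
    t_upper: float = 1.99
    fix_frequencies: bool = False
    initial_pollen: list[dict[int, float]] | None = None
    initial_ovule: list[dict[int, float]] | None = None

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class MatingParams:
    t_m: float
    t_s: float
    t_s_by_locus: dict[str, float]
    F: float
    r_p_m: float = math.nan
    r_p_s: float = math.nan
    r_p_by_locus: dict[str, float] = field(default_factory=dict)
    r_s: float = math.nan
    r_loci: float = math.nan
    pollen_freqs: dict[str, dict[int, float]] = field(default_factory=dict)
    ovule_freqs: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def alpha_m(self) -> float:
        return 1.0 - self.t_m

    @property
    def alpha_s(self) -> float:
        return 1.0 - self.t_s

    def as_dict(self) -> dict[str, float]:
        return {
            "t_m": self.t_m, "alpha_m": self.alpha_m,
            "t_s": self.t_s, "alpha_s": self.alpha_s,
            "tm_minus_ts": self.t_m - self.t_s, "F": self.F,
            "r_s": self.r_s, "r_p_m": self.r_p_m, "r_p_s": self.r_p_s,
            "rps_minus_rpm": self.r_p_s - self.r_p_m, "r_loci": self.r_loci,
        }


@dataclass
class MatingEstimates:
    point: MatingParams
    se: dict[str, float] = field(default_factory=dict)
    n_bootstrap: int = 0
    n_bootstrap_failed: int = 0
    converged: bool = False
    n_iter: int = 0
    loglik: float = math.nan
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def derived(self) -> dict[str, float]:
        return derived_quantities(self.point)


def derived_quantities(params: MatingParams) -> dict[str, float]:
    """Selfing rates, biparental-inbreeding and substructure indicators,
    and the effective number of pollen donors ``N_ep = 1/r_p(m)``
    (missing when ``r_p(m) ≤ 0``)."""
    n_ep = 1.0 / params.r_p_m if params.r_p_m and params.r_p_m > 0 else math.nan
    return {
        "alpha_m": 1.0 - params.t_m,
        "alpha_s": 1.0 - params.t_s,
        "tm_minus_ts": params.t_m - params.t_s,
        "rps_minus_rpm": params.r_p_s - params.r_p_m,
        "N_ep": n_ep,
    }


def equilibrium_outcrossing(f_is: float) -> float:
    """Equilibrium outcrossing rate t = (1 − F_is)/(1 + F_is).

    Values above 1 (negative F_is) are returned as-is; F_is = −1 is a
    domain error.
    """
    if f_is <= -1.0:
        raise ValueError("F_is must exceed -1")
    return (1.0 - f_is) / (1.0 + f_is)


# ---------------------------------------------------------------------------
# vectorized per-population likelihood structures
# ---------------------------------------------------------------------------


class _LocusData:
    """Precomputed likelihood structure at one locus for one population.

    Cells are (maternal-candidate, offspring) pairs; per cell the selfing
    likelihood ``S`` is fixed while the outcross likelihood is the dot
    product of a sparse paternal-transmission weight row ``W`` with the
    pollen frequency vector.
    """

    def __init__(self, pop: PopulationSample, locus_j: int, locus_name: str,
                 has_null: bool, off_index: dict[tuple[int, int], int]):
        self.name = locus_name
        self.has_null = has_null
        alleles: set[int] = set()
        for fam in pop.families:
            cells = [fam.maternal[locus_j]] + [o[locus_j] for o in fam.offspring]
            for g in cells:
                if g is None:
                    continue
                alleles.update(a for a in g if a not in (NULL, MISSING))
        self.alleles = ([NULL] if has_null else []) + sorted(alleles)
        self.k = len(self.alleles)
        self.aidx = {a: i for i, a in enumerate(self.alleles)}
        self.polymorphic = len(alleles) >= 2

        cand_fam: list[int] = []
        cand_x: list[int] = []
        cand_y: list[int] = []
        cell_cand: list[int] = []
        cell_off: list[int] = []
        cell_S: list[float] = []
        W_rows: list[np.ndarray] = []
        self.n_fam = len(pop.families)
        for fi, fam in enumerate(pop.families):
            cands = _maternal_candidates(fam.maternal[locus_j], has_null)
            if not cands:
                support = sorted(
                    {a for off in fam.offspring for a in off[locus_j]
                     if a not in (NULL, MISSING)}
                )
                if has_null:
                    support = [NULL] + support
                if not support:
                    support = list(self.alleles)
                cands = [
                    genotype(support[i], support[k2])
                    for i in range(len(support))
                    for k2 in range(i, len(support))
                ]
            base_cand = len(cand_fam)
            for m in cands:
                cand_fam.append(fi)
                cand_x.append(self.aidx[m[0]])
                cand_y.append(self.aidx[m[1]])
            for oi, off in enumerate(fam.offspring):
                phen = off[locus_j]
                compat = _compatible_true_genotypes(phen, has_null)
                if not compat:
                    continue  # missing data at a null-free locus: skip cell
                o_global = off_index[(fi, oi)]
                for ci, m in enumerate(cands):
                    s_val = sum(self_transition_prob(m, g) for g in compat)
                    w = np.zeros(self.k)
                    for g in compat:
                        for m_allele in m:
                            # paternal allele that completes g from m_allele
                            gx, gy = g
                            if m_allele == gx:
                                w[self.aidx[gy]] += 0.5
                            if m_allele == gy and gx != gy:
                                w[self.aidx[gx]] += 0.5
                    cell_cand.append(base_cand + ci)
                    cell_off.append(o_global)
                    cell_S.append(s_val)
                    W_rows.append(w)
        self.cand_fam = np.asarray(cand_fam, dtype=np.intp)
        self.cand_x = np.asarray(cand_x, dtype=np.intp)
        self.cand_y = np.asarray(cand_y, dtype=np.intp)
        self.n_cand = len(cand_fam)
        self.cell_cand = np.asarray(cell_cand, dtype=np.intp)
        self.cell_off = np.asarray(cell_off, dtype=np.intp)
        self.S = np.asarray(cell_S)
        self.W = np.vstack(W_rows) if W_rows else np.zeros((0, self.k))
        # counts for frequency initialization
        self.init_counts = np.zeros(self.k)
        for fam in pop.families:
            for off in fam.offspring:
                g = off[locus_j]
                if g is None or is_untyped(g):
                    continue
                for a in g:
                    if a in self.aidx:
                        self.init_counts[self.aidx[a]] += 1.0
        self.mother_counts = np.zeros(self.k)
        for fam in pop.families:
            g = fam.maternal[locus_j]
            if g is None or is_untyped(g):
                continue
            for a in g:
                if a in self.aidx:
                    self.mother_counts[self.aidx[a]] += 1.0

    # -- per-iteration quantities -------------------------------------------

    def outcross_lik(self, p: np.ndarray) -> np.ndarray:
        return self.W @ p

    def candidate_prior(self, q: np.ndarray, f_coef: float) -> np.ndarray:
        px = q[self.cand_x]
        py = q[self.cand_y]
        hom = self.cand_x == self.cand_y
        prior = np.where(
            hom,
            px * px + f_coef * px * (1.0 - px),
            2.0 * px * py * (1.0 - f_coef),
        )
        return np.clip(prior, 0.0, None)

    def family_logsumexp(self, log_cand: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-family logsumexp over candidates and the candidate posterior."""
        mx = np.full(self.n_fam, -np.inf)
        np.maximum.at(mx, self.cand_fam, log_cand)
        mx_safe = np.where(np.isfinite(mx), mx, 0.0)
        shifted = np.exp(log_cand - mx_safe[self.cand_fam])
        sums = np.bincount(self.cand_fam, weights=shifted, minlength=self.n_fam)
        log_fam = mx_safe + np.log(np.maximum(sums, _FLOOR))
        log_fam = np.where(np.isfinite(mx), log_fam, -np.inf)
        post = shifted / np.maximum(sums[self.cand_fam], _FLOOR)
        return log_fam, post


class _PopModel:
    """EM state for one population."""

    def __init__(self, dataset: StudyDataset, pop: PopulationSample,
                 null_freqs: dict[str, float], options: EMOptions):
        self.pop = pop
        self.options = options
        off_index: dict[tuple[int, int], int] = {}
        n = 0
        for fi, fam in enumerate(pop.families):
            for oi in range(fam.n_offspring):
                off_index[(fi, oi)] = n
                n += 1
        self.n_off = n
        self.fam_of_off = np.asarray(
            [fi for fi, fam in enumerate(pop.families)
             for _ in range(fam.n_offspring)], dtype=np.intp
        )
        self.loci: list[_LocusData] = []
        self.null_init: list[float] = []
        for j, locus in enumerate(dataset.loci):
            nu = float(null_freqs.get(locus.name, 0.0))
            has_null = locus.has_null and nu > 0.0 or nu > 0.0
            ld = _LocusData(pop, j, locus.name, has_null, off_index)
            self.loci.append(ld)
            self.null_init.append(nu)
        if not any(ld.polymorphic for ld in self.loci):
            raise EstimationError("all loci monomorphic; nothing to estimate")
        if len(pop.families) < 2:
            raise EstimationError("need at least 2 families")
        # state
        self.t_m = options.t_init
        self.t_s = np.full(len(self.loci), options.t_init)
        self.F = options.f_init
        self.p: list[np.ndarray] = []
        self.q: list[np.ndarray] = []
        for j, ld in enumerate(self.loci):
            nu = self.null_init[j]
            if options.initial_pollen is not None:
                vec = options.initial_pollen[j]
                p0 = np.array([vec.get(a, 0.0) for a in ld.alleles])
            else:
                counts = ld.init_counts + 0.5
                if ld.has_null:
                    counts[0] = 0.0
                p0 = counts / counts.sum()
                if ld.has_null:
                    p0 = p0 * (1.0 - max(nu, 0.02))
                    p0[0] = max(nu, 0.02)
            if options.initial_ovule is not None:
                vec = options.initial_ovule[j]
                q0 = np.array([vec.get(a, 0.0) for a in ld.alleles])
            else:
                counts = ld.mother_counts + 0.5
                if ld.has_null:
                    counts[0] = 0.0
                q0 = counts / counts.sum()
                if ld.has_null:
                    q0 = q0 * (1.0 - max(nu, 0.02))
                    q0[0] = max(nu, 0.02)
            self.p.append(p0 / p0.sum())
            self.q.append(q0 / q0.sum())

    # -- likelihood pieces ---------------------------------------------------

    def _locus_state(self, j: int):
        ld = self.loci[j]
        A = ld.outcross_lik(self.p[j])
        return ld, A

    def _locus_loglik_and_post(self, j: int, t: float):
        """Single-locus composite loglik, candidate posterior, cell arrays."""
        ld, A = self._locus_state(j)
        L = t * A + (1.0 - t) * ld.S
        L = np.maximum(L, _FLOOR)
        log_cand = np.bincount(
            ld.cell_cand, weights=np.log(L), minlength=ld.n_cand
        )
        prior = np.maximum(ld.candidate_prior(self.q[j], self.F), _FLOOR)
        log_cand = log_cand + np.log(prior)
        log_fam, post = ld.family_logsumexp(log_cand)
        return float(log_fam.sum()), post, A, L

    def _locus_loglik_t(self, j: int, t: float) -> float:
        return self._locus_loglik_and_post(j, t)[0]

    def _t_upper(self, A: np.ndarray, S: np.ndarray) -> float:
        if self.options.constrain_t_to_unit:
            return 1.0
        deficit = A < S
        if not np.any(deficit):
            return self.options.t_upper
        bound = np.min(S[deficit] / (S[deficit] - A[deficit]))
        return min(self.options.t_upper, float(bound) - 1e-9)

    def _maximize_t(self, fun: Callable[[float], float], hi: float) -> float:
        res = optimize.minimize_scalar(
            lambda t: -fun(t), bounds=(0.0, max(hi, 1e-6)), method="bounded",
            options={"xatol": 1e-8},
        )
        return float(res.x)

    def marginal_off_liks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Posterior-mixed per-offspring log outcross / self likelihoods.

        Returns (logA, logS, typed_any) with one row per offspring; loci
        where an offspring has no data contribute nothing.
        """
        logA = np.zeros(self.n_off)
        logS = np.zeros(self.n_off)
        for j, ld in enumerate(self.loci):
            if ld.cell_off.size == 0:
                continue
            _, post, A, _ = self._locus_loglik_and_post(j, float(self.t_s[j]))
            w_cell = post[ld.cell_cand]
            Abar = np.bincount(ld.cell_off, weights=w_cell * A, minlength=self.n_off)
            Sbar = np.bincount(ld.cell_off, weights=w_cell * ld.S, minlength=self.n_off)
            seen = np.bincount(ld.cell_off, minlength=self.n_off) > 0
            logA[seen] += np.log(np.maximum(Abar[seen], _FLOOR))
            logS[seen] += np.log(np.maximum(Sbar[seen], _FLOOR))
        return logA, logS, None

    def _multilocus_loglik(self, t: float, a: np.ndarray, s: np.ndarray) -> float:
        mix = t * a + (1.0 - t) * s
        if np.any(mix <= 0.0):
            return -np.inf
        return float(np.log(mix).sum())

    def composite_loglik(self) -> float:
        return sum(
            self._locus_loglik_t(j, float(self.t_s[j]))
            for j, ld in enumerate(self.loci) if ld.polymorphic
        )

    # -- EM ------------------------------------------------------------------

    def fit(self) -> tuple[bool, int, float]:
        opts = self.options
        prev = -np.inf
        converged = False
        it = 0
        self.loglik_trace: list[float] = []
        for it in range(1, opts.max_iter + 1):
            # per-locus outcrossing rates (exact 1-D ascent)
            for j, ld in enumerate(self.loci):
                if not ld.polymorphic or ld.cell_off.size == 0:
                    continue
                A = ld.outcross_lik(self.p[j])
                hi = self._t_upper(A, ld.S)
                self.t_s[j] = self._maximize_t(
                    lambda t, j=j: self._locus_loglik_t(j, t), hi
                )
            # frequency and F updates (EM counts; revert if they hurt)
            if not opts.fix_frequencies:
                before = self.composite_loglik()
                saved = ([p.copy() for p in self.p], [q.copy() for q in self.q],
                         self.F)
                self._update_frequencies()
                self._update_F()
                after = self.composite_loglik()
                if after < before - 1e-9:
                    self.p, self.q, self.F = saved
            cur = self.composite_loglik()
            self.loglik_trace.append(cur)
            if abs(cur - prev) < opts.tol:
                converged = True
                prev = cur
                break
            prev = cur
        # multilocus rate given converged per-locus machinery
        logA, logS, _ = self.marginal_off_liks()
        mx = np.maximum(logA, logS)
        a = np.exp(logA - mx)
        s = np.exp(logS - mx)
        hi = self._t_upper(a, s)
        self.t_m = self._maximize_t(
            lambda t: self._multilocus_loglik(t, a, s), hi
        )
        return converged, it, prev

    def _update_frequencies(self) -> None:
        pooled = self.options.pool_pollen_ovule
        for j, ld in enumerate(self.loci):
            if ld.cell_off.size == 0:
                continue
            t = float(self.t_s[j])
            _, post, A, L = self._locus_loglik_and_post(j, t)
            w_out = np.clip(t * A / np.maximum(L, _FLOOR), 0.0, 1.0)
            cellw = post[ld.cell_cand] * w_out
            pat_post = ld.W * self.p[j][None, :]
            pat_post /= np.maximum(pat_post.sum(axis=1, keepdims=True), _FLOOR)
            counts = (cellw[:, None] * pat_post).sum(axis=0)
            mother_counts = np.zeros(ld.k)
            np.add.at(mother_counts, ld.cand_x, post)
            np.add.at(mother_counts, ld.cand_y, post)
            if pooled:
                tot = counts + mother_counts
                vec = tot / max(tot.sum(), _FLOOR)
                self.p[j] = vec
                self.q[j] = vec.copy()
            else:
                if counts.sum() > 0:
                    self.p[j] = counts / counts.sum()
                if mother_counts.sum() > 0:
                    self.q[j] = mother_counts / mother_counts.sum()

    def _update_F(self) -> None:
        def neg(fv: float) -> float:
            total = 0.0
            for j, ld in enumerate(self.loci):
                _, post, _, _ = self._locus_loglik_and_post(j, float(self.t_s[j]))
                px = self.q[j][ld.cand_x]
                py = self.q[j][ld.cand_y]
                hom = ld.cand_x == ld.cand_y
                prior = np.where(
                    hom, px * px + fv * px * (1.0 - px),
                    2.0 * px * py * (1.0 - fv),
                )
                total += float(np.dot(post, np.log(np.maximum(prior, _FLOOR))))
            return -total

        res = optimize.minimize_scalar(
            neg, bounds=(-0.99, 0.99), method="bounded", options={"xatol": 1e-6}
        )
        self.F = float(res.x)

    # -- correlation parameters (two-stage) -----------------------------------

    def _pair_arrays(self):
        """Per sib-pair quantities for the paternity-correlation likelihood."""
        logA, logS, _ = self.marginal_off_liks()
        t = self.t_m
        mx = np.maximum(logA, logS)
        a = np.exp(logA - mx)
        s = np.exp(logS - mx)
        denom = np.maximum(t * a + (1.0 - t) * s, _FLOOR)
        w_out = np.clip(t * a / denom, 0.0, 1.0)
        pairs_i: list[int] = []
        pairs_j: list[int] = []
        start = 0
        for fam in self.pop.families:
            n_f = fam.n_offspring
            for x in range(n_f):
                for y in range(x + 1, n_f):
                    pairs_i.append(start + x)
                    pairs_j.append(start + y)
            start += n_f
        pi = np.asarray(pairs_i, dtype=np.intp)
        pj = np.asarray(pairs_j, dtype=np.intp)
        n_pairs = pi.size
        n_loci = len(self.loci)
        P_same = np.ones((n_pairs, n_loci))
        P_ind = np.ones((n_pairs, n_loci))
        informative = np.zeros(n_loci, dtype=bool)
        for j, ld in enumerate(self.loci):
            if ld.cell_off.size == 0 or not ld.polymorphic:
                continue
            _, post, A, _ = self._locus_loglik_and_post(j, float(self.t_s[j]))
            w_cell = post[ld.cell_cand]
            # posterior-mixed transmission rows and outcross likelihoods
            Wbar = np.zeros((self.n_off, ld.k))
            np.add.at(Wbar, ld.cell_off, w_cell[:, None] * ld.W)
            Abar = Wbar @ self.p[j]
            seen = np.bincount(ld.cell_off, minlength=self.n_off) > 0
            p_vec = self.p[j]
            # same father: E over father = 0.5 Σ p q1 q2 + 0.5 (Σ p q1)(Σ p q2)
            q1 = Wbar[pi]
            q2 = Wbar[pj]
            same = 0.5 * ((q1 * q2) @ p_vec) + 0.5 * Abar[pi] * Abar[pj]
            ind = Abar[pi] * Abar[pj]
            both = seen[pi] & seen[pj]
            P_same[both, j] = same[both]
            P_ind[both, j] = ind[both]
            informative[j] = True
        weight = w_out[pi] * w_out[pj]
        return P_same, P_ind, weight, informative

    @staticmethod
    def _maximize_r(P_same: np.ndarray, P_ind: np.ndarray,
                    weight: np.ndarray) -> float:
        keep = weight > 1e-6
        if keep.sum() < 1:
            return math.nan
        ps = np.maximum(P_same[keep], _FLOOR)
        pin = np.maximum(P_ind[keep], _FLOOR)
        w = weight[keep]
        diff = ps - pin

        def feasible_bounds() -> tuple[float, float]:
            lo, hi = -1.0, 1.0
            pos = diff > 0
            neg = diff < 0
            if np.any(pos):  # pin + r diff > 0  =>  r > -pin/diff
                lo = max(lo, float(np.max(-pin[pos] / diff[pos])) + 1e-9)
            if np.any(neg):
                hi = min(hi, float(np.min(-pin[neg] / diff[neg])) - 1e-9)
            return lo, hi

        lo, hi = feasible_bounds()
        if not lo < hi:
            return math.nan

        def neg(r: float) -> float:
            mix = pin + r * diff
            return -float(np.dot(w, np.log(np.maximum(mix, _FLOOR))))

        res = optimize.minimize_scalar(
            neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-6}
        )
        return float(res.x)

    def estimate_paternity_correlation(self) -> tuple[float, float, dict[str, float]]:
        P_same, P_ind, weight, informative = self._pair_arrays()
        if weight.sum() <= 1e-6:
            return math.nan, math.nan, {}
        r_p_m = self._maximize_r(P_same.prod(axis=1), P_ind.prod(axis=1), weight)
        per_locus: dict[str, float] = {}
        for j, ld in enumerate(self.loci):
            if not informative[j]:
                continue
            r_j = self._maximize_r(P_same[:, j], P_ind[:, j], weight)
            if not math.isnan(r_j):
                per_locus[ld.name] = r_j
        r_p_s = float(np.mean(list(per_locus.values()))) if per_locus else math.nan
        return r_p_m, r_p_s, per_locus

    def estimate_selfing_correlations(self) -> tuple[float, float]:
        # r_s: correlated-Bernoulli pair model of selfing status
        logA, logS, _ = self.marginal_off_liks()
        s_rate = 1.0 - self.t_m
        r_s = math.nan
        if 1e-6 < s_rate < 1.0 - 1e-6:
            mx = np.maximum(logA, logS)
            a = np.exp(logA - mx)
            sv = np.exp(logS - mx)
            pairs = []
            start = 0
            for fam in self.pop.families:
                n_f = fam.n_offspring
                for x in range(n_f):
                    for y in range(x + 1, n_f):
                        pairs.append((start + x, start + y))
                start += n_f
            if pairs:
                pi = np.array([p[0] for p in pairs])
                pj = np.array([p[1] for p in pairs])
                s11 = sv[pi] * sv[pj]
                s10 = sv[pi] * a[pj] + a[pi] * sv[pj]
                s00 = a[pi] * a[pj]
                s, o = s_rate, 1.0 - s_rate

                def neg(r: float) -> float:
                    p11 = s * s + r * s * o
                    p10 = s * o * (1.0 - r)
                    p00 = o * o + r * s * o
                    if p11 < 0 or p10 < 0 or p00 < 0:
                        return np.inf
                    lik = p11 * s11 + p10 * s10 + p00 * s00
                    return -float(np.log(np.maximum(lik, _FLOOR)).sum())

                lo = -min(s / o, o / s) + 1e-9
                res = optimize.minimize_scalar(
                    neg, bounds=(lo, 1.0 - 1e-9), method="bounded",
                    options={"xatol": 1e-6},
                )
                r_s = float(res.x)
        # r_loci: correlation across offspring of per-locus selfing posteriors
        n_loci = len(self.loci)
        U = np.full((self.n_off, n_loci), np.nan)
        for j, ld in enumerate(self.loci):
            if ld.cell_off.size == 0 or not ld.polymorphic:
                continue
            t = float(self.t_s[j])
            _, post, A, L = self._locus_loglik_and_post(j, t)
            u_cell = np.clip((1.0 - t) * ld.S / np.maximum(L, _FLOOR), 0.0, 1.0)
            w_cell = post[ld.cell_cand]
            ubar = np.bincount(ld.cell_off, weights=w_cell * u_cell,
                               minlength=self.n_off)
            seen = np.bincount(ld.cell_off, minlength=self.n_off) > 0
            U[seen, j] = ubar[seen]
        cors = []
        for x in range(n_loci):
            for y in range(x + 1, n_loci):
                both = ~np.isnan(U[:, x]) & ~np.isnan(U[:, y])
                if both.sum() < 3:
                    continue
                ux, uy = U[both, x], U[both, y]
                if np.allclose(ux, ux[0]) and np.allclose(uy, uy[0]):
                    continue
                if np.std(ux) == 0 or np.std(uy) == 0:
                    continue
                if np.allclose(ux, uy):
                    cors.append(1.0)
                else:
                    cors.append(float(np.corrcoef(ux, uy)[0, 1]))
        r_loci = float(np.mean(cors)) if cors else math.nan
        return r_s, r_loci


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------


def _null_freqs_from_screen(screen, pop_name: str) -> dict[str, float]:
    if screen is None:
        return {}
    if isinstance(screen, dict):
        return dict(screen)
    out: dict[str, float] = {}
    for res in screen:
        if res.population in ("", pop_name) and res.null_allele_flag:
            out[res.locus] = res.null_frequency_estimate or 0.05
    return out


def fit_mating_system(
    dataset: StudyDataset,
    population: str | None = None,
    screen=None,
    options: EMOptions | None = None,
    estimate_correlations: bool = True,
) -> MatingEstimates:
    """Fit the mixed-mating model to one population's progeny arrays.

    ``screen`` supplies per-locus null-allele frequencies, either as a
    ``{locus_name: frequency}`` mapping or as the screening results from
    :mod:`matearray.error_screen`.  The EM alternates exact 1-D ascent on
    the outcrossing rates with expected-count updates of the pollen and
    ovule frequency vectors and of the maternal inbreeding coefficient F;
    the reported composite log-likelihood never decreases.  Correlation
    parameters are estimated afterwards from pairwise composite
    likelihoods (two-stage).
    """
    if population is None:
        if len(dataset.populations) != 1:
            raise ValueError("specify a population for a multi-population dataset")
        population = dataset.populations[0].name
    pop = dataset.population(population)
    options = options or EMOptions()
    nulls = _null_freqs_from_screen(screen, population)
    model = _PopModel(dataset, pop, nulls, options)
    converged, n_iter, loglik = model.fit()
    poly = [ld.polymorphic for ld in model.loci]
    t_s_by = {
        ld.name: float(model.t_s[j])
        for j, ld in enumerate(model.loci) if poly[j]
    }
    params = MatingParams(
        t_m=float(model.t_m),
        t_s=float(np.mean(list(t_s_by.values()))),
        t_s_by_locus=t_s_by,
        F=float(model.F),
        pollen_freqs={
            ld.name: {a: float(f) for a, f in zip(ld.alleles, model.p[j])}
            for j, ld in enumerate(model.loci)
        },
        ovule_freqs={
            ld.name: {a: float(f) for a, f in zip(ld.alleles, model.q[j])}
            for j, ld in enumerate(model.loci)
        },
    )
    if estimate_correlations:
        r_p_m, r_p_s, per_locus = model.estimate_paternity_correlation()
        r_s, r_loci = model.estimate_selfing_correlations()
        params.r_p_m, params.r_p_s = r_p_m, r_p_s
        params.r_p_by_locus = per_locus
        params.r_s, params.r_loci = r_s, r_loci
    return MatingEstimates(
        point=params, converged=converged, n_iter=n_iter, loglik=loglik,
        loglik_trace=list(model.loglik_trace),
    )


def bootstrap_se(
    dataset: StudyDataset,
    population: str,
    estimator: Callable[[StudyDataset, str], dict[str, float]] | None = None,
    B: int = 1000,
    seed: int = 0,
    screen=None,
    options: EMOptions | None = None,
) -> tuple[dict[str, float], int]:
    """Bootstrap standard errors by resampling progeny arrays (families).

    Returns ``(se_by_parameter, n_failed)``.  The default estimator
    refits the full mating model on each replicate; any estimator mapping
    a resampled dataset to a flat parameter dict may be supplied.
    Deterministic given ``seed``; failed replicates are dropped and
    counted.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    pop = dataset.population(population)
    rng = np.random.default_rng(seed)
    if estimator is None:
        def estimator(ds: StudyDataset, name: str) -> dict[str, float]:
            est = fit_mating_system(ds, name, screen=screen, options=options)
            return est.point.as_dict()

    rows: list[dict[str, float]] = []
    failed = 0
    n_fam = len(pop.families)
    for _ in range(B):
        idx = rng.integers(0, n_fam, size=n_fam)
        fams = [
            Family(
                f"B{k}-{pop.families[i].family_id}",
                list(pop.families[i].maternal),
                [list(o) for o in pop.families[i].offspring],
            )
            for k, i in enumerate(idx)
        ]
        boot_pop = PopulationSample(
            pop.name, pop.latitude, pop.longitude, pop.altitude, fams
        )
        boot = StudyDataset(dataset.loci, [boot_pop])
        try:
            rows.append(estimator(boot, pop.name))
        except Exception:
            failed += 1
    if len(rows) < 2:
        raise EstimationError("too few successful bootstrap replicates")
    keys = rows[0].keys()
    se = {}
    for k in keys:
        vals = np.array([r.get(k, np.nan) for r in rows], dtype=float)
        vals = vals[np.isfinite(vals)]
        se[k] = float(np.std(vals, ddof=1)) if vals.size >= 2 else math.nan
    return se, failed


def fit_with_bootstrap(
    dataset: StudyDataset,
    population: str,
    B: int = 1000,
    seed: int = 0,
    screen=None,
    options: EMOptions | None = None,
) -> MatingEstimates:
    """Point estimates plus bootstrap SEs for the full parameter set."""
    est = fit_mating_system(dataset, population, screen=screen, options=options)
    se, failed = bootstrap_se(
        dataset, population, B=B, seed=seed, screen=screen, options=options
    )
    est.se = se
    est.n_bootstrap = B
    est.n_bootstrap_failed = failed
    return est
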