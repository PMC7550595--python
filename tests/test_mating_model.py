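import math
from itertools import combinations_with_replacement

import numpy as np
import pytest

from matearray.genodata import MISSING, NULL, Family, Locus, PopulationSample, StudyDataset, genotype
from matearray.mating_model import (
    EMOptions,
    EstimationError,
    bootstrap_se,
    derived_quantities,
    equilibrium_outcrossing,
    fit_mating_system,
    genotype_prior,
    infer_maternal_genotypes,
    outcross_transition_prob,
    phenotype_likelihood,
    self_transition_prob,
)
from matearray.simulate import SimulationConfig, simulate_progeny_arrays
from tests.conftest import single_pop_config


class TestTransitionProbabilities:
    def test_selfing_of_heterozygote(self):
        m = (100, 102)
        assert self_transition_prob(m, (100, 100)) == 0.25
        assert self_transition_prob(m, (100, 102)) == 0.5
        assert self_transition_prob(m, (102, 102)) == 0.25

    def test_selfing_of_homozygote(self):
        assert self_transition_prob((100, 100), (100, 100)) == 1.0

    def test_foreign_allele_impossible_under_selfing(self):
        assert self_transition_prob((100, 102), (100, 104)) == 0.0

    def test_outcross_examples(self):
        pollen = {100: 0.3, 102: 0.5, 104: 0.2}
        assert outcross_transition_prob((100, 102), (100, 100), pollen) == pytest.approx(0.15)
        assert outcross_transition_prob((100, 100), (100, 104), pollen) == pytest.approx(0.2)

    @pytest.mark.parametrize("mother", [(100, 100), (100, 102), (102, 104)])
    def test_distributions_normalize(self, mother):
        alleles = [100, 102, 104, 106]
        pollen = {100: 0.1, 102: 0.2, 104: 0.3, 106: 0.4}
        genos = [genotype(a, b) for a, b in combinations_with_replacement(alleles, 2)]
        assert sum(self_transition_prob(mother, g) for g in genos) == pytest.approx(1.0)
        assert sum(
            outcross_transition_prob(mother, g, pollen) for g in genos
        ) == pytest.approx(1.0)


class TestPhenotypeLikelihood:
    def test_reduces_to_plain_mixture_without_nulls(self):
        pollen = {100: 0.4, 102: 0.6}
        m, off, t = (100, 102), (100, 100), 0.7
        expected = t * outcross_transition_prob(m, off, pollen) + (
            1 - t
        ) * self_transition_prob(m, off)
        assert phenotype_likelihood(off, m, t, pollen, 0.0) == pytest.approx(expected)

    def test_null_mother_explains_apparent_homozygote(self):
        # mother (NULL,100); observed seed (104,104) can be true (104,NULL)
        lik = phenotype_likelihood(
            (104, 104), (NULL, 100), 0.8, {100: 0.5, 102: 0.2, 104: 0.3}, 0.2
        )
        assert lik > 0.0

    @pytest.mark.parametrize(
        "mother,t,nu",
        [((100, 102), 0.7, 0.0), ((NULL, 100), 0.7, 0.2), ((100, 100), 1.2, 0.1)],
    )
    def test_normalizes_over_observable_phenotypes(self, mother, t, nu):
        pollen = {100: 0.3, 102: 0.5, 104: 0.2}
        phens = [
            genotype(a, b)
            for a, b in combinations_with_replacement(sorted(pollen), 2)
        ] + [(MISSING, MISSING)]
        total = sum(phenotype_likelihood(ph, mother, t, pollen, nu) for ph in phens)
        assert total == pytest.approx(1.0)


class TestMaternalInference:
    def test_recorded_heterozygote_is_point_mass(self):
        fam = Family("f", [(100, 102)], [[(100, 100)]] * 10)
        post = infer_maternal_genotypes(fam, [{100: 0.5, 102: 0.5}], 0.0, [False])
        assert post[0] == {(100, 102): 1.0}

    def test_uninformative_progeny_returns_hwe_prior(self):
        fam = Family("f", [None], [[(MISSING, MISSING)]])
        freqs = {100: 0.3, 102: 0.7}
        post = infer_maternal_genotypes(fam, [freqs], 0.0, [False])
        for g, w in post[0].items():
            assert w == pytest.approx(genotype_prior(g, freqs, 0.0))

    @pytest.mark.parametrize("n_off,floor", [(6, 0.80), (8, 0.90)])
    def test_modal_posterior_recovers_true_mothers(self, n_off, floor):
        # modal recovery improves with family size; at 6 seeds the
        # Bayes-optimal rate sits just above 0.8, at 8 seeds above 0.9
        cfg = SimulationConfig(
            seed=17, n_populations=1, families_per_population=200,
            offspring_per_family=(n_off, n_off), n_loci=1,
            alleles_per_locus=4, s=0.1, generations=0,
            allele_freq_concentration=100.0,
        )
        ds, _ = simulate_progeny_arrays(cfg)
        pop = ds.populations[0]
        counts: dict[int, int] = {}
        for fam in pop.families:
            for g in [fam.maternal[0]] + [o[0] for o in fam.offspring]:
                for a in g:
                    counts[a] = counts.get(a, 0) + 1
        tot = sum(counts.values())
        freqs = {a: c / tot for a, c in counts.items()}
        hits = 0
        for fam in pop.families:
            true_mother = fam.maternal[0]
            blind = Family(fam.family_id, [None], [[o[0]] for o in fam.offspring])
            post = infer_maternal_genotypes(blind, [freqs], 0.0, [False])
            modal = max(post[0], key=post[0].get)
            hits += modal == true_mother
        assert hits / len(pop.families) >= floor


class TestFitMatingSystem:
    def test_detectable_outcrosses_drive_t_to_upper_range(self):
        # pollen carries an allele absent from every mother: each seed is a
        # visible outcross, so the outcrossing rate must fit at >= 0.99
        loci = [Locus(f"L{j}", alleles=[100, 102]) for j in range(3)]
        fams = [
            Family(
                f"f{i}", [(100, 100)] * 3,
                [[(100, 102)] * 3 for _ in range(5)],
            )
            for i in range(6)
        ]
        ds = StudyDataset(loci, [PopulationSample("p", families=fams)])
        est = fit_mating_system(ds, "p", estimate_correlations=False)
        assert est.point.t_m >= 0.99

    def test_recovery_at_study_scale(self):
        tms = []
        for seed in range(8):
            ds, _ = simulate_progeny_arrays(single_pop_config(400 + seed))
            est = fit_mating_system(ds, "pop1", estimate_correlations=False)
            tms.append(est.point.t_m)
        assert abs(float(np.mean(tms)) - 0.85) <= 0.05

    def test_loglik_trace_is_monotone(self, small_sim):
        ds, _ = small_sim
        est = fit_mating_system(ds, "pop1", estimate_correlations=False)
        trace = np.array(est.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-9)
        assert est.converged

    def test_grid_search_oracle_equivalence(self):
        """EM maximizer of t matches a dense grid search of the exact
        single-locus likelihood when frequencies are held fixed."""
        loc = Locus("L1", alleles=[100, 102])
        fam1 = Family("f1", [(100, 102)],
                      [[(100, 100)], [(100, 102)], [(100, 100)],
                       [(100, 102)], [(102, 102)]])
        fam2 = Family("f2", [(100, 100)],
                      [[(100, 100)], [(100, 100)], [(100, 102)],
                       [(100, 100)], [(100, 100)]])
        ds = StudyDataset([loc], [PopulationSample("p", families=[fam1, fam2])])
        pollen = {100: 0.6, 102: 0.4}
        opts = EMOptions(fix_frequencies=True, initial_pollen=[pollen],
                         initial_ovule=[pollen], max_iter=200)
        est = fit_mating_system(ds, "p", options=opts, estimate_correlations=False)

        def exact_loglik(t: float) -> float:
            total = 0.0
            for fam in (fam1, fam2):
                m = fam.maternal[0]
                val = genotype_prior(m, pollen, 0.0)
                for off in fam.offspring:
                    val *= phenotype_likelihood(off[0], m, t, pollen)
                if val <= 0:
                    return -math.inf
                total += math.log(val)
            return total

        grid = np.arange(0.0, 1.5, 0.001)
        t_star = grid[int(np.argmax([exact_loglik(t) for t in grid]))]
        assert abs(est.point.t_m - t_star) <= 2e-3
        assert abs(est.point.t_s - t_star) <= 2e-3

    def test_constrain_t_to_unit_caps_the_estimate(self):
        # every seed is a visible outcross: unconstrained t runs past 1,
        # the constrained fit stops at the boundary
        loci = [Locus(f"L{j}", alleles=[100, 102]) for j in range(3)]
        fams = [
            Family(f"f{i}", [(100, 100)] * 3,
                   [[(100, 102)] * 3 for _ in range(5)])
            for i in range(6)
        ]
        ds = StudyDataset(loci, [PopulationSample("p", families=fams)])
        free = fit_mating_system(ds, "p", estimate_correlations=False)
        capped = fit_mating_system(
            ds, "p", options=EMOptions(constrain_t_to_unit=True),
            estimate_correlations=False,
        )
        assert free.point.t_m > 1.0
        assert capped.point.t_m == pytest.approx(1.0, abs=1e-6)

    def test_all_monomorphic_raises(self):
        loci = [Locus("L1", alleles=[100])]
        fams = [
            Family(f"f{i}", [(100, 100)], [[(100, 100)]] * 4) for i in range(3)
        ]
        ds = StudyDataset(loci, [PopulationSample("p", families=fams)])
        with pytest.raises(EstimationError):
            fit_mating_system(ds, "p")


class TestPaternityAndSelfingCorrelations:
    def test_single_father_families_give_high_rp(self):
        cfg = single_pop_config(30, families_per_population=40,
                                offspring_per_family=(8, 8), r_p=1.0, s=0.1)
        ds, truth = simulate_progeny_arrays(cfg)
        fathers = truth.offspring[truth.offspring.father_id != ""]
        assert (fathers.groupby("family").father_id.nunique() == 1).all()
        est = fit_mating_system(ds, "pop1")
        assert est.point.r_p_m >= 0.9

    def test_independent_fathers_give_near_zero_rp(self):
        cfg = single_pop_config(31, families_per_population=100,
                                offspring_per_family=(6, 6), r_p=0.0, s=0.1)
        ds, _ = simulate_progeny_arrays(cfg)
        est = fit_mating_system(ds, "pop1")
        assert abs(est.point.r_p_m) <= 0.1

    def test_all_or_nothing_selfing_families_give_high_rs(self):
        cfg = single_pop_config(32, families_per_population=40,
                                offspring_per_family=(8, 8), s=0.5, r_s=1.0)
        ds, _ = simulate_progeny_arrays(cfg)
        est = fit_mating_system(ds, "pop1")
        assert est.point.r_s >= 0.8

    def test_homogeneous_selfing_gives_small_rs(self):
        cfg = single_pop_config(33, families_per_population=100,
                                offspring_per_family=(6, 6), s=0.3, r_s=0.0)
        ds, _ = simulate_progeny_arrays(cfg)
        est = fit_mating_system(ds, "pop1")
        assert abs(est.point.r_s) <= 0.15

    def test_rs_undefined_without_selfing(self):
        cfg = single_pop_config(34, families_per_population=20, s=0.0)
        ds, _ = simulate_progeny_arrays(cfg)
        est = fit_mating_system(ds, "pop1")
        if est.point.t_m >= 1.0 - 1e-6:
            assert math.isnan(est.point.r_s)


class TestBootstrap:
    def test_constant_estimator_has_zero_se(self, small_sim):
        ds, _ = small_sim
        se, failed = bootstrap_se(
            ds, "pop1", estimator=lambda d, p: {"c": 1.0}, B=20, seed=0
        )
        assert se["c"] == 0.0 and failed == 0

    def test_matches_binomial_se_on_proportion_estimator(self):
        cfg = single_pop_config(35, families_per_population=60,
                                offspring_per_family=(5, 5))
        ds, truth = simulate_progeny_arrays(cfg)
        selfed = dict(
            truth.offspring.groupby("family").selfed.mean()
        )

        def prop(d: StudyDataset, p: str) -> dict[str, float]:
            fams = d.population(p).families
            vals = [selfed[f.family_id.split("-", 1)[-1]] for f in fams]
            return {"p": float(np.mean(vals))}

        # family-level resampling of a family mean: SE ~ sd(family means)/sqrt(n)
        fam_means = np.array([selfed[f.family_id] for f in ds.population("pop1").families])
        analytic = float(np.std(fam_means, ddof=1) / np.sqrt(fam_means.size))
        se, _ = bootstrap_se(ds, "pop1", estimator=prop, B=400, seed=1)
        assert se["p"] == pytest.approx(analytic, rel=0.15)

    def test_same_seed_reproduces_ses(self, small_sim):
        ds, _ = small_sim
        kw = dict(B=5, seed=42, options=EMOptions(max_iter=50))
        a, _ = bootstrap_se(ds, "pop1", **kw)
        b, _ = bootstrap_se(ds, "pop1", **kw)
        assert a == b


class TestDerivedQuantities:
    def test_published_style_arithmetic(self):
        from matearray.mating_model import MatingParams

        p = MatingParams(t_m=0.843, t_s=0.672, t_s_by_locus={}, F=-0.2,
                         r_p_m=0.25, r_p_s=0.4)
        d = derived_quantities(p)
        assert d["alpha_m"] == pytest.approx(0.157)
        assert d["N_ep"] == pytest.approx(4.0)
        p2 = MatingParams(t_m=1.194, t_s=0.897, t_s_by_locus={}, F=0.0)
        assert derived_quantities(p2)["tm_minus_ts"] == pytest.approx(0.297)

    def test_nonpositive_rp_gives_missing_nep(self):
        from matearray.mating_model import MatingParams

        p = MatingParams(t_m=1.0, t_s=1.0, t_s_by_locus={}, F=0.0, r_p_m=-0.1)
        assert math.isnan(derived_quantities(p)["N_ep"])


class TestEquilibriumOutcrossing:
    @pytest.mark.parametrize(
        "f_is,expected", [(0.0, 1.0), (1 / 3, 0.5), (-0.2, 1.5), (1.0, 0.0)]
    )
    def test_values(self, f_is, expected):
        assert equilibrium_outcrossing(f_is) == pytest.approx(expected)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            equilibrium_outcrossing(-1.0)
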