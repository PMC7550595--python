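import math

import numpy as np
import pandas as pd
import pytest

from matearray.genodata import NULL
from matearray.popstruct import (
    FrequencyTable,
    allele_frequencies,
    altitude_correlation,
    altitude_difference_matrix,
    differentiation,
    distance_matrix,
    fst_multilocus,
    fst_single_locus,
    geographic_distance,
    heterozygosities,
    ibd_regression,
    pairwise_fst,
)
from matearray.simulate import SimulationConfig, simulate_population_frequencies


def table(freqs: dict, n: dict) -> FrequencyTable:
    pops = sorted({p for p, _ in freqs})
    loci = sorted({l for _, l in freqs})
    return FrequencyTable(pops, loci, freqs, n)


class TestAlleleFrequencies:
    def test_monomorphic_sample(self, toy_dataset):
        fam = toy_dataset.populations[0].families[0]
        for f in toy_dataset.populations[0].families:
            f.maternal[0] = (100, 100)
            for off in f.offspring:
                off[0] = (100, 100)
        freqs = allele_frequencies(toy_dataset)
        assert freqs.freqs[("popA", "L1")] == {100: 1.0}

    def test_direct_counting(self, toy_dataset):
        freqs = allele_frequencies(toy_dataset)
        # L2 alleles: mothers (200,202),(200,200); offspring as written
        vec = freqs.freqs[("popA", "L2")]
        assert sum(vec.values()) == pytest.approx(1.0)
        assert vec[200] == pytest.approx(11 / 14)

    def test_null_rescaling(self, toy_dataset):
        freqs = allele_frequencies(toy_dataset, {("popA", "L1"): 0.2})
        vec = freqs.freqs[("popA", "L1")]
        assert vec[NULL] == pytest.approx(0.2)
        visible = sum(f for a, f in vec.items() if a != NULL)
        assert visible == pytest.approx(0.8)


class TestHeterozygosities:
    def test_expected_het_from_frequencies(self, toy_dataset):
        freqs = allele_frequencies(toy_dataset)
        div = heterozygosities(toy_dataset, freqs)
        row = div.per_locus[(div.per_locus.locus == "L2")].iloc[0]
        vec = freqs.freqs[("popA", "L2")]
        assert row.He == pytest.approx(1 - sum(f * f for f in vec.values()))

    def test_fixed_locus_has_zero_he(self):
        ft = table({("a", "L"): {1: 1.0}, ("b", "L"): {1: 1.0}}, {"a": 10, "b": 10})
        # He computed straight from the vector
        assert 1 - sum(f * f for f in ft.freqs[("a", "L")].values()) == 0.0


class TestFstEstimator:
    def test_identical_populations_give_zero(self):
        f = {1: 0.3, 2: 0.7}
        ft = table({("a", "L"): f, ("b", "L"): f, ("c", "L"): f},
                   {"a": 30, "b": 30, "c": 30})
        fst, chi2, df, p = fst_single_locus(ft, "L")
        assert fst == pytest.approx(0.0, abs=1e-15)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0) and df == 2

    def test_fixed_difference_gives_two_under_printed_estimator(self):
        # the (r-1) denominator makes two fixed populations exceed 1: a
        # documented property of the printed formula
        ft = table({("a", "L"): {1: 1.0}, ("b", "L"): {2: 1.0}},
                   {"a": 50, "b": 50})
        fst, chi2, df, _ = fst_single_locus(ft, "L")
        assert fst == pytest.approx(2.0)
        assert chi2 == pytest.approx((2 - 1) * 50 * 2.0)

    def test_invariant_to_allele_relabeling_and_n_scaling(self):
        base = {("a", "L"): {1: 0.8, 2: 0.2}, ("b", "L"): {1: 0.4, 2: 0.6}}
        ft = table(base, {"a": 30, "b": 60})
        relabeled = table(
            {k: {v + 100: f for v, f in vec.items()} for k, vec in base.items()},
            {"a": 30, "b": 60},
        )
        scaled = table(base, {"a": 300, "b": 600})
        f0 = fst_single_locus(ft, "L")[0]
        assert fst_single_locus(relabeled, "L")[0] == pytest.approx(f0)
        assert fst_single_locus(scaled, "L")[0] == pytest.approx(f0)

    def test_size_weighted_mean_is_a_distinct_convention(self):
        # with unequal n the size-weighted p̄ variant moves the estimate
        ft = table({("a", "L"): {1: 0.9, 2: 0.1}, ("b", "L"): {1: 0.4, 2: 0.6}},
                   {"a": 10, "b": 90})
        plain = fst_single_locus(ft, "L")[0]
        weighted = fst_single_locus(ft, "L", weighted_mean=True)[0]
        assert plain != pytest.approx(weighted)

    def test_monomorphic_locus_undefined(self):
        ft = table({("a", "L"): {1: 1.0}, ("b", "L"): {1: 1.0}}, {"a": 10, "b": 10})
        with pytest.raises(ValueError):
            fst_single_locus(ft, "L")

    def test_multilocus_collapses_to_single_locus(self):
        freqs = {("a", "L"): {1: 0.9, 2: 0.1}, ("b", "L"): {1: 0.5, 2: 0.5}}
        ft = table(freqs, {"a": 20, "b": 20})
        assert fst_multilocus(ft) == pytest.approx(fst_single_locus(ft, "L")[0])

    def test_multilocus_is_ratio_of_sums(self):
        freqs = {
            ("a", "L1"): {1: 0.9, 2: 0.1}, ("b", "L1"): {1: 0.5, 2: 0.5},
            ("a", "L2"): {1: 0.2, 2: 0.8}, ("b", "L2"): {1: 0.25, 2: 0.75},
        }
        ft = table(freqs, {"a": 20, "b": 20})
        multi = fst_multilocus(ft)
        per = [fst_single_locus(ft, l)[0] for l in ("L1", "L2")]
        assert min(per) <= multi <= max(per)


class TestPairwiseFst:
    def test_duplicate_population_off_diagonal_zero(self):
        f = {1: 0.3, 2: 0.7}
        ft = table({("a", "L"): f, ("b", "L"): dict(f)}, {"a": 25, "b": 25})
        pw = pairwise_fst(ft)
        assert pw.loc["a", "b"] == 0.0 and pw.loc["a", "a"] == 0.0

    def test_consistent_with_independent_pairwise_calls(self):
        freqs = {
            ("a", "L"): {1: 0.9, 2: 0.1}, ("b", "L"): {1: 0.5, 2: 0.5},
            ("c", "L"): {1: 0.2, 2: 0.8},
        }
        ft = table(freqs, {"a": 20, "b": 20, "c": 20})
        pw = pairwise_fst(ft)
        for x, y in (("a", "b"), ("a", "c"), ("b", "c")):
            sub = ft.restrict([x, y])
            assert pw.loc[x, y] == pytest.approx(fst_multilocus(sub))

    def test_migration_reduces_differentiation(self):
        means = {}
        for m in (0.01, 0.1):
            vals = []
            for seed in range(10):
                cfg = SimulationConfig(
                    seed=seed, n_populations=4, n_loci=4, alleles_per_locus=8,
                    migration_model="island", migration_rate=m,
                    effective_size=50, generations=50,
                )
                ft = simulate_population_frequencies(cfg)
                ft.n = {p: 50.0 for p in ft.populations}
                pw = pairwise_fst(ft)
                vals.append(np.nanmean(pw.values[np.triu_indices(4, 1)]))
            means[m] = float(np.mean(vals))
        assert means[0.1] < means[0.01]


class TestGeography:
    def test_zero_distance(self):
        assert geographic_distance((25.0, 100.0), (25.0, 100.0)) == 0.0

    def test_one_degree_longitude_at_equator(self):
        assert geographic_distance((0, 0), (0, 1)) == pytest.approx(111.19, abs=0.05)

    def test_against_spherical_law_of_cosines(self):
        # Baoshan vs Nanping coordinates
        p1, p2 = (24.9833, 99.0167), (26.6333, 118.1667)
        lat1, lon1, lat2, lon2 = map(math.radians, (*p1, *p2))
        expected = 6371.0088 * math.acos(
            math.sin(lat1) * math.sin(lat2)
            + math.cos(lat1) * math.cos(lat2) * math.cos(lon2 - lon1)
        )
        assert geographic_distance(p1, p2) == pytest.approx(expected, rel=1e-6)


class TestIBDRegression:
    def test_exact_recovery_on_collinear_points(self):
        pops = ["a", "b", "c", "d"]
        d = pd.DataFrame(0.0, index=pops, columns=pops)
        f = pd.DataFrame(0.0, index=pops, columns=pops)
        a_true, b_true = -0.3, 0.12
        dists = {("a", "b"): 10, ("a", "c"): 50, ("a", "d"): 200,
                 ("b", "c"): 30, ("b", "d"): 120, ("c", "d"): 80}
        for (x, y), dist in dists.items():
            ratio = a_true + b_true * math.log(dist)
            fst = ratio / (1 + ratio)
            d.loc[x, y] = d.loc[y, x] = dist
            f.loc[x, y] = f.loc[y, x] = fst
        res = ibd_regression(f, d)
        assert res.a == pytest.approx(a_true, abs=1e-9)
        assert res.b == pytest.approx(b_true, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0)

    def test_rejects_nonpositive_distances(self):
        pops = ["a", "b", "c"]
        z = pd.DataFrame(0.0, index=pops, columns=pops)
        with pytest.raises(ValueError):
            ibd_regression(z + 0.1 - np.eye(3) * 0.1, z)


class TestAltitudeCorrelation:
    def test_proportional_gives_r_one(self):
        pops = ["a", "b", "c", "d"]
        alt = pd.DataFrame(0.0, index=pops, columns=pops)
        fst = pd.DataFrame(0.0, index=pops, columns=pops)
        rng = np.random.default_rng(0)
        for i, x in enumerate(pops):
            for y in pops[i + 1:]:
                v = float(rng.uniform(10, 500))
                alt.loc[x, y] = alt.loc[y, x] = v
                fst.loc[x, y] = fst.loc[y, x] = 0.001 * v
        r, p = altitude_correlation(fst, alt)
        assert r == pytest.approx(1.0)

    def test_zero_variance_undefined(self):
        pops = ["a", "b", "c"]
        alt = pd.DataFrame(100.0, index=pops, columns=pops)
        fst = pd.DataFrame(0.1, index=pops, columns=pops)
        r, p = altitude_correlation(fst, alt)
        assert math.isnan(r)

    def test_permuted_altitudes_have_no_mean_correlation(self, study_dataset):
        ds, _ = study_dataset
        rng = np.random.default_rng(1)
        alts = np.array([p.altitude for p in ds.populations])
        pops = [p.name for p in ds.populations]
        fst = pd.DataFrame(
            rng.uniform(0.05, 0.4, size=(6, 6)), index=pops, columns=pops
        )
        fst = (fst + fst.T) / 2
        np.fill_diagonal(fst.values, 0.0)
        rs = []
        for _ in range(100):
            perm = rng.permutation(alts)
            amat = pd.DataFrame(
                np.abs(perm[:, None] - perm[None, :]), index=pops, columns=pops
            )
            rs.append(altitude_correlation(fst, amat)[0])
        assert abs(float(np.mean(rs))) <= 0.1


def test_differentiation_and_matrices_on_study_data(study_dataset):
    ds, _ = study_dataset
    freqs = allele_frequencies(ds)
    diff = differentiation(freqs)
    assert set(diff.fst_by_locus) <= {l.name for l in ds.loci}
    assert diff.fst_multilocus > 0
    dmat = distance_matrix(ds)
    assert np.allclose(dmat.values, dmat.values.T)
    assert (dmat.values >= 0).all()
    amat = altitude_difference_matrix(ds)
    assert amat.loc["Baoshan", "Simao"] == pytest.approx(801.0)
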