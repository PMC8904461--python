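import itertools
import math
from collections import Counter

import numpy as np
import pytest
from scipy.special import gammaln

from ssrid.errors import UndefinedStatisticError
from ssrid.genotype_io import allele_frequencies
from ssrid.locus_stats import (
    expected_heterozygosity,
    hwe_test,
    observed_heterozygosity,
    pic,
    power_of_discrimination,
    probability_of_identity,
    summaries_to_frame,
    summarize_loci,
)
from ssrid.synthetic_data import SimConfig, simulate_dataset

from conftest import build_matrix


class TestObservedHeterozygosity:
    def test_one_heterozygote_of_three(self):
        m = build_matrix([[(100, 100)], [(100, 102)], [(102, 102)]])
        assert observed_heterozygosity(m, "L1") == pytest.approx(1 / 3)

    def test_all_heterozygous(self):
        m = build_matrix([[(1, 2)], [(3, 4)]])
        assert observed_heterozygosity(m, "L1") == 1.0

    def test_direct_count(self):
        m = build_matrix([[(1, 2)], [(1, 1)], [(1, 2)], [(2, 2)]])
        assert observed_heterozygosity(m, "L1") == 0.5

    def test_zero_typed_raises(self):
        m = build_matrix([[None], [None]])
        with pytest.raises(UndefinedStatisticError):
            observed_heterozygosity(m, "L1")


class TestExpectedHeterozygosity:
    def test_two_equifrequent(self):
        he, uhe = expected_heterozygosity({1: 0.5, 2: 0.5}, n_typed=10)
        assert he == pytest.approx(0.5)
        assert uhe == pytest.approx(0.5 * 20 / 19)

    def test_monomorphic(self):
        he, _ = expected_heterozygosity({1: 1.0}, n_typed=5)
        assert he == 0.0

    def test_three_allele_value(self):
        he, _ = expected_heterozygosity({1: 0.375, 2: 0.25, 3: 0.375}, n_typed=4)
        assert he == pytest.approx(0.65625)


class TestPic:
    def test_monomorphic_zero(self):
        assert pic({1: 1.0}) == pytest.approx(0.0)

    def test_two_equifrequent(self):
        assert pic({1: 0.5, 2: 0.5}) == pytest.approx(0.375)

    def test_four_equifrequent(self):
        assert pic({k: 0.25 for k in range(4)}) == pytest.approx(0.703125)

    def test_pic_bounded_by_he(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.dirichlet(np.ones(rng.integers(2, 10)))
            freqs = dict(enumerate(p))
            he, _ = expected_heterozygosity(freqs, 50)
            assert pic(freqs) <= he + 1e-12


class TestPowerOfDiscrimination:
    def test_single_genotype(self):
        m = build_matrix([[(1, 2)], [(1, 2)]])
        assert power_of_discrimination(m, "L1") == 0.0

    def test_two_equifrequent_genotypes(self):
        m = build_matrix([[(1, 1)], [(1, 2)]])
        assert power_of_discrimination(m, "L1") == pytest.approx(0.5)

    def test_three_distinct_genotypes(self):
        m = build_matrix([[(1, 1)], [(1, 2)], [(2, 2)]])
        assert power_of_discrimination(m, "L1") == pytest.approx(2 / 3)

    def test_pi_complement(self):
        assert probability_of_identity(0.0) == 1.0
        assert probability_of_identity(0.75) == 0.25

    def test_brute_force_oracle_on_simulated_loci(self):
        # PI must equal the fraction of ordered individual pairs (i, j),
        # including i = j, sharing an unordered genotype.
        checked = 0
        for seed in range(10):
            cfg = SimConfig(n_pops=1, pop_sizes=(30,), n_loci=10, alleles_min=2,
                            alleles_max=6, missing_rate=0.1, seed=seed)
            m, _ = simulate_dataset(cfg)
            for locus in m.locus_ids:
                j = m.locus_index(locus)
                typed = [tuple(c) for c in m.calls[:, j, :] if c[0] > 0]
                if not typed:
                    continue
                matches = sum(1 for a, b in itertools.product(typed, repeat=2) if a == b)
                pi_oracle = matches / len(typed) ** 2
                pd_val = power_of_discrimination(m, locus)
                assert probability_of_identity(pd_val) == pytest.approx(pi_oracle, abs=1e-12)
                checked += 1
        assert checked == 100


class TestHweChi2:
    def test_exact_proportions_give_p_one(self):
        rows = [[(1, 1)]] * 25 + [[(1, 2)]] * 50 + [[(2, 2)]] * 25
        m = build_matrix(rows)
        assert hwe_test(m, "L1", method="chi2") == pytest.approx(1.0)

    def test_heterozygote_deficit_statistic(self):
        rows = [[(1, 1)]] * 30 + [[(1, 2)]] * 40 + [[(2, 2)]] * 30
        m = build_matrix(rows)
        # chi2 = 4 on df 1
        assert hwe_test(m, "L1", method="chi2") == pytest.approx(0.04550026, abs=1e-6)

    def test_monomorphic_not_applicable(self):
        m = build_matrix([[(1, 1)], [(1, 1)]])
        with pytest.raises(UndefinedStatisticError, match="monomorphic"):
            hwe_test(m, "L1")


def _exact_hwe_p(n11, n12, n22):
    """Exhaustive conditional exact HWE p-value for a biallelic locus."""
    n = n11 + n12 + n22
    n1 = 2 * n11 + n12  # copies of allele 1

    def log_prob(h):  # h = heterozygote count, same parity as n1
        a11 = (n1 - h) // 2
        a22 = n - a11 - h
        if a11 < 0 or a22 < 0:
            return None
        return (
            gammaln(n + 1) - gammaln(a11 + 1) - gammaln(h + 1) - gammaln(a22 + 1)
            + h * math.log(2.0)
            + gammaln(n1 + 1) + gammaln(2 * n - n1 + 1) - gammaln(2 * n + 1)
        )
    probs = {}
    for h in range(n1 % 2, min(n1, 2 * n - n1) + 1, 2):
        lp = log_prob(h)
        if lp is not None:
            probs[h] = math.exp(lp)
    obs = probs[n12]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-9))


def test_hwe_exact_mc_matches_exhaustive_enumeration():
    rows = [[(1, 1)]] * 3 + [[(1, 2)]] * 1 + [[(2, 2)]] * 2
    m = build_matrix(rows)
    p_exact = _exact_hwe_p(3, 1, 2)
    p_mc = hwe_test(m, "L1", method="exact_mc", mc_reps=40_000, seed=123)
    assert p_mc == pytest.approx(p_exact, abs=0.01)


def test_hwe_exact_mc_requires_seed():
    m = build_matrix([[(1, 1)], [(1, 2)]])
    with pytest.raises(ValueError, match="seed"):
        hwe_test(m, "L1", method="exact_mc")


class TestSummarizeLoci:
    def test_composition_matches_individual_operations(self, toy_matrix):
        summaries = summarize_loci(toy_matrix)
        s = {x.locus_id: x for x in summaries}
        freqs = allele_frequencies(toy_matrix)
        assert s["L1"].Ho == observed_heterozygosity(toy_matrix, "L1")
        assert s["L1"].He == expected_heterozygosity(freqs.freqs["L1"], 3)[0]
        assert s["L1"].PIC == pic(freqs.freqs["L1"])
        assert s["L1"].PD == power_of_discrimination(toy_matrix, "L1")
        assert s["L1"].PD + s["L1"].PI == 1.0

    def test_identities_and_bounds_on_simulated_data(self):
        cfg = SimConfig(n_pops=2, pop_sizes=(20, 20), n_loci=36, alleles_min=2,
                        alleles_max=10, fst=0.05, fis=0.1, missing_rate=0.05, seed=3)
        m, _ = simulate_dataset(cfg)
        summaries = summarize_loci(m)
        assert len(summaries) == 36
        for s in summaries:
            assert s.PD + s.PI == 1.0
            assert s.PIC <= s.He + 1e-12
            assert s.He <= 1 - 1 / s.A + 1e-12
            assert 0.0 <= s.Ho <= 1.0 and 0.0 <= s.He < 1.0
            if s.He > 0:
                assert s.A >= 2

    def test_mean_pd_plus_mean_pi_is_one(self):
        cfg = SimConfig(n_pops=1, pop_sizes=(30,), n_loci=12, seed=9)
        m, _ = simulate_dataset(cfg)
        df = summaries_to_frame(summarize_loci(m))
        footer = df.iloc[-1]
        assert footer["locus"] == "mean"
        assert footer["PD"] + footer["PI"] == pytest.approx(1.0, abs=1e-12)

    def test_shape_contract_36_loci(self):
        cfg = SimConfig(n_pops=1, pop_sizes=(20,), n_loci=36, seed=4)
        m, _ = simulate_dataset(cfg)
        df = summaries_to_frame(summarize_loci(m), with_means=False)
        assert len(df) == 36


def test_ho_tracks_fis():
    # Fis > 0 depresses Ho below He; Fis = 0 keeps them close.
    cfg0 = SimConfig(n_pops=1, pop_sizes=(500,), n_loci=30, alleles_min=3, alleles_max=8,
                     fis=0.0, seed=11)
    m0, _ = simulate_dataset(cfg0)
    s0 = summarize_loci(m0)
    diff0 = np.mean([x.He - x.Ho for x in s0])
    assert abs(diff0) < 0.02

    cfg1 = SimConfig(n_pops=1, pop_sizes=(500,), n_loci=30, alleles_min=3, alleles_max=8,
                     fis=0.3, seed=11)
    m1, _ = simulate_dataset(cfg1)
    s1 = summarize_loci(m1)
    assert np.mean([x.He - x.Ho for x in s1]) > 0.05


def test_permuting_allele_columns_leaves_statistics_unchanged():
    cfg = SimConfig(n_pops=1, pop_sizes=(25,), n_loci=8, seed=21)
    m, _ = simulate_dataset(cfg)
    swapped = build_matrix(
        [[(int(b), int(a)) if a > 0 else None for a, b in m.calls[i]]
         for i in range(m.n_individuals)],
        populations=list(m.populations),
        locus_ids=list(m.locus_ids),
        individual_ids=list(m.individual_ids),
    )
    for s, t in zip(summarize_loci(m), summarize_loci(swapped)):
        assert (s.A, s.Ho, s.He, s.PIC, s.PD, s.PI) == (t.A, t.Ho, t.He, t.PIC, t.PD, t.PI)
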