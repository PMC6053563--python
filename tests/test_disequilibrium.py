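"""Exact HWE/LD tests against enumeration oracles, EM null-allele recovery,
and Bonferroni thresholds."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from ssrpopgen.disequilibrium import (
    bonferroni_adjust,
    hwe_exact_mc,
    ld_exact_mc,
    null_allele_em,
)
from ssrpopgen.simulate import SimConfig, apply_null_alleles, simulate_dataset

CHAIN = dict(dememorization=2000, batches=20, iterations_per_batch=500)


def hwe_exact_enum(genotypes):
    """Exact Levene-conditional p-value by enumerating every pairing of the
    gene multiset into genotypes (uniform over allele arrangements)."""
    genes = [a for g in genotypes for a in g]
    n = len(genotypes)

    def table_of(perm):
        return frozenset(
            Counter(tuple(sorted(perm[2 * i : 2 * i + 2])) for i in range(n)).items()
        )

    counts = Counter(table_of(p) for p in itertools.permutations(genes))
    total = sum(counts.values())
    obs = table_of(genes)
    p_obs = counts[obs] / total
    return sum(c / total for c in counts.values() if c / total <= p_obs + 1e-12)


class TestHweExact:
    def test_tiny_table_matches_enumeration(self):
        genotypes = [(1, 1), (2, 2)]
        exact = hwe_exact_enum(genotypes)
        assert exact == pytest.approx(1 / 3)
        res = hwe_exact_mc(np.array(genotypes), seed=1, **CHAIN)
        assert abs(res.pvalue - exact) <= 3 * res.se + 1e-9

    def test_three_individual_table_matches_enumeration(self):
        genotypes = [(1, 1), (1, 2), (2, 2)]
        exact = hwe_exact_enum(genotypes)
        res = hwe_exact_mc(np.array(genotypes), seed=2, **CHAIN)
        assert abs(res.pvalue - exact) <= 3 * res.se + 1e-9

    def test_all_heterozygote_sample_rejects(self):
        g = np.array([(1, 2)] * 50)
        res = hwe_exact_mc(g, seed=3, **CHAIN)
        assert res.pvalue < 0.001

    def test_monomorphic_undefined(self):
        with pytest.raises(ValueError):
            hwe_exact_mc(np.array([(1, 1), (1, 1)]))

    def test_null_rejection_rate_nominal(self):
        # HWE-simulated loci: rejection at 5% stays within the binomial band
        rng = np.random.default_rng(0)
        rejections = 0
        reps = 120
        for i in range(reps):
            p = rng.dirichlet(np.ones(4))
            g = rng.choice(4, size=(30, 2), p=p) + 1
            if np.unique(g).size < 2:
                continue
            res = hwe_exact_mc(g, dememorization=500, batches=10,
                               iterations_per_batch=200, seed=i)
            rejections += res.pvalue <= 0.05
        rate = rejections / reps
        assert rate <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / reps)


def ld_exact_enum(table):
    """Exact p for a 2x2 genotype contingency table: hypergeometric
    enumeration with log-likelihood-ratio ordering."""
    from scipy.stats import hypergeom

    table = np.asarray(table)
    r1, r2 = table.sum(axis=1)
    c1, _ = table.sum(axis=0)
    n = table.sum()

    def llr(t):
        return sum(x * math.log(x) for x in t.ravel() if x > 0)

    obs = llr(table)
    p = 0.0
    for x in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        t = np.array([[x, r1 - x], [c1 - x, r2 - (c1 - x)]])
        if llr(t) >= obs - 1e-9:
            p += hypergeom.pmf(x, n, r1, c1)
    return p


class TestLdExact:
    def test_2x2_matches_enumeration_and_fisher(self):
        # two genotype categories per locus, symmetric margins: the LLR and
        # probability orderings coincide, so Fisher's exact test agrees too
        g1 = np.array([(1, 1)] * 6 + [(1, 2)] * 6)
        g2 = np.array([(3, 3)] * 5 + [(3, 4)] * 1 + [(3, 4)] * 5 + [(3, 3)] * 1)
        table = np.array([[5, 1], [1, 5]])
        exact = ld_exact_enum(table)
        from scipy.stats import fisher_exact

        assert exact == pytest.approx(fisher_exact(table).pvalue, abs=1e-12)
        res = ld_exact_mc(g1, g2, seed=4, **CHAIN)
        assert abs(res.pvalue - exact) <= 3 * res.se + 1e-9

    def test_duplicate_locus_detected(self):
        rng = np.random.default_rng(5)
        g = rng.choice([1, 2, 3], size=(50, 2))
        res = ld_exact_mc(g, g, seed=5, **CHAIN)
        assert res.pvalue < 0.01

    def test_independent_loci_p_not_extreme(self):
        rng = np.random.default_rng(6)
        ps = []
        for i in range(40):
            g1 = rng.choice([1, 2], size=(40, 2))
            g2 = rng.choice([3, 4], size=(40, 2))
            res = ld_exact_mc(g1, g2, dememorization=500, batches=10,
                              iterations_per_batch=200, seed=i)
            ps.append(res.pvalue)
        # under the null the p-values spread over (0,1): mean near 1/2
        assert 0.3 < np.mean(ps) < 0.7

    def test_degenerate_locus_rejected(self):
        with pytest.raises(ValueError):
            ld_exact_mc(np.array([(1, 1)] * 4), np.array([(1, 2)] * 4))


class TestNullAlleleEM:
    def test_hwe_proportions_give_zero(self):
        # counts exactly at HWE for p=(0.5,0.5), n=100: 25 AA, 50 Aa, 25 aa
        g = np.array([(1, 1)] * 25 + [(1, 2)] * 50 + [(2, 2)] * 25)
        res = null_allele_em(g)
        assert res.r == pytest.approx(0.0, abs=1e-4)

    def test_recovery_at_half_thousand(self):
        ds, _ = simulate_dataset(
            SimConfig(n_areas=1, individuals_per_area=(500, 500), n_loci=4, seed=17)
        )
        noisy, _ = apply_null_alleles(ds, 0.2, seed=17)
        area = ds.areas[0]
        est = []
        for j in range(4):
            g = noisy.calls[area][:, j, :]
            typed = g[:, 0] != 0
            res = null_allele_em(g[typed], n_missing=int((~typed).sum()))
            est.append(res.r)
        assert np.mean(est) == pytest.approx(0.2, abs=0.05)

    def test_matches_grid_search_of_observed_likelihood(self):
        # biallelic case: profile the observed-data likelihood on a fine grid
        g = np.array([(1, 1)] * 30 + [(1, 2)] * 20 + [(2, 2)] * 14)
        m = 2
        res = null_allele_em(g, n_missing=m)

        def loglik(r, s):
            p1, p2 = s * (1 - r), (1 - s) * (1 - r)
            ll = 30 * math.log(p1**2 + 2 * p1 * r)
            ll += 20 * math.log(2 * p1 * p2)
            ll += 14 * math.log(p2**2 + 2 * p2 * r)
            ll += m * math.log(r**2)
            return ll

        best = max(
            ((r, s) for r in np.arange(1e-4, 0.5, 1e-4) for s in np.arange(0.3, 0.9, 2e-3)),
            key=lambda t: loglik(*t),
        )
        assert res.r == pytest.approx(best[0], abs=2e-3)

    def test_flag_threshold(self):
        g = np.array([(1, 1)] * 40 + [(2, 2)] * 40 + [(1, 2)] * 5)
        res = null_allele_em(g, n_missing=10)
        assert res.flagged == (res.r > 0.20)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,decimals,expect",
        [
            (0.05, 45, 4, 0.0011),
            (0.01, 55, 5, 0.00018),
            (0.01, 45, 4, 0.0002),
            (0.05, 1, 6, 0.05),
        ],
    )
    def test_published_thresholds(self, alpha, n, decimals, expect):
        # thresholds rounded to the precision the tables print
        assert round(bonferroni_adjust(alpha, n), decimals) == expect

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(0.05, 0)
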