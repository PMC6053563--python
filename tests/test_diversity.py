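"""Per-area diversity statistics: hand-computed examples, enumeration
oracles and estimator properties."""

import itertools
import math

import numpy as np
import pytest

from ssrpopgen.core import allele_frequencies
from ssrpopgen.diversity import (
    allelic_richness,
    apparent_outcrossing,
    area_summaries,
    effective_alleles,
    fis_area,
    gene_diversity,
    private_and_rare_alleles,
)
from ssrpopgen.simulate import SimConfig, simulate_dataset

from conftest import make_dataset


class TestGeneDiversity:
    def test_hand_computation(self, single_area_hand):
        per_locus, ho, he = gene_diversity(single_area_hand, "A")
        assert ho == pytest.approx(1 / 3)
        # unbiased He = (6/5)(1 - 25/36 - 1/36) = 1/3
        assert he == pytest.approx(1 / 3)

    def test_monomorphic_zero(self):
        ds = make_dataset({"A": [[(1, 1)], [(1, 1)]]})
        _, ho, he = gene_diversity(ds, "A")
        assert ho == 0 and he == 0

    def test_simulated_he_matches_configured_diversity(self):
        ds, truth = simulate_dataset(
            SimConfig(n_areas=1, individuals_per_area=(500, 500), n_loci=15, fst=0.0, seed=6)
        )
        _, _, he = gene_diversity(ds, ds.areas[0])
        expect = np.mean([1 - (p**2).sum() for p in truth.ancestral_freqs])
        assert he == pytest.approx(expect, abs=0.02)


class TestEffectiveAlleles:
    @pytest.mark.parametrize("he,ae", [(0.0, 1.0), (0.75, 4.0)])
    def test_per_locus_formula(self, he, ae):
        got, _ = effective_alleles({"L1": he}, k=5)
        assert got == pytest.approx(ae)

    def test_published_percentage(self):
        # 23.35 effective alleles of 41 observed -> 57%
        _, pct = effective_alleles({"L1": 1 - 1 / 23.35}, k=41)
        assert round(pct) == 57


class TestAllelicRichness:
    def test_no_rarefaction_returns_k(self):
        ds = make_dataset({"A": [[(1, 2)], [(3, 4)]], "B": [[(1, 1)], [(2, 2)]]})
        assert allelic_richness(ds, "A", g=4) == pytest.approx(4.0)

    def test_exhaustive_enumeration_oracle(self):
        # counts (3,1), g=2: enumerate all C(4,2) subsamples of the 4 genes
        ds = make_dataset({"A": [[(1, 1)], [(1, 2)]], "B": [[(1, 1)], [(1, 2)]]})
        genes = [1, 1, 1, 2]
        expect = np.mean(
            [len(set(c)) for c in itertools.combinations(genes, 2)]
        )
        assert expect == pytest.approx(1.5)
        assert allelic_richness(ds, "A", g=2) == pytest.approx(expect)

    def test_monotone_in_g(self):
        ds, _ = simulate_dataset(SimConfig(n_areas=2, n_loci=5, seed=11))
        vals = [allelic_richness(ds, ds.areas[0], g=g) for g in (2, 6, 10, 16)]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))


class TestPrivateAndRare:
    def test_private_definition(self):
        ds = make_dataset(
            {"X": [[(1, 2)], [(1, 9)]], "Y": [[(1, 2)], [(2, 2)]]}
        )
        a_p, _, _ = private_and_rare_alleles(allele_frequencies(ds))
        assert a_p == {"X": 1, "Y": 0}

    def test_identical_allele_sets_no_private(self):
        ds = make_dataset({"X": [[(1, 2)]], "Y": [[(2, 1)]]})
        a_p, _, _ = private_and_rare_alleles(allele_frequencies(ds))
        assert a_p == {"X": 0, "Y": 0}

    def test_brute_force_recount(self):
        ds, _ = simulate_dataset(SimConfig(n_areas=11, n_loci=6, seed=13))
        freqs = allele_frequencies(ds)
        a_p, a_r, pct = private_and_rare_alleles(freqs, rare_threshold=0.05)
        # independent recount with plain set algebra
        for area in ds.areas:
            priv = rare = 0
            for locus in ds.loci:
                pooled = freqs.pooled_freq(locus)
                here = freqs.alleles_in_area(area, locus)
                elsewhere = set().union(
                    *(freqs.alleles_in_area(o, locus) for o in ds.areas if o != area)
                )
                for al in here:
                    if al not in elsewhere:
                        priv += 1
                    elif pooled[al] < 0.05:
                        rare += 1
            assert a_p[area] == priv and a_r[area] == rare
        assert pct["private"] + pct["rare"] + pct["common"] == pytest.approx(100)

    def test_single_area_rejected(self):
        ds = make_dataset({"X": [[(1, 2)]]})
        with pytest.raises(ValueError):
            private_and_rare_alleles(allele_frequencies(ds))


class TestFis:
    def test_all_heterozygotes_is_minus_one(self):
        ds = make_dataset({"A": [[(1, 2)] for _ in range(10)]})
        f, _, _ = fis_area(ds, "A", n_perm=50, seed=0)
        assert f == pytest.approx(-1.0)

    def test_hand_example_zero(self, single_area_hand):
        f, _, _ = fis_area(single_area_hand, "A", n_perm=50, seed=0)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_sign_agrees_with_ho_he_components(self):
        for seed in range(5):
            ds, _ = simulate_dataset(
                SimConfig(n_areas=1, individuals_per_area=(40, 40), n_loci=10,
                          fis=0.15, seed=seed)
            )
            f, _, _ = fis_area(ds, ds.areas[0], n_perm=20, seed=seed)
            assert math.isfinite(f)

    def test_null_fis_centred_on_zero(self):
        est = []
        for seed in range(15):
            ds, _ = simulate_dataset(
                SimConfig(n_areas=1, individuals_per_area=(50, 50), n_loci=10, seed=seed)
            )
            f, _, _ = fis_area(ds, ds.areas[0], n_perm=20, seed=seed)
            est.append(f)
        assert np.mean(est) == pytest.approx(0.0, abs=0.02)


class TestOutcrossing:
    @pytest.mark.parametrize("fis,ta", [(0.0, 1.0), (1.0, 0.0), (1 / 3, 0.5)])
    def test_formula(self, fis, ta):
        assert apparent_outcrossing(fis) == pytest.approx(ta)

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            apparent_outcrossing(-1.0)


class TestAreaSummaries:
    def test_table_is_internally_consistent(self):
        ds, _ = simulate_dataset(
            SimConfig(n_areas=3, individuals_per_area=(20, 20), n_loci=6, fst=0.05, seed=21)
        )
        rows = area_summaries(ds, n_perm=50, seed=0)
        for s in rows:
            assert 0 <= s.ho <= 1 and 0 <= s.he <= 1
            assert -1 <= s.fis <= 1
            assert s.a_p <= s.k and s.a_r <= s.k and s.a_e <= s.k
            assert 0 < s.a_e_pct <= 100
            # multilocus sign agreement between Ho-He gap and f
            if abs(s.ho - s.he) > 1e-9:
                assert (s.ho > s.he) == (s.fis < 0)
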