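"""AMOVA against a longhand oracle, Nei distances, UPGMA and Mantel."""

import itertools
import math

import numpy as np
import pytest

from ssrpopgen.core import allele_frequencies
from ssrpopgen.simulate import SimConfig, simulate_dataset
from ssrpopgen.structure import (
    amova_two_level,
    mantel_test,
    nei_distance,
    upgma,
    upgma_bootstrap,
)

from conftest import make_dataset


class TestAmova:
    def test_fixed_areas_full_structure(self):
        ds = make_dataset({"A": [[(1, 1)]] * 6, "B": [[(2, 2)]] * 6})
        res = amova_two_level(ds, n_perm=100, seed=0)
        assert res.phi_st == pytest.approx(1.0)
        assert res.pct_among == pytest.approx(100.0)
        assert res.pct_among + res.pct_within == pytest.approx(100.0, abs=1e-9)

    def test_shuffled_pool_no_structure(self):
        rng = np.random.default_rng(1)
        pool = [[(int(rng.integers(1, 4)), int(rng.integers(1, 4)))] for _ in range(60)]
        ds = make_dataset({"A": pool[:30], "B": pool[30:]})
        res = amova_two_level(ds, n_perm=200, seed=1)
        assert abs(res.pct_among) < 5
        assert res.pvalue > 0.05

    def test_longhand_sums_of_squares(self):
        # 2 areas x 3 individuals x 1 biallelic locus, computed by hand from
        # the squared-Euclidean dosage distances
        ds = make_dataset(
            {
                "A": [[(1, 1)], [(1, 2)], [(1, 1)]],
                "B": [[(2, 2)], [(2, 2)], [(1, 2)]],
            }
        )
        # dosage vectors (count of allele1, allele2)
        dos = {
            "A": [(2, 0), (1, 1), (2, 0)],
            "B": [(0, 2), (0, 2), (1, 1)],
        }
        pts = dos["A"] + dos["B"]

        def d2(u, v):
            return sum((a - b) ** 2 for a, b in zip(u, v))

        N = 6
        ss_total = sum(d2(pts[i], pts[j]) for i in range(N) for j in range(i + 1, N)) / N
        ss_within = sum(
            sum(d2(grp[i], grp[j]) for i in range(3) for j in range(i + 1, 3)) / 3
            for grp in dos.values()
        )
        ss_among = ss_total - ss_within
        ms_among, ms_within = ss_among / 1, ss_within / 4
        n0 = (6 - (9 + 9) / 6) / 1
        var_among = (ms_among - ms_within) / n0
        phi = var_among / (var_among + ms_within)
        res = amova_two_level(ds, n_perm=10, seed=0)
        assert res.ms_among == pytest.approx(ms_among, abs=1e-12)
        assert res.ms_within == pytest.approx(ms_within, abs=1e-12)
        assert res.phi_st == pytest.approx(phi, abs=1e-12)


class TestNeiDistance:
    def test_identical_frequencies_zero(self):
        ds = make_dataset({"A": [[(1, 2)], [(1, 1)]], "B": [[(1, 2)], [(1, 1)]]})
        D = nei_distance(allele_frequencies(ds), "1972")
        assert D[0, 1] == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        # pop1 fixed on allele 1, pop2 at (0.5, 0.5): I = 0.5/sqrt(0.5)
        ds = make_dataset({"A": [[(1, 1)], [(1, 1)]], "B": [[(1, 2)], [(2, 1)]]})
        D = nei_distance(allele_frequencies(ds), "1972")
        assert D[0, 1] == pytest.approx(-math.log(0.5 / math.sqrt(0.5)), abs=1e-12)
        assert D[0, 1] == pytest.approx(0.3466, abs=1e-4)

    def test_unbiased_converges_to_standard(self):
        ds, _ = simulate_dataset(
            SimConfig(n_areas=2, individuals_per_area=(5000, 5000), n_loci=5,
                      fst=0.05, seed=3)
        )
        freqs = allele_frequencies(ds)
        d72 = nei_distance(freqs, "1972")[0, 1]
        d78 = nei_distance(freqs, "1978")[0, 1]
        assert abs(d72 - d78) < 1e-3

    def test_no_shared_alleles_infinite(self):
        ds = make_dataset({"A": [[(1, 1)]], "B": [[(2, 2)]]})
        D = nei_distance(allele_frequencies(ds), "1972")
        assert math.isinf(D[0, 1])


class TestUpgma:
    def test_hand_three_taxa(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = upgma(["A", "B", "C"], d)
        assert tree.height == pytest.approx(2.0)
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert inner.leaves() == frozenset({"A", "B"})
        assert inner.height == pytest.approx(1.0)

    def test_ultrametric_fixed_point(self):
        # heights of an ultrametric matrix are reproduced exactly
        d = np.array(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 4], [6, 6, 4, 0]], dtype=float
        )
        tree = upgma(list("ABCD"), d)
        assert tree.height == pytest.approx(3.0)
        # recover all pairwise distances as 2 * height of the join
        def join_height(t, x, y):
            if t.is_leaf:
                return None
            for c in t.children:
                h = join_height(c, x, y)
                if h is not None:
                    return h
            return t.height if {x, y} <= set(t.leaves()) else None

        for i, x in enumerate("ABCD"):
            for j, y in enumerate("ABCD"):
                if i < j:
                    assert 2 * join_height(tree, x, y) == pytest.approx(d[i, j])

    def test_bootstrap_separates_simulated_clusters(self):
        # two blocks of areas at different divergence: the split is supported
        rng = np.random.default_rng(5)
        k = 12
        anc1, anc2 = rng.dirichlet(np.ones(k), 2)
        genos = {}
        for name, anc in (("X", anc1), ("Y", anc2)):
            for i in range(2):
                p = rng.dirichlet(anc * 60)  # tight within-cluster scatter
                genos[f"{name}{i}"] = [
                    [tuple(rng.choice(k, size=2, p=p) + 1) for _ in range(20)]
                    for _ in range(25)
                ]
        ds = make_dataset(
            {a: g for a, g in genos.items()},
        )
        tree = upgma_bootstrap(ds, n_boot=200, seed=5)
        split = frozenset({"X0", "X1"})
        found = {c: s for c, s in tree.supports.items()}
        assert split in found and found[split] > 95

    def test_monotone_heights(self):
        ds, _ = simulate_dataset(SimConfig(n_areas=6, n_loci=8, fst=0.1, seed=6))
        tree = upgma_bootstrap(ds, n_boot=50, seed=6).tree

        def check(node):
            for c in node.children:
                if not c.is_leaf:
                    assert c.height <= node.height + 1e-12
                    check(c)

        check(tree)


class TestMantel:
    def test_identity_matrices(self):
        rng = np.random.default_rng(7)
        pts = rng.random((8, 2))
        x = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        r, p = mantel_test(x, x.copy(), n_perm=999, seed=7)
        assert r == pytest.approx(1.0)
        assert p <= 1 / 999 + 1e-6

    def test_three_labels_full_enumeration(self):
        x = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0]], dtype=float)
        y = np.array([[0, 2, 1], [2, 0, 5], [1, 5, 0]], dtype=float)
        r, p = mantel_test(x, y)
        # oracle: enumerate the 6 joint relabelings by hand
        tri = np.tril_indices(3, -1)
        xv = x[tri]
        rs = []
        for perm in itertools.permutations(range(3)):
            yp = y[np.ix_(perm, perm)]
            rs.append(np.corrcoef(xv, yp[tri])[0, 1])
        expect = sum(v >= rs[0] - 1e-12 for v in rs) / 6
        assert p == pytest.approx(expect)

    def test_joint_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        pts = rng.random((7, 2))
        x = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        y = x + rng.normal(0, 0.05, x.shape)
        y = (y + y.T) / 2
        np.fill_diagonal(y, 0)
        r1, _ = mantel_test(x, y, n_perm=99, seed=1)
        perm = rng.permutation(7)
        r2, _ = mantel_test(x[np.ix_(perm, perm)], y[np.ix_(perm, perm)], n_perm=99, seed=1)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            mantel_test(np.ones((4, 4)), np.ones((4, 4)))
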