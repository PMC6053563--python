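"""Loiselle kinship against a longhand oracle and pedigree simulations;
group coancestry and Ne closed forms."""

import numpy as np
import pytest

from ssrpopgen.coancestry import (
    coancestry_summary,
    effective_size,
    group_coancestry,
    loiselle_kinship,
)
from ssrpopgen.simulate import SimConfig, simulate_dataset

from conftest import make_dataset


def loiselle_oracle(calls):
    """Term-by-term longhand Loiselle evaluation (plain loops, own freqs)."""
    n_ind, n_loci, _ = calls.shape
    num = np.zeros((n_ind, n_ind))
    den = np.zeros((n_ind, n_ind))
    for l in range(n_loci):
        g = calls[:, l, :]
        typed = [i for i in range(n_ind) if g[i, 0] != 0]
        genes = [int(g[i, c]) for i in typed for c in (0, 1)]
        alleles = sorted(set(genes))
        if len(alleles) < 2:
            continue
        n2 = len(genes)
        for i in typed:
            for j in typed:
                if i == j:
                    continue
                for a in alleles:
                    p = genes.count(a) / n2
                    xi = (int(g[i, 0] == a) + int(g[i, 1] == a)) / 2
                    xj = (int(g[j, 0] == a) + int(g[j, 1] == a)) / 2
                    num[i, j] += (xi - p) * (xj - p) + p * (1 - p) / (n2 - 1)
                    den[i, j] += p * (1 - p)
    with np.errstate(invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


class TestLoiselle:
    def test_matches_longhand_oracle(self):
        ds = make_dataset(
            {"A": [[(1, 2), (3, 3)], [(1, 1), (3, 4)], [(2, 2), (4, 4)]]}
        )
        kin = loiselle_kinship(ds, "A")
        oracle = loiselle_oracle(ds.calls["A"])
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert kin[i, j] == pytest.approx(oracle[i, j], abs=1e-12)

    def test_null_expectation_zero(self):
        ds, _ = simulate_dataset(
            SimConfig(n_areas=1, individuals_per_area=(100, 100), n_loci=20, seed=23)
        )
        kin = loiselle_kinship(ds, ds.areas[0])
        off = kin[~np.eye(kin.shape[0], dtype=bool)]
        assert np.nanmean(off) == pytest.approx(0.0, abs=0.01)

    def test_full_sibs_near_quarter(self):
        # simulate 100 sib pairs from random parents at 20 loci, k=10
        rng = np.random.default_rng(29)
        n_loci, k = 20, 10
        freqs = [rng.dirichlet(np.ones(k)) for _ in range(n_loci)]
        genos = []
        for _ in range(100):
            mom = [(rng.choice(k, p=f) + 1, rng.choice(k, p=f) + 1) for f in freqs]
            dad = [(rng.choice(k, p=f) + 1, rng.choice(k, p=f) + 1) for f in freqs]
            for _ in range(2):  # two sibs
                genos.append(
                    [
                        (m[rng.integers(2)], d[rng.integers(2)])
                        for m, d in zip(mom, dad)
                    ]
                )
        ds = make_dataset({"A": genos})
        kin = loiselle_kinship(ds, "A")
        sib_values = [kin[2 * i, 2 * i + 1] for i in range(100)]
        assert np.mean(sib_values) == pytest.approx(0.25, abs=0.05)


class TestGroupCoancestry:
    def test_unrelated_noninbred_closed_form(self):
        n = 10
        kin = np.zeros((n, n))
        np.fill_diagonal(kin, np.nan)
        theta, _, _ = group_coancestry(kin, fis=0.0, n=n)
        assert theta == pytest.approx(1 / (2 * n))

    def test_clonal_group(self):
        n = 8
        kin = np.full((n, n), 0.5)
        np.fill_diagonal(kin, np.nan)
        theta, _, _ = group_coancestry(kin, fis=0.0, n=n)
        assert theta == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        n = 20
        kin = np.full((n, n), 0.02)
        np.fill_diagonal(kin, np.nan)
        theta, _, _ = group_coancestry(kin, fis=0.1, n=n)
        assert theta == pytest.approx((20 * 0.55 + 380 * 0.02) / 400)


class TestEffectiveSize:
    def test_unrelated_sample(self):
        ne, ratio = effective_size(0.025, 0.0, 20)
        assert ne == pytest.approx(0.5 / 0.04875)
        assert ratio == pytest.approx(ne / 20)

    def test_monoculture_limit(self):
        ne, _ = effective_size(0.5, 1.0, 10_000)
        assert ne == pytest.approx(1.0, abs=1e-3)

    def test_strictly_decreasing_in_theta_and_f(self):
        grid_t = np.linspace(0.02, 0.5, 8)
        grid_f = np.linspace(0.0, 0.9, 8)
        nes_t = [effective_size(t, 0.1, 30)[0] for t in grid_t]
        nes_f = [effective_size(0.1, f, 30)[0] for f in grid_f]
        assert all(a > b for a, b in zip(nes_t, nes_t[1:]))
        assert all(a > b for a, b in zip(nes_f, nes_f[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            effective_size(0.0, 0.0, 20)
        with pytest.raises(ValueError):
            effective_size(0.1, 0.0, 1)


class TestAreaDriver:
    def test_random_mating_representativeness(self):
        # for an unrelated non-inbred sample the formula fixes Ne/N at
        # n/(2n-1) ~ 1/2; the estimate should sit on that closed form
        ratios = []
        for seed in range(10):
            ds, _ = simulate_dataset(
                SimConfig(n_areas=1, individuals_per_area=(30, 30), n_loci=20, seed=seed)
            )
            res = coancestry_summary(ds, ds.areas[0])
            ratios.append(res.ne_over_n)
        assert np.mean(ratios) == pytest.approx(30 / 59, abs=0.05)

    def test_sib_structure_reduces_ne(self):
        # one family-structured area among unrelated areas: with the pooled
        # reference its within-area coancestry rises and Ne falls
        rng = np.random.default_rng(31)
        n_loci, k = 15, 8
        freqs = [rng.dirichlet(np.ones(k)) for _ in range(n_loci)]

        def draw_ind():
            return [(rng.choice(k, p=f) + 1, rng.choice(k, p=f) + 1) for f in freqs]

        sib_genos = []
        for _ in range(5):
            mom, dad = draw_ind(), draw_ind()
            for _ in range(6):
                sib_genos.append(
                    [(m[rng.integers(2)], d[rng.integers(2)]) for m, d in zip(mom, dad)]
                )
        unrelated = {f"U{i}": [draw_ind() for _ in range(30)] for i in range(2)}
        ds = make_dataset({"SIB": sib_genos, **unrelated})
        ne_sib = coancestry_summary(ds, "SIB").ne
        ne_unrel = coancestry_summary(ds, "U1").ne
        assert ne_sib < ne_unrel
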