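"""Exact tests of Hardy–Weinberg and linkage equilibrium, and null-allele EM.

The HWE test is the Markov-chain exact test on genotype tables with fixed
allele counts: uniform random re-pairing of genes (a random-transposition
walk over allele arrangements) whose stationary distribution induces
exactly Levene's conditional distribution over genotype tables. The
p-value is Fisher-style probability-ordered: the chain fraction of tables
no more probable than the observed one, reported with a batch-based Monte
Carlo standard error.

The LD test is the genotypic (phase-free) test of independence on the
two-locus genotype contingency table, a Metropolis chain over tables with
fixed margins under the multiple-hypergeometric null, ordered by the
log-likelihood-ratio statistic.

The null-allele estimator is the EM algorithm of Dempster et al. under
HWE with one unobservable null state: each apparent homozygote is a
mixture of a true homozygote and a visible/null heterozygote, and blank
genotypes are treated as candidate null/null homozygotes.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeDataset

__all__ = [
    "MCTestResult",
    "NullAlleleResult",
    "TestGrid",
    "hwe_exact_mc",
    "ld_exact_mc",
    "null_allele_em",
    "bonferroni_adjust",
    "hwe_grid",
    "ld_grid",
    "null_allele_grid",
    "derive_seed",
]

def _logfact(n: int) -> float:
    return math.lgamma(n + 1)


def derive_seed(global_seed: int, *tokens) -> int:
    """Stable per-test seed from a global seed and identifying tokens."""
    h = zlib.crc32(repr(tokens).encode())
    return (int(global_seed) * 1_000_003 + h) % (2**31 - 1)


@dataclass
class MCTestResult:
    pvalue: float
    se: float
    n_iter: int


def _typed_genotypes(dataset: GenotypeDataset, area: str, locus_idx: int) -> np.ndarray:
    g = dataset.calls[area][:, locus_idx, :]
    return g[g[:, 0] != MISSING]


def hwe_exact_mc(
    genotypes: np.ndarray,
    dememorization: int = 10_000,
    batches: int = 100,
    iterations_per_batch: int = 10_000,
    seed: int | None = None,
) -> MCTestResult:
    """Markov-chain exact HWE test on an (n, 2) array of typed genotypes.

    Returns the probability-ordered p-value with its batch standard error.
    Raises on monomorphic input (the test is undefined).
    """
    genotypes = np.asarray(genotypes)
    n = genotypes.shape[0]
    if n < 2 or np.unique(genotypes).size < 2:
        raise ValueError("HWE test needs >= 2 individuals and >= 2 alleles")
    rng = np.random.default_rng(seed)

    genes = genotypes.astype(np.int64).copy()  # (n, 2), mutated in place
    log2 = math.log(2.0)

    counts: dict[tuple[int, int], int] = {}
    for a, b in genes:
        key = (a, b) if a <= b else (b, a)
        counts[key] = counts.get(key, 0) + 1
    # score = h*log2 - sum log n_ij! ; higher score <=> more probable table
    score = 0.0
    for (a, b), c in counts.items():
        if a != b:
            score += c * log2
        score -= _logfact(c)
    obs_score = score
    tol = 1e-9

    def step() -> None:
        nonlocal score
        u = int(rng.integers(n))
        v = int(rng.integers(n - 1))
        if v >= u:
            v += 1
        pu = int(rng.integers(2))
        pv = int(rng.integers(2))
        au, av = genes[u, pu], genes[v, pv]
        gu_old = tuple(sorted(genes[u]))
        gv_old = tuple(sorted(genes[v]))
        genes[u, pu], genes[v, pv] = av, au
        gu_new = tuple(sorted(genes[u]))
        gv_new = tuple(sorted(genes[v]))
        if gu_old == gu_new and gv_old == gv_new:
            return
        for key in (gu_old, gv_old):
            c = counts[key]
            score += _logfact(c) - _logfact(c - 1)
            if key[0] != key[1]:
                score -= log2
            if c == 1:
                del counts[key]
            else:
                counts[key] = c - 1
        for key in (gu_new, gv_new):
            c = counts.get(key, 0)
            score += _logfact(c) - _logfact(c + 1)
            if key[0] != key[1]:
                score += log2
            counts[key] = c + 1

    for _ in range(dememorization):
        step()
    batch_means = np.empty(batches)
    for b in range(batches):
        hits = 0
        for _ in range(iterations_per_batch):
            step()
            if score <= obs_score + tol:
                hits += 1
        batch_means[b] = hits / iterations_per_batch
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(batches)) if batches > 1 else float("nan")
    return MCTestResult(pvalue=p, se=se, n_iter=batches * iterations_per_batch)


def _geno_key(pair: np.ndarray) -> tuple[int, int]:
    a, b = int(pair[0]), int(pair[1])
    return (a, b) if a <= b else (b, a)


def ld_exact_mc(
    genotypes1: np.ndarray,
    genotypes2: np.ndarray,
    dememorization: int = 10_000,
    batches: int = 100,
    iterations_per_batch: int = 10_000,
    seed: int | None = None,
) -> MCTestResult:
    """Markov-chain exact test of independence between two loci (genotypic LD).

    Both inputs are (n, 2) genotype arrays for the same individuals; rows
    with a missing genotype at either locus must be removed beforehand.
    Tables are ordered by the log-likelihood-ratio statistic.
    """
    g1 = np.asarray(genotypes1)
    g2 = np.asarray(genotypes2)
    if g1.shape[0] != g2.shape[0]:
        raise ValueError("genotype arrays must align")
    cats1 = sorted({_geno_key(r) for r in g1})
    cats2 = sorted({_geno_key(r) for r in g2})
    if len(cats1) < 2 or len(cats2) < 2:
        raise ValueError("LD test needs >= 2 distinct genotypes at each locus")
    i1 = {c: i for i, c in enumerate(cats1)}
    i2 = {c: i for i, c in enumerate(cats2)}
    table = np.zeros((len(cats1), len(cats2)), dtype=np.int64)
    for r1, r2 in zip(g1, g2):
        table[i1[_geno_key(r1)], i2[_geno_key(r2)]] += 1

    rng = np.random.default_rng(seed)
    R, Cn = table.shape

    def llr_term(x: int) -> float:
        return x * math.log(x) if x > 0 else 0.0

    stat = float(sum(llr_term(int(x)) for x in table.ravel()))
    obs_stat = stat
    tol = 1e-9

    def step() -> None:
        nonlocal stat
        r1 = int(rng.integers(R))
        r2 = int(rng.integers(R - 1))
        if r2 >= r1:
            r2 += 1
        c1 = int(rng.integers(Cn))
        c2 = int(rng.integers(Cn - 1))
        if c2 >= c1:
            c2 += 1
        # propose +1 on (r1,c1),(r2,c2) and -1 on (r1,c2),(r2,c1)
        x11, x12, x21, x22 = table[r1, c1], table[r1, c2], table[r2, c1], table[r2, c2]
        if x12 == 0 or x21 == 0:
            return
        ratio = (x12 * x21) / ((x11 + 1) * (x22 + 1))
        if rng.random() < min(1.0, ratio):
            table[r1, c1] += 1
            table[r2, c2] += 1
            table[r1, c2] -= 1
            table[r2, c1] -= 1
            stat += (
                llr_term(x11 + 1)
                - llr_term(x11)
                + llr_term(x22 + 1)
                - llr_term(x22)
                + llr_term(x12 - 1)
                - llr_term(x12)
                + llr_term(x21 - 1)
                - llr_term(x21)
            )

    for _ in range(dememorization):
        step()
    batch_means = np.empty(batches)
    for b in range(batches):
        hits = 0
        for _ in range(iterations_per_batch):
            step()
            if stat >= obs_stat - tol:
                hits += 1
        batch_means[b] = hits / iterations_per_batch
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(batches)) if batches > 1 else float("nan")
    return MCTestResult(pvalue=p, se=se, n_iter=batches * iterations_per_batch)


@dataclass
class NullAlleleResult:
    r: float
    visible_freqs: dict[int, float]
    loglik: float
    n_iter: int
    converged: bool

    @property
    def flagged(self) -> bool:
        """True when the estimate exceeds the conventional 0.20 alarm level."""
        return self.r > 0.20


def _na_loglik(
    het: dict[tuple[int, int], int],
    hom: dict[int, int],
    m: int,
    p: dict[int, float],
    r: float,
) -> float:
    ll = 0.0
    for (i, j), c in het.items():
        ll += c * math.log(max(2 * p[i] * p[j], 1e-300))
    for i, c in hom.items():
        ll += c * math.log(max(p[i] ** 2 + 2 * p[i] * r, 1e-300))
    if m:
        ll += m * math.log(max(r * r, 1e-300))
    return ll


def null_allele_em(
    genotypes: np.ndarray,
    n_missing: int = 0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> NullAlleleResult:
    """EM estimate of the null-allele frequency at one (area, locus).

    ``genotypes`` is the (n, 2) array of typed calls; ``n_missing`` counts
    blank individuals, treated as candidate null/null homozygotes. Iterates
    expected gene counts until the largest frequency change is below
    ``tol``; the observed-data log-likelihood is non-decreasing.
    """
    genotypes = np.asarray(genotypes)
    het: dict[tuple[int, int], int] = {}
    hom: dict[int, int] = {}
    for a, b in genotypes:
        a, b = int(a), int(b)
        if a == b:
            hom[a] = hom.get(a, 0) + 1
        else:
            key = (a, b) if a < b else (b, a)
            het[key] = het.get(key, 0) + 1
    alleles = sorted(set(hom) | {x for k in het for x in k})
    if not alleles:
        raise ValueError("no typed genotypes")
    n_ind = genotypes.shape[0] + n_missing
    total_genes = 2 * n_ind

    # start: observed frequencies shrunk to make room for a small null freq
    p = {a: 0.0 for a in alleles}
    for (i, j), c in het.items():
        p[i] += c
        p[j] += c
    for i, c in hom.items():
        p[i] += 2 * c
    denom = sum(p.values())
    r = 0.05 if (hom or n_missing) else 1e-6
    p = {a: v / denom * (1 - r) for a, v in p.items()}

    prev_ll = -math.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        counts = {a: 0.0 for a in alleles}
        null_count = 2.0 * n_missing
        for (i, j), c in het.items():
            counts[i] += c
            counts[j] += c
        for i, c in hom.items():
            pi = p[i]
            w = pi / (pi + 2 * r) if (pi + 2 * r) > 0 else 1.0
            counts[i] += c * (1 + w)
            null_count += c * (1 - w)
        new_p = {a: counts[a] / total_genes for a in alleles}
        new_r = null_count / total_genes
        delta = max(
            abs(new_r - r), max(abs(new_p[a] - p[a]) for a in alleles)
        )
        p, r = new_p, new_r
        ll = _na_loglik(het, hom, n_missing, p, r)
        if ll + 1e-9 < prev_ll:
            raise RuntimeError("EM log-likelihood decreased")
        prev_ll = ll
        if delta < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(f"null-allele EM did not converge in {max_iter} iterations")
    return NullAlleleResult(
        r=float(r),
        visible_freqs={a: float(v) for a, v in p.items()},
        loglik=prev_ll,
        n_iter=it,
        converged=converged,
    )


def bonferroni_adjust(alpha: float, n_tests: int) -> float:
    """Bonferroni-adjusted per-test significance threshold alpha/n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class TestGrid:
    """Area-by-locus grids of p-values / null-allele estimates with the
    Bonferroni-adjusted thresholds used to flag cells."""

    values: pd.DataFrame
    adjusted_05: float
    adjusted_01: float


def hwe_grid(
    dataset: GenotypeDataset,
    dememorization: int = 10_000,
    batches: int = 100,
    iterations_per_batch: int = 10_000,
    seed: int = 0,
) -> TestGrid:
    """HWE exact-test p-values for every (area, locus) cell."""
    rows = {}
    for area in dataset.areas:
        row = {}
        for j, locus in enumerate(dataset.loci):
            g = _typed_genotypes(dataset, area, j)
            try:
                res = hwe_exact_mc(
                    g,
                    dememorization,
                    batches,
                    iterations_per_batch,
                    seed=derive_seed(seed, "hwe", area, locus),
                )
                row[locus] = res.pvalue
            except ValueError:
                row[locus] = float("nan")
        rows[area] = row
    df = pd.DataFrame(rows).T.loc[dataset.areas, dataset.loci]
    n_tests = int(df.notna().sum().sum())
    return TestGrid(
        values=df,
        adjusted_05=bonferroni_adjust(0.05, max(n_tests, 1)),
        adjusted_01=bonferroni_adjust(0.01, max(n_tests, 1)),
    )


def ld_grid(
    dataset: GenotypeDataset,
    dememorization: int = 10_000,
    batches: int = 100,
    iterations_per_batch: int = 10_000,
    seed: int = 0,
) -> TestGrid:
    """Genotypic LD p-values for every (area, locus-pair) combination."""
    records = []
    for area in dataset.areas:
        arr = dataset.calls[area]
        for j1 in range(dataset.n_loci):
            for j2 in range(j1 + 1, dataset.n_loci):
                both = (arr[:, j1, 0] != MISSING) & (arr[:, j2, 0] != MISSING)
                g1 = arr[both, j1, :]
                g2 = arr[both, j2, :]
                pair = f"{dataset.loci[j1]}x{dataset.loci[j2]}"
                try:
                    res = ld_exact_mc(
                        g1,
                        g2,
                        dememorization,
                        batches,
                        iterations_per_batch,
                        seed=derive_seed(seed, "ld", area, pair),
                    )
                    p = res.pvalue
                except ValueError:
                    p = float("nan")
                records.append({"area": area, "pair": pair, "pvalue": p})
    df = pd.DataFrame(records)
    n_tests = len(set(df["pair"]))
    return TestGrid(
        values=df,
        adjusted_05=bonferroni_adjust(0.05, max(n_tests, 1)),
        adjusted_01=bonferroni_adjust(0.01, max(n_tests, 1)),
    )


def null_allele_grid(dataset: GenotypeDataset, tol: float = 1e-8) -> pd.DataFrame:
    """EM null-allele frequency for every (area, locus) cell."""
    rows = {}
    for area in dataset.areas:
        arr = dataset.calls[area]
        row = {}
        for j, locus in enumerate(dataset.loci):
            g = arr[:, j, :]
            typed = g[:, 0] != MISSING
            gv = g[typed]
            if gv.shape[0] == 0 or np.unique(gv).size < 2:
                row[locus] = float("nan")
                continue
            res = null_allele_em(gv, n_missing=int((~typed).sum()), tol=tol)
            row[locus] = res.r
        rows[area] = row
    return pd.DataFrame(rows).T.loc[dataset.areas, dataset.loci]
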