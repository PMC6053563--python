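"""Bayesian admixture clustering, the Evanno second-difference criterion,
and discriminant analysis of principal components (DAPC).

The admixture model assigns each gene copy a cluster of origin Z given
cluster allele frequencies P and individual membership proportions Q, and
Gibbs-samples the three blocks:

    Z_{ilc} | P, Q  ~  Categorical( Q_ik * P_{k l a} )
    P_{kl}  | Z     ~  Dirichlet( lambda + allele counts from Z )
    Q_i     | Z     ~  Dirichlet( alpha + copy counts from Z )

with a Metropolis step on the symmetric Dirichlet parameter alpha. The
model evidence is estimated from the post-burn-in log-likelihood trace as
mean(L) - var(L)/2, and the Evanno table turns evidence means and standard
deviations across replicate runs into Delta K.

An optional correlated-frequencies prior (the F-model) shrinks cluster
frequencies toward the pooled empirical frequencies with drift parameter F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import MISSING, GenotypeDataset

__all__ = [
    "ClusterRun",
    "EvannoTable",
    "admixture_gibbs",
    "evanno_delta_k",
    "dirichlet_multinomial_logml",
    "dapc",
]


def _encode(dataset: GenotypeDataset):
    """Stack all individuals; per locus map allele codes to 0..k-1 (-1 missing)."""
    calls = np.concatenate([dataset.calls[a] for a in dataset.areas], axis=0)
    labels = np.concatenate(
        [np.full(dataset.n_individuals(a), a, dtype=object) for a in dataset.areas]
    )
    ids = [i for a in dataset.areas for i in dataset.individuals[a]]
    N, L = calls.shape[0], calls.shape[1]
    X = np.full((N, L, 2), -1, dtype=np.int64)
    allele_maps = []
    for j in range(L):
        g = calls[:, j, :]
        alleles = np.unique(g[g != MISSING])
        amap = {int(a): i for i, a in enumerate(alleles)}
        allele_maps.append(alleles)
        for c in (0, 1):
            col = g[:, c]
            typed = col != MISSING
            X[typed, j, c] = np.searchsorted(alleles, col[typed])
    return X, allele_maps, labels, ids


@dataclass
class ClusterRun:
    K: int
    seed: int | None
    sweeps: int
    burn_in: int
    q_mean: np.ndarray  # (N, K)
    p_mean: list[np.ndarray]  # per locus (K, k_l)
    loglik_trace: np.ndarray
    ln_prob: float
    alpha: float
    individual_ids: list[str]
    area_labels: np.ndarray


def dirichlet_multinomial_logml(counts: np.ndarray, lam: float = 1.0) -> float:
    """Closed-form log marginal likelihood of allele counts under a
    symmetric Dirichlet(lam) frequency prior (one population), including
    the per-individual heterozygote ordering factor for diploid data is
    omitted — this matches the sampler's likelihood convention of summing
    over unordered gene copies."""
    counts = np.asarray(counts, dtype=float)
    k = counts.size
    n = counts.sum()
    return float(
        gammaln(lam * k)
        - gammaln(lam * k + n)
        + (gammaln(lam + counts) - gammaln(lam)).sum()
    )


def _categorical_rows(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Sample one index per row of an unnormalised probability matrix."""
    cum = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0]) * cum[:, -1]
    return (cum < u[:, None]).sum(axis=1)


def admixture_gibbs(
    dataset: GenotypeDataset,
    K: int,
    sweeps: int = 2_000,
    burn_in: int = 500,
    seed: int | None = None,
    lam: float = 1.0,
    alpha0: float = 1.0,
    update_alpha: bool = True,
    correlated_f: float | None = None,
) -> ClusterRun:
    """Run the admixture Gibbs sampler at a fixed number of clusters K.

    ``correlated_f`` switches on the F-model prior: cluster frequencies are
    shrunk toward the pooled sample frequencies with drift parameter F.
    Deterministic given ``seed``. Clusters are relabelled by decreasing
    total membership at the end of the run.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if sweeps <= burn_in:
        raise ValueError("sweeps must exceed burn_in")
    rng = np.random.default_rng(seed)
    X, allele_maps, labels, ids = _encode(dataset)
    N, L = X.shape[0], X.shape[1]
    k_per_locus = [m.size for m in allele_maps]

    # F-model prior pseudocounts; lam elsewhere
    prior: list[np.ndarray] = []
    for j in range(L):
        if correlated_f is not None:
            pool = np.zeros(k_per_locus[j])
            g = X[:, j, :]
            for c in (0, 1):
                idx, cnt = np.unique(g[:, c][g[:, c] >= 0], return_counts=True)
                pool[idx] += cnt
            pool = pool / pool.sum()
            prior.append(pool * (1 - correlated_f) / correlated_f)
        else:
            prior.append(np.full(k_per_locus[j], lam))

    alpha = alpha0
    Q = rng.dirichlet(np.full(K, alpha), size=N)
    P = [rng.dirichlet(np.full(k, 1.0), size=K) for k in k_per_locus]
    Z = np.zeros((N, L, 2), dtype=np.int64)

    q_acc = np.zeros((N, K))
    p_acc = [np.zeros((K, k)) for k in k_per_locus]
    trace = np.empty(sweeps)
    kept = 0
    for sweep in range(sweeps):
        # Z | P, Q and sufficient statistics
        copy_counts = np.zeros((N, K))
        allele_counts = [np.zeros((K, k)) for k in k_per_locus]
        loglik = 0.0
        for j in range(L):
            Pj = P[j]  # (K, k_j)
            for c in (0, 1):
                x = X[:, j, c]
                typed = x >= 0
                if not typed.any():
                    continue
                lik = Pj[:, x[typed]].T  # (n_typed, K)
                w = Q[typed] * lik
                tot = w.sum(axis=1)
                loglik += float(np.log(np.maximum(tot, 1e-300)).sum())
                z = _categorical_rows(rng, w)
                Z[typed, j, c] = z
                np.add.at(copy_counts, (np.where(typed)[0], z), 1.0)
                np.add.at(allele_counts[j], (z, x[typed]), 1.0)
        trace[sweep] = loglik
        # P | Z
        for j in range(L):
            conc = allele_counts[j] + prior[j]
            gam = rng.standard_gamma(conc)
            P[j] = gam / gam.sum(axis=1, keepdims=True)
        # Q | Z
        gam = rng.standard_gamma(copy_counts + alpha)
        Q = gam / gam.sum(axis=1, keepdims=True)
        # alpha Metropolis (uniform prior on (0, 10])
        if update_alpha and K > 1:
            prop = alpha + rng.normal(0, 0.05)
            if 0 < prop <= 10:
                logq = np.log(np.maximum(Q, 1e-300)).sum()
                cur = N * (gammaln(K * alpha) - K * gammaln(alpha)) + (alpha - 1) * logq
                new = N * (gammaln(K * prop) - K * gammaln(prop)) + (prop - 1) * logq
                if math.log(rng.random() + 1e-300) < new - cur:
                    alpha = prop
            alpha = min(max(alpha, 1e-3), 10.0)
        if sweep >= burn_in:
            q_acc += Q
            for j in range(L):
                p_acc[j] += P[j]
            kept += 1

    q_mean = q_acc / kept
    p_mean = [a / kept for a in p_acc]
    order = np.argsort(-q_mean.sum(axis=0), kind="stable")
    q_mean = q_mean[:, order]
    p_mean = [pm[order] for pm in p_mean]
    post = trace[burn_in:]
    ln_prob = float(post.mean() - post.var(ddof=1) / 2) if post.size > 1 else float(post.mean())
    return ClusterRun(
        K=K,
        seed=seed,
        sweeps=sweeps,
        burn_in=burn_in,
        q_mean=q_mean,
        p_mean=p_mean,
        loglik_trace=trace,
        ln_prob=ln_prob,
        alpha=float(alpha),
        individual_ids=ids,
        area_labels=labels,
    )


@dataclass
class EvannoTable:
    """Evidence means/sds per K with first and second differences and Delta K."""

    table: pd.DataFrame
    best_k: int


def evanno_delta_k(runs_by_k: dict[int, list[float]]) -> EvannoTable:
    """Delta K = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) over replicate runs.

    ``runs_by_k`` maps K to the replicate ln-prob values; at least three
    consecutive K with two replicates each are required. Delta K is
    undefined at the K extremes and wherever sd is zero.
    """
    ks = sorted(runs_by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    rows = []
    for K in ks:
        vals = np.asarray(runs_by_k[K], dtype=float)
        if vals.size < 2:
            raise ValueError(f"K={K} needs >= 2 replicates")
        rows.append({"K": K, "mean_lnP": vals.mean(), "sd_lnP": vals.std(ddof=1)})
    df = pd.DataFrame(rows).set_index("K")
    means = df["mean_lnP"]
    df["lprime"] = means.diff()
    delta = []
    for K in ks:
        if K == ks[0] or K == ks[-1]:
            delta.append(float("nan"))
            continue
        sd = df.loc[K, "sd_lnP"]
        second = means[K + 1] - 2 * means[K] + means[K - 1]
        delta.append(abs(second) / sd if sd > 0 else float("nan"))
    df["delta_K"] = delta
    valid = df["delta_K"].dropna()
    if valid.empty:
        raise ValueError("Delta K undefined everywhere (zero sd?)")
    return EvannoTable(table=df, best_k=int(valid.idxmax()))


@dataclass
class DapcResult:
    coordinates: np.ndarray  # (N, n_da)
    var_explained: np.ndarray  # per discriminant function
    groups: np.ndarray
    individual_ids: list[str]
    n_pca: int


def dapc(
    dataset: GenotypeDataset,
    groups: np.ndarray | list[str] | None = None,
    n_pca: int = 10,
    n_da: int | None = None,
) -> DapcResult:
    """Discriminant analysis of principal components on allele dosages.

    The centred and scaled individual-by-allele dosage matrix is reduced to
    ``n_pca`` principal components, then linear discriminant analysis on the
    group labels yields up to ``min(groups-1, n_pca)`` discriminant
    functions. Missing dosages are mean-imputed.
    """
    from sklearn.decomposition import PCA
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    X, _, labels, ids = _encode(dataset)
    if groups is None:
        groups = labels
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if (counts < 2).any():
        bad = uniq[counts < 2][0]
        raise ValueError(f"group {bad!r} has a single member")
    # dosage matrix
    blocks = []
    for j in range(X.shape[1]):
        k = int(X[:, j, :].max()) + 1
        block = np.zeros((X.shape[0], k))
        for c in (0, 1):
            col = X[:, j, c]
            typed = col >= 0
            block[typed, col[typed]] += 1
        miss = X[:, j, 0] < 0
        if miss.any():
            block[miss] = block[~miss].mean(axis=0)
        blocks.append(block)
    M = np.hstack(blocks)
    M = M - M.mean(axis=0)
    sd = M.std(axis=0)
    sd[sd == 0] = 1.0
    M = M / sd
    n_pca = min(n_pca, np.linalg.matrix_rank(M))
    pcs = PCA(n_components=n_pca, random_state=0).fit_transform(M)
    max_da = min(uniq.size - 1, n_pca)
    if n_da is None:
        n_da = max_da
    if n_da > max_da:
        raise ValueError(f"n_da cannot exceed {max_da}")
    lda = LinearDiscriminantAnalysis(n_components=n_da)
    coords = lda.fit_transform(pcs, groups)
    return DapcResult(
        coordinates=coords,
        var_explained=lda.explained_variance_ratio_[:n_da],
        groups=groups,
        individual_ids=ids,
        n_pca=n_pca,
    )
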