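"""Heterozygosity-excess bottleneck detection.

A population that recently shrank loses rare alleles faster than gene
diversity, so its expected heterozygosity He exceeds the equilibrium value
Heq expected from its observed allele number k. For each locus this module
simulates the mutation-drift-equilibrium distribution of Heq conditional on
the sample's gene count and allele number, under the infinite-alleles (IAM),
strict stepwise (SMM) or two-phase (TPM) mutation model, via a neutral
coalescent: a genealogy is drawn for the sampled genes, mutations are placed
uniformly on its branches, and replicates are accepted when the resulting
allele number equals the observed k (the mutation rate is first tuned by
bisection so the expected allele number matches).

Per area the per-locus standardized differences DH/sd feed two tests: a
Poisson-binomial sign test on the number of loci in excess, and a two-tailed
Wilcoxon signed-rank test on the DH values (exact by enumeration up to 25
loci, normal approximation with continuity correction above).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .core import MISSING, GenotypeDataset

__all__ = [
    "MutationModel",
    "LocusBottleneck",
    "AreaBottleneck",
    "BottleneckReport",
    "simulate_heq",
    "heterozygosity_excess",
    "sign_test",
    "wilcoxon_signed_rank",
    "bottleneck_report",
]


@dataclass(frozen=True)
class MutationModel:
    """Mutation model spec: 'iam', 'smm' or 'tpm' with its two parameters."""

    name: str = "tpm"
    tpm_pss: float = 0.95  # probability of a single +/-1 step under TPM
    tpm_variance: float = 12.0  # variance of the multi-step jump distribution

    def __post_init__(self) -> None:
        if self.name not in ("iam", "smm", "tpm"):
            raise ValueError("model must be 'iam', 'smm' or 'tpm'")
        if self.name == "tpm":
            if not (0 <= self.tpm_pss <= 1):
                raise ValueError("tpm_pss must be in [0, 1]")
            if self.tpm_variance < 1:
                raise ValueError("tpm_variance must be >= 1")

    def geometric_q(self) -> float:
        """q of the geometric jump magnitude with E[G^2] = tpm_variance."""
        v = self.tpm_variance
        return (-1 + math.sqrt(1 + 8 * v)) / (2 * v)


_COAL_RATES: dict[int, np.ndarray] = {}


def _coalescent_tree(rng: np.random.Generator, n: int):
    """Neutral coalescent genealogy: returns (parent, blen) over 2n-1 nodes,
    leaves 0..n-1, root 2n-2; branch lengths in units of 2N generations."""
    total = 2 * n - 1
    rates = _COAL_RATES.get(n)
    if rates is None:
        j = np.arange(n, 1, -1, dtype=float)
        rates = j * (j - 1) / 2.0
        _COAL_RATES[n] = rates
    node_time = np.zeros(total)
    node_time[n:] = np.cumsum(rng.exponential(1.0, size=n - 1) / rates)
    parent = np.full(total, -1, dtype=np.int64)
    u = rng.random(2 * (n - 1))
    active = list(range(n))
    for step in range(n - 1):
        m = n - step
        i1 = int(u[2 * step] * m)
        i2 = int(u[2 * step + 1] * (m - 1))
        if i2 >= i1:
            i2 += 1
        node = n + step
        parent[active[i1]] = node
        parent[active[i2]] = node
        # swap-remove the higher pick, then overwrite the lower with the
        # new node (lo <= m-2 always, so the slot is still in range)
        hi, lo = (i1, i2) if i1 > i2 else (i2, i1)
        active[hi] = active[-1]
        active.pop()
        active[lo] = node
    blen = np.zeros(total)
    has_parent = parent >= 0
    blen[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
    return parent, blen


def _leaf_states(
    parent: np.ndarray,
    mut_branches: np.ndarray,
    n: int,
    model: MutationModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Allele state of each leaf given the branch index of every mutation."""
    total = parent.size
    state = np.zeros(total, dtype=np.int64)
    if model.name == "iam":
        # only the most recent mutation on a lineage matters: a branch with
        # >= 1 mutation assigns a brand-new allele to everything below it
        label = np.zeros(total, dtype=np.int64)
        fresh = np.unique(mut_branches)
        label[fresh] = np.arange(1, fresh.size + 1)
        for v in range(total - 2, -1, -1):  # parents are always created later
            state[v] = label[v] if label[v] else state[parent[v]]
        return state[:n]
    # stepwise models: sum of signed steps along the path
    m = mut_branches.size
    if model.name == "smm":
        steps = rng.integers(0, 2, size=m) * 2 - 1
    else:
        mags = np.ones(m, dtype=np.int64)
        multi = rng.random(m) >= model.tpm_pss
        n_multi = int(multi.sum())
        if n_multi:
            mags[multi] = rng.geometric(model.geometric_q(), size=n_multi)
        steps = mags * (rng.integers(0, 2, size=m) * 2 - 1)
    deltas = np.zeros(total, dtype=np.int64)
    np.add.at(deltas, mut_branches, steps)
    for v in range(total - 2, -1, -1):
        state[v] = state[parent[v]] + deltas[v]
    return state[:n]


def _unbiased_he(states: np.ndarray) -> float:
    n = states.size
    _, counts = np.unique(states, return_counts=True)
    p2 = float(((counts / n) ** 2).sum())
    return n / (n - 1) * (1 - p2)


def _simulate_once(
    rng: np.random.Generator, n_genes: int, theta: float, model: MutationModel
):
    parent, blen = _coalescent_tree(rng, n_genes)
    cum = np.cumsum(blen)
    total_len = cum[-1]
    n_mut = rng.poisson(theta / 2 * total_len)
    if n_mut == 0:
        return 1, np.zeros(n_genes, dtype=np.int64)
    # place mutations uniformly on total branch length
    mut_branches = np.searchsorted(cum, rng.random(n_mut) * total_len)
    states = _leaf_states(parent, mut_branches, n_genes, model, rng)
    k = int(np.unique(states).size)
    return k, states


def _iam_expected_k(theta: float, n: int) -> float:
    i = np.arange(n)
    return float((theta / (theta + i)).sum())


def _tune_theta(
    rng: np.random.Generator,
    n_genes: int,
    k_obs: int,
    model: MutationModel,
    pilot: int = 120,
    rounds: int = 10,
) -> float:
    """Bisection on log-theta so the mean simulated allele number hits k_obs."""
    # IAM closed form brackets the answer for all models
    lo, hi = 1e-4, 1e5
    f = lambda th: _iam_expected_k(th, n_genes) - k_obs
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    theta = math.sqrt(lo * hi)
    if model.name == "iam":
        return theta
    lo, hi = theta / 30, theta * 30
    for _ in range(rounds):
        mid = math.sqrt(lo * hi)
        ks = [_simulate_once(rng, n_genes, mid, model)[0] for _ in range(pilot)]
        if np.mean(ks) < k_obs:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def simulate_heq(
    n_genes: int,
    k_obs: int,
    model: MutationModel | str = "tpm",
    iterations: int = 1_000,
    seed: int | None = None,
    theta: float | None = None,
) -> np.ndarray:
    """Equilibrium sample of unbiased He values conditional on (n_genes, k_obs).

    Rejection-samples coalescent replicates until ``iterations`` of them show
    exactly ``k_obs`` alleles; aborts if the acceptance rate falls below
    0.1%. ``theta`` overrides the bisection-tuned mutation parameter.
    """
    if isinstance(model, str):
        model = MutationModel(name=model)
    if not (2 <= k_obs <= n_genes):
        raise ValueError("need 2 <= k_obs <= n_genes")
    if iterations < 100:
        raise ValueError("iterations must be >= 100")
    rng = np.random.default_rng(seed)
    if theta is None:
        theta = _tune_theta(rng, n_genes, k_obs, model)
    out = np.empty(iterations)
    accepted = 0
    attempts = 0
    while accepted < iterations:
        k, states = _simulate_once(rng, n_genes, theta, model)
        attempts += 1
        if k == k_obs:
            out[accepted] = _unbiased_he(states)
            accepted += 1
        if attempts >= 2000 and accepted / attempts < 0.001:
            raise RuntimeError(
                f"acceptance rate below 0.1% at n={n_genes}, k={k_obs}; "
                "check the mutation model or supply theta explicitly"
            )
    return out


@dataclass
class LocusBottleneck:
    locus: str
    he_obs: float
    k: int
    n_genes: int
    heq_mean: float
    heq_sd: float
    dh: float
    dh_over_sd: float
    excess: bool
    p_excess: float  # P(Heq < He_obs) under equilibrium


def heterozygosity_excess(
    dataset: GenotypeDataset,
    area: str,
    model: MutationModel | str = "tpm",
    iterations: int = 1_000,
    seed: int | None = None,
    exclude_loci: list[str] | None = None,
) -> list[LocusBottleneck]:
    """Per-locus equilibrium comparison for one area.

    Monomorphic loci (and any explicitly excluded) are skipped. Fewer than
    four usable loci leaves the area tests weakly powered.
    """
    if isinstance(model, str):
        model = MutationModel(name=model)
    exclude = set(exclude_loci or [])
    rng = np.random.default_rng(seed)
    arr = dataset.calls[area]
    out = []
    for j, locus in enumerate(dataset.loci):
        if locus in exclude:
            continue
        g = arr[:, j, :]
        typed = g[:, 0] != MISSING
        gt = g[typed]
        n = gt.shape[0]
        if n < 2:
            continue
        genes = gt.ravel()
        alleles, counts = np.unique(genes, return_counts=True)
        k = int(alleles.size)
        if k < 2:
            continue
        he = _unbiased_he(genes)
        heq = simulate_heq(
            2 * n, k, model, iterations, seed=int(rng.integers(2**31))
        )
        mean, sd = float(heq.mean()), float(heq.std(ddof=1))
        dh = he - mean
        p_exc = float(((heq < he).sum() + 0.5 * (heq == he).sum()) / heq.size)
        p_exc = min(max(p_exc, 1e-6), 1 - 1e-6)
        out.append(
            LocusBottleneck(
                locus=locus,
                he_obs=he,
                k=k,
                n_genes=2 * n,
                heq_mean=mean,
                heq_sd=sd,
                dh=dh,
                dh_over_sd=dh / sd if sd > 0 else float("nan"),
                excess=dh > 0,
                p_excess=p_exc,
            )
        )
    return out


def _poisson_binomial_pmf(probs: np.ndarray) -> np.ndarray:
    """Exact Poisson-binomial pmf over 0..L successes by convolution."""
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1 - p, p])
    return pmf


def sign_test(excess_flags: list[bool], p_excess: list[float]) -> float:
    """Two-tailed sign test on the number of heterozygosity-excess loci.

    Under equilibrium locus l is in excess with probability ``p_excess[l]``
    (from its own null simulation); the count of excess loci is
    Poisson-binomial. The p-value doubles the smaller inclusive tail,
    capped at 1.
    """
    if not excess_flags:
        raise ValueError("need at least one usable locus")
    probs = np.asarray(p_excess, dtype=float)
    if probs.size != len(excess_flags):
        raise ValueError("flags and probabilities must align")
    k = int(sum(excess_flags))
    pmf = _poisson_binomial_pmf(probs)
    p_lo = float(pmf[: k + 1].sum())
    p_hi = float(pmf[k:].sum())
    return min(1.0, 2 * min(p_lo, p_hi))


def wilcoxon_signed_rank(dh_values: np.ndarray) -> float:
    """Two-tailed Wilcoxon signed-rank p for the per-locus DH values.

    Zeros are dropped, ties mid-ranked. Exact null distribution (dynamic
    programming over the 2^L sign assignments) for up to 25 loci, normal
    approximation with continuity correction above.
    """
    d = np.asarray(dh_values, dtype=float)
    d = d[d != 0]
    L = d.size
    if L == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if L <= 25:
        # scale mid-ranks (halves) to integers
        r2 = np.round(ranks * 2).astype(int)
        total = int(r2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in r2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total + 1 - r]
            dist = 0.5 * (dist + shifted)
        w2 = int(round(w_plus * 2))
        p_lo = float(dist[: w2 + 1].sum())
        p_hi = float(dist[w2:].sum())
        return min(1.0, 2 * min(p_lo, p_hi))
    mean = L * (L + 1) / 4
    # tie-corrected variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = L * (L + 1) * (2 * L + 1) / 24 - (tie_counts**3 - tie_counts).sum() / 48
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
    from scipy.stats import norm

    return float(min(1.0, 2 * norm.sf(abs(z))))


@dataclass
class AreaBottleneck:
    area: str
    model: str
    n_deficit: int
    n_excess: int
    sign_p: float
    wilcoxon_p: float
    loci: list[LocusBottleneck] = field(default_factory=list)


@dataclass
class BottleneckReport:
    """Per-area, per-model bottleneck test table."""

    rows: list[AreaBottleneck]
    iterations: int
    seed: int | None


def bottleneck_report(
    dataset: GenotypeDataset,
    models: tuple[str, ...] = ("tpm", "smm"),
    iterations: int = 1_000,
    seed: int | None = None,
    exclude_loci: list[str] | None = None,
    tpm_pss: float = 0.95,
    tpm_variance: float = 12.0,
) -> BottleneckReport:
    """Run the excess tests for every area under each mutation model."""
    rows = []
    rng = np.random.default_rng(seed)
    for area in dataset.areas:
        for name in models:
            model = MutationModel(name=name, tpm_pss=tpm_pss, tpm_variance=tpm_variance)
            loci = heterozygosity_excess(
                dataset,
                area,
                model,
                iterations,
                seed=int(rng.integers(2**31)),
                exclude_loci=exclude_loci,
            )
            if not loci:
                continue
            flags = [l.excess for l in loci]
            probs = [l.p_excess for l in loci]
            rows.append(
                AreaBottleneck(
                    area=area,
                    model=name,
                    n_deficit=sum(not f for f in flags),
                    n_excess=sum(flags),
                    sign_p=sign_test(flags, probs),
                    wilcoxon_p=wilcoxon_signed_rank(np.array([l.dh for l in loci])),
                    loci=loci,
                )
            )
    return BottleneckReport(rows=rows, iterations=iterations, seed=seed)
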