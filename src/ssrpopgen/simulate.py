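"""Synthetic SSR genotype datasets with known ground truth.

Two generators are provided:

* :func:`simulate_dataset` — the workhorse. Area allele frequencies are drawn
  from the Balding–Nichols model: ancestral frequencies ``p`` are Dirichlet(1)
  over the allele states of each locus, and each area draws its own frequency
  vector from ``Dirichlet(p (1-F)/F)``, which has mean ``p`` and expected
  Wright fixation index ``F`` among areas. Within-area inbreeding is induced
  by an identity-by-descent mixture: with probability ``F_IS`` a genotype's
  two genes are copies of a single draw, otherwise two independent draws.
  This gives exact control of the expected F-statistics and is instant to
  sample, which is what estimator-recovery tests need.

* :func:`simulate_bottleneck_history` — a forward Wright–Fisher simulation
  with strict stepwise mutation, used to create areas that genuinely went
  through a recent reduction in size; the main generator cannot produce the
  transient allele-number/heterozygosity disequilibrium a bottleneck leaves.

Null alleles are overlaid afterwards by :func:`apply_null_alleles`: a null /
visible heterozygote is scored as a visible homozygote, a null / null
genotype drops out as missing (the classic apparent-null-homozygote).

Defaults mirror the study design the package targets: 11 areas of 16–30
diploid individuals, 10 loci with 8–14 alleles each, among-area F around
0.04–0.06 and within-area inbreeding 0–0.28.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, GenotypeDataset

__all__ = [
    "BottleneckSpec",
    "SimConfig",
    "SimTruth",
    "simulate_dataset",
    "apply_null_alleles",
    "simulate_bottleneck_history",
]

#: First allele state label; consecutive integers keep SMM ordering meaningful.
BASE_ALLELE = 100


@dataclass
class BottleneckSpec:
    """Recent-bottleneck history: which areas shrink, to what size, how long."""

    areas: list[int]  # indices of bottlenecked areas
    n_b: int = 10  # bottleneck census size (diploids)
    generations: int = 20  # duration of the bottleneck
    n_eq: int = 100  # pre-bottleneck equilibrium size (diploids)
    burn_in: int = 1000  # generations of burn-in toward mutation-drift equilibrium

    def __post_init__(self) -> None:
        if self.n_b < 2:
            raise ValueError("bottleneck size n_b must be >= 2")


@dataclass
class SimConfig:
    n_areas: int = 11
    individuals_per_area: tuple[int, int] = (16, 30)
    n_loci: int = 10
    alleles_per_locus: tuple[int, int] = (8, 14)
    fst: float = 0.05
    fis: float = 0.0
    null_freq: float | list[float] = 0.0
    missing_rate: float = 0.0
    mu: float = 5e-4  # SSR stepwise mutation rate (forward simulation only)
    bottleneck: BottleneckSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fst < 1):
            raise ValueError("fst must be in [0, 1)")
        if not (0 <= self.fis < 1):
            raise ValueError("fis must be in [0, 1)")
        nulls = self.null_freq if isinstance(self.null_freq, list) else [self.null_freq]
        if any(not (0 <= r < 1) for r in nulls):
            raise ValueError("null_freq must be in [0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_areas < 1 or self.n_loci < 1:
            raise ValueError("counts must be positive")

    def null_freqs(self) -> list[float]:
        if isinstance(self.null_freq, list):
            if len(self.null_freq) != self.n_loci:
                raise ValueError("per-locus null_freq list must have n_loci entries")
            return list(self.null_freq)
        return [self.null_freq] * self.n_loci


@dataclass
class SimTruth:
    """Ground truth emitted next to a simulated dataset."""

    ancestral_freqs: list[np.ndarray]
    area_freqs: dict[str, list[np.ndarray]]
    allele_states: list[np.ndarray]
    fst: float
    fis: float
    null_freq: list[float] = field(default_factory=list)
    bottleneck_flags: dict[str, bool] = field(default_factory=dict)


def _area_labels(n: int) -> list[str]:
    return [f"A{i + 1:02d}" for i in range(n)]


def simulate_dataset(config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Draw a multi-area SSR dataset under the Balding–Nichols / IBD-mixture model.

    Deterministic given ``config.seed``. Null alleles and missing data are
    applied after genotype draws, in that order.
    """
    rng = np.random.default_rng(config.seed)
    labels = _area_labels(config.n_areas)
    lo, hi = config.individuals_per_area
    n_ind = rng.integers(lo, hi + 1, size=config.n_areas)
    klo, khi = config.alleles_per_locus
    k_per_locus = rng.integers(klo, khi + 1, size=config.n_loci)

    ancestral: list[np.ndarray] = []
    states: list[np.ndarray] = []
    area_freqs: dict[str, list[np.ndarray]] = {a: [] for a in labels}
    for k in k_per_locus:
        p = rng.dirichlet(np.ones(k))
        ancestral.append(p)
        states.append(np.arange(BASE_ALLELE, BASE_ALLELE + k))
    for a in labels:
        for p in ancestral:
            if config.fst == 0:
                area_freqs[a].append(p.copy())
            else:
                scale = (1 - config.fst) / config.fst
                area_freqs[a].append(rng.dirichlet(p * scale))

    loci = [f"L{j + 1:02d}" for j in range(config.n_loci)]
    individuals: dict[str, list[str]] = {}
    calls: dict[str, np.ndarray] = {}
    for ai, a in enumerate(labels):
        n = int(n_ind[ai])
        individuals[a] = [f"{a}_{i + 1:03d}" for i in range(n)]
        arr = np.empty((n, config.n_loci, 2), dtype=np.int64)
        for j in range(config.n_loci):
            p = area_freqs[a][j]
            st = states[j]
            g1 = rng.choice(st, size=n, p=p)
            g2 = rng.choice(st, size=n, p=p)
            ibd = rng.random(n) < config.fis
            g2 = np.where(ibd, g1, g2)
            arr[:, j, 0] = g1
            arr[:, j, 1] = g2
        calls[a] = arr

    dataset = GenotypeDataset(areas=labels, individuals=individuals, loci=loci, calls=calls)
    nulls = config.null_freqs()
    if any(r > 0 for r in nulls):
        dataset, _ = apply_null_alleles(dataset, nulls, rng=rng)
    if config.missing_rate > 0:
        for a in labels:
            arr = dataset.calls[a]
            drop = rng.random(arr.shape[:2]) < config.missing_rate
            arr[drop] = MISSING
    truth = SimTruth(
        ancestral_freqs=ancestral,
        area_freqs=area_freqs,
        allele_states=states,
        fst=config.fst,
        fis=config.fis,
        null_freq=nulls,
        bottleneck_flags={a: False for a in labels},
    )
    return dataset, truth


def apply_null_alleles(
    dataset: GenotypeDataset,
    null_freq: float | list[float],
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[GenotypeDataset, int]:
    """Overlay genotyping null alleles on a dataset.

    Each gene independently becomes null with the per-locus probability;
    a null/visible heterozygote is recorded as a visible homozygote and a
    null/null genotype as missing. Returns the new dataset and the number of
    genotype calls altered.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rates = (
        list(null_freq)
        if isinstance(null_freq, (list, tuple, np.ndarray))
        else [float(null_freq)] * dataset.n_loci
    )
    if len(rates) != dataset.n_loci:
        raise ValueError("need one null frequency per locus")
    if any(not (0 <= r <= 1) for r in rates):
        raise ValueError("null frequencies must be in [0, 1]")
    converted = 0
    new_calls: dict[str, np.ndarray] = {}
    for area in dataset.areas:
        arr = dataset.calls[area].copy()
        for j, r in enumerate(rates):
            if r == 0:
                continue
            typed = arr[:, j, 0] != MISSING
            is_null = rng.random((arr.shape[0], 2)) < r
            both = typed & is_null.all(axis=1)
            first = typed & is_null[:, 0] & ~is_null[:, 1]
            second = typed & is_null[:, 1] & ~is_null[:, 0]
            arr[both, j, :] = MISSING
            arr[first, j, 0] = arr[first, j, 1]
            arr[second, j, 1] = arr[second, j, 0]
            converted += int(both.sum() + first.sum() + second.sum())
        new_calls[area] = arr
    out = GenotypeDataset(
        areas=list(dataset.areas),
        individuals={a: list(v) for a, v in dataset.individuals.items()},
        loci=list(dataset.loci),
        calls=new_calls,
    )
    return out, converted


def _wright_fisher_locus(
    rng: np.random.Generator,
    n_eq: int,
    burn_in: int,
    mu: float,
    post_size: int,
    post_generations: int,
) -> np.ndarray:
    """Evolve one locus forward: burn-in at ``n_eq`` diploids, then
    ``post_generations`` at ``post_size``; returns the final gene pool."""
    genes = np.full(2 * n_eq, BASE_ALLELE, dtype=np.int64)
    for size, gens in ((n_eq, burn_in), (post_size, post_generations)):
        for _ in range(gens):
            genes = genes[rng.integers(0, genes.size, size=2 * size)]
            n_mut = rng.binomial(2 * size, mu)
            if n_mut:
                idx = rng.integers(0, genes.size, size=n_mut)
                genes[idx] += rng.integers(0, 2, size=n_mut) * 2 - 1
    return genes


def simulate_bottleneck_history(config: SimConfig) -> tuple[GenotypeDataset, SimTruth]:
    """Forward Wright–Fisher simulation with SMM mutation and optional bottlenecks.

    Every area evolves independently from the same starting state; areas
    listed in ``config.bottleneck.areas`` spend the final ``generations`` at
    the reduced size ``n_b`` while the others stay at ``n_eq``. The final
    generation is sampled to the configured census sizes.
    """
    if config.bottleneck is None:
        raise ValueError("config.bottleneck must be set")
    if config.mu <= 0:
        raise ValueError("mu must be positive for the forward simulation")
    spec = config.bottleneck
    rng = np.random.default_rng(config.seed)
    labels = _area_labels(config.n_areas)
    lo, hi = config.individuals_per_area
    n_ind = rng.integers(lo, hi + 1, size=config.n_areas)
    flagged = {labels[i] for i in spec.areas}

    loci = [f"L{j + 1:02d}" for j in range(config.n_loci)]
    individuals: dict[str, list[str]] = {}
    calls: dict[str, np.ndarray] = {}
    for ai, area in enumerate(labels):
        n = int(n_ind[ai])
        individuals[area] = [f"{area}_{i + 1:03d}" for i in range(n)]
        arr = np.empty((n, config.n_loci, 2), dtype=np.int64)
        is_b = area in flagged
        for j in range(config.n_loci):
            pool = _wright_fisher_locus(
                rng,
                n_eq=spec.n_eq,
                burn_in=spec.burn_in,
                mu=config.mu,
                post_size=spec.n_b if is_b else spec.n_eq,
                post_generations=spec.generations,
            )
            # one more round of WF reproduction into the sample itself, so the
            # sampled census may exceed the (bottlenecked) population size
            sample = rng.choice(pool, size=2 * n, replace=True)
            arr[:, j, 0] = sample[:n]
            arr[:, j, 1] = sample[n:]
        calls[area] = arr

    dataset = GenotypeDataset(areas=labels, individuals=individuals, loci=loci, calls=calls)
    truth = SimTruth(
        ancestral_freqs=[],
        area_freqs={},
        allele_states=[],
        fst=0.0,
        fis=0.0,
        null_freq=[0.0] * config.n_loci,
        bottleneck_flags={a: a in flagged for a in labels},
    )
    return dataset, truth
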