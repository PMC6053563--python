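"""Weir–Cockerham F-statistics, pairwise FST (optionally null-allele
corrected), bootstrap confidence intervals and island-model gene flow.

Variance components follow Weir & Cockerham (1984): per locus and allele,
with ``r`` populations of sizes ``n_i`` (typed individuals), allele
frequencies ``p_i`` and heterozygote frequencies ``h_i``,

    a  — among-population component,
    b  — among-individual within-population component,
    c  — within-individual component,

and the multilocus estimators are ratios of components summed over alleles
and loci: theta = a/(a+b+c), f = 1 - c/(b+c), F = 1 - c/(a+b+c), so the
identity (1-F) = (1-f)(1-theta) holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeDataset

__all__ = [
    "LocusComponents",
    "GlobalFStats",
    "PairwiseMatrix",
    "wc_components",
    "single_pop_components",
    "multilocus_estimates",
    "global_fstats",
    "pairwise_fst",
    "migrants_crow_aoki",
    "classify_fst",
]


@dataclass
class LocusComponents:
    """Summed-over-alleles WC variance components for one locus."""

    locus: str
    a: float
    b: float
    c: float

    @property
    def total(self) -> float:
        return self.a + self.b + self.c


def _pop_stats(arr: np.ndarray, locus_idx: int, alleles: np.ndarray):
    """Per-allele frequency and heterozygote frequency in one area at one locus."""
    g = arr[:, locus_idx, :]
    typed = g[:, 0] != MISSING
    g = g[typed]
    n = g.shape[0]
    if n == 0:
        return 0, None, None
    p = np.array([(g == a).sum() for a in alleles], dtype=float) / (2 * n)
    het = g[:, 0] != g[:, 1]
    h = np.array([((g == a).any(axis=1) & het).sum() for a in alleles], dtype=float) / n
    return n, p, h


def wc_components(
    dataset: GenotypeDataset, grouping: list[str] | None = None
) -> list[LocusComponents]:
    """Per-locus Weir–Cockerham variance components over the given areas.

    Unequal sample sizes enter through the n_c weighting; loci with fewer
    than two populations typed or no variation contribute zero components.
    """
    areas = grouping if grouping is not None else dataset.areas
    if len(areas) < 2:
        raise ValueError("need at least two areas")
    out = []
    for j, locus in enumerate(dataset.loci):
        alleles = set()
        for area in areas:
            g = dataset.calls[area][:, j, :]
            alleles.update(g[g != MISSING].tolist())
        alleles = np.array(sorted(alleles))
        stats = []
        for area in areas:
            n, p, h = _pop_stats(dataset.calls[area], j, alleles)
            if n > 0:
                stats.append((n, p, h))
        if len(stats) < 2 or len(alleles) < 2:
            out.append(LocusComponents(locus, 0.0, 0.0, 0.0))
            continue
        r = len(stats)
        ns = np.array([s[0] for s in stats], dtype=float)
        P = np.stack([s[1] for s in stats])  # (r, n_alleles)
        H = np.stack([s[2] for s in stats])
        nbar = ns.mean()
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        pbar = (ns[:, None] * P).sum(axis=0) / (r * nbar)
        s2 = (ns[:, None] * (P - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (ns[:, None] * H).sum(axis=0) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        out.append(LocusComponents(locus, float(a.sum()), float(b.sum()), float(c.sum())))
    return out


def single_pop_components(
    dataset: GenotypeDataset, area: str
) -> list[tuple[str, float, float]]:
    """Per-locus (b, c) components for one population; f = 1 - sum(c)/sum(b+c).

    The single-population reduction of the WC components: per allele,
    ``b = n/(n-1) [p(1-p) - (2n-1)/(4n) h]`` and ``c = h/2``.
    """
    out = []
    arr = dataset.calls[area]
    for j, locus in enumerate(dataset.loci):
        g = arr[:, j, :]
        typed = g[:, 0] != MISSING
        g = g[typed]
        n = g.shape[0]
        if n < 2:
            out.append((locus, 0.0, 0.0))
            continue
        alleles = np.unique(g)
        if alleles.size < 2:
            out.append((locus, 0.0, 0.0))
            continue
        p = np.array([(g == a).sum() for a in alleles], dtype=float) / (2 * n)
        het = g[:, 0] != g[:, 1]
        h = np.array([((g == a).any(axis=1) & het).sum() for a in alleles], dtype=float) / n
        b = n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)
        c = h / 2
        out.append((locus, float(b.sum()), float(c.sum())))
    return out


def multilocus_estimates(components: list[LocusComponents]) -> tuple[float, float, float]:
    """(f, theta, F) = (F_IS, F_ST, F_IT) from summed components."""
    A = sum(lc.a for lc in components)
    B = sum(lc.b for lc in components)
    C = sum(lc.c for lc in components)
    tot = A + B + C
    if tot == 0:
        return float("nan"), float("nan"), float("nan")
    f = 1 - C / (B + C) if (B + C) != 0 else float("nan")
    theta = A / tot
    F = 1 - C / tot
    return f, theta, F


@dataclass
class GlobalFStats:
    """Global multilocus F-statistics with bootstrap CIs and a theta p-value."""

    fis: float
    fst: float
    fit: float
    fis_ci: tuple[float, float]
    fst_ci: tuple[float, float]
    fit_ci: tuple[float, float]
    fst_pvalue: float
    nm: float
    n_areas: int

    def summary(self) -> str:
        rows = [
            ("F_IS", self.fis, self.fis_ci),
            ("F_ST", self.fst, self.fst_ci),
            ("F_IT", self.fit, self.fit_ci),
        ]
        lines = ["stat\testimate\tCI_low\tCI_high"]
        for name, est, (lo, hi) in rows:
            lines.append(f"{name}\t{est:.3f}\t{lo:.3f}\t{hi:.3f}")
        lines.append(f"N_m\t{self.nm:.2f}\t-\t-")
        lines.append(f"F_ST p-value\t{self.fst_pvalue:.4g}\t-\t-")
        return "\n".join(lines)


def _permuted_dataset(dataset: GenotypeDataset, rng: np.random.Generator) -> GenotypeDataset:
    """Shuffle individuals among areas, keeping area sizes."""
    stacked = np.concatenate([dataset.calls[a] for a in dataset.areas], axis=0)
    perm = rng.permutation(stacked.shape[0])
    stacked = stacked[perm]
    calls = {}
    start = 0
    for a in dataset.areas:
        n = dataset.n_individuals(a)
        calls[a] = stacked[start : start + n]
        start += n
    return GenotypeDataset(
        areas=list(dataset.areas),
        individuals={a: list(v) for a, v in dataset.individuals.items()},
        loci=list(dataset.loci),
        calls=calls,
    )


def global_fstats(
    dataset: GenotypeDataset,
    n_boot: int = 10_000,
    n_perm: int = 1_000,
    ci_level: float = 0.95,
    seed: int | None = None,
) -> GlobalFStats:
    """Multilocus F_IS/F_ST/F_IT with bootstrap-over-loci CIs.

    Significance of theta comes from permuting individuals among areas;
    CIs are percentile bootstraps over loci.
    """
    rng = np.random.default_rng(seed)
    comps = wc_components(dataset)
    fis, fst, fit = multilocus_estimates(comps)
    usable = [lc for lc in comps if lc.total != 0]
    if len(usable) >= 2:
        trip = np.array([[lc.a, lc.b, lc.c] for lc in usable])
        idx = rng.integers(0, len(usable), size=(n_boot, len(usable)))
        sums = trip[idx].sum(axis=1)  # (n_boot, 3)
        tot = sums.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            bf = 1 - sums[:, 2] / (sums[:, 1] + sums[:, 2])
            bt = sums[:, 0] / tot
            bF = 1 - sums[:, 2] / tot
        q = [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100]
        fis_ci = tuple(np.nanpercentile(bf, q))
        fst_ci = tuple(np.nanpercentile(bt, q))
        fit_ci = tuple(np.nanpercentile(bF, q))
    else:
        fis_ci = fst_ci = fit_ci = (float("nan"), float("nan"))
    count = 0
    for _ in range(n_perm):
        perm = _permuted_dataset(dataset, rng)
        _, t, _ = multilocus_estimates(wc_components(perm))
        if t >= fst:
            count += 1
    pval = (count + 1) / (n_perm + 1)
    nm = migrants_crow_aoki(fst, dataset.n_areas) if fst > 0 else float("inf")
    return GlobalFStats(
        fis=fis,
        fst=fst,
        fit=fit,
        fis_ci=fis_ci,
        fst_ci=fst_ci,
        fit_ci=fit_ci,
        fst_pvalue=pval,
        nm=nm,
        n_areas=dataset.n_areas,
    )


@dataclass
class PairwiseMatrix:
    """Symmetric area-by-area FST matrix with zero diagonal."""

    areas: list[str]
    values: np.ndarray

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.areas.index(a), self.areas.index(b)])


def _ena_corrected_freqs(dataset: GenotypeDataset, areas: list[str]):
    """Per-(area, locus) visible-allele frequencies re-estimated by the
    null-allele EM and renormalised over visible states."""
    from .disequilibrium import null_allele_em

    corrected: dict[tuple[str, int], dict[int, float]] = {}
    for area in areas:
        arr = dataset.calls[area]
        for j in range(dataset.n_loci):
            g = arr[:, j, :]
            typed = g[:, 0] != MISSING
            gv = g[typed]
            n_missing = int((~typed).sum())
            if gv.shape[0] == 0 or np.unique(gv).size < 2:
                corrected[(area, j)] = {}
                continue
            res = null_allele_em(gv, n_missing=n_missing)
            vis = res.visible_freqs
            tot = sum(vis.values())
            corrected[(area, j)] = {a: v / tot for a, v in vis.items()} if tot > 0 else {}
    return corrected


def _pair_theta(
    dataset: GenotypeDataset,
    pair: tuple[str, str],
    corrected=None,
) -> float:
    """Multilocus WC theta for one pair of areas, optionally with ENA-corrected
    allele frequencies."""
    A = B = C = 0.0
    any_locus = False
    for j in range(dataset.n_loci):
        alleles = set()
        stats = []
        for area in pair:
            g = dataset.calls[area][:, j, :]
            alleles.update(g[g != MISSING].tolist())
        alleles_arr = np.array(sorted(alleles))
        if alleles_arr.size < 2:
            continue
        for area in pair:
            n, p, h = _pop_stats(dataset.calls[area], j, alleles_arr)
            if n == 0:
                continue
            if corrected is not None and corrected.get((area, j)):
                cf = corrected[(area, j)]
                p = np.array([cf.get(int(a), 0.0) for a in alleles_arr])
            stats.append((n, p, h))
        if len(stats) < 2:
            continue
        ns = np.array([s[0] for s in stats], dtype=float)
        P = np.stack([s[1] for s in stats])
        H = np.stack([s[2] for s in stats])
        r = 2
        nbar = ns.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - (ns**2).sum() / (r * nbar)) / (r - 1)
        pbar = (ns[:, None] * P).sum(axis=0) / (r * nbar)
        s2 = (ns[:, None] * (P - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (ns[:, None] * H).sum(axis=0) / (r * nbar)
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        A += a.sum()
        B += b.sum()
        C += c.sum()
        any_locus = True
    if not any_locus or (A + B + C) == 0:
        return float("nan")
    return A / (A + B + C)


def pairwise_fst(dataset: GenotypeDataset, ena: bool = False) -> PairwiseMatrix:
    """Pairwise multilocus WC theta between all area pairs.

    With ``ena=True``, per-(area, locus) allele frequencies are first
    re-estimated by the null-allele EM with the null state excluded and
    visible frequencies rescaled, following the ENA correction; on data free
    of null alleles this is the identity.
    """
    corrected = _ena_corrected_freqs(dataset, dataset.areas) if ena else None
    n = dataset.n_areas
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            t = _pair_theta(dataset, (dataset.areas[i], dataset.areas[j]), corrected)
            m[i, j] = m[j, i] = t
    return PairwiseMatrix(areas=list(dataset.areas), values=m)


def migrants_crow_aoki(theta: float, n_areas: int) -> float:
    """Island-model number of migrants Nm = (1/(4 alpha)) (1/theta - 1).

    ``alpha = (n/(n-1))^2`` corrects for a finite number of islands ``n``
    (the number of sampled areas).
    """
    if n_areas < 2:
        raise ValueError("need at least two areas")
    if not (0 < theta < 1):
        raise ValueError("theta must be in (0, 1) for a finite migrant estimate")
    alpha = (n_areas / (n_areas - 1)) ** 2
    return (1 / (4 * alpha)) * (1 / theta - 1)


def classify_fst(theta: float) -> str:
    """Differentiation band: low <0.05, intermediate 0.05-0.15, high
    0.15-0.25, very high >0.25."""
    if theta < 0.05:
        return "low"
    if theta < 0.15:
        return "intermediate"
    if theta <= 0.25:
        return "high"
    return "very high"
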