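"""Per-area SSR diversity statistics.

For each sampling area this module computes the classic descriptive table:
allele counts (k), rarefied allelic richness (A_ri), effective number of
alleles (A_e = 1/(1-H_e) per locus, summed over loci) and its percentage of
k, private (A_p) and rare (A_r) alleles, observed and unbiased expected
heterozygosity, the Weir–Cockerham within-area fixation index f (F_IS) with
a within-area allele-permutation p-value and a bootstrap-over-loci CI, and
the apparent outcrossing rate t_a = (1-F_IS)/(1+F_IS).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .core import MISSING, AlleleFreqTable, GenotypeDataset, allele_frequencies
from .fstats import single_pop_components

__all__ = [
    "AreaSummary",
    "gene_diversity",
    "effective_alleles",
    "allelic_richness",
    "private_and_rare_alleles",
    "fis_area",
    "apparent_outcrossing",
    "area_summaries",
]


@dataclass
class AreaSummary:
    """One row of the per-area diversity table."""

    area: str
    n: int
    k: int
    a_ri: float
    a_e: float
    a_e_pct: float
    a_p: int
    a_r: int
    ho: float
    he: float
    fis: float
    fis_p: float
    fis_ci: tuple[float, float]
    t_a: float
    ne: float | None = None
    ne_over_n: float | None = None


def gene_diversity(dataset: GenotypeDataset, area: str):
    """Per-locus and mean observed / unbiased expected heterozygosity.

    H_o is the heterozygote fraction among typed genotypes; H_e is Nei's
    unbiased gene diversity (2n/(2n-1))(1 - sum p^2). Loci with no data in
    the area are excluded from the means.

    Returns ``(per_locus, mean_ho, mean_he)`` where ``per_locus`` maps locus
    name to ``(ho, he, n_typed)``.
    """
    arr = dataset.calls[area]
    per_locus: dict[str, tuple[float, float, int]] = {}
    hos, hes = [], []
    for j, locus in enumerate(dataset.loci):
        g = arr[:, j, :]
        typed = g[:, 0] != MISSING
        g = g[typed]
        n = g.shape[0]
        if n == 0:
            continue
        ho = float((g[:, 0] != g[:, 1]).mean())
        p = np.unique(g, return_counts=True)[1] / (2 * n)
        if n > 1:
            he = (2 * n) / (2 * n - 1) * (1 - float((p**2).sum()))
        else:
            he = 1 - float((p**2).sum())
        per_locus[locus] = (ho, he, n)
        hos.append(ho)
        hes.append(he)
    if not hos:
        raise ValueError(f"area {area!r} has no typed genotypes")
    return per_locus, float(np.mean(hos)), float(np.mean(hes))


def effective_alleles(he_per_locus: dict[str, float], k: int) -> tuple[float, float]:
    """Effective number of alleles A_e = sum over loci of 1/(1-H_e,l), plus
    its percentage of the observed allele count k."""
    ae = 0.0
    for he in he_per_locus.values():
        if he >= 1:
            raise ValueError("per-locus He must be < 1")
        ae += 1 / (1 - he)
    return ae, 100 * ae / k if k else float("nan")


def _rarefied_locus(counts: dict[int, int], g: int) -> float:
    """Expected allele number in a random subsample of g genes."""
    n2 = sum(counts.values())
    if g > n2:
        raise ValueError("rarefaction size exceeds gene count")
    log_denom = gammaln(n2 - g + 1) + gammaln(g + 1) - gammaln(n2 + 1)
    total = 0.0
    for c in counts.values():
        rem = n2 - c
        if rem < g:
            total += 1.0
        else:
            log_num = gammaln(rem + 1) - gammaln(rem - g + 1) - gammaln(g + 1)
            total += 1.0 - math.exp(log_num + log_denom)
    return total


def allelic_richness(
    dataset: GenotypeDataset,
    area: str,
    g: int | None = None,
    freqs: AlleleFreqTable | None = None,
) -> float:
    """Rarefied allelic richness: mean over loci of the expected number of
    alleles in a subsample of ``g`` genes (El Mousadik & Petit rarefaction).

    By default ``g`` is, per locus, twice the smallest typed sample over
    areas, so all areas are compared at a common size.
    """
    if freqs is None:
        freqs = allele_frequencies(dataset)
    vals = []
    for locus in dataset.loci:
        counts = freqs.counts(area, locus)
        if not counts:
            continue
        if g is None:
            gl = min(
                freqs.gene_count(a, locus)
                for a in dataset.areas
                if freqs.gene_count(a, locus) > 0
            )
        else:
            gl = g
        if gl < 2:
            raise ValueError("rarefaction size must be >= 2")
        gl = min(gl, freqs.gene_count(area, locus))
        vals.append(_rarefied_locus(counts, gl))
    return float(np.mean(vals))


def private_and_rare_alleles(
    freqs: AlleleFreqTable, rare_threshold: float = 0.05
):
    """Private and rare allele counts per area, plus species-level percentages.

    A private allele occurs in exactly one area; a rare allele has pooled
    frequency below ``rare_threshold`` and is not private; the remainder are
    common. Returns ``(a_p, a_r, percentages)`` with per-area dicts and a
    dict of species-level percentages over distinct (locus, allele) states.
    """
    if len(freqs.areas) < 2:
        raise ValueError("private alleles need at least two areas")
    a_p = {a: 0 for a in freqs.areas}
    a_r = {a: 0 for a in freqs.areas}
    n_private = n_rare = n_total = 0
    for locus in freqs.loci:
        pooled = freqs.pooled_freq(locus)
        presence = {
            allele: [a for a in freqs.areas if allele in freqs.alleles_in_area(a, locus)]
            for allele in pooled
        }
        for allele, areas_with in presence.items():
            n_total += 1
            if len(areas_with) == 1:
                n_private += 1
                a_p[areas_with[0]] += 1
            elif pooled[allele] < rare_threshold:
                n_rare += 1
                for a in areas_with:
                    a_r[a] += 1
    pct = {
        "private": 100 * n_private / n_total if n_total else 0.0,
        "rare": 100 * n_rare / n_total if n_total else 0.0,
        "common": 100 * (n_total - n_private - n_rare) / n_total if n_total else 0.0,
    }
    return a_p, a_r, pct


def _fis_from_calls(arr: np.ndarray) -> float:
    """Multilocus single-population WC f from a calls array (n, L, 2)."""
    B = C = 0.0
    n_all, n_loci = arr.shape[0], arr.shape[1]
    for j in range(n_loci):
        g = arr[:, j, :]
        typed = g[:, 0] != MISSING
        g = g[typed]
        n = g.shape[0]
        if n < 2:
            continue
        alleles = np.unique(g)
        if alleles.size < 2:
            continue
        p = np.array([(g == a).sum() for a in alleles], dtype=float) / (2 * n)
        het = g[:, 0] != g[:, 1]
        h = np.array([((g == a).any(axis=1) & het).sum() for a in alleles], dtype=float) / n
        B += float((n / (n - 1) * (p * (1 - p) - (2 * n - 1) / (4 * n) * h)).sum())
        C += float((h / 2).sum())
    if B + C == 0:
        return float("nan")
    return 1 - C / (B + C)


def fis_area(
    dataset: GenotypeDataset,
    area: str,
    n_perm: int = 1_000,
    n_boot: int = 1_000,
    ci_level: float = 0.95,
    seed: int | None = None,
):
    """Within-area multilocus F_IS with permutation p-value and bootstrap CI.

    f is the single-population Weir–Cockerham estimator (ratio of summed
    variance components over loci). The p-value permutes alleles among
    individuals within the area, locus by locus, and counts permutations
    with |f| at least the observed; the CI is a percentile bootstrap over
    loci.
    """
    rng = np.random.default_rng(seed)
    comps = single_pop_components(dataset, area)
    B = sum(b for _, b, _ in comps)
    C = sum(c for _, _, c in comps)
    if B + C == 0:
        raise ValueError(f"F_IS undefined: all loci monomorphic in area {area!r}")
    f_obs = 1 - C / (B + C)

    arr = dataset.calls[area]
    count = 0
    for _ in range(n_perm):
        perm = arr.copy()
        for j in range(arr.shape[1]):
            g = perm[:, j, :]
            typed = g[:, 0] != MISSING
            genes = g[typed].ravel()
            rng.shuffle(genes)
            g[typed] = genes.reshape(-1, 2)
        f_p = _fis_from_calls(perm)
        if not math.isnan(f_p) and abs(f_p) >= abs(f_obs):
            count += 1
    p = (count + 1) / (n_perm + 1)

    usable = [(b, c) for _, b, c in comps if (b + c) != 0]
    if len(usable) >= 2:
        bc = np.array(usable)
        idx = rng.integers(0, len(usable), size=(n_boot, len(usable)))
        sums = bc[idx].sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            boots = 1 - sums[:, 1] / sums.sum(axis=1)
        q = [(1 - ci_level) / 2 * 100, (1 + ci_level) / 2 * 100]
        ci = tuple(np.nanpercentile(boots, q))
    else:
        ci = (float("nan"), float("nan"))
    return f_obs, p, ci


def apparent_outcrossing(fis: float) -> float:
    """Apparent outcrossing rate t_a = (1 - F_IS)/(1 + F_IS).

    The raw value is returned (it may exceed 1 for negative F_IS); clipping
    for display is left to report rendering.
    """
    if fis <= -1:
        raise ValueError("t_a undefined for F_IS <= -1")
    return (1 - fis) / (1 + fis)


def area_summaries(
    dataset: GenotypeDataset,
    rare_threshold: float = 0.05,
    rarefaction_g: int | None = None,
    n_perm: int = 1_000,
    seed: int | None = None,
) -> list[AreaSummary]:
    """Build the full per-area diversity table (one :class:`AreaSummary` per area)."""
    freqs = allele_frequencies(dataset)
    a_p, a_r, _ = private_and_rare_alleles(freqs, rare_threshold)
    rng = np.random.default_rng(seed)
    out = []
    for area in dataset.areas:
        per_locus, mean_ho, mean_he = gene_diversity(dataset, area)
        k = sum(freqs.allele_count(area, locus) for locus in dataset.loci)
        he_per_locus = {l: he for l, (_, he, _) in per_locus.items()}
        ae, ae_pct = effective_alleles(he_per_locus, k)
        ari = allelic_richness(dataset, area, g=rarefaction_g, freqs=freqs)
        fis, fis_p, fis_ci = fis_area(
            dataset, area, n_perm=n_perm, seed=int(rng.integers(2**31))
        )
        out.append(
            AreaSummary(
                area=area,
                n=dataset.n_individuals(area),
                k=k,
                a_ri=ari,
                a_e=ae,
                a_e_pct=ae_pct,
                a_p=a_p[area],
                a_r=a_r[area],
                ho=mean_ho,
                he=mean_he,
                fis=fis,
                fis_p=fis_p,
                fis_ci=fis_ci,
                t_a=apparent_outcrossing(fis),
            )
        )
    return out
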