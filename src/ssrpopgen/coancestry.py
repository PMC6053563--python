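"""Loiselle pairwise kinship, group coancestry and coancestry-based Ne.

The effective size of a sampled group follows from its group coancestry
``Theta`` (mean coancestry over all ordered pairs, self-pairs included) and
inbreeding ``F``:

    Ne = 0.5 / [ Theta (n-1)/n + (1+F)/(2n) ]

which reduces to ``Ne -> n`` behaviour for unrelated, non-inbred samples
(Theta = 1/(2n), F = 0 gives Ne = n^2/(2n-1)), and to Ne -> 1 for a clonal,
fully inbred group. ``Ne/N`` is the genetic representativeness of the
sample: the fraction of sampled individuals that behave as ideal-population
equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import MISSING, GenotypeDataset

__all__ = [
    "CoancestryResult",
    "loiselle_kinship",
    "group_coancestry",
    "effective_size",
    "coancestry_summary",
]


def loiselle_kinship(
    dataset: GenotypeDataset, area: str, reference: str = "area"
) -> np.ndarray:
    """Pairwise Loiselle kinship matrix for one area.

    ``reference`` selects the allele frequencies the estimator is relative
    to: the area's own sample (``"area"``) or the pooled sample over all
    areas (``"pooled"``, the usual choice when within-area family structure
    must register — self-referenced kinship averages to zero by
    construction). Per locus and allele, with dosages x in {0, 0.5, 1},

        num += (x_i - p)(x_j - p) + p(1-p)/(2n - 1)
        den += p(1-p)

    and the multilocus coefficient is the ratio of sums over loci; loci at
    which either member of a pair is untyped are skipped in both sums.
    Entries for pairs sharing no typed locus are NaN; the diagonal is NaN
    (self-coancestry is supplied analytically by :func:`group_coancestry`).
    """
    if reference not in ("area", "pooled"):
        raise ValueError("reference must be 'area' or 'pooled'")
    arr = dataset.calls[area]
    n_ind = arr.shape[0]
    if n_ind < 2:
        raise ValueError("kinship needs at least two individuals")
    num = np.zeros((n_ind, n_ind))
    den = np.zeros((n_ind, n_ind))
    for j in range(dataset.n_loci):
        g = arr[:, j, :]
        typed = g[:, 0] != MISSING
        gt = g[typed]
        n = gt.shape[0]
        if n < 2:
            continue
        if reference == "pooled":
            pool = np.concatenate([dataset.calls[a][:, j, :].ravel() for a in dataset.areas])
            pool = pool[pool != MISSING]
            ref_alleles, ref_counts = np.unique(pool, return_counts=True)
            n_ref = pool.size // 2
        else:
            ref_alleles, ref_counts = np.unique(gt, return_counts=True)
            n_ref = n
        alleles, counts = ref_alleles, ref_counts
        if alleles.size < 2:
            continue
        p = counts / (2 * n_ref)
        n = n_ref  # reference sample size drives the bias correction
        # dosage fractions (n_typed, k)
        X = (
            (gt[:, 0][:, None] == alleles[None, :]).astype(float)
            + (gt[:, 1][:, None] == alleles[None, :])
        ) / 2
        dev = X - p
        corr = float((p * (1 - p)).sum()) / (2 * n - 1)
        d = float((p * (1 - p)).sum())
        block = dev @ dev.T + corr
        idx = np.where(typed)[0]
        num[np.ix_(idx, idx)] += block
        den[np.ix_(idx, idx)] += d
    with np.errstate(divide="ignore", invalid="ignore"):
        kin = np.where(den > 0, num / den, np.nan)
    np.fill_diagonal(kin, np.nan)
    return kin


def group_coancestry(
    kinship: np.ndarray,
    fis: float,
    n: int | None = None,
    floor_negative: bool = True,
) -> tuple[float, float, bool]:
    """Group coancestry Theta from a kinship matrix and the area's F_IS.

    Theta = [n * s + n(n-1) * fbar] / n^2 with self-coancestry
    s = (1 + F)/2 and fbar the mean off-diagonal kinship. Negative F (for
    the self term) and negative fbar are floored at zero by default —
    coancestry of an individual with itself cannot drop below 1/2 and a
    negative mean relatedness would inflate Ne beyond the sample size.

    Returns ``(theta, fbar_raw, floored)``.
    """
    kinship = np.asarray(kinship, dtype=float)
    if kinship.ndim != 2 or kinship.shape[0] != kinship.shape[1]:
        raise ValueError("kinship must be square")
    if n is None:
        n = kinship.shape[0]
    if n < 2:
        raise ValueError("group coancestry needs n >= 2")
    off = kinship[~np.eye(kinship.shape[0], dtype=bool)]
    off = off[~np.isnan(off)]
    fbar_raw = float(off.mean()) if off.size else 0.0
    f_self = fis if not floor_negative else max(fis, 0.0)
    fbar = fbar_raw if not floor_negative else max(fbar_raw, 0.0)
    floored = floor_negative and (fbar_raw < 0 or fis < 0)
    s = (1 + f_self) / 2
    theta = (n * s + n * (n - 1) * fbar) / n**2
    return theta, fbar_raw, floored


def effective_size(theta: float, fis: float, n: int) -> tuple[float, float]:
    """Coancestry-based effective size Ne and representativeness Ne/N.

    ``Ne = 0.5 / [theta (n-1)/n + (1+F)/(2n)]``; the same F floor as in
    :func:`group_coancestry` should be applied by the caller for
    consistency.
    """
    if not (0 < theta <= 1):
        raise ValueError("theta must be in (0, 1]")
    if fis <= -1:
        raise ValueError("F must exceed -1")
    if n < 2:
        raise ValueError("n must be >= 2")
    denom = theta * (n - 1) / n + (1 + fis) / (2 * n)
    if denom <= 0:
        raise ValueError("non-positive denominator in Ne formula")
    ne = 0.5 / denom
    return ne, ne / n


@dataclass
class CoancestryResult:
    area: str
    kinship: np.ndarray
    theta: float
    fbar_raw: float
    fis: float
    n: int
    ne: float
    ne_over_n: float
    floored: bool


def _quick_fis(dataset: GenotypeDataset, area: str) -> float:
    from .diversity import _fis_from_calls

    return _fis_from_calls(dataset.calls[area])


def coancestry_summary(
    dataset: GenotypeDataset,
    area: str,
    fis: float | None = None,
    floor_negative: bool = True,
    reference: str = "pooled",
) -> CoancestryResult:
    """Kinship matrix, group coancestry, Ne and Ne/N for one area.

    Kinship is referenced to the pooled sample by default so that
    within-area family structure depresses Ne; pass ``reference="area"``
    for strictly self-referenced coancestry.
    """
    if fis is None:
        fis = _quick_fis(dataset, area)
    kin = loiselle_kinship(dataset, area, reference=reference)
    n = dataset.n_individuals(area)
    theta, fbar_raw, floored = group_coancestry(kin, fis, n, floor_negative)
    f_used = max(fis, 0.0) if floor_negative else fis
    ne, ratio = effective_size(theta, f_used, n)
    return CoancestryResult(
        area=area,
        kinship=kin,
        theta=theta,
        fbar_raw=fbar_raw,
        fis=fis,
        n=n,
        ne=ne,
        ne_over_n=ratio,
        floored=floored,
    )
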