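"""Among-area structure: AMOVA, Nei genetic distance, UPGMA with locus
bootstrap, and the Mantel test of isolation by distance.

AMOVA operates on squared-Euclidean distances between individual
allele-dosage vectors (the standard codominant encoding) and partitions the
sums of squares among and within areas; its fixation analogue Phi_ST is the
among-area variance fraction, tested by permuting individuals among areas.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .core import MISSING, AlleleFreqTable, GenotypeDataset

__all__ = [
    "AmovaResult",
    "DistanceTree",
    "TreeNode",
    "amova_two_level",
    "nei_distance",
    "upgma",
    "upgma_bootstrap",
    "mantel_test",
]


# -- AMOVA -----------------------------------------------------------------


@dataclass
class AmovaResult:
    ms_among: float
    ms_within: float
    var_among: float
    var_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    pvalue: float
    n_perm: int


def _dosage_sq_distances(dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise squared-Euclidean dosage distances over all individuals.

    Per locus, the distance is summed over allele-dosage differences; pairs
    missing a locus average over their shared loci (scaled back to the full
    locus count). Returns (d2, group_index).
    """
    blocks = []
    masks = []
    all_calls = np.concatenate([dataset.calls[a] for a in dataset.areas], axis=0)
    groups = np.concatenate(
        [np.full(dataset.n_individuals(a), gi) for gi, a in enumerate(dataset.areas)]
    )
    N = all_calls.shape[0]
    for j in range(dataset.n_loci):
        g = all_calls[:, j, :]
        typed = g[:, 0] != MISSING
        alleles = np.unique(g[g != MISSING])
        if alleles.size == 0:
            continue
        X = (
            (g[:, 0][:, None] == alleles[None, :]).astype(float)
            + (g[:, 1][:, None] == alleles[None, :])
        )
        X[~typed] = np.nan
        blocks.append(X)
        masks.append(typed)
    d2 = np.zeros((N, N))
    shared = np.zeros((N, N))
    for X, typed in zip(blocks, masks):
        t = typed.astype(float)
        pair_typed = np.outer(t, t)
        Xf = np.nan_to_num(X)
        sq = (Xf**2).sum(axis=1)
        dist = sq[:, None] + sq[None, :] - 2 * Xf @ Xf.T
        d2 += np.where(pair_typed > 0, dist, 0.0)
        shared += pair_typed
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(shared > 0, d2 / shared, 0.0) * len(blocks)
    np.fill_diagonal(d2, 0.0)
    return d2, groups


def _amova_from_d2(d2: np.ndarray, groups: np.ndarray):
    N = d2.shape[0]
    labels = np.unique(groups)
    r = labels.size
    ss_total = d2[np.triu_indices(N, 1)].sum() / N
    ss_within = 0.0
    sizes = []
    for g in labels:
        idx = np.where(groups == g)[0]
        n_g = idx.size
        sizes.append(n_g)
        if n_g > 1:
            sub = d2[np.ix_(idx, idx)]
            ss_within += sub[np.triu_indices(n_g, 1)].sum() / n_g
    sizes = np.array(sizes, dtype=float)
    ss_among = ss_total - ss_within
    df_among = r - 1
    df_within = N - r
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within > 0 else float("nan")
    n0 = (N - (sizes**2).sum() / N) / df_among
    var_within = ms_within
    var_among = (ms_among - ms_within) / n0
    total = var_among + var_within
    phi = var_among / total if total != 0 else float("nan")
    return ms_among, ms_within, var_among, var_within, phi


def amova_two_level(
    dataset: GenotypeDataset, n_perm: int = 1_000, seed: int | None = None
) -> AmovaResult:
    """Two-level AMOVA (among areas / within areas) with permutation p-value."""
    if dataset.n_areas < 2:
        raise ValueError("AMOVA needs at least two areas")
    d2, groups = _dosage_sq_distances(dataset)
    ms_a, ms_w, var_a, var_w, phi = _amova_from_d2(d2, groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        phi_p = _amova_from_d2(d2, perm)[4]
        if phi_p >= phi:
            count += 1
    p = (count + 1) / (n_perm + 1)
    total = var_a + var_w
    return AmovaResult(
        ms_among=ms_a,
        ms_within=ms_w,
        var_among=var_a,
        var_within=var_w,
        pct_among=100 * var_a / total,
        pct_within=100 * var_w / total,
        phi_st=phi,
        pvalue=p,
        n_perm=n_perm,
    )


# -- Nei distance ----------------------------------------------------------


def _nei_locus_terms(freqs: AlleleFreqTable, variant: str):
    """Per-locus (Jxy, Jx, Jy) terms for every area pair; used directly and
    by the locus bootstrap."""
    areas = freqs.areas
    loci = freqs.loci
    n_l = len(loci)
    jxy = {}
    jx = np.zeros((len(areas), n_l))
    for ai, a in enumerate(areas):
        for li, locus in enumerate(loci):
            p = freqs.freq(a, locus)
            j_raw = sum(v * v for v in p.values())
            if variant == "1978":
                n2 = freqs.gene_count(a, locus)
                jx[ai, li] = (n2 * j_raw - 1) / (n2 - 1) if n2 > 1 else j_raw
            else:
                jx[ai, li] = j_raw
    for ai, bi in itertools.combinations(range(len(areas)), 2):
        arr = np.zeros(n_l)
        for li, locus in enumerate(loci):
            pa = freqs.freq(areas[ai], locus)
            pb = freqs.freq(areas[bi], locus)
            arr[li] = sum(pa.get(al, 0.0) * pb[al] for al in pb)
        jxy[(ai, bi)] = arr
    return jx, jxy


def nei_distance(
    freqs: AlleleFreqTable, variant: str = "1978", locus_subset: np.ndarray | None = None
) -> np.ndarray:
    """Nei genetic distance matrix D = -ln I between all area pairs.

    ``variant='1972'`` is the standard distance; ``'1978'`` substitutes
    unbiased within-area homozygosities (the small-sample correction).
    Pairs with no shared alleles get ``inf``.
    """
    if variant not in ("1972", "1978"):
        raise ValueError("variant must be '1972' or '1978'")
    jx, jxy = _nei_locus_terms(freqs, variant)
    n = len(freqs.areas)
    sel = locus_subset if locus_subset is not None else np.arange(jx.shape[1])
    D = np.zeros((n, n))
    for (ai, bi), arr in jxy.items():
        num = arr[sel].sum()
        den = math.sqrt(max(jx[ai, sel].sum(), 0.0) * max(jx[bi, sel].sum(), 0.0))
        if num <= 0 or den <= 0:
            D[ai, bi] = D[bi, ai] = float("inf")
        else:
            identity = num / den
            D[ai, bi] = D[bi, ai] = -math.log(min(identity, 1.0)) if identity < 1 else 0.0
    return D


# -- UPGMA -----------------------------------------------------------------


@dataclass
class TreeNode:
    """UPGMA dendrogram node: a leaf (label) or an internal node with two
    children, a height, and bootstrap support in percent."""

    label: str | None = None
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        out: set[str] = set()
        for c in self.children:
            out |= c.leaves()
        return frozenset(out)

    def newick(self, with_support: bool = True) -> str:
        def render(node: TreeNode, parent_height: float) -> str:
            blen = parent_height - node.height
            if node.is_leaf:
                return f"{node.label}:{blen:.6f}"
            inner = ",".join(render(c, node.height) for c in node.children)
            sup = (
                f"{node.support:.0f}"
                if (with_support and node.support is not None)
                else ""
            )
            return f"({inner}){sup}:{blen:.6f}"

        if self.is_leaf:
            return f"{self.label};"
        inner = ",".join(render(c, self.height) for c in self.children)
        sup = f"{self.support:.0f}" if (with_support and self.support is not None) else ""
        return f"({inner}){sup};"


def upgma(labels: list[str], dmat: np.ndarray) -> TreeNode:
    """Average-linkage (UPGMA) clustering with deterministic tie-breaking:
    among equally close pairs, the lexicographically smallest pair of
    cluster labels is joined first."""
    if not np.all(np.isfinite(dmat)):
        raise ValueError("UPGMA needs finite distances")
    clusters: dict[str, TreeNode] = {l: TreeNode(label=l) for l in labels}
    sizes = {l: 1 for l in labels}
    keys = {l: (l,) for l in labels}  # sorted member tuple for tie-breaks
    d = {
        frozenset((a, b)): float(dmat[i, j])
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
        if i < j
    }
    names = list(labels)
    counter = 0
    while len(names) > 1:
        best = None
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                dist = d[frozenset((a, b))]
                pair_key = tuple(sorted((keys[a], keys[b])))
                cand = (dist, pair_key, a, b)
                if best is None or cand < best:
                    best = cand
        dist, _, a, b = best
        counter += 1
        new = f"__c{counter}"
        node = TreeNode(children=[clusters[a], clusters[b]], height=dist / 2)
        clusters[new] = node
        sizes[new] = sizes[a] + sizes[b]
        keys[new] = tuple(sorted(keys[a] + keys[b]))
        for other in names:
            if other in (a, b):
                continue
            da = d[frozenset((a, other))]
            db = d[frozenset((b, other))]
            d[frozenset((new, other))] = (sizes[a] * da + sizes[b] * db) / (
                sizes[a] + sizes[b]
            )
        names = [x for x in names if x not in (a, b)] + [new]
    return clusters[names[0]]


@dataclass
class DistanceTree:
    labels: list[str]
    distances: np.ndarray
    tree: TreeNode
    supports: dict[frozenset[str], float]
    n_boot: int


def _internal_clades(tree: TreeNode) -> set[frozenset[str]]:
    out = set()

    def walk(node: TreeNode):
        if not node.is_leaf:
            leaves = node.leaves()
            if 1 < len(leaves):
                out.add(leaves)
            for c in node.children:
                walk(c)

    walk(tree)
    return out


def upgma_bootstrap(
    dataset: GenotypeDataset,
    variant: str = "1978",
    n_boot: int = 1_000,
    seed: int | None = None,
    freqs: AlleleFreqTable | None = None,
) -> DistanceTree:
    """UPGMA tree on the Nei distance matrix with locus-bootstrap supports.

    Support of an internal node is the percentage of trees built from
    loci resampled with replacement that contain the same leaf set.
    """
    if dataset.n_areas < 3:
        raise ValueError("need at least three areas")
    if freqs is None:
        freqs = AlleleFreqTable(dataset)
    if dataset.n_loci < 2:
        raise ValueError("locus bootstrap needs at least two loci")
    dmat = nei_distance(freqs, variant)
    tree = upgma(dataset.areas, dmat)
    clades = _internal_clades(tree)
    counts = {c: 0 for c in clades}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        sel = rng.integers(0, dataset.n_loci, size=dataset.n_loci)
        bmat = nei_distance(freqs, variant, locus_subset=sel)
        if not np.all(np.isfinite(bmat)):
            continue
        btree = upgma(dataset.areas, bmat)
        bclades = _internal_clades(btree)
        for c in clades:
            if c in bclades:
                counts[c] += 1
    supports = {c: 100 * counts[c] / n_boot for c in clades}

    def annotate(node: TreeNode):
        if not node.is_leaf:
            node.support = supports.get(node.leaves())
            for c in node.children:
                annotate(c)

    annotate(tree)
    return DistanceTree(
        labels=list(dataset.areas),
        distances=dmat,
        tree=tree,
        supports=supports,
        n_boot=n_boot,
    )


# -- Mantel ----------------------------------------------------------------


def mantel_test(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 9_999,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-tailed Mantel test of matrix association (positive correlation).

    r is the Pearson correlation over lower-triangle entries; the p-value
    permutes the rows/columns of ``y`` jointly. For six or fewer labels all
    permutations are enumerated exactly; otherwise ``n_perm`` random
    permutations are drawn and the add-one estimator is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.shape[0] != x.shape[1]:
        raise ValueError("matrices must be square and congruent")
    n = x.shape[0]
    tri = np.tril_indices(n, -1)
    xv = x[tri]
    if np.std(xv) == 0 or np.std(y[tri]) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")

    def corr(perm: np.ndarray) -> float:
        yp = y[np.ix_(perm, perm)]
        return float(np.corrcoef(xv, yp[tri])[0, 1])

    r_obs = corr(np.arange(n))
    if n <= 6:
        rs = [corr(np.array(p)) for p in itertools.permutations(range(n))]
        p = sum(r >= r_obs - 1e-12 for r in rs) / len(rs)
        return r_obs, p
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if corr(rng.permutation(n)) >= r_obs - 1e-12:
            count += 1
    return r_obs, (count + 1) / (n_perm + 1)
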