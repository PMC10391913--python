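"""Allele-sharing distances and bootstrapped neighbor-joining trees.

The pairwise distance between individuals i and j is the mean over shared
genotyped SNP sites of a per-site contribution d_ij in {0, 0.5, 1}:

* identical homozygotes            -> 0
* homozygote vs heterozygote       -> 0.5
* both heterozygous                -> 0.5
* opposite homozygotes             -> 1

This is the expected allele difference between one allele drawn at random
from each individual: d_ij = p_i (1 - p_j) + p_j (1 - p_i) with
p = dosage / 2, equivalently (x_i + x_j - x_i x_j) / 2 on dosages — the
unique bilinear extension of the four canonical genotype-pair cases (note
a heterozygote is at distance 0.5 even from itself; the self-distance of
an individual is defined as 0). Sites where either genotype is missing
are excluded pair by pair (pairwise-complete), so the distance is always
a mean per-site value in [0, 1].

Trees are built with Saitou-Nei neighbor joining, deterministically
(lowest-index pair on Q ties). Bootstrap support resamples SNP sites
(columns) with replacement and counts, for each internal split of the
original tree, the replicates whose tree contains the same bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_genotypes import MISSING, GenotypeMatrix


def site_distance(g_i: int, g_j: int) -> float:
    """Per-site allele-sharing contribution for two non-missing dosages.

    Expected difference of one random allele from each individual:
    0 for identical homozygotes, 0.5 when either genotype is heterozygous,
    1 for opposite homozygotes.
    """
    if g_i == MISSING or g_j == MISSING:
        raise ValueError("site_distance requires non-missing genotypes")
    if g_i not in (0, 1, 2) or g_j not in (0, 1, 2):
        raise ValueError("dosages must be 0, 1 or 2")
    return (g_i + g_j - g_i * g_j) / 2.0


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray          # symmetric, zero diagonal, entries in [0, 1]
    n_shared: np.ndarray   # per pair, sites with both genotypes present

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix not symmetric")


def pairwise_distance(gm: GenotypeMatrix, i: str | int, j: str | int) -> float:
    """Mean per-site distance between two samples (pairwise-complete)."""
    ii = gm.samples.index(i) if isinstance(i, str) else i
    jj = gm.samples.index(j) if isinstance(j, str) else j
    xi, xj = gm.dosage[:, ii], gm.dosage[:, jj]
    ok = (xi != MISSING) & (xj != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"no shared genotyped sites for pair ({i}, {j})")
    a = xi[ok].astype(float)
    b = xj[ok].astype(float)
    return float((a + b - a * b).sum()) / (2.0 * n)


def distance_matrix(gm: GenotypeMatrix) -> DistanceMatrix:
    """All-pairs allele-sharing distance matrix (matrix-product fast path
    when no genotype is missing)."""
    return _distance_from_dosage(gm.dosage, list(gm.samples))


def _distance_from_dosage(dosage: np.ndarray, samples: list[str]) -> DistanceMatrix:
    X = dosage.astype(float).T  # samples x sites
    n = X.shape[0]
    n_sites = X.shape[1]
    if not (dosage == MISSING).any():
        # per-site contribution (x_i + x_j - x_i x_j)/2 summed over sites
        S = X.sum(axis=1)
        d = (S[:, None] + S[None, :] - X @ X.T) / (2.0 * n_sites)
        np.fill_diagonal(d, 0.0)
        shared = np.full((n, n), n_sites, dtype=int)
        return DistanceMatrix(samples, d, shared)
    ok = (dosage != MISSING).T.astype(float)          # samples x sites
    Xz = np.where(dosage.T == MISSING, 0.0, X)
    d = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=int)
    for a in range(n):
        both = ok[a] * ok                             # n x sites
        num = (Xz[a] + Xz - Xz[a] * Xz) * both
        cnt = both.sum(axis=1)
        if (cnt[np.arange(n) != a] == 0).any():
            bad = [samples[b] for b in range(n) if b != a and cnt[b] == 0]
            raise ValueError(f"no shared genotyped sites for pairs with {samples[a]}: {bad}")
        d[a] = num.sum(axis=1) / (2.0 * np.maximum(cnt, 1))
        shared[a] = cnt
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(samples, d, shared)


@dataclass
class _Node:
    name: str | None = None
    children: list[tuple["_Node", float]] = field(default_factory=list)

    def leaves(self) -> frozenset[str]:
        if not self.children:
            return frozenset([self.name])
        out: set[str] = set()
        for ch, _ in self.children:
            out |= ch.leaves()
        return frozenset(out)


@dataclass
class TreeResult:
    newick: str
    root: _Node
    labels: list[str]
    splits: set[frozenset[str]] = field(default_factory=set)
    support: dict[frozenset[str], int] = field(default_factory=dict)
    n_reps: int = 0


def _to_newick(node: _Node, support: dict[frozenset[str], int] | None = None) -> str:
    if not node.children:
        return node.name
    parts = []
    for ch, bl in node.children:
        label = ""
        if ch.children and support is not None:
            key = _canonical_split(ch.leaves(), _ALL_LEAVES.get())
            if key in support:
                label = str(support[key])
        parts.append(f"{_to_newick(ch, support)}{label}:{bl:.10g}")
    return "(" + ",".join(parts) + ")"


class _AllLeaves:
    """Thread-local-ish holder for the full leaf set during serialization."""

    def __init__(self) -> None:
        self._v: frozenset[str] | None = None

    def set(self, v: frozenset[str]) -> None:
        self._v = v

    def get(self) -> frozenset[str]:
        return self._v


_ALL_LEAVES = _AllLeaves()


def _canonical_split(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    """Represent a bipartition by the side not containing the
    lexicographically smallest leaf (orientation-free)."""
    anchor = min(all_leaves)
    return all_leaves - side if anchor in side else side


def tree_splits(root: _Node) -> set[frozenset[str]]:
    """Non-trivial bipartitions induced by the internal edges."""
    all_leaves = root.leaves()
    out: set[frozenset[str]] = set()

    def walk(node: _Node) -> None:
        for ch, _ in node.children:
            if ch.children:
                side = ch.leaves()
                if 2 <= len(side) <= len(all_leaves) - 2:
                    out.add(_canonical_split(side, all_leaves))
                walk(ch)

    walk(root)
    return out


def nj_tree(dm: DistanceMatrix, clamp_negative: bool = True) -> TreeResult:
    """Saitou-Nei neighbor joining; deterministic (lowest-index tie-break).

    With ``clamp_negative`` a negative branch length is set to zero and the
    deficit transferred to the sibling branch so the pair distance is
    preserved; raw lengths are kept otherwise.
    """
    m = len(dm.labels)
    if m < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.d.astype(float).copy()
    nodes: list[_Node] = [_Node(name=l) for l in dm.labels]
    active = list(range(m))

    def adjust(li: float, lj: float) -> tuple[float, float]:
        if not clamp_negative:
            return li, lj
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    while len(active) > 3:
        k = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (k - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest-index tie-break: first argmin in row-major order
        flat = int(np.argmin(Q))
        ai, aj = divmod(flat, k)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (k - 2))
        lj = dij - li
        li, lj = adjust(li, lj)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(new)
        u = len(nodes) - 1
        D = np.pad(D, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            D[u, x] = D[x, u] = 0.5 * (D[i, x] + D[j, x] - dij)
        active = [x for x in active if x not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    if clamp_negative:
        li, lj, lk = (max(x, 0.0) for x in (li, lj, lk))
    root = _Node(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    _ALL_LEAVES.set(root.leaves())
    res = TreeResult(
        newick=_to_newick(root) + ";",
        root=root,
        labels=list(dm.labels),
        splits=tree_splits(root),
    )
    return res


def bootstrap_support(
    gm: GenotypeMatrix,
    n_reps: int = 1000,
    seed: int | None = None,
    clamp_negative: bool = True,
) -> TreeResult:
    """NJ tree with site-resampling bootstrap support.

    Each replicate draws ``n_sites`` SNP columns with replacement,
    recomputes the distance matrix and NJ tree, and increments the count
    of every internal split of the original tree present in the replicate.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    base = nj_tree(distance_matrix(gm), clamp_negative=clamp_negative)
    support = {s: 0 for s in base.splits}
    for _ in range(n_reps):
        idx = rng.integers(0, gm.n_sites, size=gm.n_sites)
        rep = nj_tree(
            _distance_from_dosage(gm.dosage[idx], list(gm.samples)),
            clamp_negative=clamp_negative,
        )
        for s in base.splits & rep.splits:
            support[s] += 1
    base.support = support
    base.n_reps = n_reps
    _ALL_LEAVES.set(base.root.leaves())
    base.newick = _to_newick(base.root, support) + ";"
    return base


def is_monophyletic(tree: TreeResult, labels: set[str]) -> bool:
    """True if ``labels`` form one side of a split (or a cherry/leaf set
    hanging off a single edge) in the unrooted tree."""
    all_leaves = tree.root.leaves()
    target = frozenset(labels)
    if target == all_leaves or len(target) <= 1:
        return True
    if len(target) == len(all_leaves) - 1:
        return True  # complement is a single leaf: trivially one edge
    return _canonical_split(target, all_leaves) in tree.splits


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels).to_csv(path, sep="\t")
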