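"""Population structure: PCA and neighbor-joining trees with bootstrap.

PCA uses Patterson normalization (center each site by its mean genotype,
scale by sqrt(p̄(1-p̄)) with p̄ the mean allele frequency), mean-imputes
missing calls, and takes the eigendecomposition of the sample covariance.

The tree side provides an allele-sharing distance (mean |g_i - g_j|/2 over
co-genotyped sites), Saitou–Nei neighbor joining with deterministic
lowest-index tie-breaking, and site-resampling bootstrap support computed
as the fraction of replicate trees containing each internal bipartition of
the full-data tree. Negative branch lengths are retained (and flagged)
rather than clamped, preserving exact inversion of additive distance
matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .genotype import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class TreeNode:
    """A (sub)tree: leaves carry a name, internal nodes carry children with
    branch lengths and optionally a bootstrap support value."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self, with_support: bool = True) -> str:
        return self._newick(with_support) + ";"

    def _newick(self, with_support: bool) -> str:
        if self.is_leaf:
            return self.name or ""
        inner = ",".join(
            f"{child._newick(with_support)}:{length:.6g}"
            for child, length in self.children
        )
        label = ""
        if with_support and self.support is not None:
            label = f"{self.support:.3g}"
        return f"({inner}){label}"

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between all leaf pairs (for additivity checks)."""
        result: dict[tuple[str, str], float] = {}

        def walk(node: "TreeNode") -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}  # type: ignore[dict-item]
            maps = []
            for child, length in node.children:
                m = walk(child)
                maps.append({k: v + length for k, v in m.items()})
            for i in range(len(maps)):
                for j in range(i + 1, len(maps)):
                    for a, da in maps[i].items():
                        for b, db in maps[j].items():
                            key = (a, b) if a < b else (b, a)
                            result[key] = da + db
            merged: dict[str, float] = {}
            for m in maps:
                merged.update(m)
            return merged

        walk(self)
        return result


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    def to_phylip(self) -> str:
        lines = [f"{len(self.ids)}"]
        for name, row in zip(self.ids, self.values):
            lines.append(name.ljust(10) + " ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca(
    gm_or_calls, n_components: int = 10, scale: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Patterson-normalized PCA of a genotype matrix.

    Accepts a GenotypeMatrix or a raw (samples × sites) call array.
    Returns (coordinates, explained_variance_ratio); coordinates are
    eigenvectors of the sample covariance scaled by sqrt(eigenvalue),
    ordered by decreasing eigenvalue, with a deterministic sign convention
    (largest-magnitude loading positive). ``scale=False`` disables the
    sqrt(p̄(1-p̄)) scaling (centering only); note the scaling itself
    depends on the mean genotype, so only the unscaled variant is exactly
    invariant to shifting a site's coding by a constant.
    """
    calls = gm_or_calls.calls if isinstance(gm_or_calls, GenotypeMatrix) else gm_or_calls
    X = np.asarray(calls, dtype=np.float64)
    X = np.where(X < 0, np.nan, X)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least 2 samples")
    mu = np.nanmean(X, axis=0)
    p = mu / 2.0
    with np.errstate(invalid="ignore"):
        denom = np.sqrt(p * (1.0 - p)) if scale else np.ones_like(p)
    keep = (np.nanvar(X, axis=0) > 0) & (denom > 0)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 polymorphic sites; PCA undefined")
    X = (X[:, keep] - mu[keep]) / denom[keep]
    X[np.isnan(X)] = 0.0  # mean imputation after centering
    cov = X @ X.T / X.shape[1]
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    k = min(n_components, len(eigval))
    coords = eigvec[:, :k] * np.sqrt(eigval[:k])
    for j in range(k):  # deterministic sign
        i_max = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    total = eigval.sum()
    evr = eigval[:k] / total if total > 0 else np.zeros(k)
    return coords, evr


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def pairwise_distance(
    gm: GenotypeMatrix, metric: str = "allele_sharing"
) -> DistanceMatrix:
    """Pairwise genetic distance between samples.

    ``allele_sharing``: mean over co-genotyped sites of |g_i - g_j| / 2.
    ``mismatch``: proportion of co-genotyped sites with different codes.
    A sample pair with no co-genotyped site is an error.
    """
    calls = gm.calls.astype(np.float64)
    ok = calls >= 0
    n = gm.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"samples {gm.samples[i]!r} and {gm.samples[j]!r} share "
                    "no genotyped site"
                )
            if metric == "allele_sharing":
                dij = float(np.abs(calls[i, both] - calls[j, both]).sum() / (2.0 * m))
            elif metric == "mismatch":
                dij = float((calls[i, both] != calls[j, both]).sum() / m)
            else:
                raise ValueError(f"unknown metric {metric!r}")
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(ids=list(gm.samples), values=d)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining.

    Q-criterion agglomeration with ties broken toward the lowest index
    pair; terminates in an unrooted tree represented by a trifurcating
    root. Negative branch lengths are kept (flagged in the log) so that
    additive matrices are inverted exactly.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=s) for s in dm.ids]
    d = dm.values.astype(np.float64).copy()
    n_negative = 0

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest-index tie rule: argmin of flattened row-major scan
        flat = int(np.argmin(q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0 or lj < 0:
            n_negative += 1
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        d_new = (d[i, :] + d[j, :] - d[i, j]) / 2.0
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], d_new[keep][None, :]])
        d = np.hstack([d, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]

    # final three nodes join at the unrooted center
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    l0 = (d01 + d02 - d12) / 2.0
    l1 = (d01 + d12 - d02) / 2.0
    l2 = (d02 + d12 - d01) / 2.0
    if min(l0, l1, l2) < 0:
        n_negative += 1
    if n_negative:
        logger.info("neighbor_joining: %d negative branch length event(s) retained", n_negative)
    return TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Internal-edge bipartitions, canonicalised as the side not containing
    the lexicographically smallest leaf. Trivial splits are excluded."""
    all_leaves = tree.leaves()
    anchor = min(all_leaves)
    total = frozenset(all_leaves)
    out: set[frozenset[str]] = set()

    def walk(node: TreeNode) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])  # type: ignore[list-item]
        below = frozenset()
        for child, _ in node.children:
            below |= walk(child)
        if node is not tree and 2 <= len(below) <= len(all_leaves) - 2:
            side = below if anchor not in below else total - below
            out.add(side)
        return below

    walk(tree)
    return out


def bootstrap_support(
    gm: GenotypeMatrix,
    reps: int = 1000,
    seed: int = 0,
    metric: str = "allele_sharing",
    resampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
) -> TreeNode:
    """NJ tree with bootstrap support on internal edges.

    Sites are resampled with replacement ``reps`` times; support for each
    internal bipartition of the full-data tree is the fraction of
    replicate trees containing it. ``resampler(rng, n_sites)`` can replace
    the default with-replacement draw (e.g. the identity, for testing).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    tree = neighbor_joining(pairwise_distance(gm, metric=metric))
    target = bipartitions(tree)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    for _ in range(reps):
        if resampler is None:
            idx = rng.integers(0, gm.n_sites, size=gm.n_sites)
        else:
            idx = resampler(rng, gm.n_sites)
        # resampled site sets need not stay sorted/unique, so build the
        # distance matrix directly from the resampled calls
        rep_tree = neighbor_joining(
            DistanceMatrix(
                ids=list(gm.samples),
                values=_distance_from_calls(gm.calls[:, idx], metric),
            )
        )
        rep_bps = bipartitions(rep_tree)
        for bp in target:
            if bp in rep_bps:
                counts[bp] += 1

    def annotate(node: TreeNode, total: frozenset[str], anchor: str) -> frozenset[str]:
        if node.is_leaf:
            return frozenset([node.name])  # type: ignore[list-item]
        below = frozenset()
        for child, _ in node.children:
            below |= annotate(child, total, anchor)
        if node is not tree and 2 <= len(below) <= len(total) - 2:
            side = below if anchor not in below else total - below
            node.support = counts[side] / reps
        return below

    leaves = frozenset(tree.leaves())
    annotate(tree, leaves, min(leaves))
    return tree


def _distance_from_calls(calls: np.ndarray, metric: str) -> np.ndarray:
    c = calls.astype(np.float64)
    ok = c >= 0
    n = c.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError("sample pair with no co-genotyped site")
            if metric == "allele_sharing":
                d[i, j] = d[j, i] = np.abs(c[i, both] - c[j, both]).sum() / (2.0 * m)
            else:
                d[i, j] = d[j, i] = (c[i, both] != c[j, both]).sum() / m
    return d
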