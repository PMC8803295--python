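"""Nei's standard genetic distance, neighbor-joining, locus bootstrap.

Distance: for populations X, Y with per-locus allele frequencies p, q the
gene identities are j_X = sum p^2, j_Y = sum q^2, j_XY = sum p q.  Nei's
standard distance uses arithmetic means of these identities across loci,

    D = -ln( J_XY / sqrt(J_X * J_Y) ).

With the sample-size bias correction (default), the within-population
identity at a locus typed in n diploids is (2n * sum p^2 - 1) / (2n - 1),
the unbiased estimator of the expected homozygosity.  Populations sharing
no alleles anywhere give J_XY = 0 and an infinite distance flag.

Trees: Saitou-Nei neighbor joining with a deterministic tie-break (the
first minimal Q-matrix pair in current node order) and a clamping rule for
negative branch lengths (clamped to zero, the deficit transferred to the
sister branch so the pair's patristic distance is preserved).  Node support
comes from resampling loci with replacement and counting, for each internal
edge of the original tree, the percentage of replicate trees containing the
same leaf bipartition.  Output is Newick with integer-percent supports as
internal node labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geno_io import GenotypeTable, allele_frequencies


# ---------------------------------------------------------------------------
# Nei's standard distance
# ---------------------------------------------------------------------------

def nei_distance(gt: GenotypeTable, popmap=None, bias_corrected: bool = True,
                 ) -> pd.DataFrame:
    """Symmetric matrix of Nei's standard distances between populations.

    Loci untyped in either member of a pair are skipped for that pair; a
    pair with no shared typed locus reports NA, a pair with no shared
    alleles reports ``inf``.
    """
    labels = gt.populations if popmap is None else gt.group_labels(popmap)
    pops = list(dict.fromkeys(labels))
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    freqs = allele_frequencies(gt, labels)
    return nei_distance_from_freqs(freqs, gt.locus_names, bias_corrected)


def nei_distance_from_freqs(freqs, locus_names, bias_corrected: bool = True,
                            loci: list[str] | None = None) -> pd.DataFrame:
    """Distance matrix from an :class:`AlleleFreqTable` (resamplable loci)."""
    pops = freqs.groups
    loci = list(locus_names) if loci is None else loci
    D = pd.DataFrame(0.0, index=pops, columns=pops)
    for x in range(len(pops)):
        for y in range(x + 1, len(pops)):
            jx_l, jy_l, jxy_l = [], [], []
            for loc in loci:
                fx = freqs.freqs.get((pops[x], loc))
                fy = freqs.freqs.get((pops[y], loc))
                if fx is None or fy is None:
                    continue
                jx = sum(v * v for v in fx.values())
                jy = sum(v * v for v in fy.values())
                jxy = sum(v * fy.get(a, 0.0) for a, v in fx.items())
                if bias_corrected:
                    nx = freqs.gene_copies[(pops[x], loc)]
                    ny = freqs.gene_copies[(pops[y], loc)]
                    if nx > 1:
                        jx = (nx * jx - 1.0) / (nx - 1.0)
                    if ny > 1:
                        jy = (ny * jy - 1.0) / (ny - 1.0)
                jx_l.append(jx)
                jy_l.append(jy)
                jxy_l.append(jxy)
            if not jx_l:
                d = np.nan
            else:
                JX, JY, JXY = (float(np.mean(v)) for v in (jx_l, jy_l, jxy_l))
                denom = np.sqrt(max(JX, 0.0) * max(JY, 0.0))
                d = np.inf if JXY <= 0.0 or denom <= 0.0 \
                    else max(-np.log(JXY / denom), 0.0)
            D.iloc[x, y] = D.iloc[y, x] = d
    return D


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: int | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary internal root."""

    root: TreeNode

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self.root.leaves())

    def newick(self) -> str:
        def render(node: TreeNode) -> str:
            if not node.children:
                return node.label or ""
            inner = ",".join(f"{render(c)}:{ln:.6g}"
                             for c, ln in node.children)
            tag = "" if node.support is None else str(node.support)
            return f"({inner}){tag}"
        return render(self.root) + ";"

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Non-trivial splits, keyed by their canonical side.

        The canonical side of a split is the one NOT containing the
        alphabetically first leaf, so both orientations compare equal.
        """
        all_leaves = set(self.root.leaves())
        ref = min(all_leaves)
        out: dict[frozenset[str], TreeNode] = {}

        def walk(node: TreeNode) -> None:
            for child, _ in node.children:
                side = set(child.leaves())
                if 1 < len(side) < len(all_leaves) - 1:
                    canon = frozenset(side if ref not in side
                                      else all_leaves - side)
                    out[canon] = child
                walk(child)

        walk(self.root)
        return out


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sister."""
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(d: pd.DataFrame) -> PhyloTree:
    """Saitou-Nei neighbor joining on a labelled distance matrix.

    Ties in the Q matrix break deterministically to the first minimal
    (i, j) pair in current node order (original label order, then internal
    nodes in creation order).  Infinite entries are refused: prune the
    offending taxa first.
    """
    labels = list(d.index)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    D = d.to_numpy(dtype=float).copy()
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite distances; prune taxa with infinite "
                         "or undefined entries before building the tree")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    nodes: list[TreeNode] = [TreeNode(label=l) for l in labels]
    active = list(range(len(labels)))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for a in range(m):
            for b in range(a + 1, m):
                if best is None or Q[a, b] < Q[best] - 1e-12:
                    best = (a, b)
        a, b = best                                      # type: ignore
        i, j = active[a], active[b]
        li = sub[a, b] / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lj = sub[a, b] - li
        li, lj = _clamp_pair(li, lj)
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        nodes.append(new)
        u = len(nodes) - 1
        D = np.pad(D, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = (D[i, k] + D[j, k] - D[i, j]) / 2.0
        active = [k for k in active if k not in (i, j)] + [u]

    # final trifurcation: exact solve of the three pairwise equations
    i, j, k = active
    dij, dik, djk = D[i, j], D[i, k], D[j, k]
    li = (dij + dik - djk) / 2.0
    lj = (dij + djk - dik) / 2.0
    lk = (dik + djk - dij) / 2.0
    root = TreeNode(children=[(nodes[i], max(li, 0.0)),
                              (nodes[j], max(lj, 0.0)),
                              (nodes[k], max(lk, 0.0))])
    return PhyloTree(root)


def tree_distance(tree: PhyloTree) -> pd.DataFrame:
    """Patristic leaf-to-leaf distances (oracle helper for additivity)."""
    labels = tree.leaf_labels
    D = pd.DataFrame(0.0, index=labels, columns=labels)

    def walk(node: TreeNode, acc: float, dists: dict[str, float]) -> None:
        if not node.children:
            dists[node.label] = acc         # type: ignore[index]
            return
        for child, ln in node.children:
            walk(child, acc + ln, dists)

    def pairwise(node: TreeNode) -> None:
        for child, ln in node.children:
            pairwise(child)
        # combine distances across sibling subtrees at this node
        sub: list[dict[str, float]] = []
        for child, ln in node.children:
            dists: dict[str, float] = {}
            walk(child, ln, dists)
            sub.append(dists)
        for x in range(len(sub)):
            for y in range(x + 1, len(sub)):
                for lx, dx in sub[x].items():
                    for ly, dy in sub[y].items():
                        D.loc[lx, ly] = D.loc[ly, lx] = dx + dy

    pairwise(tree.root)
    return D


def bootstrap_support(gt: GenotypeTable, popmap=None, n_boot: int = 1000,
                      bias_corrected: bool = True, seed: int = 0,
                      ) -> PhyloTree:
    """NJ tree with locus-bootstrap supports on internal edges.

    Loci are resampled with replacement ``n_boot`` times; support is the
    percentage of replicate trees containing each original bipartition.
    """
    if gt.n_loci < 2:
        raise ValueError("bootstrap needs at least 2 loci")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    labels = gt.populations if popmap is None else gt.group_labels(popmap)
    freqs = allele_frequencies(gt, labels)
    base = nj_tree(nei_distance_from_freqs(freqs, gt.locus_names,
                                           bias_corrected))
    splits = base.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    loci = list(gt.locus_names)
    for _ in range(n_boot):
        sample = [loci[i] for i in rng.integers(0, len(loci), len(loci))]
        d = nei_distance_from_freqs(freqs, gt.locus_names, bias_corrected,
                                    loci=sample)
        if not np.all(np.isfinite(d.to_numpy())):
            continue
        rep = nj_tree(d).bipartitions()
        for s in counts:
            if s in rep:
                counts[s] += 1
    for s, node in splits.items():
        node.support = int(round(100.0 * counts[s] / n_boot))
    return base
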