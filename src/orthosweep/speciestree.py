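"""Quartet-agreement species-tree estimation from gene trees.

The objective is the total number of gene-tree quartets that agree with
the candidate topology (summed over gene trees and over all four-leaf
subsets both trees carry).  Exhaustive enumeration serves as a global
optimum and oracle for up to 8 taxa; the scalable path is stepwise
random-order leaf insertion followed by nearest-neighbour-interchange
hill climbing, both deterministic for a fixed seed.

Unresolved gene-tree quartets (polytomies) and quartets touching taxa a
gene tree lacks contribute nothing to the score.  Only the topology is
estimated: branch lengths are left unset.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io_formats import read_newick
from .treestats import bipartition_masks, leaf_mask, taxon_index

_MAX_EXHAUSTIVE = 8


@dataclass
class QuartetScore:
    """An unrooted topology and its quartet-agreement score."""

    topology: dendropy.Tree
    score: int
    co_optima: list[str] = field(default_factory=list)  # canonical Newicks


# ---------------------------------------------------------------------------
# Quartet codes: one int8 per 4-taxon subset per tree
# ---------------------------------------------------------------------------


def _quartet_array(n_taxa: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(n_taxa), 4)), dtype=np.int64)


def _codes_from_masks(
    bips: list[int], tree_mask: int, quartets: np.ndarray, n_taxa: int
) -> np.ndarray:
    """Code per quartet: 0 = q0q1|q2q3, 1 = q0q2|q1q3, 2 = q0q3|q1q2, -1 = none.

    Quartets with a taxon absent from the tree, or unresolved in it,
    get -1.
    """
    nq = len(quartets)
    codes = np.full(nq, -1, dtype=np.int8)
    if not bips or nq == 0:
        return codes
    member = np.zeros((len(bips), n_taxa), dtype=bool)
    for i, m in enumerate(bips):
        for t in range(n_taxa):
            member[i, t] = bool((m >> t) & 1)
    present = np.array([bool((tree_mask >> t) & 1) for t in range(n_taxa)])
    q = quartets
    a, b, c, d = (member[:, q[:, k]] for k in range(4))  # each (nb, nq)
    p0 = ((a == b) & (c == d) & (a != c)).any(axis=0)
    p1 = ((a == c) & (b == d) & (a != b)).any(axis=0)
    p2 = ((a == d) & (b == c) & (a != b)).any(axis=0)
    codes[p0] = 0
    codes[p1] = 1
    codes[p2] = 2
    in_tree = present[q].all(axis=1)
    codes[~in_tree] = -1
    return codes


def _tree_codes(tree: dendropy.Tree, index: dict[str, int], quartets: np.ndarray) -> np.ndarray:
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    known = [l for l in leaves if l in index]
    mask = leaf_mask(known, index)
    bips = sorted(bipartition_masks(tree, index)) if len(known) >= 4 else []
    return _codes_from_masks(bips, mask, quartets, len(index))


def _gene_code_matrix(
    gene_trees: list[dendropy.Tree], index: dict[str, int], quartets: np.ndarray
) -> np.ndarray:
    return np.stack([_tree_codes(gt, index, quartets) for gt in gene_trees])


def _score_codes(topo_codes: np.ndarray, gene_codes: np.ndarray) -> int:
    usable = (topo_codes[None, :] >= 0) & (gene_codes >= 0)
    return int(((gene_codes == topo_codes[None, :]) & usable).sum())


def quartet_agreement_score(
    topology: dendropy.Tree, gene_trees: list[dendropy.Tree]
) -> int:
    """Total gene-tree quartets agreeing with the topology."""
    labels = {leaf.taxon.label for leaf in topology.leaf_node_iter()}
    index = taxon_index(labels)
    quartets = _quartet_array(len(index))
    topo_codes = _tree_codes(topology, index, quartets)
    gene_codes = _gene_code_matrix(gene_trees, index, quartets)
    return _score_codes(topo_codes, gene_codes)


# ---------------------------------------------------------------------------
# Internal unrooted-tree scaffold (taxa are integers 0..n-1)
# ---------------------------------------------------------------------------


class _UTree:
    """Mutable unrooted binary tree; leaves are taxon indices >= 0."""

    def __init__(self, t0: int, t1: int, t2: int, t3: int, pairing: int, n_taxa: int):
        # pairing 0: t0t1|t2t3, 1: t0t2|t1t3, 2: t0t3|t1t2
        x, y = -1, -2
        pairs = {
            0: ((t0, t1), (t2, t3)),
            1: ((t0, t2), (t1, t3)),
            2: ((t0, t3), (t1, t2)),
        }[pairing]
        self.adj: dict[int, list[int]] = {
            x: [pairs[0][0], pairs[0][1], y],
            y: [pairs[1][0], pairs[1][1], x],
            pairs[0][0]: [x],
            pairs[0][1]: [x],
            pairs[1][0]: [y],
            pairs[1][1]: [y],
        }
        self._next = -3
        self.n_taxa = n_taxa

    def copy(self) -> "_UTree":
        t = object.__new__(_UTree)
        t.adj = {k: list(v) for k, v in self.adj.items()}
        t._next = self._next
        t.n_taxa = self.n_taxa
        return t

    def edges(self) -> list[tuple[int, int]]:
        seen: set[tuple[int, int]] = set()
        for u, nbrs in self.adj.items():
            for v in nbrs:
                seen.add((u, v) if u <= v else (v, u))
        return sorted(seen)

    def insert_leaf(self, taxon: int, edge: tuple[int, int]) -> None:
        u, v = edge
        w = self._next
        self._next -= 1
        self.adj[u] = [w if x == v else x for x in self.adj[u]]
        self.adj[v] = [w if x == u else x for x in self.adj[v]]
        self.adj[w] = [u, v, taxon]
        self.adj[taxon] = [w]

    def leaf_masks(self) -> tuple[list[int], int]:
        """Canonical non-trivial bipartition masks and the full leaf mask."""
        full = 0
        for node in self.adj:
            if node >= 0:
                full |= 1 << node
        low_bit = full & -full
        # root at an arbitrary leaf's neighbour; subtree masks per edge
        start = next(n for n in self.adj if n >= 0)
        masks: list[int] = []
        below: dict[tuple[int, int], int] = {}

        def down(u: int, parent: int) -> int:
            if u >= 0:
                below[(parent, u)] = 1 << u
                return 1 << u
            m = 0
            for v in self.adj[u]:
                if v != parent:
                    m |= down(v, u)
            below[(parent, u)] = m
            return m

        root = self.adj[start][0]
        down(root, start)
        for (parent, u), m in below.items():
            side = (full ^ m) if (m & low_bit) else m
            if side.bit_count() >= 2 and (full ^ side).bit_count() >= 2:
                masks.append(side)
        return sorted(set(masks)), full

    def internal_edges(self) -> list[tuple[int, int]]:
        return [e for e in self.edges() if e[0] < 0 and e[1] < 0]

    def nni_neighbors(self, edge: tuple[int, int]) -> list["_UTree"]:
        u, v = edge
        nu = [x for x in self.adj[u] if x != v]
        nv = [x for x in self.adj[v] if x != u]
        out = []
        for swap_v in (nv[0], nv[1]):
            t = self.copy()
            b = nu[1]
            # swap subtree b (at u) with swap_v (at v)
            t.adj[u] = [swap_v if x == b else x for x in t.adj[u]]
            t.adj[v] = [b if x == swap_v else x for x in t.adj[v]]
            t.adj[b] = [v if x == u else x for x in t.adj[b]]
            t.adj[swap_v] = [u if x == v else x for x in t.adj[swap_v]]
            out.append(t)
        return out

    def newick(self, labels: list[str]) -> str:
        start = min(n for n in self.adj if n >= 0)
        hub = self.adj[start][0]

        def sub(u: int, parent: int) -> str:
            if u >= 0:
                return labels[u]
            parts = sorted(sub(v, u) for v in self.adj[u] if v != parent)
            return "(" + ",".join(parts) + ")"

        parts = sorted(sub(v, hub) for v in self.adj[hub] if v != start)
        return f"({labels[start]},{','.join(parts)});"


def _utree_codes(tree: _UTree, quartets: np.ndarray) -> np.ndarray:
    bips, full = tree.leaf_masks()
    return _codes_from_masks(bips, full, quartets, tree.n_taxa)


def _all_topologies(n: int):
    """Yield every unrooted binary topology on taxa 0..n-1 (stepwise addition)."""
    for pairing in (0, 1, 2):
        t = _UTree(0, 1, 2, 3, pairing, n)
        yield from _grow(t, 4, n)


def _grow(tree: _UTree, next_taxon: int, n: int):
    if next_taxon == n:
        yield tree
        return
    for edge in tree.edges():
        t = tree.copy()
        t.insert_leaf(next_taxon, edge)
        yield from _grow(t, next_taxon + 1, n)


def _resolve_taxa(gene_trees, taxa):
    if taxa is None:
        s: set[str] = set()
        for gt in gene_trees:
            s.update(leaf.taxon.label for leaf in gt.leaf_node_iter())
        taxa = sorted(s)
    else:
        taxa = sorted(taxa)
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")
    return taxa


def exhaustive_search(
    gene_trees: list[dendropy.Tree], taxa: list[str] | None = None
) -> QuartetScore:
    """Globally optimal topology by enumerating all unrooted binary trees.

    Limited to 8 taxa (10,395 topologies).  Ties are broken by the
    lexicographically smallest canonical Newick; all co-optima are
    reported.
    """
    taxa = _resolve_taxa(gene_trees, taxa)
    n = len(taxa)
    if n > _MAX_EXHAUSTIVE:
        raise ValueError(f"exhaustive search limited to {_MAX_EXHAUSTIVE} taxa, got {n}")
    index = {lbl: i for i, lbl in enumerate(taxa)}
    quartets = _quartet_array(n)
    gene_codes = _gene_code_matrix(gene_trees, index, quartets)
    best_score = -1
    best: list[str] = []
    for topo in _all_topologies(n):
        s = _score_codes(_utree_codes(topo, quartets), gene_codes)
        if s > best_score:
            best_score = s
            best = [topo.newick(taxa)]
        elif s == best_score:
            best.append(topo.newick(taxa))
    best = sorted(best)
    return QuartetScore(read_newick(best[0]), best_score, best)


def greedy_search(
    gene_trees: list[dendropy.Tree],
    taxa: list[str] | None = None,
    rng: np.random.Generator | int | None = None,
) -> QuartetScore:
    """Stepwise random-order insertion plus NNI hill climbing.

    Each leaf is placed on the score-maximising edge (first edge in
    deterministic order wins ties); hill climbing accepts the first
    improving nearest-neighbour interchange and stops at a local
    optimum.  Deterministic given the seed.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    taxa = _resolve_taxa(gene_trees, taxa)
    n = len(taxa)
    index = {lbl: i for i, lbl in enumerate(taxa)}
    quartets = _quartet_array(n)
    gene_codes = _gene_code_matrix(gene_trees, index, quartets)

    def score(t: _UTree) -> int:
        return _score_codes(_utree_codes(t, quartets), gene_codes)

    order = list(rng.permutation(n))
    t0, t1, t2, t3 = order[:4]
    tree = max(
        (_UTree(t0, t1, t2, t3, p, n) for p in (0, 1, 2)),
        key=lambda t: (score(t)),
    )
    for taxon in order[4:]:
        best_tree, best_s = None, -1
        for edge in tree.edges():
            cand = tree.copy()
            cand.insert_leaf(taxon, edge)
            s = score(cand)
            if s > best_s:
                best_tree, best_s = cand, s
        tree = best_tree

    current = score(tree)
    improved = True
    while improved:
        improved = False
        for edge in tree.internal_edges():
            for nbr in tree.nni_neighbors(edge):
                s = score(nbr)
                if s > current:
                    assert s >= current  # hill climbing never decreases
                    tree, current = nbr, s
                    improved = True
                    break
            if improved:
                break
    return QuartetScore(read_newick(tree.newick(taxa)), current, [tree.newick(taxa)])
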