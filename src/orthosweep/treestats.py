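"""Tree comparison and per-branch concordance statistics.

Bipartitions (unrooted splits) and clades (rooted clusters) are encoded
as bitmasks over a shared taxon index, which makes Robinson-Foulds
distances, clade recovery, gene concordance factors and quartet support
simple set arithmetic.  Gene trees may miss taxa; each statistic
restricts itself to the leaves a gene tree actually carries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import nan

import dendropy
import numpy as np

from .io_formats import read_newick


@dataclass(frozen=True)
class Bipartition:
    """An unordered split of the taxon set into two non-empty sides."""

    side_a: frozenset[str]
    side_b: frozenset[str]

    def __post_init__(self) -> None:
        if not self.side_a or not self.side_b:
            raise ValueError("both sides of a bipartition must be non-empty")
        if self.side_a & self.side_b:
            raise ValueError("bipartition sides overlap")

    @property
    def nontrivial(self) -> bool:
        return len(self.side_a) >= 2 and len(self.side_b) >= 2

    def __eq__(self, other) -> bool:
        if not isinstance(other, Bipartition):
            return NotImplemented
        return {self.side_a, self.side_b} == {other.side_a, other.side_b}

    def __hash__(self) -> int:
        return hash(frozenset((self.side_a, self.side_b)))


@dataclass
class BranchConcordance:
    """Per-branch concordance summary against a set of gene trees."""

    branch: Bipartition
    gcf_pct: float = nan  # percent; NaN when no gene tree is decisive
    n_decisive: int = 0
    n_concordant: int = 0
    q1: float = nan  # concordant quartet fraction
    q2: float = nan
    q3: float = nan
    n_quartets: int = 0  # resolved gene-tree quartet observations


# ---------------------------------------------------------------------------
# Bitmask encoding
# ---------------------------------------------------------------------------


def taxon_index(labels) -> dict[str, int]:
    return {label: i for i, label in enumerate(sorted(labels))}


def leaf_mask(labels, index: dict[str, int]) -> int:
    m = 0
    for label in labels:
        m |= 1 << index[label]
    return m


def _node_masks(tree: dendropy.Tree, index: dict[str, int]) -> dict:
    """Leaf-set bitmask of every node, by postorder accumulation."""
    masks: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            masks[node] = 1 << index[node.taxon.label]
        else:
            m = 0
            for ch in node.child_nodes():
                m |= masks[ch]
            masks[node] = m
    return masks


def clade_masks(tree: dendropy.Tree, index: dict[str, int]) -> set[int]:
    """Masks of internal, non-root clades of a rooted tree."""
    masks = _node_masks(tree, index)
    root = tree.seed_node
    return {m for node, m in masks.items() if not node.is_leaf() and node is not root}


def bipartition_masks(tree: dendropy.Tree, index: dict[str, int]) -> set[int]:
    """Canonical masks of the non-trivial unrooted bipartitions.

    Each split is represented by the side not containing the
    lowest-index taxon of the tree, so the representation is rooting
    independent.
    """
    masks = _node_masks(tree, index)
    full = masks[tree.seed_node]
    low_bit = full & -full
    out: set[int] = set()
    for node, m in masks.items():
        if node is tree.seed_node:
            continue
        side = (full ^ m) if (m & low_bit) else m
        if _popcount(side) >= 2 and _popcount(full ^ side) >= 2:
            out.add(side)
    return out


def _popcount(x: int) -> int:
    return int(x).bit_count()


def _restrict(masks: set[int], subset: int, full: int) -> set[int]:
    """Restrict splits to a leaf subset, re-canonicalise, drop trivial."""
    low_bit = subset & -subset
    out: set[int] = set()
    for m in masks:
        r = m & subset
        side = (subset ^ r) if (r & low_bit) else r
        if _popcount(side) >= 2 and _popcount(subset ^ side) >= 2:
            out.add(side)
    return out


def _mask_to_labels(mask: int, index: dict[str, int]) -> frozenset[str]:
    rev = {i: lbl for lbl, i in index.items()}
    return frozenset(rev[i] for i in range(len(index)) if (mask >> i) & 1)


# ---------------------------------------------------------------------------
# Robinson-Foulds distance and clade recovery
# ---------------------------------------------------------------------------


def rf_distance(
    t1: dendropy.Tree,
    t2: dendropy.Tree,
    mode: str = "unrooted",
    prune_to_common: bool = False,
) -> int:
    """Robinson-Foulds distance between two trees.

    Unrooted mode counts the symmetric difference of non-trivial
    bipartition sets; rooted mode the symmetric difference of internal
    non-root clade sets.  With ``prune_to_common`` both trees are
    restricted to their shared leaves first.
    """
    if mode not in ("rooted", "unrooted"):
        raise ValueError(f"unknown mode {mode!r}")
    l1 = {leaf.taxon.label for leaf in t1.leaf_node_iter()}
    l2 = {leaf.taxon.label for leaf in t2.leaf_node_iter()}
    if l1 != l2 and not prune_to_common:
        raise ValueError("leaf sets differ; pass prune_to_common=True to compare anyway")
    common = l1 & l2
    min_leaves = 3 if mode == "rooted" else 4
    if len(common) < min_leaves:
        raise ValueError(f"need at least {min_leaves} shared leaves, have {len(common)}")
    index = taxon_index(l1 | l2)
    sub = leaf_mask(common, index)
    if mode == "unrooted":
        full1 = leaf_mask(l1, index)
        full2 = leaf_mask(l2, index)
        s1 = _restrict(bipartition_masks(t1, index), sub, full1)
        s2 = _restrict(bipartition_masks(t2, index), sub, full2)
    else:
        s1 = {m & sub for m in clade_masks(t1, index)}
        s2 = {m & sub for m in clade_masks(t2, index)}
        s1 = {m for m in s1 if 2 <= _popcount(m) < _popcount(sub)}
        s2 = {m for m in s2 if 2 <= _popcount(m) < _popcount(sub)}
    return len(s1 ^ s2)


def clade_recovery(
    tree: dendropy.Tree, reference_clades: list[set[str] | frozenset[str]]
) -> list[bool]:
    """For each reference leaf set, is it exactly a clade of the rooted tree?"""
    leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for clade in reference_clades:
        unknown = set(clade) - leaves
        if unknown:
            raise ValueError(f"reference clade contains unknown leaves {sorted(unknown)}")
    index = taxon_index(leaves)
    masks = set(_node_masks(tree, index).values())
    return [leaf_mask(c, index) in masks for c in reference_clades]


# ---------------------------------------------------------------------------
# Gene concordance factor
# ---------------------------------------------------------------------------


def gene_concordance_factor(
    species_tree: dendropy.Tree, gene_trees: list[dendropy.Tree]
) -> list[BranchConcordance]:
    """gCF per internal species-tree branch.

    A gene tree is decisive for a branch when both sides of the branch's
    bipartition, restricted to the gene tree's leaves, keep at least two
    taxa; it is concordant when that restricted bipartition occurs in
    the gene tree.  gCF = 100 x concordant / decisive.
    """
    sp_leaves = {leaf.taxon.label for leaf in species_tree.leaf_node_iter()}
    index = taxon_index(sp_leaves)
    full = leaf_mask(sp_leaves, index)
    sp_bips = sorted(bipartition_masks(species_tree, index))
    gene_info = []
    for gt in gene_trees:
        g_leaves = {leaf.taxon.label for leaf in gt.leaf_node_iter()}
        gmask = leaf_mask(g_leaves & sp_leaves, index)
        if len(g_leaves) >= 4:
            gbips = _restrict(bipartition_masks(gt, index), gmask, gmask)
        else:
            gbips = set()
        gene_info.append((gmask, gbips))
    out = []
    for bip in sp_bips:
        decisive = concordant = 0
        for gmask, gbips in gene_info:
            a = bip & gmask
            b = (full ^ bip) & gmask
            if _popcount(a) < 2 or _popcount(b) < 2:
                continue
            decisive += 1
            low_bit = gmask & -gmask
            side = (gmask ^ a) if (a & low_bit) else a
            if side in gbips:
                concordant += 1
        bc = BranchConcordance(
            branch=Bipartition(_mask_to_labels(bip, index), _mask_to_labels(full ^ bip, index)),
            n_decisive=decisive,
            n_concordant=concordant,
        )
        if decisive:
            bc.gcf_pct = 100.0 * concordant / decisive
        out.append(bc)
    return out


# ---------------------------------------------------------------------------
# Quartet support
# ---------------------------------------------------------------------------


def _quartet_topology(gbips: set[int], gmask: int, a: int, b: int, c: int, d: int) -> int:
    """Topology a quartet of taxon bits induces in a gene tree.

    Returns 0 for ab|cd, 1 for ac|bd, 2 for ad|bc, -1 if unresolved.
    The gene tree's splits are canonical masks within ``gmask``.
    """
    for m in gbips:
        ina, inb, inc, ind = bool(m & a), bool(m & b), bool(m & c), bool(m & d)
        if ina == inb and inc == ind and ina != inc:
            return 0
        if ina == inc and inb == ind and ina != inb:
            return 1
        if ina == ind and inb == inc and ina != inb:
            return 2
    return -1


def _branch_clusters(species_tree, masks, full):
    """For each internal branch, the four adjacent subtree leaf masks.

    Yields (branch_mask, (a1, a2, b1, b2)) with a1|a2 the child side and
    b1|b2 the far side of the branch.
    """
    node_mask = masks
    root = species_tree.seed_node
    root_children = root.child_nodes()
    for node in species_tree.preorder_node_iter():
        if node is root or node.is_leaf():
            continue
        m = node_mask[node]
        other = full ^ m
        if _popcount(m) < 2 or _popcount(other) < 2:
            continue
        kids = node.child_nodes()
        if len(kids) != 2:
            continue  # quartet support needs binary branches
        a1, a2 = node_mask[kids[0]], node_mask[kids[1]]
        parent = node.parent_node
        siblings = [ch for ch in parent.child_nodes() if ch is not node]
        if parent is root and len(root_children) == 2:
            sib = siblings[0]
            sk = sib.child_nodes()
            if len(sk) != 2:
                continue
            b1, b2 = node_mask[sk[0]], node_mask[sk[1]]
        else:
            b1 = node_mask[siblings[0]] if siblings else 0
            b2 = other ^ b1
            if b1 == 0 or b2 == 0:
                continue
        yield m, (a1, a2, b1, b2)


def _mask_bits(mask: int) -> list[int]:
    bits = []
    while mask:
        low = mask & -mask
        bits.append(low)
        mask ^= low
    return bits


def quartet_support(
    species_tree: dendropy.Tree,
    gene_trees: list[dendropy.Tree],
    max_quartets_per_branch: int = 1000,
    rng: np.random.Generator | None = None,
) -> list[BranchConcordance]:
    """Quartet support (q1/q2/q3) per internal species-tree branch.

    For each branch the four adjacent subtree clusters define the
    quartets (one leaf per cluster).  Over all gene trees carrying the
    four sampled leaves, the three possible quartet topologies are
    tallied; q1 is the fraction concordant with the species tree.
    Exhaustive when the quartet count fits under the cap, otherwise
    uniformly sampled with ``rng``.
    """
    sp_leaves = {leaf.taxon.label for leaf in species_tree.leaf_node_iter()}
    index = taxon_index(sp_leaves)
    full = leaf_mask(sp_leaves, index)
    masks = _node_masks(species_tree, index)
    gene_info = []
    for gt in gene_trees:
        g_leaves = {leaf.taxon.label for leaf in gt.leaf_node_iter()}
        gmask = leaf_mask(g_leaves & sp_leaves, index)
        gbips = _restrict(bipartition_masks(gt, index), gmask, gmask) if len(g_leaves) >= 4 else set()
        gene_info.append((gmask, gbips))
    out = []
    seen_branches: set[int] = set()
    low_bit = full & -full
    for branch_mask, (a1, a2, b1, b2) in _branch_clusters(species_tree, masks, full):
        canon = (full ^ branch_mask) if (branch_mask & low_bit) else branch_mask
        if canon in seen_branches:
            continue
        seen_branches.add(canon)
        bits = [_mask_bits(x) for x in (a1, a2, b1, b2)]
        n_quartets = np.prod([len(b) for b in bits])
        if n_quartets <= max_quartets_per_branch:
            quartets = list(itertools.product(*bits))
        else:
            if rng is None:
                raise ValueError("sampling required (quartet count over cap) but no rng given")
            quartets = [
                tuple(b[rng.integers(len(b))] for b in bits)
                for _ in range(max_quartets_per_branch)
            ]
        tally = [0, 0, 0]
        for qa, qb, qc, qd in quartets:
            probe = qa | qb | qc | qd
            for gmask, gbips in gene_info:
                if (gmask & probe) != probe:
                    continue
                topo = _quartet_topology(gbips, gmask, qa, qb, qc, qd)
                if topo >= 0:
                    tally[topo] += 1
        total = sum(tally)
        bc = BranchConcordance(
            branch=Bipartition(
                _mask_to_labels(branch_mask, index),
                _mask_to_labels(full ^ branch_mask, index),
            ),
            n_quartets=total,
        )
        if total:
            bc.q1, bc.q2, bc.q3 = (t / total for t in tally)
        out.append(bc)
    return out


def branch_concordance_table(
    species_tree: dendropy.Tree,
    gene_trees: list[dendropy.Tree],
    max_quartets_per_branch: int = 1000,
    rng: np.random.Generator | None = None,
) -> list[BranchConcordance]:
    """Combined gCF and quartet support per branch."""
    gcf = gene_concordance_factor(species_tree, gene_trees)
    qs = quartet_support(species_tree, gene_trees, max_quartets_per_branch, rng)
    by_branch = {bc.branch: bc for bc in qs}
    for bc in gcf:
        q = by_branch.get(bc.branch)
        if q is not None:
            bc.q1, bc.q2, bc.q3, bc.n_quartets = q.q1, q.q2, q.q3, q.n_quartets
    return gcf


# ---------------------------------------------------------------------------
# Rooting helpers
# ---------------------------------------------------------------------------


def root_on_outgroup(
    tree: dendropy.Tree, outgroup: str, prune_outgroup: bool = False
) -> dendropy.Tree:
    """Return a copy rooted on the given outgroup leaf (optionally pruned)."""
    t = tree.clone(depth=1)
    node = None
    for leaf in t.leaf_node_iter():
        if leaf.taxon.label == outgroup:
            node = leaf
            break
    if node is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    length = node.edge.length
    t.reroot_at_edge(node.edge, length1=(length or 0) / 2, length2=(length or 0) / 2)
    if prune_outgroup:
        t.prune_taxa_with_labels([outgroup], suppress_unifurcations=True)
        # pruning can leave the seed node with a single child
        if len(t.seed_node.child_nodes()) == 1:
            t.seed_node = t.seed_node.child_nodes()[0]
            t.seed_node.parent_node = None
    return t


def annotate_tree(
    species_tree: dendropy.Tree, table: list[BranchConcordance]
) -> dendropy.Tree:
    """Copy of the species tree with ``gcf/q1`` internal node labels."""
    t = species_tree.clone(depth=1)
    leaves = {leaf.taxon.label for leaf in t.leaf_node_iter()}
    index = taxon_index(leaves)
    full = leaf_mask(leaves, index)
    low_bit = full & -full
    by_mask = {}
    for bc in table:
        m = leaf_mask(bc.branch.side_a, index)
        side = (full ^ m) if (m & low_bit) else m
        by_mask[side] = bc
    masks = _node_masks(t, index)
    for node in t.preorder_node_iter():
        if node.is_leaf() or node is t.seed_node:
            continue
        m = masks[node]
        side = (full ^ m) if (m & low_bit) else m
        bc = by_mask.get(side)
        if bc is not None:
            gcf = "NA" if bc.gcf_pct != bc.gcf_pct else f"{bc.gcf_pct:.1f}"
            q1 = "NA" if bc.q1 != bc.q1 else f"{bc.q1:.3f}"
            node.label = f"{gcf}/{q1}"
    return t
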