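import itertools

import dendropy
import numpy as np
import pytest

from orthosweep.io_formats import read_newick
from orthosweep.synthdata import MSCParams, simulate_gene_trees, simulate_species_tree
from orthosweep.treestats import (
    Bipartition,
    clade_recovery,
    gene_concordance_factor,
    quartet_support,
    rf_distance,
    root_on_outgroup,
)


def _random_binary_tree(labels, rng):
    nodes = [f"{l}" for l in labels]
    newicks = list(nodes)
    while len(newicks) > 2:
        i, j = sorted(rng.choice(len(newicks), size=2, replace=False))
        b = newicks.pop(j)
        a = newicks.pop(i)
        newicks.append(f"({a},{b})")
    return read_newick(f"({newicks[0]},{newicks[1]});")


class TestRF:
    def test_identity(self, gene_tree_panel):
        sp, _ = gene_tree_panel
        assert rf_distance(sp, sp, mode="unrooted") == 0
        assert rf_distance(sp, sp, mode="rooted") == 0

    def test_four_leaf_disjoint_splits(self):
        t1 = read_newick("((A,B),(C,D));")
        t2 = read_newick("((A,C),(B,D));")
        assert rf_distance(t1, t2) == 2

    def test_four_leaf_values_are_zero_or_two(self, rng):
        for _ in range(20):
            t1 = _random_binary_tree("ABCD", rng)
            t2 = _random_binary_tree("ABCD", rng)
            assert rf_distance(t1, t2) in (0, 2)

    def test_leafset_mismatch_requires_pruning(self):
        t1 = read_newick("((A,B),(C,D));")
        t2 = read_newick("((A,B),(C,E));")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)

    def test_matches_dendropy_oracle(self, rng):
        """Independent check against dendropy's symmetric-difference RF."""
        labels = [f"t{i}" for i in range(10)]
        for _ in range(25):
            t1 = _random_binary_tree(labels, rng)
            t2 = _random_binary_tree(labels, rng)
            ns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(
                data=t1.as_string(schema="newick"), schema="newick", taxon_namespace=ns
            )
            d2 = dendropy.Tree.get(
                data=t2.as_string(schema="newick"), schema="newick", taxon_namespace=ns
            )
            expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert rf_distance(t1, t2, mode="unrooted") == expected

    def test_metric_properties(self, rng):
        labels = [f"t{i}" for i in range(8)]
        trees = [_random_binary_tree(labels, rng) for _ in range(6)]
        for a, b, c in itertools.combinations(trees, 3):
            dab = rf_distance(a, b)
            dbc = rf_distance(b, c)
            dac = rf_distance(a, c)
            assert dab == rf_distance(b, a)
            assert dac <= dab + dbc


class TestCladeRecovery:
    def test_present_and_absent(self):
        t = read_newick("((A,B),C);")
        assert clade_recovery(t, [{"A", "B"}, {"A", "C"}]) == [True, False]

    def test_full_leaf_set_is_root_clade(self):
        t = read_newick("((A,B),C);")
        assert clade_recovery(t, [{"A", "B", "C"}]) == [True]

    def test_reference_clades_all_true_on_reference(self, gene_tree_panel):
        sp, _ = gene_tree_panel
        from orthosweep.treestats import _node_masks, taxon_index

        leaves = {l.taxon.label for l in sp.leaf_node_iter()}
        idx = taxon_index(leaves)
        rev = {i: l for l, i in idx.items()}
        clades = [
            frozenset(rev[i] for i in range(len(idx)) if (m >> i) & 1)
            for node, m in _node_masks(sp, idx).items()
            if not node.is_leaf()
        ]
        assert all(clade_recovery(sp, clades))

    def test_unknown_leaf_rejected(self):
        t = read_newick("((A,B),C);")
        with pytest.raises(ValueError):
            clade_recovery(t, [{"A", "Z"}])


class TestGCF:
    def test_direct_count(self):
        sp = read_newick("((A,B),(C,D));")
        genes = [
            read_newick("((A,B),(C,D));"),
            read_newick("((A,B),(C,D));"),
            read_newick("((A,C),(B,D));"),
        ]
        (bc,) = gene_concordance_factor(sp, genes)
        assert bc.n_decisive == 3
        assert bc.gcf_pct == pytest.approx(100 * 2 / 3)

    def test_identical_gene_trees_give_100_everywhere(self, gene_tree_panel):
        sp, _ = gene_tree_panel
        for k in (1, 5):
            for bc in gene_concordance_factor(sp, [sp] * k):
                assert bc.gcf_pct == 100.0

    def test_missing_taxa_make_gene_indecisive(self):
        sp = read_newick("((A,B),(C,D));")
        gene = read_newick("((B,C),D);")  # side {A,B} restricted to {B}
        (bc,) = gene_concordance_factor(sp, [gene])
        assert bc.n_decisive == 0
        assert np.isnan(bc.gcf_pct)

    def test_polytomy_is_decisive_but_discordant(self):
        sp = read_newick("((A,B),(C,D));")
        gene = read_newick("(A,B,C,D);")
        (bc,) = gene_concordance_factor(sp, [gene])
        assert bc.n_decisive == 1
        assert bc.gcf_pct == 0.0


class TestQuartetSupport:
    def test_single_quartet_enumeration(self):
        sp = read_newick("((A,B),(C,D));")
        genes = [
            read_newick("((A,B),(C,D));"),
            read_newick("((A,B),(C,D));"),
            read_newick("((A,C),(B,D));"),
        ]
        (bc,) = quartet_support(sp, genes)
        assert (bc.q1, bc.q2, bc.q3) == pytest.approx((2 / 3, 1 / 3, 0.0))

    def test_concordant_panel_gives_q1_one(self, gene_tree_panel):
        sp, _ = gene_tree_panel
        for bc in quartet_support(sp, [sp] * 4):
            assert bc.q1 == pytest.approx(1.0)
            assert bc.q1 + bc.q2 + bc.q3 == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, gene_tree_panel):
        sp, genes = gene_tree_panel
        for bc in quartet_support(sp, genes):
            if bc.n_quartets:
                assert bc.q1 + bc.q2 + bc.q3 == pytest.approx(1.0)

    def test_exhaustive_equals_bruteforce(self, rng):
        """Cap high enough to enumerate: matches a direct per-quartet tally."""
        sp = simulate_species_tree(7, rng=3)
        genes = simulate_gene_trees(sp, MSCParams(n_species=7, n_genes=15, seed=3))
        from orthosweep.treestats import (
            _branch_clusters,
            _node_masks,
            bipartition_masks,
            leaf_mask,
            taxon_index,
        )

        leaves = {l.taxon.label for l in sp.leaf_node_iter()}
        idx = taxon_index(leaves)
        full = leaf_mask(leaves, idx)
        results = quartet_support(sp, genes, max_quartets_per_branch=10**9)
        masks = _node_masks(sp, idx)
        clusters = {}
        seen = set()
        low = full & -full
        for bm, quad in _branch_clusters(sp, masks, full):
            canon = (full ^ bm) if (bm & low) else bm
            if canon not in seen:
                seen.add(canon)
                clusters[canon] = quad
        assert len(clusters) == len(results)
        for bc in results:
            m = leaf_mask(bc.branch.side_a, idx)
            canon = (full ^ m) if (m & low) else m
            a1, a2, b1, b2 = clusters[canon]
            tally = [0, 0, 0]
            for qa, qb, qc, qd in itertools.product(
                *[[1 << i for i in range(len(idx)) if (x >> i) & 1] for x in (a1, a2, b1, b2)]
            ):
                for gt in genes:
                    gl = {l.taxon.label for l in gt.leaf_node_iter()}
                    gidx_mask = leaf_mask(gl, idx)
                    if (gidx_mask & (qa | qb | qc | qd)) != (qa | qb | qc | qd):
                        continue
                    gbips = bipartition_masks(gt, idx)
                    topo = -1
                    for gm in gbips:
                        ins = [bool(gm & q) for q in (qa, qb, qc, qd)]
                        if ins[0] == ins[1] and ins[2] == ins[3] and ins[0] != ins[2]:
                            topo = 0
                        elif ins[0] == ins[2] and ins[1] == ins[3] and ins[0] != ins[1]:
                            topo = 1
                        elif ins[0] == ins[3] and ins[1] == ins[2] and ins[0] != ins[1]:
                            topo = 2
                        if topo >= 0:
                            break
                    if topo >= 0:
                        tally[topo] += 1
            total = sum(tally)
            assert bc.n_quartets == total
            if total:
                assert (bc.q1, bc.q2, bc.q3) == pytest.approx(
                    tuple(t / total for t in tally)
                )


class TestRooting:
    def test_root_and_prune_outgroup(self):
        t = read_newick("(((A,B),C),OUT);")
        rooted = root_on_outgroup(t, "OUT", prune_outgroup=True)
        labels = sorted(l.taxon.label for l in rooted.leaf_node_iter())
        assert labels == ["A", "B", "C"]
        assert clade_recovery(rooted, [{"A", "B"}]) == [True]

    def test_missing_outgroup_rejected(self):
        t = read_newick("((A,B),C);")
        with pytest.raises(ValueError):
            root_on_outgroup(t, "OUT")


class TestBipartitionType:
    def test_unordered_equality(self):
        a = Bipartition(frozenset("AB"), frozenset("CD"))
        b = Bipartition(frozenset("CD"), frozenset("AB"))
        assert a == b and hash(a) == hash(b)

    def test_overlap_rejected(self):
        with pytest.raises(ValueError):
            Bipartition(frozenset("AB"), frozenset("BC"))
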