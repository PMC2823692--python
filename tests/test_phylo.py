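import itertools
import math

import numpy as np
import pytest

from sialome.io import SequenceRecord, write_newick
from sialome.phylo import (Clade, DistanceMatrix, protein_distance, nj_tree,
                           bootstrap_support, bipartitions)
from sialome import simulate as sm


def _prot(rid, seq):
    return SequenceRecord(id=rid, seq=seq, alphabet="protein", validate=False)


# ---------------------------------------------------------------------------
# oracles


def random_additive(rng, n):
    """A random binary tree and its exact path-length distance matrix."""
    labels = [f"T{i}" for i in range(n)]
    nodes = [Clade(name=l) for l in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.branch_length = float(rng.uniform(0.1, 2.0))
        b.branch_length = float(rng.uniform(0.1, 2.0))
        nodes.append(Clade(children=[a, b]))
    tree = nodes[0]

    # leaf-to-leaf path lengths
    def paths(node, acc):
        if node.is_leaf:
            return {node.name: acc}
        out = {}
        for c in node.children:
            out.update(paths(c, acc + c.branch_length))
        return out

    dist = {}
    def pairs(node):
        for c in node.children:
            pairs(c)
        sides = [paths(c, c.branch_length) for c in node.children]
        for s1, s2 in itertools.combinations(sides, 2):
            for l1, d1 in s1.items():
                for l2, d2 in s2.items():
                    dist[frozenset((l1, l2))] = d1 + d2
    pairs(tree)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = dist[frozenset((labels[i], labels[j]))]
    return tree, DistanceMatrix(labels, d)


def all_topologies(labels):
    """Every unrooted binary topology, by sequential edge insertion."""
    if len(labels) == 3:
        yield Clade(children=[Clade(name=l) for l in labels])
        return
    first, rest = labels[-1], labels[:-1]
    for base in all_topologies(rest):
        edges = []

        def collect(node):
            for i, c in enumerate(node.children):
                edges.append((node, i))
                collect(c)
        collect(base)
        for node, i in edges:
            import copy
            t = copy.deepcopy(base)
            # find the matching edge in the copy
            stack = [(t, base)]
            target = None
            while stack:
                ct, cb = stack.pop()
                if cb is node:
                    target = ct
                    break
                stack.extend(zip(ct.children, cb.children))
            child = target.children[i]
            target.children[i] = Clade(children=[child, Clade(name=first)])
            yield t


def ls_fit_residual(topology, dm):
    """Least-squares branch-length fit residual of a topology to a matrix."""
    labels = dm.labels
    index = {l: i for i, l in enumerate(labels)}
    # collect edges as (bitmask of leaves below, edge id)
    edges = []

    def mask(node):
        if node.is_leaf:
            m = 1 << index[node.name]
        else:
            m = 0
            for c in node.children:
                m |= mask(c)
        edges.append(m)
        return m

    for c in topology.children:
        mask(c)
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.array([dm.d[i, j] for i, j in pairs])
    for r, (i, j) in enumerate(pairs):
        for e, m in enumerate(edges):
            if ((m >> i) & 1) != ((m >> j) & 1):
                A[r, e] = 1.0
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ x - y) ** 2))


# ---------------------------------------------------------------------------


class TestProteinDistance:
    def test_identical_sequences(self):
        dm = protein_distance([_prot("a", "MKTA"), _prot("b", "MKTA")])
        assert dm.d[0, 1] == 0.0

    def test_p_and_poisson_closed_forms(self):
        recs = [_prot("a", "AAAA"), _prot("b", "AAAT")]
        assert protein_distance(recs).d[0, 1] == pytest.approx(0.25)
        poisson = protein_distance(recs, model="poisson").d[0, 1]
        assert poisson == pytest.approx(-math.log(0.75))

    def test_pairwise_deletion_of_gap_and_x_columns(self):
        recs = [_prot("a", "MK-TX"), _prot("b", "MKATA")]
        dm = protein_distance(recs)
        assert dm.d[0, 1] == 0.0  # only M,K,T columns compared

    def test_row_order_invariance(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        recs = [_prot(f"s{i}", "".join(rng.choice(aas, size=40)))
                for i in range(4)]
        d1 = protein_distance(recs)
        d2 = protein_distance(list(reversed(recs)))
        for i, li in enumerate(d1.labels):
            for j, lj in enumerate(d1.labels):
                i2, j2 = d2.labels.index(li), d2.labels.index(lj)
                assert d1.d[i, j] == pytest.approx(d2.d[i2, j2])

    def test_degenerate_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            protein_distance([_prot("a", "--X"), _prot("b", "AK-")])
        with pytest.raises(ValueError, match="infinite"):
            protein_distance([_prot("a", "AAAA"), _prot("b", "TTTT")],
                             model="poisson")
        with pytest.raises(ValueError):
            protein_distance([_prot("a", "AAA"), _prot("b", "AAAA")])

    def test_matrix_validation(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "a"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestNeighborJoining:
    def test_recovers_the_worked_additive_example_exactly(self):
        labels = ["A", "B", "C", "D"]
        d = np.array([[0, 3, 8, 9], [3, 0, 9, 10],
                      [8, 9, 0, 9], [9, 10, 9, 0]], float)
        tree = nj_tree(DistanceMatrix(labels, d))
        assert write_newick(tree) == "(C:4,D:5,(A:1,B:2):3);"

    def test_three_taxon_closed_form(self):
        d = np.array([[0, 5, 7], [5, 0, 8], [7, 8, 0]], float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], d))
        bl = {l.name: l.branch_length for l in tree.leaves()}
        assert bl["a"] == pytest.approx((5 + 7 - 8) / 2)
        assert bl["b"] == pytest.approx((5 + 8 - 7) / 2)
        assert bl["c"] == pytest.approx((7 + 8 - 5) / 2)

    def test_tie_broken_deterministically(self):
        # equidistant ultrametric 4-taxon matrix: every Q is tied
        d = np.full((4, 4), 2.0)
        np.fill_diagonal(d, 0.0)
        labels = ["a", "b", "c", "d"]
        t1 = nj_tree(DistanceMatrix(labels, d))
        t2 = nj_tree(DistanceMatrix(labels, d))
        assert write_newick(t1) == write_newick(t2)
        # the joined pair is the lexicographically smallest
        assert frozenset(
            (frozenset(("a", "b")), frozenset(("c", "d")))
        ) in bipartitions(t1)

    @pytest.mark.parametrize("n", [5, 8, 12])
    def test_exact_recovery_of_random_additive_matrices(self, n, rng):
        for _ in range(3):
            true, dm = random_additive(rng, n)
            est = nj_tree(dm)
            assert bipartitions(est) == bipartitions(true)
            # path metric equality: rebuild distances from the NJ tree
            est_dm = _tree_path_matrix(est, dm.labels)
            assert np.allclose(est_dm, dm.d, atol=1e-9)

    def test_matches_all_topology_least_squares_oracle(self, rng):
        for _ in range(3):
            true, dm = random_additive(rng, 6)
            est = nj_tree(dm)
            best_topo, best_res = None, np.inf
            for topo in all_topologies(dm.labels):
                res = ls_fit_residual(topo, dm)
                if res < best_res - 1e-12:
                    best_topo, best_res = topo, res
            assert best_res < 1e-12  # the generating topology fits exactly
            assert bipartitions(best_topo) == bipartitions(est)

    def test_independent_nj_implementation_agrees(self, rng):
        """Cross-check topology against scikit-bio on a noisy matrix."""
        import skbio
        true, dm = random_additive(rng, 7)
        noisy = dm.d + rng.uniform(0, 0.05, dm.d.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0.0)
        ours = nj_tree(DistanceMatrix(dm.labels, noisy))
        ref = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=dm.labels))
        ref_bips = set()
        all_leaves = frozenset(dm.labels)
        for node in ref.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_leaves) - 1:
                ref_bips.add(frozenset((side, all_leaves - side)))
        assert bipartitions(ours) == ref_bips

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0., 1.], [1., 0.]])))


def _tree_path_matrix(tree, labels):
    index = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))

    def paths(node, acc):
        if node.is_leaf:
            return {node.name: acc}
        out = {}
        for c in node.children:
            out.update(paths(c, acc + c.branch_length))
        return out

    def walk(node):
        for c in node.children:
            walk(c)
        sides = [paths(c, c.branch_length) for c in node.children]
        for s1, s2 in itertools.combinations(sides, 2):
            for l1, d1 in s1.items():
                for l2, d2 in s2.items():
                    i, j = index[l1], index[l2]
                    d[i, j] = d[j, i] = d1 + d2

    walk(tree)
    return d


class TestBootstrap:
    def _two_group_alignment(self):
        # two clearly distinct groups, zero within-group variation
        a = "ACDEFGHIKL" * 6
        b = "LMNPQRSTVW" * 6
        return [_prot("a1", a), _prot("a2", a), _prot("b1", b), _prot("b2", b)]

    def test_unanimous_split_gets_full_support(self):
        tree = bootstrap_support(self._two_group_alignment(),
                                 n_replicates=50, seed=1)
        supports = [c.support for c in tree.children if not c.is_leaf]
        assert supports and all(s == 100 for s in supports)

    def test_single_replicate_supports_are_binary(self):
        recs, _ = sm.simulate_protein_family(60, 5, 0.3, seed=2)
        tree = bootstrap_support(recs, n_replicates=1, seed=3)

        def collect(node, acc):
            for c in node.children:
                if not c.is_leaf and c.support is not None:
                    acc.append(c.support)
                collect(c, acc)
            return acc

        assert set(collect(tree, [])) <= {0, 100}

    def test_seed_reproducibility_and_sampling_noise(self):
        recs, _ = sm.simulate_protein_family(120, 6, 0.25, seed=4)

        def supports(seed, reps=200):
            tree = bootstrap_support(recs, n_replicates=reps, seed=seed)
            out = {}
            all_leaves = frozenset(tree.leaf_names())

            def walk(node):
                for c in node.children:
                    if not c.is_leaf and c.support is not None:
                        side = frozenset(c.leaf_names())
                        out[frozenset((side, all_leaves - side))] = c.support
                    walk(c)

            walk(tree)
            return out

        s1 = supports(seed=7)
        s2 = supports(seed=7)
        s3 = supports(seed=8)
        assert s1 == s2
        # different seeds agree within a few binomial SEs (~3.5 pts at p=0.5)
        for bp in set(s1) & set(s3):
            assert abs(s1[bp] - s3[bp]) <= 15

    def test_input_order_invariance_of_supports(self):
        recs = self._two_group_alignment()
        t1 = bootstrap_support(recs, n_replicates=30, seed=5)
        t2 = bootstrap_support(list(reversed(recs)), n_replicates=30, seed=5)
        assert bipartitions(t1) == bipartitions(t2)

    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support([_prot("a", "M"), _prot("b", "K"),
                               _prot("c", "T")], n_replicates=10, seed=0)
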