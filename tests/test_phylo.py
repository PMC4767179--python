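import numpy as np
import pytest
from skbio import TreeNode

from algbarcode.align import DistanceMatrix, distance_matrix
from algbarcode.phylo import bootstrap_support, is_monophyletic, nj_tree, tree_splits

from conftest import records


def _leaf_distances(tree: TreeNode) -> DistanceMatrix:
    """Path-length distances between leaves of a branch-lengthed tree."""
    tips = sorted(tree.tips(), key=lambda t: t.name)
    labels = tuple(t.name for t in tips)
    n = len(tips)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tips[i].distance(tips[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values / max(1.0, values.max()))


def _random_binary_tree(rng, n_leaves: int) -> TreeNode:
    nodes = [TreeNode(name=f"t{i}", length=float(rng.uniform(0.05, 1.0))) for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.05, 1.0)))
        parent.extend([nodes[i], nodes[j]])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    root = TreeNode()
    root.extend(nodes)
    return root


def test_three_taxa_closed_form():
    dm = DistanceMatrix(labels=("A", "B", "C"),
                        values=np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]]))
    tree = nj_tree(dm)
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths["A"] == pytest.approx(0.1)
    assert lengths["B"] == pytest.approx(0.2)
    assert lengths["C"] == pytest.approx(0.4)


def test_additive_four_taxon_matrix_recovered_exactly():
    """Matrix from tree ((A:1,B:2):1,(C:3,D:4)) is inverted exactly."""
    D = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    ) / 10
    tree = nj_tree(DistanceMatrix(labels=("A", "B", "C", "D"), values=D))
    assert tree_splits(tree) == {frozenset({"C", "D"})}
    lengths = {t.name: t.length for t in tree.tips()}
    assert lengths == pytest.approx({"A": 0.1, "B": 0.2, "C": 0.3, "D": 0.4})


def test_nj_needs_three_taxa():
    dm = DistanceMatrix(labels=("A", "B"), values=np.array([[0, 0.1], [0.1, 0]]))
    with pytest.raises(ValueError, match="at least 3"):
        nj_tree(dm)


def test_nj_recovers_random_additive_trees_up_to_8_taxa(rng):
    for n in (4, 5, 6, 7, 8):
        for _ in range(4):
            true = _random_binary_tree(rng, n)
            dm = _leaf_distances(true)
            est = nj_tree(dm)
            assert tree_splits(est) == tree_splits(true), n


def test_nj_topology_agrees_with_skbio_on_random_matrices(rng):
    """Independent oracle: scikit-bio's own NJ implementation."""
    from skbio.tree import nj as skbio_nj
    from skbio import DistanceMatrix as SkbioDM

    for _ in range(5):
        true = _random_binary_tree(rng, 6)
        dm = _leaf_distances(true)
        est = nj_tree(dm)
        sk = skbio_nj(SkbioDM(dm.values, ids=dm.labels))
        assert tree_splits(est) == tree_splits(sk)


def test_conspecific_sequences_form_a_clade(small_db):
    cfg, recs, truth = small_db
    dm = distance_matrix(recs)
    tree = nj_tree(dm)
    for species, group in truth.groupby("species"):
        assert is_monophyletic(tree, set(group["id"])), species


def test_edge_count_is_2n_minus_3(small_db):
    cfg, recs, truth = small_db
    tree = nj_tree(distance_matrix(recs))
    n = len(recs)
    edges = sum(1 for node in tree.traverse(include_self=False))
    assert edges == 2 * n - 3


def test_monophyly_complement_duality_and_singletons():
    tree = TreeNode.read(["((A,B),(C,D),E);"])
    assert is_monophyletic(tree, {"A", "B"})
    assert is_monophyletic(tree, {"C", "D", "E"})  # complement of {A,B}
    assert is_monophyletic(tree, {"E"})
    assert not is_monophyletic(tree, {"A", "C"})
    with pytest.raises(ValueError, match="unknown"):
        is_monophyletic(tree, {"Z"})


def test_monophyly_agrees_with_graph_cut_oracle(rng):
    """Independent oracle: bipartitions via edge removal in a networkx graph."""
    import itertools
    import networkx as nx

    tree = _random_binary_tree(rng, 6)
    graph = nx.Graph()
    counter = itertools.count()
    names = {}

    def walk(node):
        if node not in names:
            names[node] = node.name or f"int{next(counter)}"
        for child in node.children:
            names[child] = child.name or f"int{next(counter)}"
            graph.add_edge(names[node], names[child])
            walk(child)

    walk(tree)
    leaves = {t.name for t in tree.tips()}
    oracle_sets = set()
    for edge in list(graph.edges):
        g2 = graph.copy()
        g2.remove_edge(*edge)
        comp = next(iter(nx.connected_components(g2)))
        oracle_sets.add(frozenset(comp & leaves))
    for size in (2, 3):
        for subset in itertools.combinations(sorted(leaves), size):
            sub = frozenset(subset)
            expected = sub in oracle_sets or (frozenset(leaves - sub)) in oracle_sets
            assert is_monophyletic(tree, sub) is expected, subset


def test_bootstrap_duplicate_taxa_get_full_support(rng):
    # two identical sequences must group together in every replicate
    base = "".join(rng.choice(list("ACGT"), 200))
    from algbarcode.simulate import mutate_sequence

    seqs = [base, base] + [mutate_sequence(base, d, s).sequence for s, d in ((1, 0.3), (2, 0.35), (3, 0.4))]
    recs = records(*seqs)
    tree = bootstrap_support(recs, n_reps=30, seed=4)
    supports = {
        frozenset(t.name for t in node.tips()): node.support
        for node in tree.non_tips(include_self=False)
        if hasattr(node, "support")
    }
    found = [v for k, v in supports.items() if set(k) in ({"r0", "r1"}, {"r2", "r3", "r4"})]
    assert found and all(v == 1.0 for v in found)


def test_bootstrap_reproducible_and_bounded(small_db):
    cfg, recs, truth = small_db
    subset = recs[::3]
    t1 = bootstrap_support(subset, n_reps=25, seed=11)
    t2 = bootstrap_support(subset, n_reps=25, seed=11)
    s1 = sorted(n.support for n in t1.non_tips(include_self=False) if hasattr(n, "support"))
    s2 = sorted(n.support for n in t2.non_tips(include_self=False) if hasattr(n, "support"))
    assert s1 == s2
    assert all(0.0 <= s <= 1.0 for s in s1)


def test_bootstrap_converges_to_high_replicate_reference(rng):
    # hierarchical data with well-separated depths, so every split of the
    # full-data tree is strongly supported and replicate counts converge
    from algbarcode.simulate import mutate_sequence

    base = "".join(rng.choice(list("ACGT"), 300))
    anc = mutate_sequence(base, 0.2, 50).sequence
    anc2 = mutate_sequence(anc, 0.1, 54).sequence
    seqs = [
        base,
        mutate_sequence(base, 0.02, 51).sequence,
        anc,
        mutate_sequence(anc2, 0.02, 52).sequence,
        mutate_sequence(anc2, 0.02, 53).sequence,
    ]
    subset = records(*seqs)

    def supports(tree):
        return {
            frozenset(t.name for t in node.tips()): node.support
            for node in tree.non_tips(include_self=False)
            if hasattr(node, "support")
        }

    ref = supports(bootstrap_support(subset, n_reps=400, seed=1))
    low = supports(bootstrap_support(subset, n_reps=100, seed=2))
    for split, value in low.items():
        assert abs(value - ref.get(split, 0.0)) <= 0.05


def test_bootstrap_rejects_zero_reps(small_db):
    cfg, recs, truth = small_db
    with pytest.raises(ValueError, match="n_reps"):
        bootstrap_support(recs[:4], n_reps=0)
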