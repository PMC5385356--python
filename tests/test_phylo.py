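import io
import itertools
import math

import numpy as np
import pytest

from consmotif.phylo import (
    DistanceMatrix,
    bootstrap_supports,
    nj_tree,
    tn93_distance,
    tree_path_lengths,
)
from consmotif.simulate import SimulationConfig, build_tree
from .conftest import make_alignment


def _mutate_balanced(seq: str, swaps: list[tuple[str, str, int]]) -> str:
    """Apply composition-preserving substitutions: for each (x, y, k), k
    fresh x-sites become y and k fresh y-sites become x (2k differences per
    swap, never touching a site twice)."""
    out = list(seq)
    available = {nt: [i for i, c in enumerate(seq) if c == nt] for nt in "ACGT"}
    for x, y, k in swaps:
        xi = [available[x].pop(0) for _ in range(k)]
        yi = [available[y].pop(0) for _ in range(k)]
        for i in xi:
            out[i] = y
        for i in yi:
            out[i] = x
    return "".join(out)


class TestTN93:
    def test_identity_is_zero(self):
        a = "ACGT" * 50
        assert tn93_distance(a, a) == 0.0

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=120))
            b = "".join(rng.choice(list("ACGT"), size=120))
            assert tn93_distance(a, b) == pytest.approx(tn93_distance(b, a))

    def test_transversions_only_uniform_composition(self):
        # 600 nt, 30 transversions, uniform base composition: value frozen
        # from an independent numeric evaluation of the TN93 closed form.
        a = "ACGT" * 150
        b = _mutate_balanced(a, [("A", "C", 15)])
        assert tn93_distance(a, b) == pytest.approx(0.0519867761, abs=1e-9)

    def test_equal_frequencies_matches_k2p(self):
        # equal base frequencies, equal purine/pyrimidine transition counts
        a = "ACGT" * 150
        b = _mutate_balanced(a, [("A", "G", 5), ("C", "T", 5), ("A", "C", 10), ("G", "T", 10)])
        P, Q = 20 / 600, 40 / 600
        k2p = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert tn93_distance(a, b) == pytest.approx(k2p, abs=1e-9)

    def test_jc69_limit(self):
        # transitions = half the transversions (the JC69 expectation):
        # TN93 collapses to the Jukes-Cantor distance.
        a = "ACGT" * 150
        b = _mutate_balanced(a, [("A", "G", 5), ("C", "T", 5), ("A", "C", 10), ("G", "T", 10)])
        p = 60 / 600
        jc = -0.75 * math.log(1 - 4 * p / 3)
        assert tn93_distance(a, b) == pytest.approx(jc, abs=1e-9)

    def test_gapped_sites_excluded_pairwise(self):
        a = "ACGT" * 10 + "----"
        b = "ACGT" * 10 + "ACGT"
        assert tn93_distance(a, b) == 0.0

    def test_all_gaps_errors(self):
        with pytest.raises(ValueError, match="comparable"):
            tn93_distance("----", "AAAA")

    def test_saturation_returns_cap(self, caplog):
        a = "AC" * 50
        b = "CA" * 50  # every site a transversion
        with caplog.at_level("WARNING"):
            assert tn93_distance(a, b, cap=5.0) == 5.0
        assert any("saturation" in m.lower() or "cap" in m.lower() for m in caplog.messages)


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(("A", "B", "C"), np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
        tree = nj_tree(dm)
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(("A", "B"), np.zeros((2, 2))))

    def test_additive_five_taxon_recovered(self):
        # caterpillar ((A:1,B:2):1,(C:3,D:1):2,E:4) -> additive matrix
        ids = ("A", "B", "C", "D", "E")
        paths = {
            ("A", "B"): 3, ("A", "C"): 7, ("A", "D"): 5, ("A", "E"): 6,
            ("B", "C"): 8, ("B", "D"): 6, ("B", "E"): 7,
            ("C", "D"): 4, ("C", "E"): 9, ("D", "E"): 7,
        }
        D = np.zeros((5, 5))
        for (x, y), v in paths.items():
            i, j = ids.index(x), ids.index(y)
            D[i, j] = D[j, i] = v
        tree = nj_tree(DistanceMatrix(ids, D))
        rec = tree_path_lengths(tree)
        for (x, y), v in paths.items():
            assert rec[frozenset((x, y))] == pytest.approx(v, abs=1e-9)
        assert frozenset("CD") in tree.bipartitions() or frozenset("ABE") in tree.bipartitions()

    def test_star_distances_give_zero_internal_branches(self):
        n = 5
        D = np.ones((n, n)) - np.eye(n)
        tree = nj_tree(DistanceMatrix(tuple("ABCDE"), D))
        internal = [nd for nd in tree.internal_nodes() if nd is not tree.root]
        assert all(nd.length == pytest.approx(0.0, abs=1e-12) for nd in internal)

    def test_matches_dendropy_topology(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = 7
            M = rng.random((n, n))
            D = M + M.T
            np.fill_diagonal(D, 0)
            ids = tuple(f"x{i}" for i in range(n))
            mine = nj_tree(DistanceMatrix(ids, D)).bipartitions()
            csv = (
                "," + ",".join(ids) + "\n"
                + "\n".join(ids[i] + "," + ",".join(map(str, D[i])) for i in range(n))
            )
            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(io.StringIO(csv), delimiter=",")
            dtree = pdm.nj_tree()
            taxa, anchor = frozenset(ids), min(ids)
            theirs = set()
            for node in dtree.preorder_node_iter():
                if node.parent_node and not node.is_leaf():
                    side = frozenset(l.taxon.label for l in node.leaf_iter())
                    if 2 <= len(side) <= n - 2:
                        theirs.add(taxa - side if anchor in side else side)
            assert mine == theirs


def _two_clade_alignment(n_per_clade=3, n_codons=20, third_pos_changes=8):
    """Two clades of identical sequences, moderately diverged between clades."""
    rng = np.random.default_rng(42)
    from consmotif.seqio import SENSE_CODONS

    base = list(rng.choice(SENSE_CODONS, size=n_codons))
    other = list(base)
    changed = 0
    for j in range(n_codons):
        if changed == third_pos_changes:
            break
        for nt in "ACGT":
            cand = other[j][:2] + nt
            if cand != other[j] and cand in SENSE_CODONS:
                other[j] = cand
                changed += 1
                break
    rows = ["".join(base)] * n_per_clade + ["".join(other)] * n_per_clade
    ids = [f"a{i}" for i in range(n_per_clade)] + [f"b{i}" for i in range(n_per_clade)]
    return make_alignment(rows, ids)


class TestBootstrap:
    def test_separating_bipartition_gets_full_support(self):
        aln = _two_clade_alignment()
        tree = bootstrap_supports(aln, n_reps=100, seed=0)
        bip = frozenset(["b0", "b1", "b2"])
        assert bip in tree.bipartitions()
        supports = {
            nd.support for nd in tree.internal_nodes() if nd.support is not None
        }
        assert supports and all(0 <= s <= 100 for s in supports)
        # find the separating node's support
        found = []
        for node in tree.internal_nodes():
            leafset = frozenset(l.name for l in node.leaves())
            if leafset in (bip, frozenset(["a0", "a1", "a2"])):
                found.append(node.support)
        assert found and all(s == 100.0 for s in found if s is not None)

    def test_same_seed_reproducible(self):
        aln = _two_clade_alignment()
        t1 = bootstrap_supports(aln, n_reps=50, seed=123)
        t2 = bootstrap_supports(aln, n_reps=50, seed=123)
        assert t1.to_newick() == t2.to_newick()

    def test_invalid_reps(self):
        with pytest.raises(ValueError):
            bootstrap_supports(_two_clade_alignment(), n_reps=0)


class TestTreeUtilities:
    def test_simulated_tree_total_length(self):
        cfg = SimulationConfig(n_taxa=12, tree_length=2.5, seed=5)
        tree = build_tree(cfg, np.random.default_rng(5))
        total = 0.0

        def rec(node):
            nonlocal total
            for c in node.children:
                total += c.length
                rec(c)

        rec(tree.root)
        assert total == pytest.approx(2.5)

    def test_newick_roundtrips_through_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        aln = _two_clade_alignment()
        tree = bootstrap_supports(aln, n_reps=10, seed=1)
        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(tree.leaf_names)
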