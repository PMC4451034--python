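"""Distance matrices, neighbor joining (vs additive-tree truth and an
independent library implementation), Fitch parsimony (vs exhaustive
enumeration) and bootstrap support."""

import itertools

import dendropy
import numpy as np
import pytest

from transpoly.trees import (
    _bipartitions,
    bootstrap_support,
    fitch_score,
    nj_tree,
    pdistance_matrix,
    read_newick,
    write_newick,
)

from conftest import make_alignment, random_alignment


class TestPDistance:
    def test_identical_sequences_zero(self):
        aln = make_alignment(["ACGT", "ACGT", "ACGT"])
        _, D = pdistance_matrix(aln)
        assert np.allclose(D, 0)

    def test_two_differences_over_hundred(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=100))
        other = list(base)
        other[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[10]]
        other[90] = {"A": "C", "C": "G", "G": "T", "T": "A"}[other[90]]
        aln = make_alignment([base, "".join(other), base])
        _, D = pdistance_matrix(aln)
        assert D[0, 1] == pytest.approx(0.02)

    def test_matches_brute_force(self, rng):
        aln = random_alignment(rng, n=8, length=120, n_variable=10, gap_prob=0.03)
        labels, D = pdistance_matrix(aln)
        seqs = [r.sequence for r in aln.records]
        for i in range(8):
            for j in range(8):
                comp = [
                    (a, b)
                    for a, b in zip(seqs[i], seqs[j])
                    if a not in "-N" and b not in "-N"
                ]
                expect = sum(a != b for a, b in comp) / len(comp)
                assert D[i, j] == pytest.approx(expect)

    def test_no_comparable_columns_raises_with_pair(self):
        aln = make_alignment(["A-", "-A", "AA"], ids=["x", "y", "z"])
        with pytest.raises(ValueError, match="'x' and 'y'"):
            pdistance_matrix(aln)


def _leaf_edge_lengths(tree):
    return {
        l.taxon.label: l.edge.length for l in tree.leaf_node_iter()
    }


def random_additive_tree(rng, n_taxa):
    """Random topology with random positive branch lengths, plus its
    leaf-to-leaf path-distance matrix."""
    labels = [f"t{i}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    import random as pyrandom

    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_taxa,
        taxon_namespace=tns, rng=pyrandom.Random(int(rng.integers(2**31))),
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    D = np.zeros((n_taxa, n_taxa))
    for i, ti in enumerate(tns):
        for j, tj in enumerate(tns):
            D[i, j] = pdm.distance(ti, tj)
    return tree, [t.label for t in tns], D


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 2, 4], [2, 0, 4], [4, 4, 0]])
        tree = nj_tree(D, ["A", "B", "C"])
        lens = _leaf_edge_lengths(tree)
        assert lens == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_recovers_additive_tree_topologies(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 11))
            truth, labels, D = random_additive_tree(rng, n)
            est = nj_tree(D, labels)
            assert _bipartitions(est) == _bipartitions(truth)

    def test_agrees_with_library_nj_on_additive_input(self, rng):
        truth, labels, D = random_additive_tree(rng, 8)
        est = nj_tree(D, labels)
        # independent implementation: dendropy's NJ
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=_csv_of(D, labels), delimiter=","
        )
        lib = pdm.nj_tree()
        assert _bipartitions(est) == _bipartitions(lib)

    def test_deterministic_under_ties(self):
        # equidistant taxa: every Q entry ties; result must be stable
        D = np.ones((4, 4)) - np.eye(4)
        t1 = nj_tree(D, list("ABCD")).as_string(schema="newick")
        t2 = nj_tree(D, list("ABCD")).as_string(schema="newick")
        assert t1 == t2

    def test_asymmetric_matrix_raises(self):
        D = np.array([[0.0, 1, 2], [1.5, 0, 1], [2, 1, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(D, list("ABC"))


def fitch_oracle(tree, leaf_states):
    """Exhaustive minimization over all internal-state assignments."""
    internals = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    states = sorted(set(leaf_states.values()))
    best = None
    for combo in itertools.product(states, repeat=len(internals)):
        assign = {id(nd): s for nd, s in zip(internals, combo)}
        for nd in tree.leaf_node_iter():
            assign[id(nd)] = leaf_states[nd.taxon.label]
        changes = sum(
            assign[id(nd)] != assign[id(nd.parent_node)]
            for nd in tree.preorder_node_iter()
            if nd.parent_node is not None
        )
        best = changes if best is None else min(best, changes)
    return best


def newick_tree(s):
    return dendropy.Tree.get(data=s, schema="newick")


class TestFitch:
    @pytest.mark.parametrize(
        "newick,states,expected",
        [
            ("((A,B),(C,D));", {"A": "x", "B": "x", "C": "y", "D": "y"}, 1),
            ("((A,B),(C,D));", {"A": "x", "B": "y", "C": "x", "D": "y"}, 2),
            ("((A,B),(C,D));", {"A": "x", "B": "x", "C": "x", "D": "x"}, 0),
        ],
    )
    def test_known_scores(self, newick, states, expected):
        score, assignment = fitch_score(newick_tree(newick), states)
        assert score == expected
        assert all(assignment[l] == states[l] for l in states)

    def test_matches_exhaustive_enumeration(self, rng):
        shapes = ["((A,B),(C,D),E);", "(((A,B),C),((D,E),F));", "((A,(B,C)),(D,(E,F)));"]
        for newick in shapes:
            tree = newick_tree(newick)
            leaves = [l.taxon.label for l in tree.leaf_node_iter()]
            for _ in range(20):
                states = {l: "xyz"[rng.integers(3)] for l in leaves}
                score, _ = fitch_score(tree, states)
                assert score == fitch_oracle(tree, states)

    def test_unlabeled_leaf_raises(self):
        with pytest.raises(ValueError, match="E"):
            fitch_score(newick_tree("((A,B),(C,E));"), {"A": "x", "B": "x", "C": "y"})


class TestBootstrap:
    def _two_clade_alignment(self, rng):
        base = rng.choice(list("ACGT"), size=200)
        b = base.copy()
        for pos in rng.choice(200, 40, replace=False):
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        seqs = []
        for grp in (base, b):
            for _ in range(3):
                s = grp.copy()
                pos = rng.integers(200)
                s[pos] = {"A": "G", "C": "T", "G": "A", "T": "C"}[s[pos]]
                seqs.append("".join(s))
        return make_alignment(seqs)

    def test_clear_split_gets_high_support(self, rng):
        aln = self._two_clade_alignment(rng)
        tree = bootstrap_support(aln, n_reps=50, seed=0)
        split = frozenset(["s0", "s1", "s2"])
        other = frozenset(["s3", "s4", "s5"])
        supports = {
            frozenset(l.taxon.label for l in nd.leaf_iter()): nd.support
            for nd in tree.postorder_internal_node_iter()
            if nd.parent_node is not None and hasattr(nd, "support")
        }
        found = [v for k, v in supports.items() if k in (split, other)]
        assert found and max(found) >= 0.95

    def test_single_replicate_supports_are_zero_or_one(self, rng):
        aln = self._two_clade_alignment(rng)
        tree = bootstrap_support(aln, n_reps=1, seed=3)
        vals = [
            nd.support
            for nd in tree.postorder_internal_node_iter()
            if hasattr(nd, "support")
        ]
        assert vals and set(vals) <= {0.0, 1.0}

    def test_fixed_seed_is_byte_identical(self, rng, tmp_path):
        aln = self._two_clade_alignment(rng)
        p1, p2 = tmp_path / "a.nwk", tmp_path / "b.nwk"
        write_newick(bootstrap_support(aln, n_reps=20, seed=7), p1)
        write_newick(bootstrap_support(aln, n_reps=20, seed=7), p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert read_newick(p1) is not None


def _csv_of(D, labels):
    import io

    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(lab + "," + ",".join(str(x) for x in D[i]) + "\n")
    buf.seek(0)
    return buf
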