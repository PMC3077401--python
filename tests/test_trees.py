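from io import StringIO

import numpy as np
import pytest
from skbio import TreeNode

from domo.architecture import extract_trd_instances, infer_family_architectures
from domo.model import TRDInstance
from domo.simulate import SimParams, simulate_family
from domo.trees import (
    LabeledTree,
    build_nj_tree,
    collapse_zero_branches,
    position_mixing_score,
)

from conftest import random_dna
from oracles import brute_force_parsimony


def make_instance(seq_id, pos, seq):
    return TRDInstance(seq_id, pos, 0, len(seq), seq, strain=seq_id, locus_id="L1")


def labeled_from_newick(newick):
    return LabeledTree.from_newick(newick)


class TestBuildNJTree:
    def test_four_taxon_additive_topology_recovered(self):
        """Sequences engineered so distances are near-additive on ((A,B),(C,D))."""
        rng = np.random.default_rng(0)
        core = random_dna(rng, 300)

        def mutate(seq, sites):
            out = list(seq)
            for i in sites:
                out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
            return "".join(out)

        # left pair shares mutations 0-59, right pair shares 150-209;
        # each leaf adds private mutations
        left = mutate(core, range(0, 60))
        right = mutate(core, range(150, 210))
        leaves = {
            "A": mutate(left, range(220, 235)),
            "B": mutate(left, range(240, 255)),
            "C": mutate(right, range(260, 275)),
            "D": mutate(right, range(280, 295)),
        }
        instances = [
            make_instance(name, 1 + (name in "CD"), seq)
            for name, seq in leaves.items()
        ]
        tree = build_nj_tree(instances)
        names = {t.name for t in tree.tree.tips()}
        ab = tree.tree.lca([n for n in tree.tree.tips() if n.name.startswith(("A", "B"))])
        assert {t.name for t in ab.tips()} == {n for n in names if n[0] in "AB"}

    def test_three_taxa_closed_form_branch_lengths(self):
        """The unique 3-taxon tree has the three-point branch lengths
        l_x = (d_xy + d_xz - d_yz)/2 etc., from the realized distances."""
        from domo.clustering import pairwise_identity

        rng = np.random.default_rng(8)
        a, b, c = (random_dna(rng, 100) for _ in range(3))
        d_xy = 1 - pairwise_identity(a, b)
        d_xz = 1 - pairwise_identity(a, c)
        d_yz = 1 - pairwise_identity(b, c)
        instances = [
            make_instance("x", 1, a),
            make_instance("y", 1, b),
            make_instance("z", 2, c),
        ]
        tree = build_nj_tree(instances)
        lengths = {t.name.split("|")[0]: t.length for t in tree.tree.tips()}
        assert lengths["x"] == pytest.approx((d_xy + d_xz - d_yz) / 2, abs=1e-9)
        assert lengths["y"] == pytest.approx((d_xy + d_yz - d_xz) / 2, abs=1e-9)
        assert lengths["z"] == pytest.approx((d_xz + d_yz - d_xy) / 2, abs=1e-9)

    def test_identical_sequences_do_not_crash(self):
        seq = random_dna(np.random.default_rng(1), 100)
        instances = [make_instance(f"g{i}", 1 + i % 2, seq) for i in range(4)]
        tree = build_nj_tree(instances)
        assert all((t.length or 0) <= 1e-9 for t in tree.tree.tips())

    def test_fewer_than_three_instances_is_an_error(self):
        seq = random_dna(np.random.default_rng(2), 50)
        with pytest.raises(ValueError):
            build_nj_tree([make_instance("a", 1, seq), make_instance("b", 2, seq)])

    def test_newick_round_trip_preserves_topology_and_positions(self):
        rng = np.random.default_rng(3)
        instances = [
            make_instance(f"g{i}", 1 + i % 2, random_dna(rng, 120)) for i in range(5)
        ]
        tree = build_nj_tree(instances)
        again = LabeledTree.from_newick(tree.to_newick())
        assert again.positions == tree.positions
        assert again.tree.compare_rfd(tree.tree) == 0


class TestPositionMixingScore:
    def test_caterpillar_separated_scores_one(self):
        tree = labeled_from_newick(
            "(((a|pos1:1,b|pos1:1):1,c|pos1:1):1,(d|pos2:1,(e|pos2:1,f|pos2:1):1):1);"
        )
        assert position_mixing_score(tree) == 1

    def test_alternating_four_leaves_scores_two(self):
        tree = labeled_from_newick("((a|pos1:1,b|pos2:1):1,(c|pos1:1,d|pos2:1):1);")
        assert position_mixing_score(tree) == 2

    def test_single_position_is_an_error(self):
        tree = labeled_from_newick("((a|pos1:1,b|pos1:1):1,c|pos1:1);")
        with pytest.raises(ValueError, match="single position"):
            position_mixing_score(tree)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_parsimony(self, seed):
        """Hartigan equals exhaustive internal-state enumeration (<=12 leaves)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        names = [f"g{i}|pos{1 + int(rng.integers(0, 2))}" for i in range(n)]
        if len({nm.split('|')[1] for nm in names}) < 2:
            names[0] = "g0|pos1"
            names[1] = "g1|pos2"
        # random binary tree by sequential attachment
        newick = names[0]
        for nm in names[1:]:
            newick = f"({newick}:1,{nm}:1)"
        tree = labeled_from_newick(newick + ";")
        got = position_mixing_score(tree)
        expected = brute_force_parsimony(tree.tree, tree.positions)
        assert got == expected

    def test_collapse_removes_arbitrary_zero_length_resolution(self):
        # the zero-length internal branch hides (a1,(b... arrangement
        tree = labeled_from_newick(
            "((m|pos1:0.0,(x|pos2:0.0,y|pos2:0.0):0.0):0.2,(p|pos1:0.1,q|pos1:0.1):0.2);"
        )
        collapsed = collapse_zero_branches(tree.tree)
        polytomy = [n for n in collapsed.traverse() if len(n.children) > 2]
        assert polytomy
        assert position_mixing_score(tree) == 2


class TestSignatureOnSimulations:
    @pytest.mark.parametrize("seed", range(5))
    def test_substitution_only_separates_and_movement_mixes(self, seed):
        for counts, want_mixed in [({"SUBSTITUTION": 2}, False), ({"MOVEMENT": 1}, True)]:
            records, truth = simulate_family(
                SimParams(event_counts=counts, seed=60 + seed)
            )
            architectures, _c, failures = infer_family_architectures(records)
            assert not failures
            instances, _ = extract_trd_instances(records, architectures)
            for locus in ("L1", "L2"):
                sub = [t for t in instances if t.locus_id == locus]
                score = position_mixing_score(build_nj_tree(sub))
                moved = any(
                    e["type"] == "MOVEMENT" and e["locus"] == locus
                    for e in truth["events"]
                )
                if moved:
                    assert score >= 2
                else:
                    assert score == 1
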