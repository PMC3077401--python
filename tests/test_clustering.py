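import numpy as np
import pytest

from domo.clustering import (
    cluster_trds,
    label_of,
    label_position_matrix,
    pairwise_identity,
)
from domo.model import TRDInstance
from domo.simulate import SimParams, simulate_family
from domo.architecture import extract_trd_instances, infer_family_architectures

from conftest import random_dna
from oracles import gotoh_global


def make_instance(seq_id, pos, seq, locus="L1"):
    return TRDInstance(seq_id, pos, 0, len(seq), seq, strain=seq_id, locus_id=locus)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        seq = random_dna(np.random.default_rng(0), 400)
        assert pairwise_identity(seq, seq) == 1.0

    def test_hand_alignment_example(self):
        # 7/8 matches, no gap is optimal
        assert pairwise_identity("ACGTACGT", "ACGAACGT") == pytest.approx(0.875)

    def test_deletion_identity_matches_dp_oracle(self):
        rng = np.random.default_rng(1)
        x = random_dna(rng, 120)
        deleted = x[:40] + x[50:]  # 10 bases removed
        got = pairwise_identity(x, deleted)
        _score, identities, length = gotoh_global(x, deleted)
        assert got == pytest.approx(identities / length)

    @pytest.mark.parametrize("seed", range(5))
    def test_alignment_score_matches_dp_oracle(self, seed):
        from domo.clustering import _aligner

        rng = np.random.default_rng(seed)
        a = random_dna(rng, int(rng.integers(30, 60)))
        b = random_dna(rng, int(rng.integers(30, 60)))
        expected_score, _i, _l = gotoh_global(a, b)
        assert _aligner.score(a, b) == pytest.approx(expected_score)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = random_dna(rng, 80), random_dna(rng, 90)
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


class TestClusterTRDs:
    def test_simulated_family_reproduces_truth_labels(self):
        records, truth = simulate_family(
            SimParams(event_counts={"MOVEMENT": 1, "SUBSTITUTION": 1}, seed=30)
        )
        architectures, _c, failures = infer_family_architectures(records)
        assert not failures
        instances, _ = extract_trd_instances(records, architectures)
        labels = label_of(cluster_trds(instances))
        # cluster labels must induce the same partition as the truth labels
        truth_of = {
            (sid, int(p)): lab
            for sid, row in truth["truth_labels"].items()
            for p, lab in row.items()
        }
        grouping = {}
        for key, label in labels.items():
            grouping.setdefault(label, set()).add(truth_of[key])
        assert all(len(v) == 1 for v in grouping.values())
        assert len(grouping) == len(set(truth_of.values()))

    def test_robust_to_point_mutation_noise(self):
        """Mutated copies of a moved domain still cluster with their source."""
        for seed in range(3):
            records, truth = simulate_family(
                SimParams(
                    event_counts={"MOVEMENT": 1},
                    point_mutation_rate=0.01,
                    seed=40 + seed,
                )
            )
            architectures, _c, failures = infer_family_architectures(records)
            assert not failures
            instances, _ = extract_trd_instances(records, architectures)
            labels = label_of(cluster_trds(instances))
            truth_of = {
                (sid, int(p)): lab
                for sid, row in truth["truth_labels"].items()
                for p, lab in row.items()
            }
            grouping = {}
            for key, label in labels.items():
                grouping.setdefault(label, set()).add(truth_of[key])
            assert all(len(v) == 1 for v in grouping.values())
            assert len(grouping) == len(set(truth_of.values()))

    def test_all_identical_instances_form_one_cluster(self):
        seq = random_dna(np.random.default_rng(3), 400)
        instances = [make_instance(f"g{i}", 1 + i % 2, seq) for i in range(4)]
        clusters = cluster_trds(instances)
        assert len(clusters) == 1 and clusters[0].label == "a"

    def test_threshold_one_separates_every_distinct_sequence(self):
        rng = np.random.default_rng(4)
        seqs = [random_dna(rng, 200) for _ in range(3)]
        instances = [make_instance(f"g{i}", 1, s) for i, s in enumerate(seqs + seqs)]
        assert len(cluster_trds(instances, threshold=1.0)) == 3

    def test_partition_property(self, annotated_family):
        _r, _t, _a, instances, clusters, _m = annotated_family
        seen = [m.key for c in clusters for m in c.members]
        assert sorted(seen) == sorted(t.key for t in instances)
        assert len(seen) == len(set(seen))

    def test_label_stability_under_input_permutation(self):
        rng = np.random.default_rng(5)
        seqs = [random_dna(rng, 150) for _ in range(4)]
        instances = [make_instance(f"g{i}", 1, seqs[i % 4]) for i in range(8)]
        base = label_of(cluster_trds(instances))
        rng.shuffle(instances)
        assert label_of(cluster_trds(instances)) == base

    def test_no_instances_is_an_error(self):
        with pytest.raises(ValueError):
            cluster_trds([])


class TestLabelPositionMatrix:
    def test_cross_position_entry_is_the_movement_signature(self, annotated_family):
        records, truth, architectures, instances, clusters, matrix = annotated_family
        move = next(e for e in truth["events"] if e["type"] == "MOVEMENT")
        labels = label_of(clusters)
        src, dst = move["positions"]
        donor_label = labels[(move["donor"], src)]
        assert labels[(move["recipient"], dst)] == donor_label

    def test_absent_slots_are_dashed(self, annotated_family):
        _r, truth, architectures, _i, _c, matrix = annotated_family
        deleted = next(e for e in truth["events"] if e["type"] == "DELETION")
        row = matrix.loc[
            (deleted["recipient"], deleted["locus"])
        ]
        assert row[2] == "—"

    def test_single_allele_matrix(self):
        seq = random_dna(np.random.default_rng(6), 300)
        inst = [make_instance("g1", 1, seq), make_instance("g1", 2, seq[::-1])]
        from domo.model import GeneArchitecture

        arch = GeneArchitecture("g1", [(0, 300), (400, 700)])
        matrix = label_position_matrix(cluster_trds(inst), [arch], {"g1": "L1"})
        assert matrix.shape == (1, 2)

    def test_missing_instance_is_an_error(self, annotated_family):
        _r, _t, architectures, instances, _c, _m = annotated_family
        clusters = cluster_trds(instances[:-1])
        with pytest.raises(ValueError, match="missing"):
            label_position_matrix(clusters, list(architectures.values()), {})
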