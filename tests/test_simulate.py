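import numpy as np
import pytest

from domo.clustering import pairwise_identity
from domo.model import DomoError
from domo.simulate import (
    SimParams,
    apply_event,
    build_allele,
    generate_trd_pool,
    init_family,
    make_context,
    replay_truth,
    simulate_family,
)

from conftest import ALL_EVENTS


class TestPool:
    def test_cross_subfamily_members_diverge_below_60_percent(self):
        params = SimParams(trd_pool_size=2, seed=0)
        pool = generate_trd_pool(params, np.random.default_rng(0))
        assert [label for label, _ in pool] == ["a", "b"]
        assert all(len(seq) == 400 for _, seq in pool)
        assert pairwise_identity(pool[0][1], pool[1][1]) < 0.60

    def test_all_members_stay_below_cluster_threshold(self):
        params = SimParams(trd_pool_size=8, seed=1)
        pool = generate_trd_pool(params, np.random.default_rng(1))
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                assert pairwise_identity(pool[i][1], pool[j][1]) < 0.78

    def test_pool_of_one_is_an_error(self):
        with pytest.raises(ValueError):
            SimParams(trd_pool_size=1)

    def test_same_seed_gives_identical_pool(self):
        params = SimParams(trd_pool_size=4, seed=5)
        p1 = generate_trd_pool(params, np.random.default_rng(5))
        p2 = generate_trd_pool(params, np.random.default_rng(5))
        assert p1 == p2


class TestBuildAllele:
    def setup_method(self):
        self.params = SimParams.group2(seed=2)
        self.rng = np.random.default_rng(2)
        self.ctx = make_context(self.params, self.rng)

    def test_component_layout_and_lengths(self):
        allele = build_allele("a", "b", 3, self.params, self.ctx, rng=self.rng)
        kinds = [c.kind for c in allele.components]
        assert kinds == ["flank5", "x", "trd", "y", "central", "x", "trd", "y", "flank3"]
        smap = {
            i: (kind, e - s) for i, (kind, cls, s, e) in enumerate(allele.slot_map())
        }
        assert smap[1] == ("x", 37) and smap[5] == ("x", 37)
        assert smap[3] == ("y", 49) and smap[7] == ("y", 49)
        assert smap[4] == ("central", 36)  # 3 copies of the 12-bp unit
        assert len(allele.sequence) == sum(len(c.seq) for c in allele.components)

    def test_identical_labels_give_identical_slots(self):
        allele = build_allele("a", "a", 2, self.params, self.ctx, rng=self.rng)
        t1, t2 = allele.trd_components()
        assert t1.seq == t2.seq

    def test_copies_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside range"):
            build_allele("a", "b", 9, self.params, self.ctx, rng=self.rng)


class TestApplyEvent:
    def family(self, seed=3, **kw):
        params = SimParams(seed=seed, **kw)
        rng = np.random.default_rng(seed)
        return init_family(params, rng), rng

    def test_movement_copies_donor_slot_exactly(self):
        family, rng = self.family()
        family, plan = apply_event(family, "MOVEMENT", rng)
        donor = family.by_id(plan["donor"])
        recipient = family.by_id(plan["recipient"])
        src, dst = plan["positions"]
        assert (
            recipient.trd_components()[dst - 1].seq
            == donor.trd_components()[src - 1].seq
        )

    def test_deletion_collapses_to_single_cassette(self):
        family, rng = self.family()
        family, plan = apply_event(family, "DELETION", rng)
        recipient = family.by_id(plan["recipient"])
        assert recipient.n_trds == 1
        kinds = [c.kind for c in recipient.components]
        assert kinds.count("x") == 1 and kinds.count("y") == 1

    def test_duplication_yields_three_trds_with_identical_tail_slots(self):
        family, rng = self.family()
        family, plan = apply_event(family, "DUPLICATION", rng)
        recipient = family.by_id(plan["recipient"])
        assert recipient.n_trds == 3
        trds = recipient.trd_components()
        assert trds[1].seq == trds[2].seq

    def test_duplication_without_z_repeat_is_an_error(self):
        family, rng = self.family(repeat_z_len=None)
        with pytest.raises(DomoError, match="repeat_z"):
            apply_event(family, "DUPLICATION", rng)

    def test_conservation_outside_the_recombined_slot(self):
        family, rng = self.family()
        before = {a.seq_id: a.sequence for a in family.alleles}
        family, plan = apply_event(family, "SUBSTITUTION", rng)
        for allele in family.alleles:
            if allele.seq_id == plan["recipient"]:
                slots = allele.trd_slots()
                s, e = slots[plan["positions"][0] - 1]
                seq = allele.sequence
                assert seq[:s] == before[allele.seq_id][:s]
                assert seq[e:] == before[allele.seq_id][e:]
            else:
                assert allele.sequence == before[allele.seq_id]


class TestSimulateFamily:
    def test_no_events_no_noise_is_the_clonal_identity_case(self):
        records, truth = simulate_family(SimParams(seed=4))
        assert truth["events"] == [] and truth["mutations"] == []
        rebuilt = {a["seq_id"]: a for a in truth["ancestral"]}
        for rec in records:
            assert rec.sequence == "".join(
                c["seq"] for c in rebuilt[rec.seq_id]["components"]
            )

    def test_same_seed_reproduces_identical_sequences(self):
        params = dict(event_counts=dict(ALL_EVENTS), seed=6)
        r1, t1 = simulate_family(SimParams(**params))
        r2, t2 = simulate_family(SimParams(**params))
        assert r1 == r2 and t1 == t2

    def test_event_bookkeeping_matches_requested_counts(self):
        records, truth = simulate_family(
            SimParams(event_counts={"MOVEMENT": 3}, n_alleles_per_locus=4, seed=7)
        )
        assert sum(e["type"] == "MOVEMENT" for e in truth["events"]) == 3

    def test_replay_reproduces_emitted_sequences_byte_identically(
        self, all_events_family
    ):
        _params, records, truth = all_events_family
        assert [r.sequence for r in replay_truth(truth)] == [
            r.sequence for r in records
        ]

    def test_replay_with_mutations(self):
        records, truth = simulate_family(
            SimParams(event_counts={"MOVEMENT": 1}, point_mutation_rate=0.01, seed=8)
        )
        assert truth["mutations"]
        assert [r.sequence for r in replay_truth(truth)] == [
            r.sequence for r in records
        ]

    def test_preserve_repeats_keeps_repeat_copies_exact(self):
        records, truth = simulate_family(
            SimParams(point_mutation_rate=0.02, seed=9)
        )
        x = truth["repeats"]["X"]
        for rec in records:
            assert rec.sequence.count(x) == 2

    def test_architecture_validity_of_every_emitted_allele(self):
        from domo.architecture import infer_family_architectures

        records, truth = simulate_family(
            SimParams(event_counts=dict(ALL_EVENTS), seed=10)
        )
        architectures, _consensus, failures = infer_family_architectures(records)
        assert not failures
        for rec in records:
            assert (
                architectures[rec.seq_id].n_trds
                == len(truth["truth_labels"][rec.seq_id])
            )
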