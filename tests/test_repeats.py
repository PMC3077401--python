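import numpy as np
import pytest

from domo.repeats import (
    classify_repeat_pairs,
    find_direct_repeat_pairs,
    find_repeat_copies,
    find_tandem_repeat,
)
from domo.simulate import GROUP2_UNIT, TYPE_IIG_UNIT, plant_repeat_pair

from conftest import random_dna
from oracles import oracle_repeat_pairs, oracle_tandem


class TestDirectRepeatPairs:
    @pytest.mark.parametrize("length", [37, 14])
    def test_planted_exact_pair_recovered_at_exact_coordinates(self, length):
        seq, left, right = plant_repeat_pair(
            np.random.default_rng(7), 1000, length, 100, 463
        )
        pairs = find_direct_repeat_pairs(seq, min_len=12, max_mismatch_frac=0.0)
        hits = [p for p in pairs if p.left == left and p.right == right]
        assert len(hits) == 1
        assert hits[0].length_bp == length and hits[0].identity == 1.0

    def test_min_len_floor(self):
        with pytest.raises(ValueError, match="seed-length floor"):
            find_direct_repeat_pairs("ACGT" * 100, min_len=7)

    def test_too_short_sequence_yields_nothing(self):
        assert find_direct_repeat_pairs("ACGTACGT") == []

    def test_mismatched_pair_detected_within_budget(self):
        rng = np.random.default_rng(3)
        seq, left, right = plant_repeat_pair(rng, 800, 40, 50, 300)
        # two mismatches in the right copy: 2/40 = 0.05 <= 0.1
        s = list(seq)
        for offset in (10, 25):
            i = right[0] + offset
            s[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[i]]
        pairs = find_direct_repeat_pairs("".join(s), max_mismatch_frac=0.1)
        hit = [p for p in pairs if p.left[0] == left[0]]
        assert hit and hit[0].identity >= 0.9

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        """Detector output equals full enumeration on random sequences,
        half of them with a planted degenerate pair."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(150, 301))
        seq = random_dna(rng, n)
        if seed % 2:
            rep = random_dna(rng, int(rng.integers(12, 40)))
            L = len(rep)
            p2_lo = 10 + L + 50
            if p2_lo < n - L:
                p2 = int(rng.integers(p2_lo, n - L))
                seq = seq[:10] + rep + seq[10 + L : p2] + rep + seq[p2 + L :]
        got = sorted(
            (p.left, p.right, p.length_bp, p.identity)
            for p in find_direct_repeat_pairs(seq)
        )
        assert got == oracle_repeat_pairs(seq)

    def test_random_sequence_with_no_planted_repeat_is_empty(self):
        seq = random_dna(np.random.default_rng(0), 500)
        pairs = find_direct_repeat_pairs(seq, min_len=12, max_mismatch_frac=0.0)
        assert pairs == []
        assert oracle_repeat_pairs(seq, frac=0.0) == []


class TestClassification:
    @staticmethod
    def allele_sequence(seed, group2=True):
        from domo.simulate import SimParams, build_allele, make_context

        params = SimParams.group2(seed=seed) if group2 else SimParams(seed=seed)
        rng = np.random.default_rng(seed)
        ctx = make_context(params, rng)
        return build_allele("a", "b", 3, params, ctx, rng=rng).sequence

    def test_group2_layout_assigns_x_and_y(self):
        seq = self.allele_sequence(5)
        pairs = classify_repeat_pairs(
            find_direct_repeat_pairs(seq, max_mismatch_frac=0.0), seq
        )
        by_class = {p.class_name: p for p in pairs if p.class_name}
        assert by_class["X"].length_bp == 37
        assert by_class["Y"].length_bp == 49
        # interleaving xL < yL < xR < yR
        x, y = by_class["X"], by_class["Y"]
        assert x.left[0] < y.left[0] < x.right[0] < y.right[0]

    def test_z_pair_inside_trd2_region_assigned_z(self):
        seq = self.allele_sequence(6, group2=False)
        pairs = classify_repeat_pairs(
            find_direct_repeat_pairs(seq, max_mismatch_frac=0.0), seq
        )
        classes = sorted(p.class_name for p in pairs if p.class_name)
        assert classes == ["X", "Y", "Z"]
        z = next(p for p in pairs if p.class_name == "Z")
        assert z.length_bp == 14

    def test_single_pair_classified_x_like(self):
        seq, left, right = plant_repeat_pair(np.random.default_rng(2), 600, 30, 50, 300)
        pairs = classify_repeat_pairs(
            find_direct_repeat_pairs(seq, max_mismatch_frac=0.0), seq
        )
        assert [p.class_name for p in pairs] == ["X"]


def rotations(unit):
    return {unit[i:] + unit[:i] for i in range(len(unit))}


class TestTandemRepeat:
    def test_three_copies_of_printed_group2_unit(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 150) + GROUP2_UNIT * 3 + random_dna(rng, 150)
        t = find_tandem_repeat(seq)
        assert (t.unit_length_bp, t.copy_number) == (12, 3)
        # a flank base matching the unit's tail can shift the phase; the
        # reported unit is then a rotation of the printed one
        assert t.unit_sequence in rotations(GROUP2_UNIT)

    def test_four_copies_of_24bp_unit_with_one_mismatch(self):
        rng = np.random.default_rng(2)
        copies = list(TYPE_IIG_UNIT * 4)
        copies[24 * 2 + 7] = "A" if copies[24 * 2 + 7] != "A" else "C"  # copy 3
        seq = random_dna(rng, 80) + "".join(copies) + random_dna(rng, 80)
        t = find_tandem_repeat(seq)
        assert (t.unit_length_bp, t.copy_number) == (24, 4)
        assert t.unit_sequence in rotations(TYPE_IIG_UNIT)  # consensus heals the mismatch

    def test_random_sequence_with_no_period_returns_absent(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            seq = random_dna(rng, 200)
            expected = oracle_tandem(seq, unit_range=(6, 30), frac=0.0)
            got = find_tandem_repeat(seq, unit_len_range=(6, 30), max_mismatch_frac=0.0)
            if expected is None:
                assert got is None
            else:
                assert (got.start, got.unit_length_bp, got.copy_number) == expected

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_period_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        unit = random_dna(rng, int(rng.integers(6, 25)))
        k = int(rng.integers(2, 5))
        seq = random_dna(rng, 60) + unit * k + random_dna(rng, 60)
        got = find_tandem_repeat(seq, unit_len_range=(6, 30))
        exp = oracle_tandem(seq, unit_range=(6, 30))
        assert exp is not None and got is not None
        assert (got.start, got.unit_length_bp, got.copy_number) == exp

    def test_self_consistency_on_reported_interval(self):
        rng = np.random.default_rng(9)
        seq = random_dna(rng, 100) + GROUP2_UNIT * 4 + random_dna(rng, 100)
        t = find_tandem_repeat(seq)
        again = find_tandem_repeat(seq[t.start : t.end])
        assert (again.unit_sequence, again.copy_number) == (
            t.unit_sequence,
            t.copy_number,
        )


class TestFindRepeatCopies:
    def test_locates_single_copies_exactly(self):
        rng = np.random.default_rng(10)
        rep = random_dna(rng, 37)
        seq = random_dna(rng, 200) + rep + random_dna(rng, 300) + rep + random_dna(rng, 100)
        assert find_repeat_copies(seq, rep) == [(200, 237), (537, 574)]

    def test_tolerates_mismatches_when_asked(self):
        rng = np.random.default_rng(11)
        rep = random_dna(rng, 30)
        mutated = "A" + rep[1:] if rep[0] != "A" else "C" + rep[1:]
        seq = random_dna(rng, 50) + mutated + random_dna(rng, 50)
        assert find_repeat_copies(seq, rep, max_mismatch_frac=0.0) == []
        assert find_repeat_copies(seq, rep, max_mismatch_frac=0.1) == [(50, 80)]
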