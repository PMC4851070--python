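"""One-hot gesture encoding, dual-bit test codes, and popcount matching."""

import logging

import numpy as np
import pytest

import signcomp as sc
from signcomp.codec import (
    CodeTable,
    GestureCode,
    build_code_table,
    decode_code,
    encode_gesture,
    encode_subclass,
    encode_test,
    match_code,
    match_scores,
)
from signcomp.core import ComponentInventory

PAPER_COUNTS = (11, 5, 3, 3, 13)


def inventory_with_counts(counts):
    comps = {}
    for name, n in zip(sc.COMPONENTS, counts):
        comps[name] = ComponentInventory(n=n, centers=np.zeros((n, 2)))
    return sc.SubclassInventory(components=comps)


@pytest.fixture(scope="module")
def paper_inventory():
    return inventory_with_counts(PAPER_COUNTS)


class TestEncodeSubclass:
    @pytest.mark.parametrize("i, n, expected", [
        (4, 11, "00010000000"),
        (1, 5, "10000"),
        (12, 13, "0000000000010"),
    ])
    def test_printed_segments(self, i, n, expected):
        assert "".join(map(str, encode_subclass(i, n))) == expected

    @pytest.mark.parametrize("i, n", [(0, 5), (6, 5), (-1, 3)])
    def test_out_of_range_rejected(self, i, n):
        with pytest.raises(sc.ValidationError):
            encode_subclass(i, n)


class TestEncodeGesture:
    def test_reference_worked_example(self, paper_inventory):
        rep = sc.ComponentRepresentation.from_tuple(
            [4, 4, 5, 5, 1, 4, 2, 2, 2, 3, 3, 3, 12])
        code = encode_gesture(rep, paper_inventory)
        assert code.as_string(sep=" ") == (
            "00010000000 00010000000 00001000000 00001 10000 00010 "
            "010 010 010 001 001 001 0000000000010")
        assert len(code) == 3 * 11 + 3 * 5 + 3 * 3 + 3 * 3 + 13 == 79
        assert code.popcount() == 13
        assert decode_code(code).as_tuple() == rep.as_tuple()

    def test_bounds_violation_rejected(self, paper_inventory):
        rep = sc.ComponentRepresentation.from_tuple([12] + [1] * 12)
        with pytest.raises(sc.ValidationError):
            encode_gesture(rep, paper_inventory)

    def test_encoding_is_a_bijection(self, rng):
        """decode . encode is the identity on random inventories/reps."""
        for _ in range(1000):
            counts = tuple(int(rng.integers(2, 14)) for _ in range(5))
            inv = inventory_with_counts(counts)
            values = [int(rng.integers(1, counts[{"handshape": 0,
                                                  "orientation": 1,
                                                  "axis": 2, "rotation": 3,
                                                  "trajectory": 4}[comp]] + 1))
                      for _name, comp, _stage in sc.ELEMENTS]
            rep = sc.ComponentRepresentation.from_tuple(values)
            assert decode_code(encode_gesture(rep, inv)).as_tuple() == \
                rep.as_tuple()


class TestCodeTable:
    def test_one_code_per_target_gesture(self, paper_inventory, rng):
        reps = {}
        seen = set()
        while len(reps) < 110:
            values = tuple(
                int(rng.integers(1, paper_inventory.component(comp).n + 1))
                for _n, comp, _s in sc.ELEMENTS)
            if values not in seen:
                seen.add(values)
                reps[f"W{len(reps):03d}"] = \
                    sc.ComponentRepresentation.from_tuple(values)
        table = build_code_table(reps, paper_inventory)
        assert len(table) == 110
        assert all(len(c) == 79 for c in table.entries.values())

    def test_duplicate_codes_are_logged_not_rejected(self, paper_inventory,
                                                     caplog):
        rep = sc.ComponentRepresentation.from_tuple([1] * 13)
        with caplog.at_level(logging.WARNING, logger="signcomp.codec"):
            table = build_code_table({"A": rep, "B": rep}, paper_inventory)
        assert len(table) == 2
        assert any("shares its code" in r.message for r in caplog.records)

    def test_json_round_trip(self, paper_inventory, tmp_path):
        from signcomp import io as sio
        reps = {"A": sc.ComponentRepresentation.from_tuple([1] * 13),
                "B": sc.ComponentRepresentation.from_tuple([2] * 13)}
        table = build_code_table(reps, paper_inventory)
        sio.save_code_table(table, tmp_path / "t.json")
        back = sio.load_code_table(tmp_path / "t.json")
        assert back.gesture_ids == table.gesture_ids
        np.testing.assert_array_equal(back.matrix(), table.matrix())


def rankings_for(rep, counts, second_choice=None):
    """Perfect rankings: planted subclass first, a deterministic runner-up."""
    by_comp = dict(zip(sc.COMPONENTS, counts))
    out = {}
    for name, comp, _stage in sc.ELEMENTS:
        n = by_comp[comp]
        best = rep.element(name)
        order = [best] + [i for i in range(1, n + 1) if i != best]
        if second_choice is not None and len(order) > 1:
            order[1] = second_choice(best, n)
        out[name] = [(i, float(-k)) for k, i in enumerate(order)]
    return out


class TestEncodeTest:
    def test_dual_bit_segment(self):
        inv = inventory_with_counts((11, 2, 2, 2, 2))
        rankings = {name: [(1, 0.0), (2, -1.0)] for name in sc.ELEMENT_NAMES}
        rankings["sb"] = [(4, 0.0), (7, -1.0), (1, -2.0)]
        code = encode_test(rankings, inv)
        assert code.segments()[0].tolist() == \
            [0, 0, 0, 1, 0, 0, 1, 0, 0, 0, 0]

    def test_popcount_is_26_with_two_plus_subclasses(self, paper_inventory,
                                                     rng):
        rep = sc.ComponentRepresentation.from_tuple([1] * 13)
        code = encode_test(rankings_for(rep, PAPER_COUNTS), paper_inventory)
        assert code.popcount() == 26

    def test_single_subclass_component_gets_one_bit(self):
        counts = (2, 1, 2, 2, 2)
        inv = inventory_with_counts(counts)
        rep = sc.ComponentRepresentation.from_tuple([1] * 13)
        code = encode_test(rankings_for(rep, counts), inv)
        # orientation segments (elements 4-6) have a single bit each
        assert code.popcount() == 26 - 3

    def test_missing_element_rejected(self, paper_inventory):
        rankings = {name: [(1, 0.0)] for name in sc.ELEMENT_NAMES[:-1]}
        with pytest.raises(sc.ValidationError, match="tr"):
            encode_test(rankings, paper_inventory)


class TestMatchCode:
    def test_top1_match_scores_thirteen(self, paper_inventory):
        by_comp = dict(zip(sc.COMPONENTS, PAPER_COUNTS))
        caps = [by_comp[comp] for _n, comp, _s in sc.ELEMENTS]
        reps = {f"W{i}": sc.ComponentRepresentation.from_tuple(
            [min(2 * i + 1, n) for n in caps]) for i in range(4)}
        table = build_code_table(reps, paper_inventory)
        x = encode_test(
            rankings_for(reps["W2"], PAPER_COUNTS,
                         second_choice=lambda best, n: best - 1 or 2),
            paper_inventory)
        scores = match_scores(x, table)
        assert scores.max() == 13
        assert match_code(x, table) == "W2"

    def test_all_zero_code_ties_to_first_entry(self, paper_inventory):
        reps = {"A": sc.ComponentRepresentation.from_tuple([1] * 13),
                "B": sc.ComponentRepresentation.from_tuple([2] * 13)}
        table = build_code_table(reps, paper_inventory)
        zero = GestureCode(bits=np.zeros(79, dtype=np.uint8),
                           segment_lengths=table.segment_lengths)
        with pytest.warns(UserWarning, match="tie"):
            assert match_code(zero, table) == "A"

    def test_length_mismatch_rejected(self, paper_inventory):
        reps = {"A": sc.ComponentRepresentation.from_tuple([1] * 13)}
        table = build_code_table(reps, paper_inventory)
        other = inventory_with_counts((2, 2, 2, 2, 2))
        x = encode_gesture(sc.ComponentRepresentation.from_tuple([1] * 13),
                           other)
        with pytest.raises(sc.ValidationError, match="mismatch"):
            match_code(x, table)

    def test_matching_with_perfect_rankings_equals_lookup(self, rng):
        """Dual-bit matching recovers the encoded gesture on random worlds."""
        for _ in range(200):
            counts = tuple(int(rng.integers(2, 9)) for _ in range(5))
            inv = inventory_with_counts(counts)
            by_comp = dict(zip(sc.COMPONENTS, counts))
            reps, seen = {}, set()
            while len(reps) < 8:
                values = tuple(int(rng.integers(1, by_comp[comp] + 1))
                               for _n, comp, _s in sc.ELEMENTS)
                if values not in seen:
                    seen.add(values)
                    reps[f"G{len(reps)}"] = \
                        sc.ComponentRepresentation.from_tuple(values)
            table = build_code_table(reps, inv)
            target = f"G{int(rng.integers(0, 8))}"
            x = encode_test(rankings_for(reps[target], counts), inv)
            scores = match_scores(x, table)
            assert scores[table.gesture_ids.index(target)] == 13
            # no other entry can exceed 13 by construction
            assert match_scores(x, table).max() == 13

    def test_consistent_permutation_invariance(self, paper_inventory, rng):
        reps = {f"G{i}": sc.ComponentRepresentation.from_tuple(
            list(rng.integers(1, 3, size=13))) for i in range(5)}
        table = build_code_table(reps, paper_inventory)
        x = encode_test(rankings_for(next(iter(reps.values())), PAPER_COUNTS),
                        paper_inventory)
        perm = rng.permutation(79)
        permuted_table = CodeTable(entries={
            gid: GestureCode(bits=c.bits[perm],
                             segment_lengths=c.segment_lengths)
            for gid, c in table.entries.items()})
        x_perm = GestureCode(bits=x.bits[perm],
                             segment_lengths=x.segment_lengths)
        np.testing.assert_array_equal(match_scores(x, table),
                                      match_scores(x_perm, permuted_table))
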