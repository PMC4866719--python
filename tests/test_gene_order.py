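"""Circular gene-order normalization, comparison and event detection."""

import numpy as np
import pytest

from mitocomp.gene_order import (
    GeneOrder,
    RearrangementEvent,
    breakpoint_distance,
    detect_duplications,
    detect_events,
    normalize,
    pcg_order_identical,
    syntenic_blocks,
)
from mitocomp.synthetic import apply_events, clitellate_template, random_event


def _adjacency_oracle(o: GeneOrder) -> set:
    out = set()
    n = len(o.labels)
    for i in range(n):
        x, sx = o.labels[i], o.strands[i]
        y, sy = o.labels[(i + 1) % n], o.strands[(i + 1) % n]
        flip = {"+": "-", "-": "+"}
        out.add(frozenset({(x, sx, y, sy), (y, flip[sy], x, flip[sx])}))
    return out


class TestNormalize:
    def test_already_anchored_unchanged(self):
        o = GeneOrder(["cox1", "trnD", "atp8"], ["+"] * 3, True)
        assert normalize(o) == o

    def test_rotation_to_anchor(self):
        o = GeneOrder(["trnD", "atp8", "cox1"], ["+"] * 3, True)
        assert normalize(o).labels == ["cox1", "trnD", "atp8"]

    def test_minus_strand_anchor_reverses_and_flips(self):
        o = GeneOrder(["trnD", "cox1", "atp8"], ["+", "-", "+"], True)
        n = normalize(o)
        assert n.labels == ["cox1", "trnD", "atp8"]
        assert n.strands == ["+", "-", "-"]

    def test_idempotent(self, template):
        rng = np.random.default_rng(5)
        for _ in range(20):
            k = int(rng.integers(len(template.labels)))
            o = GeneOrder(
                template.labels[k:] + template.labels[:k],
                template.strands[k:] + template.strands[:k],
                True,
            )
            once = normalize(o)
            assert normalize(once) == once

    def test_anchor_missing_or_duplicated_errors(self):
        with pytest.raises(ValueError, match="anchor"):
            normalize(GeneOrder(["trnD", "atp8"], ["+", "+"], True))
        with pytest.raises(ValueError, match="anchor"):
            normalize(GeneOrder(["cox1", "cox1"], ["+", "+"], True))


class TestPcgOrderIdentical:
    def test_trna_placement_does_not_matter(self, template):
        moved = apply_events(
            template,
            [RearrangementEvent("translocation", ["trnG"], to_index=20)],
        )
        assert pcg_order_identical(moved, template)

    def test_nad2_nad3_swap_differs(self, template):
        """The eunicid arrangement (nad2 and nad3 exchanged) is detected as a
        different protein-coding gene order."""
        swapped = apply_events(
            template, [RearrangementEvent("adjacent_swap", ["nad3", "nad2"])]
        )
        # adjacent_swap on non-adjacent genes just exchanges their slots
        assert not pcg_order_identical(swapped, template)

    def test_reflexive(self, template):
        assert pcg_order_identical(template, template)


class TestBreakpointDistance:
    def test_self_distance_zero(self, template):
        assert breakpoint_distance(template, template) == 0

    def test_matches_bruteforce_adjacency_oracle(self):
        labels = list("abcde")
        ref = GeneOrder(labels, ["+"] * 5, True)
        rng = np.random.default_rng(0)
        for _ in range(100):
            perm = [str(x) for x in rng.permutation(labels)]
            strands = [str(rng.choice(["+", "-"])) for _ in perm]
            q = GeneOrder(perm, strands, True)
            expected = len(_adjacency_oracle(q) - _adjacency_oracle(ref))
            assert breakpoint_distance(q, ref) == expected
            assert breakpoint_distance(ref, q) == breakpoint_distance(q, ref)

    def test_triangle_inequality_spot_checks(self):
        labels = list("abcde")
        rng = np.random.default_rng(1)
        orders = [
            GeneOrder([str(x) for x in rng.permutation(labels)],
                      [str(rng.choice(["+", "-"])) for _ in labels], True)
            for _ in range(12)
        ]
        for a in orders[:4]:
            for b in orders[4:8]:
                for c in orders[8:]:
                    assert breakpoint_distance(a, c) <= (
                        breakpoint_distance(a, b) + breakpoint_distance(b, c)
                    )

    def test_single_translocation_on_ten_genes_gives_three(self):
        labels = [f"g{i}" for i in range(10)]
        ref = GeneOrder(labels, ["+"] * 10, True)
        q = GeneOrder(labels[:2] + labels[3:7] + ["g2"] + labels[7:], ["+"] * 10, True)
        assert breakpoint_distance(q, ref) == 3

    def test_duplicates_rejected_with_guidance(self):
        a = GeneOrder(["cox1", "trnD", "trnD"], ["+"] * 3, True)
        b = GeneOrder(["cox1", "trnD", "trnD"], ["+"] * 3, True)
        with pytest.raises(ValueError, match="detect_duplications"):
            breakpoint_distance(a, b)


class TestDuplications:
    def test_trnd_duplication_at_cox2_atp8_junction(self, template):
        q = apply_events(template, [RearrangementEvent("duplication", ["trnD"])])
        dups = detect_duplications(q)
        assert [(l, c) for l, c, _ in dups] == [("trnD", 2)]
        i = q.labels.index("cox2")
        assert q.labels[i:i + 4] == ["cox2", "trnD", "trnD", "atp8"]

    def test_no_duplicates_empty(self, template):
        assert detect_duplications(template) == []

    def test_triplicated_gene_count_three(self, template):
        q = apply_events(template, [RearrangementEvent("duplication", ["trnD"])] * 2)
        assert [(l, c) for l, c, _ in detect_duplications(q)] == [("trnD", 3)]


class TestDetectEvents:
    def test_identical_orders_no_events(self, template):
        assert detect_events(template, template) == []

    def test_adjacent_swap_named(self, template):
        """The trnA x trnS2 pattern: two neighbouring tRNAs switch places."""
        q = apply_events(
            template, [RearrangementEvent("adjacent_swap", ["trnA", "trnS2"])]
        )
        events = detect_events(q, template)
        assert len(events) == 1
        assert events[0].kind == "adjacent_swap"
        assert set(events[0].genes) == {"trnA", "trnS2"}

    @pytest.mark.parametrize(
        "kind", ["duplication", "loss", "adjacent_swap", "inversion", "translocation"]
    )
    def test_single_event_recovery_200_seeds(self, template, kind):
        """Applying one random event and re-detecting it recovers the kind
        and genes in at least 99% of 200 seeded trials."""
        rng = np.random.default_rng(hash(kind) % 2**31)
        ok = 0
        for _ in range(200):
            ev = random_event(template, kind, rng)
            q = apply_events(template, [ev])
            det = detect_events(q, template)
            if (
                len(det) == 1
                and det[0].kind == kind
                and set(ev.genes) <= set(det[0].genes)
            ):
                ok += 1
        assert ok >= 198

    def test_empty_orders_error(self):
        with pytest.raises(ValueError):
            GeneOrder([], [], True)


class TestSyntenicBlocks:
    def test_identical_orders_one_block(self, template):
        blocks = syntenic_blocks(template, template)
        assert len(blocks) == 1
        assert set(blocks[0]) == set(template.labels)

    def test_block_exchange_keeps_blocks_intact(self):
        """The sipunculid pattern: nad2-cob and nad4L-nad4 exchange places as
        whole blocks; both are reported intact."""
        ref = GeneOrder(
            ["cox1", "nad2", "cob", "trnA", "nad4L", "nad4", "trnB"],
            ["+"] * 7, True,
        )
        q = GeneOrder(
            ["cox1", "nad4L", "nad4", "trnA", "nad2", "cob", "trnB"],
            ["+"] * 7, True,
        )
        blocks = syntenic_blocks(q, ref)
        assert ["nad4L", "nad4"] in blocks
        assert ["nad2", "cob"] in blocks

    def test_disjoint_label_sets_empty(self):
        a = GeneOrder(["x", "y"], ["+", "+"], True)
        b = GeneOrder(["p", "q"], ["+", "+"], True)
        assert syntenic_blocks(a, b) == []
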