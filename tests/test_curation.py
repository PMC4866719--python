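"""Start-codon assignment and stop-codon classification rules."""

import numpy as np
import pytest

from mitocomp.curation import assign_start, classify_stop, curate_genome
from mitocomp.model import GeneFeature, Mitogenome, rotate
from mitocomp.synthetic import (
    DEFAULT_STOP_PLAN,
    SimulationConfig,
    generate_genome,
    template_kinds,
    clitellate_template,
)


def _mini_genome(cds_seq: str, downstream_kind: str = "tRNA", gap: int = 0,
                 upstream_tail: str = "TAA") -> tuple[Mitogenome, GeneFeature]:
    """[tRNA 60bp | CDS | gap | downstream 60bp] on a small circle."""
    up = "G" * 57 + upstream_tail[-3:]
    spacer = "C" * gap
    down = "G" * 60
    seq = up + cds_seq + spacer + down
    a = len(up)
    b = a + len(cds_seq)
    feats = [
        GeneFeature("trnV", "tRNA", 0, 60),
        GeneFeature("nad3", "CDS", a, b),
        GeneFeature("trnW" if downstream_kind == "tRNA" else "nad4",
                    downstream_kind, b + gap, b + gap + 60),
    ]
    m = Mitogenome(id="mini", length=len(seq), sequence=seq, features=feats,
                   topology="linear")
    return m, feats[1]


class TestAssignStart:
    def test_atg_at_junction_offset_zero(self):
        m, cds = _mini_genome("ATG" + "GCA" * 20 + "TAA")
        d = assign_start(m, cds)
        assert (d.start_codon, d.start_offset) == ("ATG", 0)
        assert d.start_pos == cds.start

    def test_ttg_chosen_when_no_atg_in_window(self):
        """The alternative TTG start is accepted when no ATG occurs within
        the 10-codon window (the glossiphoniid cox3 situation)."""
        m, cds = _mini_genome("TTG" + "GCA" * 20 + "TAA")
        d = assign_start(m, cds)
        assert (d.start_codon, d.start_offset) == ("TTG", 0)

    def test_atg_preferred_over_earlier_gtg(self):
        # GTG at codon 0, ATG at codon 3: ATG wins despite being later
        body = "GTG" + "CCA" + "CCT" + "ATG" + "GCA" * 18 + "TAA"
        m, cds = _mini_genome(body)
        d = assign_start(m, cds)
        assert (d.start_codon, d.start_offset) == ("ATG", 3)

    def test_no_candidate_reports_none_with_note(self):
        m, cds = _mini_genome("CCA" * 30 + "TAA")
        d = assign_start(m, cds)
        assert d.start_codon is None
        assert any("no start codon" in n for n in d.notes)

    def test_scan_starts_after_upstream_feature(self):
        # junction codon belongs to the scan even before the annotated start
        m, cds = _mini_genome("ATG" + "GCA" * 20 + "TAA", gap=0)
        d = assign_start(m, cds, window=1)
        assert d.start_codon == "ATG"


class TestClassifyStop:
    def test_canonical_taa_before_trna(self):
        m, cds = _mini_genome("ATG" + "GAA" * 10 + "TAA")
        d = classify_stop(m, cds)
        assert (d.stop_class, d.stop_codon) == ("canonical", "TAA")

    def test_partial_t_at_abutting_trna(self):
        m, cds = _mini_genome("ATG" + "GAA" * 10 + "T")
        d = classify_stop(m, cds)
        assert (d.stop_class, d.stop_codon) == ("partial_T", "T")
        assert any("adenylation" in n for n in d.notes)

    def test_partial_ta_at_abutting_trna(self):
        m, cds = _mini_genome("ATG" + "GAA" * 10 + "TA")
        d = classify_stop(m, cds)
        assert (d.stop_class, d.stop_codon) == ("partial_TA", "TA")

    def test_partial_requires_gap_zero(self):
        m, cds = _mini_genome("ATG" + "GAA" * 10 + "T", gap=4)
        d = classify_stop(m, cds)
        assert d.stop_class == "overlap"

    def test_partial_never_before_non_trna(self):
        """A trailing T before a downstream CDS is not a partial stop."""
        m, cds = _mini_genome("ATG" + "GAA" * 10 + "T", downstream_kind="CDS")
        d = classify_stop(m, cds)
        assert d.stop_class == "overlap"

    def test_overlap_into_downstream_cds(self):
        # no stop, downstream CDS starts 6 bp before the annotated CDS end
        up = "G" * 60
        cds_seq = "ATG" + "GAA" * 10
        seq = up + cds_seq + "ATGCCACCT" + "G" * 51
        feats = [
            GeneFeature("trnV", "tRNA", 0, 60),
            GeneFeature("nad4L", "CDS", 60, 60 + len(cds_seq) + 6),
            GeneFeature("nad4", "CDS", 60 + len(cds_seq), 60 + len(cds_seq) + 60),
        ]
        m = Mitogenome(id="ov", length=len(seq), sequence=seq, features=feats,
                       topology="linear")
        d = classify_stop(m, feats[1])
        assert d.stop_class == "overlap"
        assert d.overlap_len == 6

    def test_cds_shorter_than_codon_errors(self):
        m, cds = _mini_genome("ATG" + "GAA" * 10 + "TAA")
        cds_short = GeneFeature("nad3", "CDS", cds.start, cds.start + 2)
        with pytest.raises(ValueError, match="shorter"):
            classify_stop(m, cds_short)


class TestCurateGenome:
    def test_recovers_generator_plan_exactly(self):
        """Parameter recovery: configured start codons and stop classes are
        reproduced on synthetic genomes with randomized valid plans."""
        kinds = template_kinds()
        order = clitellate_template().labels
        rng = np.random.default_rng(123)
        for trial in range(10):
            plan, starts = _random_plan(order, kinds, rng)
            cfg = SimulationConfig(seed=1000 + trial, stop_class_plan=plan,
                                   start_codon_plan=starts)
            m = generate_genome(cfg)
            got = {d.gene: (d.start_codon, d.stop_class) for d in curate_genome(m)}
            want = {g: (starts.get(g, "ATG"), plan[g]) for g in plan}
            assert got == want

    def test_all_canonical_plan_gives_13_canonical(self):
        plan = {g: "canonical" for g in DEFAULT_STOP_PLAN}
        m = generate_genome(SimulationConfig(seed=7, stop_class_plan=plan))
        decs = curate_genome(m)
        assert len(decs) == 13
        assert all(d.stop_class == "canonical" for d in decs)

    def test_empty_cds_list_gives_empty_decisions(self):
        m = Mitogenome(id="x", length=200, sequence="A" * 200,
                       features=[GeneFeature("trnD", "tRNA", 0, 60)])
        assert curate_genome(m) == []

    def test_decisions_invariant_under_rotation(self, plain_genome):
        ref = {d.gene: (d.start_codon, d.stop_class, d.overlap_len)
               for d in curate_genome(plain_genome)}
        for k in (1, 4444, 9999):
            rot = {d.gene: (d.start_codon, d.stop_class, d.overlap_len)
                   for d in curate_genome(rotate(plain_genome, k))}
            assert rot == ref


def _random_plan(order, kinds, rng):
    """Random valid stop/start plans for the template junction structure."""
    plan, starts = {}, {}
    labels = list(order)
    for i, lab in enumerate(labels):
        if kinds.get(lab) != "CDS":
            continue
        nxt = labels[(i + 1) % len(labels)]
        if kinds.get(nxt) == "tRNA":
            plan[lab] = str(rng.choice(
                ["canonical", "partial_T", "partial_TA", "overlap"],
                p=[0.4, 0.25, 0.25, 0.1],
            ))
        else:
            plan[lab] = str(rng.choice(["canonical", "overlap"], p=[0.6, 0.4]))
        starts[lab] = str(rng.choice(["ATG", "GTG", "TTG"], p=[0.6, 0.2, 0.2]))
    return plan, starts
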