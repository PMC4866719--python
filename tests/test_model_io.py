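"""Genome data model and GenBank/FASTA/TSV round trips."""

import numpy as np
import pytest

from mitocomp.gb_io import feature_table, normalize_label, read_genbank, write_genbank
from mitocomp.model import GeneFeature, Mitogenome, base_label, gene_order_of, rotate
from mitocomp.synthetic import SimulationConfig, generate_genome


class TestCoordinateConversion:
    def test_toy_record_maps_to_zero_based_half_open(self, toy_genbank):
        m = read_genbank(toy_genbank)
        spans = [(f.label, f.start, f.end) for f in m.features]
        assert spans == [
            ("cox1", 0, 1536),
            ("trnD", 1536, 1600),
            ("atp8", 1600, 1759),
            ("pCR", 1759, 1900),
        ]
        assert m.topology == "circular"
        assert m.length == 1900

    def test_join_location_becomes_wraps_origin(self, tmp_path, toy_genbank):
        text = toy_genbank.read_text().replace(
            "     D-loop          1760..1900",
            "     tRNA            join(1840..1900,1..5)\n"
            '                     /gene="tRNA-His"',
        )
        p = tmp_path / "wrap.gb"
        p.write_text(text)
        m = read_genbank(p)
        f = next(f for f in m.features if f.label == "trnH")
        assert f.wraps_origin
        assert (f.start, f.end) == (1839, 5)
        assert f.span_length(m.length) == 66

    def test_unknown_label_kept_as_noncoding_with_warning(self, tmp_path, toy_genbank):
        text = toy_genbank.read_text().replace('/gene="ATP8"', '/gene="mystery9"')
        p = tmp_path / "unk.gb"
        p.write_text(text)
        with pytest.warns(UserWarning, match="mystery9"):
            m = read_genbank(p)
        f = next(f for f in m.features if f.start == 1600)
        assert f.kind == "noncoding"
        assert f.source_label == "mystery9"


class TestRoundTrip:
    def test_genbank_round_trip_is_lossless(self, tmp_path):
        """label/kind/coords/strand/anticodon survive write+read, 25 genomes."""
        for seed in range(25):
            m = generate_genome(SimulationConfig(seed=seed, genome_id=f"rt{seed}"))
            p = tmp_path / f"{seed}.gb"
            write_genbank(m, p)
            m2 = read_genbank(p)
            key = lambda g: [
                (f.label, f.kind, f.start, f.end, f.strand, f.anticodon) for f in g.features
            ]
            assert key(m) == key(m2)
            assert m2.sequence == m.sequence
            assert m2.topology == "circular"

    def test_wrapped_feature_round_trips_via_join(self, tmp_path, plain_genome):
        m = rotate(plain_genome, plain_genome.features[0].end - 10)
        assert any(f.wraps_origin for f in m.features)
        p = tmp_path / "wrap.gb"
        write_genbank(m, p)
        m2 = read_genbank(p)
        w1 = [(f.label, f.start, f.end) for f in m.features if f.wraps_origin]
        w2 = [(f.label, f.start, f.end) for f in m2.features if f.wraps_origin]
        assert w1 == w2

    def test_empty_feature_list_still_valid_file(self, tmp_path):
        m = Mitogenome(id="empty", length=100, sequence="A" * 100)
        p = tmp_path / "e.gb"
        write_genbank(m, p)
        assert read_genbank(p).features == []


class TestLabels:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("COX1", "cox1"), ("COI", "cox1"), ("cox1", "cox1"),
            ("CYTB", "cob"), ("cob", "cob"), ("ND4L", "nad4L"),
            ("tRNA-Asp", "trnD"), ("trnd", "trnD"), ("12S rRNA", "rrnS"),
            ("16S", "rrnL"), ("control region", "pCR"),
        ],
    )
    def test_synonym_normalization(self, raw, expected):
        assert normalize_label(raw) == expected

    def test_leu_ser_paralogs_resolved_by_anticodon(self):
        assert normalize_label("tRNA-Leu", anticodon="TAG") == "trnL1"
        assert normalize_label("tRNA-Leu", anticodon="TAA") == "trnL2"
        assert normalize_label("tRNA-Ser", anticodon="TCT") == "trnS1"
        assert normalize_label("tRNA-Ser", anticodon="TGA") == "trnS2"

    def test_duplicate_isotypes_suffixed_in_coordinate_order(self, lamothei_genome):
        labels = [f.label for f in lamothei_genome.features if f.base == "trnD"]
        assert labels == ["trnD", "trnD2"]
        assert base_label("trnD2") == "trnD"
        assert base_label("trnL2") == "trnL2"  # canonical paralog, not a copy


class TestModelInvariants:
    def test_validation_rejects_bad_coordinates(self):
        m = Mitogenome(id="x", length=100)
        m.features.append(GeneFeature("cox1", "CDS", 50, 40))
        with pytest.raises(ValueError, match="coordinates"):
            m.validate()

    def test_at_most_one_control_region(self):
        m = Mitogenome(id="x", length=1000)
        m.features = [
            GeneFeature("pCR", "control_region", 0, 100),
            GeneFeature("pCR", "control_region", 200, 300),
        ]
        with pytest.raises(ValueError, match="control_region"):
            m.validate()

    def test_trna_length_window_enforced(self):
        m = Mitogenome(id="x", length=1000)
        m.features = [GeneFeature("trnD", "tRNA", 0, 40)]
        with pytest.raises(ValueError, match="50-90"):
            m.validate()

    def test_clitellate_checker_passes_synthetic(self, plain_genome):
        assert plain_genome.check_clitellate() == []


class TestGeneOrder:
    def test_gene_order_of_toy(self, toy_genbank):
        m = read_genbank(toy_genbank)
        assert gene_order_of(m, include_rna=True).labels == ["cox1", "trnD", "atp8", "pCR"]
        assert gene_order_of(m, include_rna=False).labels == ["cox1", "atp8"]

    def test_gene_order_invariant_under_rotation(self, plain_genome):
        base = gene_order_of(plain_genome).labels
        rng = np.random.default_rng(0)
        for _ in range(5):
            k = int(rng.integers(1, plain_genome.length))
            rot = gene_order_of(rotate(plain_genome, k)).labels
            assert len(rot) == len(base)
            i = rot.index("cox1")
            assert rot[i:] + rot[:i] == base[base.index("cox1"):] + base[:base.index("cox1")]

    def test_wrap_origin_gene_listed_once_first(self, plain_genome):
        m = rotate(plain_genome, plain_genome.features[0].end - 10)
        wrapped = next(f for f in m.features if f.wraps_origin)
        order = gene_order_of(m)
        assert order.labels[0] == wrapped.base
        assert order.labels.count(wrapped.base) == 1

    def test_feature_table_export(self, toy_genbank):
        tsv = feature_table(read_genbank(toy_genbank))
        lines = tsv.strip().split("\n")
        assert lines[0].split("\t") == [
            "id", "label", "kind", "start", "end", "strand", "anticodon"
        ]
        assert len(lines) == 5
        assert "trnD\ttRNA\t1536\t1600\t+\tGTC" in tsv
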