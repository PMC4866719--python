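import pytest

from mitocomp.synthetic import (
    SimulationConfig,
    generate_genome,
    placobdella_like_config,
    clitellate_template,
)


@pytest.fixture(scope="session")
def template():
    return clitellate_template()


@pytest.fixture(scope="session")
def plain_genome():
    """Default synthetic clitellate genome (seed 1)."""
    return generate_genome(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def lamothei_genome():
    """Placobdella-lamothei-like genome: duplicated trnD with a 128 bp
    spacer and a GTC->ATC anticodon shift, TTG cox3, GTG nad1."""
    return generate_genome(placobdella_like_config(seed=3, species="lamothei"))


@pytest.fixture(scope="session")
def parasitica_genome():
    """Placobdella-parasitica-like genome: directly abutting identical
    trnD copies."""
    return generate_genome(placobdella_like_config(seed=4, species="parasitica"))


@pytest.fixture()
def toy_genbank(tmp_path):
    """Hand-written 4-feature GenBank toy record, 1900 bp."""
    seq = ("atgc" * 475)
    lines = [
        "LOCUS       TOY00001                1900 bp    DNA     circular INV 01-JAN-2000",
        "DEFINITION  toy record.",
        "ACCESSION   TOY00001",
        "VERSION     TOY00001.1",
        "FEATURES             Location/Qualifiers",
        "     source          1..1900",
        '                     /organism="toy"',
        "     CDS             1..1536",
        '                     /gene="COX1"',
        "     tRNA            1537..1600",
        '                     /gene="tRNA-Asp"',
        '                     /anticodon="(seq:gtc)"',
        "     CDS             1601..1759",
        '                     /gene="ATP8"',
        "     D-loop          1760..1900",
        "ORIGIN",
    ]
    for i in range(0, 1900, 60):
        chunk = seq[i:i + 60]
        parts = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {parts}")
    lines.append("//")
    p = tmp_path / "toy.gb"
    p.write_text("\n".join(lines) + "\n")
    return p
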