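"""GenBank / FASTA / TSV input-output for annotated mitogenomes.

GenBank flat files use 1-based inclusive coordinates; internally everything
is 0-based half-open. Gene labels are normalized through a user-extensible
synonym table (GenBank annotation vocabularies are notoriously inconsistent);
a second copy of a tRNA isotype is suffixed (``trnD``, ``trnD2``) in
coordinate order. Leu/Ser paralogs are disambiguated by anticodon when one is
annotated (trnL1 decodes with tag, trnL2 with taa; trnS1 tct, trnS2 tga),
otherwise by their order relative to the reference template.
"""

from __future__ import annotations

import csv
import re
import warnings
from importlib import resources
from io import StringIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from mitocomp.model import (
    GeneFeature,
    LS_PARALOG_BY_ANTICODON,
    Mitogenome,
    TRNA_LABELS,
    base_label,
    copy_label,
)

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}

_KIND_TO_GB = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "control_region": "D-loop",
    "noncoding": "misc_feature",
}
_GB_TO_KIND = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "control_region",
    "misc_feature": "noncoding",
}


def _load_synonyms() -> dict[str, str]:
    table = {}
    text = resources.files("mitocomp.data").joinpath("gene_synonyms.tsv").read_text()
    for row in csv.DictReader(StringIO(text), delimiter="\t"):
        table[row["synonym"].lower()] = row["canonical"]
    return table


_SYNONYMS = _load_synonyms()


def add_synonym(synonym: str, canonical: str) -> None:
    """Extend the gene-name synonym table at run time."""
    _SYNONYMS[synonym.lower()] = canonical


def normalize_label(raw: str, anticodon: str | None = None) -> str | None:
    """Map an annotation label to the controlled vocabulary.

    Returns None when the label is unrecognized. tRNA names such as
    ``tRNA-Asp`` map to ``trnD``; Leu/Ser need an anticodon (or an explicit
    trnL1/trnL2-style name) to resolve the paralog.
    """
    if raw is None:
        return None
    s = raw.strip()
    low = s.lower().replace("_", " ").replace("  ", " ")
    if low in _SYNONYMS:
        return _SYNONYMS[low]
    m = re.fullmatch(r"trn([a-z])([12])?(?:\s*\d+)?", low)
    if m:
        letter = m.group(1).upper()
        suffix = m.group(2) or ""
        cand = f"trn{letter}{suffix}"
        if cand in TRNA_LABELS:
            return cand
        if f"trn{letter}" in TRNA_LABELS:
            return f"trn{letter}"
    m = re.fullmatch(r"trna[- ]?([a-z]{3})\s*(?:\(([a-z]{3})\))?", low)
    if m:
        aa = _AA3_TO_1.get(m.group(1))
        if aa is None:
            return None
        if aa in ("L", "S"):
            anti = (m.group(2) or anticodon or "").lower()
            label = LS_PARALOG_BY_ANTICODON.get(anti)
            return label  # None when paralog cannot be resolved yet
        cand = f"trn{aa}"
        return cand if cand in TRNA_LABELS else None
    return None


def _extract_anticodon(quals: dict) -> str | None:
    for key in ("anticodon", "note"):
        for val in quals.get(key, []):
            m = re.search(r"seq\s*:\s*([acgtACGT]{3})", val)
            if m:
                return m.group(1).upper()
            m = re.fullmatch(r"\s*([acgtACGT]{3})\s*", val)
            if m and key == "anticodon":
                return m.group(1).upper()
    return None


def read_genbank(path) -> Mitogenome:
    """Read one GenBank record into a :class:`Mitogenome`."""
    try:
        record = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise ValueError(f"malformed GenBank file {path}: {exc}") from exc
    topology = record.annotations.get("topology", "linear")
    length = len(record.seq) if len(record.seq) else None
    sequence = str(record.seq) if length else None
    if length is None:
        # ORIGIN omitted; fall back to the largest coordinate
        length = max((int(f.location.end) for f in record.features), default=0)
        sequence = None

    feats: list[GeneFeature] = []
    for f in record.features:
        if f.type == "source":
            continue
        kind = _GB_TO_KIND.get(f.type)
        if kind is None:
            continue
        quals = f.qualifiers
        raw = (quals.get("gene") or quals.get("product") or quals.get("note") or [None])[0]
        anticodon = _extract_anticodon(quals)
        strand = "-" if f.location.strand == -1 else "+"
        parts = sorted(f.location.parts, key=lambda p: int(p.start))
        wraps = len(parts) > 1 and int(parts[0].start) == 0 and int(parts[-1].end) == length
        if wraps:
            start = int(parts[-1].start)
            end = int(parts[0].end)
        else:
            start = int(f.location.start)
            end = int(f.location.end)

        label = normalize_label(raw, anticodon=anticodon)
        source_label = None
        if label is None and kind == "tRNA" and anticodon:
            label = LS_PARALOG_BY_ANTICODON.get(anticodon.lower())
        if label is None and kind == "tRNA":
            aa = _unresolved_ls_aa(raw)
            if aa is not None:
                label = f"?{aa}"  # Leu/Ser paralog resolved in a post-pass
        if label is None:
            if kind == "control_region":
                label = "pCR"
            elif raw is not None and kind != "noncoding":
                warnings.warn(f"unknown gene label {raw!r}; keeping as noncoding")
                kind, label, source_label = "noncoding", "noncoding", raw
            else:
                label, source_label = "noncoding", raw
        feats.append(
            GeneFeature(
                label=label, kind=kind, start=start, end=end, strand=strand,
                anticodon=anticodon, wraps_origin=wraps, source_label=source_label,
            )
        )

    _resolve_ls_paralogs(feats)
    _suffix_duplicates(feats)
    return Mitogenome(
        id=record.id or record.name,
        length=length,
        taxon=record.annotations.get("organism", ""),
        topology="circular" if topology == "circular" else "linear",
        sequence=sequence,
        features=feats,
    )


def _unresolved_ls_aa(raw: str | None) -> str | None:
    if raw is None:
        return None
    m = re.fullmatch(r"trna[- ]?(leu|ser)", raw.strip().lower())
    if m:
        return m.group(1)[0].upper()
    m = re.fullmatch(r"trn([ls])", raw.strip().lower())
    if m:
        return m.group(1).upper()
    return None


# paralog order as they occur around the reference clitellate template
_LS_TEMPLATE_ORDER = {"L": ["trnL2", "trnL1"], "S": ["trnS2", "trnS1"]}


def _resolve_ls_paralogs(feats: list[GeneFeature]) -> None:
    """Assign trnL1/trnL2 (trnS1/trnS2) to Leu/Ser tRNAs lacking an anticodon,
    by coordinate order following the reference template's paralog order."""
    for aa in ("L", "S"):
        pending = sorted(
            (f for f in feats if f.label == f"?{aa}"), key=lambda f: f.start
        )
        if not pending:
            continue
        taken = {f.label for f in feats}
        names = [n for n in _LS_TEMPLATE_ORDER[aa] if n not in taken]
        for f in pending:
            f.label = names.pop(0) if names else _LS_TEMPLATE_ORDER[aa][-1]


def _suffix_duplicates(feats: list[GeneFeature]) -> None:
    """Suffix repeated isotypes (trnD, trnD2, ...) in coordinate order."""
    feats.sort(key=lambda f: (f.start, f.end))
    seen: dict[str, int] = {}
    for f in feats:
        if f.label == "noncoding":
            continue
        b = base_label(f.label)
        seen[b] = seen.get(b, 0) + 1
        f.label = copy_label(b, seen[b])


def write_genbank(m: Mitogenome, path, include_sequence: bool = True) -> None:
    """Write a Mitogenome as a GenBank flat file re-readable by read_genbank."""
    if include_sequence and m.sequence is None:
        raise ValueError("genome has no sequence; pass include_sequence=False")
    seq = Seq(m.sequence if m.sequence is not None else "N" * m.length)
    record = SeqRecord(seq, id=m.id, name=m.id[:16].replace(" ", "_"), description=m.taxon)
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = m.topology
    record.annotations["organism"] = m.taxon
    for f in m.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps_origin:
            loc = CompoundLocation(
                [SimpleLocation(f.start, m.length, strand), SimpleLocation(0, f.end, strand)]
            )
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        quals: dict[str, list[str]] = {"gene": [f.label]}
        if f.anticodon:
            quals["anticodon"] = [f"(seq:{f.anticodon.lower()})"]
        if f.source_label:
            quals["note"] = [f.source_label]
        record.features.append(SeqFeature(loc, type=_KIND_TO_GB[f.kind], qualifiers=quals))
    SeqIO.write(record, path, "genbank")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file."""
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]


def write_fasta(m: Mitogenome, path) -> None:
    if m.sequence is None:
        raise ValueError("genome has no sequence")
    rec = SeqRecord(Seq(m.sequence), id=m.id, description=m.taxon)
    SeqIO.write(rec, path, "fasta")


def feature_table(m: Mitogenome) -> str:
    """TSV feature-table export (id, label, kind, start, end, strand, anticodon)."""
    out = ["id\tlabel\tkind\tstart\tend\tstrand\tanticodon"]
    for f in m.features:
        out.append(
            f"{m.id}\t{f.label}\t{f.kind}\t{f.start}\t{f.end}\t{f.strand}\t"
            f"{f.anticodon or ''}"
        )
    return "\n".join(out) + "\n"
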