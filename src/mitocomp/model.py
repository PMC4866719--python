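"""Data model for annotated mitochondrial genomes.

Coordinates are 0-based half-open internally; GenBank I/O converts from the
1-based inclusive interchange convention. A feature that spans the origin of
a circular genome is stored contiguously with ``wraps_origin=True`` (its
``start`` lies near the end of the sequence and its ``end`` near the
beginning), so span arithmetic is done modulo the genome length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

# the 13 mitochondrial protein-coding genes
PCG_LABELS = frozenset({
    "cox1", "cox2", "cox3", "cob", "atp6", "atp8",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
})

RRNA_LABELS = frozenset({"rrnS", "rrnL"})

# 22 tRNAs of the metazoan mitogenome; Leu and Ser occur as two paralogs each
TRNA_LABELS = frozenset(
    {"trn" + aa for aa in "ACDEFGHIKMNPQRTVWY"} | {"trnL1", "trnL2", "trnS1", "trnS2"}
)

# anticodon (DNA alphabet) -> Leu/Ser paralog name
LS_PARALOG_BY_ANTICODON = {"tag": "trnL1", "taa": "trnL2", "tct": "trnS1", "tga": "trnS2"}

CONTROLLED_LABELS = PCG_LABELS | RRNA_LABELS | TRNA_LABELS | {"pCR", "noncoding"}

VALID_KINDS = ("CDS", "tRNA", "rRNA", "control_region", "noncoding")

def base_label(label: str) -> str:
    """Strip a duplicate-copy suffix, returning the base isotype label.

    ``trnD2`` -> ``trnD`` but ``trnL1``/``trnS2`` (canonical paralogs) are kept;
    their duplicates use an underscore (``trnL1_2`` -> ``trnL1``). Non-tRNA
    labels are returned unchanged (``cox1`` is a name, not a copy).
    """
    if label in CONTROLLED_LABELS:
        return label
    m = re.match(r"^(trn(?:[A-Z]|L1|L2|S1|S2))(?:_?\d+)$", label)
    if m and m.group(1) in TRNA_LABELS:
        return m.group(1)
    m = re.match(r"^(.*?)_\d+$", label)
    if m and m.group(1) in CONTROLLED_LABELS:
        return m.group(1)
    return label


def copy_label(base: str, index: int) -> str:
    """Label for the ``index``-th copy (1-based) of an isotype."""
    if index == 1:
        return base
    sep = "_" if base in {"trnL1", "trnL2", "trnS1", "trnS2"} else ""
    return f"{base}{sep}{index}"


@dataclass
class GeneFeature:
    """One typed gene feature on a mitogenome."""

    label: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    anticodon: str | None = None
    wraps_origin: bool = False
    source_label: str | None = None  # original text when label was unrecognized

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.anticodon is not None and not re.fullmatch(r"[ACGT]{3}", self.anticodon.upper()):
            raise ValueError(f"anticodon must match [ACGT]{{3}}, got {self.anticodon!r}")

    @property
    def base(self) -> str:
        return base_label(self.label)

    def span_length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return genome_length - self.start + self.end
        return self.end - self.start

    def positions(self, genome_length: int) -> range | list[int]:
        if self.wraps_origin:
            return list(range(self.start, genome_length)) + list(range(self.end))
        return range(self.start, self.end)


@dataclass
class Mitogenome:
    """An annotated (optionally sequence-bearing) mitochondrial genome."""

    id: str
    length: int
    taxon: str = ""
    topology: str = "circular"
    sequence: str | None = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"topology must be circular or linear, got {self.topology!r}")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != declared length {self.length}"
                )
        self.sort_features()

    def sort_features(self) -> None:
        self.features.sort(key=lambda f: (f.start, f.end))

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise ValueError on any structural invariant violation."""
        n_cr = 0
        for f in self.features:
            if f.base not in CONTROLLED_LABELS:
                raise ValueError(f"label {f.label!r} not in controlled vocabulary")
            if f.kind == "control_region":
                n_cr += 1
            if f.wraps_origin:
                if self.topology != "circular":
                    raise ValueError(f"{f.label}: wraps_origin on a linear genome")
                if not (0 <= f.end <= f.start < self.length):
                    raise ValueError(f"{f.label}: bad wrapped coordinates {f.start}..{f.end}")
            else:
                if not (0 <= f.start < f.end <= self.length):
                    raise ValueError(f"{f.label}: bad coordinates {f.start}..{f.end}")
            if f.kind == "tRNA" and not 50 <= f.span_length(self.length) <= 90:
                raise ValueError(
                    f"{f.label}: tRNA length {f.span_length(self.length)} outside 50-90"
                )
        if n_cr > 1:
            raise ValueError(f"{n_cr} control_region features; at most one allowed")

    def check_clitellate(self) -> list[str]:
        """Check the 37-gene single-strand property; return list of problems."""
        problems = []
        genes = [f for f in self.features if f.kind in ("CDS", "tRNA", "rRNA")]
        if len(genes) < 37:
            problems.append(f"only {len(genes)} genes, expected >=37")
        kinds = {"CDS": 0, "tRNA": 0, "rRNA": 0}
        for f in genes:
            kinds[f.kind] += 1
        if kinds["CDS"] != 13:
            problems.append(f"{kinds['CDS']} protein-coding genes, expected 13")
        if kinds["tRNA"] < 22:
            problems.append(f"{kinds['tRNA']} tRNA genes, expected >=22")
        if kinds["rRNA"] != 2:
            problems.append(f"{kinds['rRNA']} rRNA genes, expected 2")
        strands = {f.strand for f in genes}
        if len(strands) > 1:
            problems.append("genes on both strands; clitellate mitogenomes are single-strand")
        return problems

    # -- sequence access ----------------------------------------------------

    def feature_sequence(self, f: GeneFeature) -> str:
        if self.sequence is None:
            raise ValueError("genome carries no sequence")
        if f.wraps_origin:
            seq = self.sequence[f.start:] + self.sequence[: f.end]
        else:
            seq = self.sequence[f.start: f.end]
        if f.strand == "-":
            seq = revcomp(seq)
        return seq

    def base_at(self, pos: int) -> str:
        if self.sequence is None:
            raise ValueError("genome carries no sequence")
        return self.sequence[pos % self.length]

    # -- neighbours on the circle -------------------------------------------

    def gene_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind in ("CDS", "tRNA", "rRNA")]

    def upstream_feature(self, f: GeneFeature) -> GeneFeature | None:
        """The previous gene feature in annotation order (cyclic for circular
        genomes). Annotation order, not gap size, so overlapping neighbours
        (nad4L/nad4) resolve correctly."""
        return self._neighbor(f, direction=-1)

    def downstream_feature(self, f: GeneFeature) -> GeneFeature | None:
        """The next gene feature in annotation order (cyclic)."""
        return self._neighbor(f, direction=+1)

    def _neighbor(self, f: GeneFeature, direction: int) -> GeneFeature | None:
        genes = sorted(self.gene_features(), key=lambda g: (g.start, g.end))
        if f not in genes:
            genes = sorted(genes + [f], key=lambda g: (g.start, g.end))
        if len(genes) < 2:
            return None
        i = next(k for k, g in enumerate(genes) if g is f)
        j = i + direction
        if self.topology == "circular":
            return genes[j % len(genes)]
        return genes[j] if 0 <= j < len(genes) else None


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTRYKMBDHVN", "TGCAYRMKVHDBN"))[::-1]


def rotate(m: Mitogenome, offset: int) -> Mitogenome:
    """Rotate a circular genome so old position ``offset`` becomes position 0."""
    if m.topology != "circular":
        raise ValueError("can only rotate a circular genome")
    L = m.length
    offset %= L
    seq = None
    if m.sequence is not None:
        seq = m.sequence[offset:] + m.sequence[:offset]
    feats = []
    for f in m.features:
        start = (f.start - offset) % L
        span = f.span_length(L)
        end = start + span
        if end <= L:
            feats.append(replace(f, start=start, end=end, wraps_origin=False))
        else:
            feats.append(replace(f, start=start, end=end - L, wraps_origin=True))
    return Mitogenome(
        id=m.id, length=L, taxon=m.taxon, topology=m.topology, sequence=seq, features=feats
    )


def gene_order_of(m: Mitogenome, include_rna: bool = True):
    """Circular ordered list of gene labels and strands, from position 0.

    With ``include_rna=False`` only the 13 protein-coding genes are kept.
    Labels are reported as base isotypes (both copies of a duplicated tRNA
    appear under the same name, as in a gene-order diagram).
    """
    from mitocomp.gene_order import GeneOrder

    feats = [f for f in m.features if f.kind != "noncoding"]
    if include_rna:
        keep = feats
    else:
        keep = [f for f in feats if f.base in PCG_LABELS]
    if not keep:
        raise ValueError("genome has no gene features")
    # a wrap-origin feature sorts by its (high) start; list it once, first
    wrapped = [f for f in keep if f.wraps_origin]
    plain = [f for f in keep if not f.wraps_origin]
    ordered = wrapped + plain
    return GeneOrder(
        labels=[f.base for f in ordered],
        strands=[f.strand for f in ordered],
        circular=m.topology == "circular",
    )
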