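"""Codon counting and codon-usage statistics under the invertebrate
mitochondrial genetic code.

The motivating question: when a tRNA gene is duplicated and one copy's
anticodon mutates (trnD GUC -> AUC, switching affinity from GAC to GAT), does
the genome's usage of the two synonymous aspartate codons shift? The tools
here count codons per genome, build the per-genome GAC/GAT contingency table,
test it with the exact conditional R x 2 test, and search for the largest
groups of genomes whose aspartate codon usage is statistically homogeneous.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from io import StringIO
from typing import Iterable, Sequence

from Bio.Data import CodonTable

from mitocomp.curation import CurationDecision, curate_genome
from mitocomp.exact_tests import fisher_exact_rx2
from mitocomp.model import Mitogenome

INVERTEBRATE_MITO_TABLE = 5


@dataclass
class CodonCounts:
    """Per-genome codon counts, keyed amino acid -> codon -> count."""

    genome_id: str
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    stop_counts: dict[str, int] = field(default_factory=dict)
    code_table: int = INVERTEBRATE_MITO_TABLE

    def add(self, codon: str, aa: str) -> None:
        self.counts.setdefault(aa, {}).setdefault(codon, 0)
        self.counts[aa][codon] += 1

    def total(self) -> int:
        return sum(c for by_codon in self.counts.values() for c in by_codon.values())

    def aa_count(self, aa: str) -> int:
        return sum(self.counts.get(aa, {}).values())

    def codon_count(self, codon: str) -> int:
        for by_codon in self.counts.values():
            if codon in by_codon:
                return by_codon[codon]
        return 0


def count_codons(
    m: Mitogenome,
    decisions: Sequence[CurationDecision] | None = None,
    code_table: int = INVERTEBRATE_MITO_TABLE,
) -> CodonCounts:
    """Count in-frame codons over all CDSs of a genome.

    Reading starts at the curated start position (decisions are computed on
    the fly when not supplied); an incomplete terminal T/TA is excluded by
    construction and stop codons are tallied separately.
    """
    if m.sequence is None:
        raise ValueError("genome carries no sequence")
    try:
        table = CodonTable.unambiguous_dna_by_id[code_table]
    except KeyError as exc:
        raise ValueError(f"unknown genetic code table {code_table}") from exc
    if decisions is None:
        decisions = curate_genome(m)
    by_gene = {d.gene: d for d in decisions}

    out = CodonCounts(genome_id=m.id, code_table=code_table)
    for f in m.features:
        if f.kind != "CDS":
            continue
        span = f.span_length(m.length)
        if span < 3:
            raise ValueError(f"{f.label}: CDS shorter than one codon")
        seq = m.feature_sequence(f)
        dec = by_gene.get(f.label)
        if dec is not None and dec.start_pos is not None:
            offset = (dec.start_pos - f.start) % m.length
            if 0 < offset < span:
                seq = seq[offset:]
        n = len(seq) // 3
        for k in range(n):
            codon = seq[3 * k: 3 * k + 3]
            if codon in table.stop_codons:
                out.stop_counts[codon] = out.stop_counts.get(codon, 0) + 1
            else:
                aa = table.forward_table.get(codon)
                if aa is not None:
                    out.add(codon, aa)
    return out


@dataclass
class AspContingencyTable:
    """R x 2 table of GAC/GAT counts per genome (one row per genome)."""

    row_labels: list[str]
    a: list[int]  # GAC
    b: list[int]  # GAT
    groups: list[str] | None = None

    def __post_init__(self) -> None:
        if not (len(self.row_labels) == len(self.a) == len(self.b)):
            raise ValueError("row_labels, a and b must have equal length")
        if len(self.a) < 2:
            raise ValueError("need at least 2 rows")
        if any(x < 0 for x in self.a) or any(x < 0 for x in self.b):
            raise ValueError("counts must be nonnegative")

    @property
    def r(self) -> list[int]:
        return [x + y for x, y in zip(self.a, self.b)]

    @property
    def c1(self) -> int:
        return sum(self.a)

    @property
    def c2(self) -> int:
        return sum(self.b)

    @property
    def n(self) -> int:
        return self.c1 + self.c2

    def rows(self) -> list[tuple[int, int]]:
        return list(zip(self.a, self.b))

    def subset(self, labels: Iterable[str]) -> "AspContingencyTable":
        labels = list(labels)
        idx = [self.row_labels.index(l) for l in labels]
        return AspContingencyTable(
            row_labels=labels,
            a=[self.a[i] for i in idx],
            b=[self.b[i] for i in idx],
            groups=[self.groups[i] for i in idx] if self.groups else None,
        )


def asp_table(counts: Sequence[CodonCounts]) -> AspContingencyTable:
    """Build the aspartate GAC/GAT contingency table from per-genome counts."""
    if len(counts) < 2:
        raise ValueError("need counts for at least 2 genomes")
    return AspContingencyTable(
        row_labels=[c.genome_id for c in counts],
        a=[c.codon_count("GAC") for c in counts],
        b=[c.codon_count("GAT") for c in counts],
    )


def load_clitellata_asp_table() -> AspContingencyTable:
    """The published aspartate codon-usage counts for nine clitellate
    mitogenomes (five oligochaetes, four leeches), shipped as package data."""
    text = resources.files("mitocomp.data").joinpath(
        "clitellata_asp_codon_usage.tsv"
    ).read_text()
    labels, groups, a, b = [], [], [], []
    for row in csv.DictReader(StringIO(text), delimiter="\t"):
        labels.append(row["organism"])
        groups.append(row["group"])
        a.append(int(row["gac"]))
        b.append(int(row["gat"]))
    return AspContingencyTable(row_labels=labels, a=a, b=b, groups=groups)


def gac_gat_ratio(a: int, b: int) -> float | None:
    """GAC/GAT ratio rounded half-up to 2 decimals; None when undefined (b=0)."""
    if b == 0:
        return None
    q = Decimal(a) / Decimal(b)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def aa_frequencies(counts: CodonCounts) -> dict[str, float]:
    """Amino-acid frequency vector (stop codons excluded); sums to 1."""
    total = counts.total()
    if total == 0:
        raise ValueError("no codons counted")
    return {aa: counts.aa_count(aa) / total for aa in sorted(counts.counts)}


@dataclass
class SubgroupResult:
    """Maximal homogeneous row subsets of a contingency table."""

    groups: list[tuple[tuple[str, ...], float]]
    alpha: float

    def labels(self) -> list[tuple[str, ...]]:
        return [g for g, _ in self.groups]


def homogeneous_subgroups(
    t: AspContingencyTable, alpha: float = 0.05
) -> SubgroupResult:
    """Progressively remove rows to find all maximal homogeneous subsets.

    Enumerates row subsets of size >= 2 in decreasing size; a subset is
    homogeneous iff its exact R x 2 p-value exceeds ``alpha``. Only maximal
    homogeneous subsets are reported (every strict superset is significant);
    subsets contained in an already-accepted group are skipped, which keeps
    the search well inside the claimed budget.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if len(t.a) < 3:
        raise ValueError("need at least 3 rows to search for subgroups")
    labels = t.row_labels
    found: list[tuple[tuple[str, ...], float]] = []
    for size in range(len(labels), 1, -1):
        for combo in itertools.combinations(range(len(labels)), size):
            names = tuple(labels[i] for i in combo)
            if any(set(names) <= set(g) for g, _ in found):
                continue
            p = fisher_exact_rx2([(t.a[i], t.b[i]) for i in combo])
            if p > alpha:
                found.append((names, p))
    return SubgroupResult(groups=found, alpha=alpha)


def augment_pvalue(
    t: AspContingencyTable, group: Iterable[str], extra: str
) -> float:
    """Exact p-value for a named candidate group plus one named row."""
    sub = t.subset(list(group) + [extra])
    return fisher_exact_rx2(sub.rows())


def codon_usage_report(counts: Sequence[CodonCounts]) -> str:
    """TSV: per genome, aspartate GAC/GAT counts and ratio."""
    out = ["genome\tgac\tgat\tratio_gac_gat"]
    for c in counts:
        a, b = c.codon_count("GAC"), c.codon_count("GAT")
        r = gac_gat_ratio(a, b)
        out.append(f"{c.genome_id}\t{a}\t{b}\t{'undefined' if r is None else f'{r:.2f}'}")
    return "\n".join(out) + "\n"
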