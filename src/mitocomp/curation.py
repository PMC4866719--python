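"""Start-codon assignment and stop-codon classification for mitochondrial CDSs.

Mitochondrial protein genes are packed: starts are recognized as the first
plausible initiation triplet immediately following the 3' end of the upstream
gene, and stops are frequently incomplete (a bare T or TA at a tRNA junction,
completed to TAA by post-transcriptional 3' adenylation of the mRNA). When
neither a canonical nor a partial stop fits, the gene is recorded as
overlapping its downstream neighbour (the classic nad4L/nad4 arrangement).

Rules implemented:

* start: scan in-frame triplets from the first base after the upstream
  feature's 3' end (or from the annotated start, if the upstream feature
  overlaps it), over a window of ``window`` codons; the first candidate from
  the start set wins, except that ATG anywhere in the window is preferred
  over a non-ATG candidate.
* stop: (1) a final in-frame TAA/TAG that does not overlap a tRNA is
  canonical; (2) a trailing in-frame T or TA directly abutting a downstream
  tRNA (gap 0) is a partial stop; (3) otherwise the CDS is classified as
  overlapping, with the overlap length recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from mitocomp.model import GeneFeature, Mitogenome

DEFAULT_START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG")


@dataclass
class CurationDecision:
    gene: str
    start_codon: str | None = None
    start_pos: int | None = None
    start_offset: int | None = None  # codons downstream of the junction
    stop_class: str | None = None  # canonical | partial_TA | partial_T | overlap
    stop_codon: str | None = None
    overlap_len: int = 0
    notes: list[str] = field(default_factory=list)


def _signed_distance(a: int, b: int, length: int) -> int:
    """Signed circular distance from a to b, wrapped into (-L/2, L/2]."""
    return (b - a + length // 2) % length - length // 2


def _circular_slice(seq: str, start: int, n: int) -> str:
    L = len(seq)
    start %= L
    if start + n <= L:
        return seq[start: start + n]
    return seq[start:] + seq[: (start + n) % L]


def assign_start(
    m: Mitogenome,
    cds: GeneFeature,
    window: int = 10,
    candidates: tuple[str, ...] = DEFAULT_START_CODONS,
) -> CurationDecision:
    """Choose a start codon for ``cds`` by scanning from the upstream junction."""
    if m.sequence is None:
        raise ValueError("genome carries no sequence")
    if cds.strand != "+":
        raise ValueError(
            "curation assumes plus-strand genes (single-strand mitogenomes)"
        )
    dec = CurationDecision(gene=cds.label)
    upstream = m.upstream_feature(cds)
    origin = cds.start
    if upstream is not None:
        up_end = upstream.end % m.length if upstream.wraps_origin else upstream.end
        d = _signed_distance(up_end % m.length, cds.start, m.length)
        if d >= 0:
            # clean junction: scan begins right after the upstream 3' end
            origin = (cds.start - d) % m.length
        else:
            dec.notes.append(
                f"upstream {upstream.label} ends inside the CDS; scanning from the annotated start"
            )
    found: list[tuple[int, str]] = []
    for k in range(window):
        triplet = _circular_slice(m.sequence, origin + 3 * k, 3)
        if triplet in candidates:
            found.append((k, triplet))
    choice = None
    for k, t in found:
        if t == "ATG":
            choice = (k, t)
            break
    if choice is None and found:
        choice = found[0]
    if choice is None:
        dec.start_codon = None
        dec.notes.append(f"no start codon in {window}-codon window after the junction")
    else:
        k, t = choice
        dec.start_codon = t
        dec.start_offset = k
        dec.start_pos = (origin + 3 * k) % m.length
    return dec


def classify_stop(m: Mitogenome, cds: GeneFeature) -> CurationDecision:
    """Classify the CDS 3' end as canonical / partial_TA / partial_T / overlap."""
    if m.sequence is None:
        raise ValueError("genome carries no sequence")
    if cds.strand != "+":
        raise ValueError(
            "curation assumes plus-strand genes (single-strand mitogenomes)"
        )
    span = cds.span_length(m.length)
    if span < 3:
        raise ValueError(f"{cds.label}: CDS shorter than one codon")
    dec = CurationDecision(gene=cds.label)
    seq = m.feature_sequence(cds)
    rem = span % 3
    downstream = m.downstream_feature(cds)
    cds_end = cds.end % m.length if cds.wraps_origin else cds.end
    gap = None
    if downstream is not None:
        gap = _signed_distance(cds_end, downstream.start, m.length)

    if rem == 0 and seq[-3:] in STOP_CODONS:
        overlaps_trna = (
            downstream is not None and downstream.kind == "tRNA" and gap is not None and gap < 0
        )
        if not overlaps_trna:
            dec.stop_class = "canonical"
            dec.stop_codon = seq[-3:]
            return dec
        dec.notes.append("in-frame stop overlaps a tRNA; not counted as canonical")

    if (
        downstream is not None
        and downstream.kind == "tRNA"
        and gap == 0
    ):
        if rem == 1 and seq[-1] == "T":
            dec.stop_class = "partial_T"
            dec.stop_codon = "T"
            dec.notes.append("completed to TAA by post-transcriptional 3' adenylation")
            return dec
        if rem == 2 and seq[-2:] == "TA":
            dec.stop_class = "partial_TA"
            dec.stop_codon = "TA"
            dec.notes.append("completed to TAA by post-transcriptional 3' adenylation")
            return dec

    dec.stop_class = "overlap"
    dec.stop_codon = ""
    dec.overlap_len = max(0, -gap) if gap is not None else 0
    if downstream is not None:
        dec.notes.append(
            f"3' end overlaps or abuts {downstream.label} without a stop "
            f"(overlap {dec.overlap_len} bp)"
        )
    return dec


def curate_genome(
    m: Mitogenome,
    window: int = 10,
    candidates: tuple[str, ...] = DEFAULT_START_CODONS,
) -> list[CurationDecision]:
    """One combined start+stop decision per CDS, in genomic order."""
    decisions = []
    for f in m.features:
        if f.kind != "CDS":
            continue
        start_dec = assign_start(m, f, window=window, candidates=candidates)
        stop_dec = classify_stop(m, f)
        start_dec.stop_class = stop_dec.stop_class
        start_dec.stop_codon = stop_dec.stop_codon
        start_dec.overlap_len = stop_dec.overlap_len
        start_dec.notes.extend(stop_dec.notes)
        decisions.append(start_dec)
    return decisions


def curation_report(decisions: list[CurationDecision]) -> str:
    """TSV report: gene, start_codon, start_pos, stop_class, stop_codon, overlap_len."""
    out = ["gene\tstart_codon\tstart_pos\tstop_class\tstop_codon\toverlap_len\tnotes"]
    for d in decisions:
        out.append(
            f"{d.gene}\t{d.start_codon or ''}\t"
            f"{'' if d.start_pos is None else d.start_pos}\t"
            f"{d.stop_class}\t{d.stop_codon}\t{d.overlap_len}\t{'; '.join(d.notes)}"
        )
    return "\n".join(out) + "\n"
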