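"""Intergenic spans, putative control region (pCR), and duplicate-tRNA reports.

The pCR is the major non-coding, AT-rich region of the mitogenome; in
clitellates it sits between trnR and trnH. Operationally we call the longest
non-gene span the pCR candidate and flag whether it is flanked by trnR
(upstream) and trnH (downstream). Intergenic accounting treats only CDS,
tRNA and rRNA features as genomic cover, so an annotated control-region
feature is itself reported as non-coding space.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align

from mitocomp.model import GeneFeature, Mitogenome, base_label


@dataclass
class IntergenicSpan:
    start: int
    end: int  # half-open; may be < start for a span wrapping the origin
    length: int
    flanking: tuple[str | None, str | None]
    at_content: float | None = None


def _at_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return sum(1 for c in seq if c in "ATW") / len(seq)


def find_intergenic(m: Mitogenome, min_len: int = 1) -> list[IntergenicSpan]:
    """All spans not covered by a gene feature, longest first.

    Circular genomes include the wrap-around span. ``at_content`` is filled
    when the genome carries a sequence.
    """
    genes = m.gene_features()
    L = m.length
    if not genes:
        return []
    covered = bytearray(L)
    for f in genes:
        for p in f.positions(L):
            covered[p] = 1
    spans: list[IntergenicSpan] = []
    # walk the circle starting at a covered position so wrap spans stay whole
    try:
        anchor = covered.index(1)
    except ValueError:
        return []
    i = anchor
    run_start = None
    for k in range(L):
        pos = (anchor + k) % L
        if not covered[pos]:
            if run_start is None:
                run_start = pos
        elif run_start is not None:
            spans.append(_make_span(m, run_start, pos))
            run_start = None
    if run_start is not None:
        spans.append(_make_span(m, run_start, anchor))
    spans = [s for s in spans if s.length >= min_len]
    spans.sort(key=lambda s: -s.length)
    return spans


def _make_span(m: Mitogenome, start: int, end: int) -> IntergenicSpan:
    L = m.length
    length = (end - start) % L or (L if start == end else 0)
    seq = None
    if m.sequence is not None:
        seq = (
            m.sequence[start:end]
            if start < end
            else m.sequence[start:] + m.sequence[:end]
        )
    up = down = None
    genes = m.gene_features()
    if genes:
        def end_of(f: GeneFeature) -> int:
            return f.end % L if f.wraps_origin else f.end

        up = min(genes, key=lambda f: (start - end_of(f)) % L).label
        down = min(genes, key=lambda f: (f.start - end) % L).label
    return IntergenicSpan(
        start=start,
        end=end % L,
        length=length,
        flanking=(up, down),
        at_content=_at_fraction(seq) if seq is not None else None,
    )


def identify_pcr(m: Mitogenome) -> tuple[IntergenicSpan, bool]:
    """Longest intergenic span as the pCR candidate, plus a conformance flag.

    The flag is True iff the span lies between trnR (upstream) and trnH
    (downstream), the clitellate arrangement.
    """
    spans = find_intergenic(m)
    if not spans:
        raise ValueError("no intergenic spans found")
    pcr = spans[0]
    up, down = pcr.flanking
    flag = (
        up is not None and down is not None
        and base_label(up) == "trnR" and base_label(down) == "trnH"
    )
    return pcr, flag


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = 1
    al.mismatch_score = -1
    al.open_gap_score = -2
    al.extend_gap_score = -2
    return al


def percent_identity(seq1: str, seq2: str) -> float:
    """Global-alignment identity: matches / alignment columns (0..1).

    Scoring: match +1, mismatch -1, gap -2.
    """
    aln = _aligner().align(seq1, seq2)[0]
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return matches / len(s1)


@dataclass
class TrnaCopyReport:
    isotype: str
    copy_labels: list[str]
    anticodons: list[str | None]
    junction: tuple[str | None, str | None]
    spacer_lengths: list[int]
    identity: float | None


def compare_trna_copies(m: Mitogenome, isotype: str) -> TrnaCopyReport:
    """Characterize a multi-copy tRNA: anticodons, junction, spacers, identity.

    ``spacer_lengths`` are the gaps between consecutive copies (negative
    values denote overlap); ``identity`` is the pairwise percent identity of
    the first two copies from global alignment (needs sequence).
    """
    copies = [f for f in m.features if f.kind == "tRNA" and f.base == base_label(isotype)]
    if len(copies) < 2:
        raise ValueError(
            f"{isotype}: found {len(copies)} copy(ies); need at least 2 "
            "(single-copy or absent isotypes have nothing to compare)"
        )
    copies.sort(key=lambda f: f.start)
    L = m.length
    spacers = []
    for f1, f2 in zip(copies, copies[1:]):
        e = f1.end % L if f1.wraps_origin else f1.end
        gap = (f2.start - e) % L
        if gap > L // 2:
            gap -= L
        spacers.append(gap)
    others = [f for f in m.gene_features() if f.base != base_label(isotype)]
    up = down = None
    if others:
        first, last = copies[0], copies[-1]
        end_of = lambda f: f.end % L if f.wraps_origin else f.end
        up = min(others, key=lambda f: (first.start - end_of(f)) % L).label
        down = min(others, key=lambda f: (f.start - end_of(last)) % L).label
    identity = None
    if m.sequence is not None:
        identity = percent_identity(
            m.feature_sequence(copies[0]), m.feature_sequence(copies[1])
        )
    return TrnaCopyReport(
        isotype=base_label(isotype),
        copy_labels=[f.label for f in copies],
        anticodons=[f.anticodon for f in copies],
        junction=(up, down),
        spacer_lengths=spacers,
        identity=identity,
    )


def length_conservation_check(m: Mitogenome) -> tuple[int, int]:
    """(gene+intergenic accounted length, genome length); equal when gene
    spans plus intergenic spans minus pairwise overlaps tile the circle."""
    genes = m.gene_features()
    L = m.length
    covered = bytearray(L)
    for f in genes:
        for p in f.positions(L):
            covered[p] = 1
    gene_cover = sum(covered)
    intergenic = sum(s.length for s in find_intergenic(m))
    return gene_cover + intergenic, L
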