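"""End-to-end analysis pipeline: curation, gene order, codon usage, tRNA/pCR.

Runs the full comparative workflow over a set of annotated genomes (real or
simulated) and produces plain-text/TSV outputs. Deterministic given inputs
and seed.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

from mitocomp import __version__
from mitocomp.codon_usage import (
    AspContingencyTable,
    asp_table,
    codon_usage_report,
    count_codons,
    gac_gat_ratio,
    homogeneous_subgroups,
)
from mitocomp.curation import curate_genome, curation_report
from mitocomp.exact_tests import fisher_exact_rx2
from mitocomp.gene_order import detect_duplications, detect_events, normalize
from mitocomp.model import Mitogenome, gene_order_of
from mitocomp.synthetic import clitellate_template
from mitocomp.trna_pcr import compare_trna_copies, identify_pcr


@dataclass
class PipelineResult:
    genomes: list[Mitogenome]
    curation: dict[str, list] = field(default_factory=dict)
    events: dict[str, list] = field(default_factory=dict)
    duplications: dict[str, list] = field(default_factory=dict)
    counts: list = field(default_factory=list)
    table: AspContingencyTable | None = None
    fisher_p: float | None = None
    subgroups: object = None
    pcr: dict[str, tuple] = field(default_factory=dict)
    trna_reports: dict[str, list] = field(default_factory=dict)
    summary: str = ""


def run_pipeline(
    genomes: list[Mitogenome],
    reference=None,
    alpha: float = 0.05,
    seed: int = 0,
    log=sys.stderr,
) -> PipelineResult:
    if not genomes:
        raise ValueError("no input genomes")
    res = PipelineResult(genomes=genomes)
    ref = reference if reference is not None else clitellate_template()
    lines = [
        f"mitocomp {__version__} pipeline report",
        f"seed={seed} alpha={alpha} genomes={len(genomes)}",
        "",
    ]

    for m in genomes:
        res.curation[m.id] = curate_genome(m) if m.sequence else []
        order = gene_order_of(m)
        res.duplications[m.id] = detect_duplications(order)
        res.events[m.id] = detect_events(order, ref)
        try:
            res.pcr[m.id] = identify_pcr(m)
        except ValueError:
            res.pcr[m.id] = None
        res.trna_reports[m.id] = [
            compare_trna_copies(m, lab) for lab, _, _ in res.duplications[m.id]
            if lab.startswith("trn")
        ]
        lines.append(
            f"{m.id}: {len(m.features)} features, "
            f"{len(res.events[m.id])} event(s) vs reference, "
            f"duplications: {[(l, c) for l, c, _ in res.duplications[m.id]] or 'none'}"
        )

    with_seq = [m for m in genomes if m.sequence]
    if len(with_seq) >= 2:
        res.counts = [count_codons(m, res.curation[m.id]) for m in with_seq]
        res.table = asp_table(res.counts)
        res.fisher_p = fisher_exact_rx2(res.table.rows())
        lines.append("")
        lines.append(
            f"aspartate GAC/GAT heterogeneity: exact p = {res.fisher_p:.6g}"
        )
        if len(res.table.a) >= 3:
            res.subgroups = homogeneous_subgroups(res.table, alpha=alpha)
            for g, p in res.subgroups.groups:
                lines.append(f"  homogeneous group (p={p:.4g}): {', '.join(g)}")

    for m in genomes:
        if res.pcr.get(m.id):
            span, ok = res.pcr[m.id]
            verdict = "clitellate trnR/trnH position" if ok else "position atypical"
            lines.append(
                f"{m.id}: pCR candidate {span.length} bp between "
                f"{span.flanking[0]} and {span.flanking[1]} ({verdict})"
            )
        for rep in res.trna_reports.get(m.id, []):
            ident = "n/a" if rep.identity is None else f"{100 * rep.identity:.1f}%"
            lines.append(
                f"{m.id}: {rep.isotype} x{len(rep.copy_labels)} "
                f"anticodons {rep.anticodons} spacer {rep.spacer_lengths} "
                f"identity {ident}"
            )
    res.summary = "\n".join(lines) + "\n"
    return res


def write_report(res: PipelineResult, outdir) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.txt").write_text(res.summary)
    for m in res.genomes:
        if res.curation.get(m.id):
            (out / f"{m.id}.curation.tsv").write_text(
                curation_report(res.curation[m.id])
            )
    if res.counts:
        (out / "codon_usage.tsv").write_text(codon_usage_report(res.counts))
    if res.table is not None:
        rows = ["genome\tgac\tgat\tratio"]
        for lab, a, b in zip(res.table.row_labels, res.table.a, res.table.b):
            r = gac_gat_ratio(a, b)
            rows.append(f"{lab}\t{a}\t{b}\t{'undefined' if r is None else f'{r:.2f}'}")
        (out / "asp_table.tsv").write_text("\n".join(rows) + "\n")
    ev_rows = ["genome\tkind\tgenes\tfrom_index\tto_index"]
    for gid, events in res.events.items():
        for e in events:
            ev_rows.append(
                f"{gid}\t{e.kind}\t{','.join(e.genes)}\t"
                f"{'' if e.from_index is None else e.from_index}\t"
                f"{'' if e.to_index is None else e.to_index}"
            )
    (Path(outdir) / "events.tsv").write_text("\n".join(ev_rows) + "\n")


def genome_map(m: Mitogenome, width: int = 100) -> str:
    """Plain-text linear genome map: scaled gene boxes as character runs."""
    scale = width / m.length
    line = ["."] * width
    labels = []
    for f in m.features:
        a = int(f.start * scale)
        b = max(a + 1, int(f.end * scale)) if not f.wraps_origin else width
        ch = f.label[0] if f.kind != "control_region" else "*"
        for i in range(a, min(b, width)):
            line[i] = ch
        labels.append(f"{f.label}@{f.start}")
    return m.id + "\n" + "".join(line) + "\n" + " ".join(labels) + "\n"
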