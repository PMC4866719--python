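"""Aspartate codon usage across clitellate mitogenomes.

Loads the packaged GAC/GAT counts for nine clitellate mitochondrial genomes
(five earthworms, four leeches), tests whether codon usage is homogeneous
with the exact conditional R x 2 test, and searches for the largest groups
of genomes that do share a codon-usage profile.

Run:  python examples/codon_usage_analysis.py
"""

from mitocomp.codon_usage import (
    augment_pvalue,
    gac_gat_ratio,
    homogeneous_subgroups,
    load_clitellata_asp_table,
)
from mitocomp.exact_tests import fisher_exact_rx2

table = load_clitellata_asp_table()

print("genome                      GAC  GAT  ratio")
for label, a, b in zip(table.row_labels, table.a, table.b):
    print(f"{label:<27} {a:>3}  {b:>3}  {gac_gat_ratio(a, b):>5.2f}")

p_all = fisher_exact_rx2(table.rows())
print(f"\nexact test, all {len(table.a)} genomes: p = {p_all:.4g}")
print("-> aspartate codon usage is strongly heterogeneous across Clitellata.")

print("\nmaximal homogeneous subgroups (alpha = 0.05):")
res = homogeneous_subgroups(table, alpha=0.05)
for group, p in res.groups:
    print(f"  p = {p:.4f}: {', '.join(group)}")

oligo = [l for l, g in zip(table.row_labels, table.groups) if g == "Oligochaeta"]
trio = ["Whitmania pigra", "Haementeria officinalis", "Placobdella parasitica"]
for name, group in [("oligochaetes", oligo), ("leech trio", trio)]:
    p = augment_pvalue(table, group, "Placobdella lamothei")
    print(f"\nadding P. lamothei to the {name}: p = {p:.6g} "
          f"({'significant' if p < 0.05 else 'not significant'})")
print("-> P. lamothei, whose second trnD carries the AUC anticodon, fits "
      "neither group: its aspartate codon usage has shifted toward GAT/GAC "
      "balance.")
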