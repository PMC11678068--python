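#!/usr/bin/env python
"""Positive-selection incidence and rate profiles by expression group.

Tabulates the fraction of ω > 1 loci per abundance tertile, profiles the
phylostratum and ω by expression-breadth class, and summarises rates per
chromosome.
"""

from pathlib import Path

import pandas as pd

import divergelens as dl

RESULTS = Path(__file__).resolve().parent.parent / "results"
table = pd.read_csv(RESULTS / "analysis_table.tsv", sep="\t", na_values=["n.a."])

inc = dl.incidence_by_group(table, table["gea_tertile"])
inc["table"].to_csv(RESULTS / "incidence_by_tertile.tsv", sep="\t", index=False)
print("omega > 1 incidence by abundance tertile:")
print(inc["table"].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(f"chi-square = {inc['chi2']:.1f}, df = {inc['df']}, p = {inc['p']:.3g}")

order = ["not_expressed", "specific", "broad"]
for value, label in (("ps", "phylostratum"), ("omega", "omega")):
    prof = dl.group_profile(table, table["breadth_class"], value=value, order=order)
    prof["table"].to_csv(RESULTS / f"{value}_by_breadth.tsv", sep="\t", index=False)
    print(f"\n{label} by expression-breadth class "
          f"(one-way ANOVA p = {prof['anova_p']:.3g}):")
    print(prof["table"].to_string(index=False, float_format=lambda v: f"{v:.3f}"))

chrom = dl.chromosome_summary(table)
chrom["table"].to_csv(RESULTS / "chromosome_summary.tsv", sep="\t", index=False)
n_sig = int((chrom["pairwise_p"].to_numpy() < 0.05).sum() // 2)
print(f"\nper-chromosome summary (pairwise omega t-tests: {n_sig} of "
      f"{len(chrom['table']) * (len(chrom['table']) - 1) // 2} pairs significant):")
print(chrom["table"].to_string(index=False, float_format=lambda v: f"{v:.4f}"))
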