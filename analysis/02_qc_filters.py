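#!/usr/bin/env python
"""Apply the per-locus quality-control filters.

Removes loci with Ka > 1 or Ks > 5, zero or missing rates, then trims the
top and bottom 2.5% of the Ks distribution, and reports what each rule
removed.  The filtered table feeds every later analysis.
"""

import json
from pathlib import Path

import divergelens as dl

RESULTS = Path(__file__).resolve().parent.parent / "results"
loci = dl.read_locus_table(RESULTS / "synthetic" / "loci.tsv")

filtered, log = dl.apply_qc_filters(loci)
dl.write_locus_table(filtered, RESULTS / "loci_filtered.tsv")
with open(RESULTS / "qc_log.json", "w") as fh:
    json.dump(log, fh, indent=2)

print(f"input loci: {log['input']}")
for rule in ("zero_or_na", "ka_gt_max", "ks_gt_max", "ks_trim"):
    print(f"  removed by {rule}: {log[rule]}")
print(f"kept: {log['kept']} ({log['kept'] / log['input']:.1%})")
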