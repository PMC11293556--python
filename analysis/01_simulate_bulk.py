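#!/usr/bin/env python
"""Generate the bulk study dataset.

Writes the synthetic transcriptome (GTF + FASTA), the planted truth tables
(200 m6A sites with stoichiometry pi ~ U[0.2, 1], 50 SNPs, 100
condition-independent background sites), the SNP mask VCF, and three
site-count replicates for each of the four conditions (E-YTH, E-YTHmut,
APOBEC1-only, WT) under results/bulk/data/.
"""

import argparse
from pathlib import Path

from dartcall import simulate as sim
from dartcall.annotation_io import write_site_counts

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--out", type=Path, default=Path("results/bulk/data"))
args = parser.parse_args()

scenario, samples = sim.bulk_basic(seed=args.seed)
args.out.mkdir(parents=True, exist_ok=True)
scenario.write(args.out)
for cond, tables in samples.items():
    write_site_counts(tables, args.out / f"counts_{cond}.tsv")
    n = sum(len(t) for t in tables)
    print(f"{cond}: 3 replicates, {n} site rows")

truth = scenario.truth
print(f"\nplanted: {len(truth.m6a)} m6A sites "
      f"(pi in [{truth.m6a.pi.min():.2f}, {truth.m6a.pi.max():.2f}]), "
      f"{len(truth.snps)} SNPs, {len(truth.artifacts)} background sites")
print(f"candidate cytidines: {len(scenario.c_sites)}")
print(f"wrote dataset to {args.out}")
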