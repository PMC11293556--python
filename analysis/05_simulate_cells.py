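#!/usr/bin/env python
"""Generate the single-cell study dataset.

Four clusters of 30 E-YTH + 30 E-YTHmut cells each; cluster c4 carries a
5x nonspecific editing background. 60 planted m6A sites (15 homogeneous in
30% of cells, 10 SNP-mimics homogeneous in every cell), 50 masked SNPs and
30 background sites; matched bulk control replicates are simulated on the
same site universe. Written under results/sc/data/.
"""

import argparse
from pathlib import Path

from dartcall import simulate as sim
from dartcall.annotation_io import write_site_counts

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--out", type=Path, default=Path("results/sc/data"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

scenario, cells, plan, controls = sim.sc_clusters(seed=args.seed)
scenario.write(args.out)
cells.write(args.out / "cell_counts.tsv", args.out / "clusters.tsv")
cells.subset("YTH").write(args.out / "yth_cells.tsv",
                          args.out / "yth_clusters.tsv")
cells.subset("YTHmut").write(args.out / "mut_cells.tsv",
                             args.out / "mut_clusters.tsv")
for cond, tables in controls.items():
    write_site_counts(tables, args.out / f"bulk_{cond}.tsv")

for cl in plan.clusters:
    print(f"cluster {cl.name}: lambda={cl.lam}, "
          f"{cl.n_yth} YTH + {cl.n_mut} YTHmut cells")
truth = scenario.truth
print(f"planted: {len(truth.m6a)} m6A "
      f"({(truth.m6a.h == 1).sum()} SNP-mimics, "
      f"{((truth.m6a.h > 0) & (truth.m6a.h < 1)).sum()} homogeneous-in-some), "
      f"{len(truth.snps)} SNPs, {len(truth.artifacts)} background sites")
print(f"wrote dataset to {args.out}")
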