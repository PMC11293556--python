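#!/usr/bin/env python
"""Metagene geometry of the bulk m6A calls.

Maps the calls from 02_call_bulk_m6a.py onto transcript meta-coordinates:
region composition (5'UTR / CDS / 3'UTR / downstream of the 3' end) and the
site density around the stop codon (500 nt either side, 25-nt bins). Also
profiles a dedicated 500-site planting at Normal(+118, 30) nt downstream of
the stop to verify the geometry end to end.
"""

import argparse
from pathlib import Path

import pandas as pd

from dartcall import simulate as sim
from dartcall.annotation_io import load_transcript_models
from dartcall.metagene import map_sites, region_pie, stop_codon_profile

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=42)
parser.add_argument("--calls", type=Path, default=Path("results/bulk/m6a_calls.tsv"))
parser.add_argument("--gtf", type=Path,
                    default=Path("results/bulk/data/transcripts.gtf"))
parser.add_argument("--out", type=Path, default=Path("results/metagene"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

ts = load_transcript_models(args.gtf)
calls = pd.read_csv(args.calls, sep="\t", dtype={"chrom": str})
keys = [(r.chrom, int(r.pos), r.strand) for r in calls.itertuples()]
positions = map_sites(keys, ts)

pie = region_pie(positions)
pie.to_csv(args.out / "call_region_fractions.tsv", sep="\t", index=False)
print("region composition of bulk calls:")
print(pie.to_string(index=False))

profile = stop_codon_profile(positions)
profile.to_frame().to_csv(args.out / "call_stop_codon_profile.tsv",
                          sep="\t", index=False)
print(f"\nmodal 25-nt bin midpoint: {profile.peak_offset:+.1f} nt from the "
      f"stop codon ({profile.n_in_window} sites in the window)")

# independent 500-site geometric check
scenario, m6a = sim.metagene_sites(seed=args.seed, n_sites=500)
pos500 = map_sites([(r.chrom, int(r.pos), r.strand)
                    for r in m6a.itertuples()], scenario.ts)
prof500 = stop_codon_profile(pos500)
prof500.to_frame().to_csv(args.out / "planted500_profile.tsv", sep="\t",
                          index=False)
mapped = {p.key: p.offset_from_stop for p in pos500}
exact = sum(1 for r in m6a.itertuples()
            if mapped.get((r.chrom, int(r.pos), r.strand)) == r.offset)
print(f"\n500-site planting: {exact}/500 offsets re-derived exactly; "
      f"modal bin midpoint {prof500.peak_offset:+.1f} nt")
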