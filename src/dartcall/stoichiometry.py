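"""m/k stoichiometry analysis.

The editing ratio m/k at a called site estimates the fraction of transcript
copies carrying the modification: m/k = 1 means every covered copy is
modified at that site ("homogeneous"), m/k = 0.25 that a quarter are.
Ratio analyses exclude observations with coverage below 10 reads, and
m/k = 1 is integer equality m == k (counts are integers; no tolerance).

The homogeneous-site heuristic guards against unannotated germline variants
mimicking m/k = 1: a site qualifies only if, besides a cell with m == k, at
least five *other* cells show sub-stoichiometric editing (m/k < 0.9) at
coverage >= 10. A true SNP edits every covering cell completely and can
never satisfy that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation_io import TranscriptSet
from .edit_detection import SiteKey
from .metagene import TranscriptLocator
from .sc_calling import CellM6AProfile

MIN_K = 10


def records_frame(rows: Iterable[tuple[SiteKey, str, int, int]]) -> pd.DataFrame:
    """Long-form stoichiometry records: (site key, observation id, m, k)."""
    data = [(c, p, s, obs, m, k) for (c, p, s), obs, m, k in rows]
    df = pd.DataFrame(data, columns=["chrom", "pos", "strand", "obs", "m", "k"])
    df["ratio"] = df.m / df.k
    df["is_homogeneous_here"] = df.m == df.k
    df["meets_min_k"] = df.k >= MIN_K
    return df


def records_from_profiles(profiles: list[CellM6AProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for key, rec in p.sites.items():
            rows.append((key, p.barcode, rec.m, rec.k))
    return records_frame(rows)


def mk_histogram(records: pd.DataFrame, min_ratio: float = 0.05,
                 bin_width: float = 0.05, min_k: int = MIN_K) -> pd.DataFrame:
    """Site counts per m/k bin over [min_ratio, 1.0], with a dedicated
    terminal bin for exactly m == k. Records below the coverage floor or
    the minimum ratio are excluded."""
    sub = records[(records.k >= min_k) & (records.ratio >= min_ratio)]
    exact_one = sub[sub.m == sub.k]
    rest = sub[sub.m != sub.k]
    edges = np.round(np.arange(min_ratio, 1.0 + bin_width / 2, bin_width), 10)
    counts, _ = np.histogram(rest.ratio, bins=edges)
    rows = [(float(edges[i]), float(edges[i + 1]), int(counts[i]))
            for i in range(len(counts))]
    rows.append((1.0, 1.0, int(len(exact_one))))
    return pd.DataFrame(rows, columns=["bin_start", "bin_end", "n_sites"])


@dataclass
class HomogeneousSiteSet:
    sites: dict[SiteKey, tuple[int, int]]  # key -> (n_cells_at_1, n_below_0.9)

    def __contains__(self, key: SiteKey) -> bool:
        return key in self.sites

    def __len__(self):
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        rows = [(c, p, s, n1, nb) for (c, p, s), (n1, nb)
                in sorted(self.sites.items())]
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand",
                                           "n_cells_at_1", "n_cells_below_0.9"])


def find_homogeneous_sites(records: pd.DataFrame,
                           n_other_min: int = 5,
                           ratio_below: float = 0.9,
                           k_min: int = MIN_K) -> HomogeneousSiteSet:
    """Sites with m/k = 1 in some cell that are corroborated by >=
    ``n_other_min`` other cells with m/k < ``ratio_below`` at coverage >=
    ``k_min``. Cells where the site itself is at ratio 1 never count as
    "other" corroborating cells."""
    sub = records[records.k >= k_min]
    out: dict[SiteKey, tuple[int, int]] = {}
    for key, grp in sub.groupby(["chrom", "pos", "strand"], sort=False):
        at_one = grp[grp.m == grp.k]
        if len(at_one) == 0:
            continue
        others = grp[grp.m != grp.k]
        below = others[others.ratio < ratio_below]
        n_below = below.obs.nunique()
        if n_below >= n_other_min:
            out[(key[0], int(key[1]), key[2])] = (int(at_one.obs.nunique()),
                                                  int(n_below))
    return HomogeneousSiteSet(out)


def contrast_conditions(wt_records: pd.DataFrame, ko_records: pd.DataFrame,
                        min_k: int = MIN_K) -> pd.DataFrame:
    """Per-site WT-vs-KO ratio comparison.

    Ratios are replicate-pooled (sum m / sum k over observations at
    coverage >= min_k). Classes: ``lost`` (KO ratio 0), ``reduced``
    (0 < KO < WT), ``unchanged`` otherwise; sites without adequate KO
    coverage are ``uncalled`` rather than lost."""
    def pooled(df):
        sub = df[df.k >= min_k]
        g = sub.groupby(["chrom", "pos", "strand"]).agg(m=("m", "sum"),
                                                        k=("k", "sum"))
        g["ratio"] = g.m / g.k
        return g

    wt = pooled(wt_records)
    ko = pooled(ko_records)
    if len(wt) == 0 or not wt.index.intersection(ko.index).size:
        import logging
        logging.getLogger(__name__).warning("no shared sites between "
                                            "conditions")
    merged = wt[["ratio"]].rename(columns={"ratio": "ratio_wt"}).join(
        ko[["ratio"]].rename(columns={"ratio": "ratio_ko"}), how="left")
    def classify(row):
        if np.isnan(row.ratio_ko):
            return "uncalled"
        if row.ratio_ko == 0:
            return "lost"
        if row.ratio_ko < row.ratio_wt:
            return "reduced"
        return "unchanged"
    merged["class"] = merged.apply(classify, axis=1)
    return merged.reset_index()


def per_gene_mk(records: pd.DataFrame, ts: TranscriptSet,
                min_k: int = MIN_K) -> pd.DataFrame:
    """Per (gene, observation) m/k summary: site count, max and mean ratio.
    Sites outside any gene's exon span are labeled ``intergenic``."""
    locator = TranscriptLocator(ts, downstream=0)
    sub = records[records.k >= min_k].copy()
    genes = []
    for chrom, pos, strand in zip(sub.chrom, sub.pos, sub.strand):
        cands = [tm for tm in locator.candidates(chrom, int(pos), strand)
                 if tm.genomic_to_mature(int(pos)) is not None]
        if cands:
            tm = min(cands, key=lambda t: (-t.mature_length, t.transcript_id))
            genes.append(tm.gene_id)
        else:
            genes.append("intergenic")
    sub["gene_id"] = genes
    g = sub.groupby(["gene_id", "obs"]).agg(
        n_sites=("ratio", "size"), max_ratio=("ratio", "max"),
        mean_ratio=("ratio", "mean"))
    return g.reset_index()
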