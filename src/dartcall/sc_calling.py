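"""Per-cell m6A calling with cluster-specific mutant-background correction.

Cells are treated as independent samples: the bulk per-site filters
(FDR < 0.01 within the cell, m >= 2, k >= 10, m/k > 5%, SNP mask) are
applied per cell, bulk WT/APOBEC1 control sites are excluded, sites present
in the bulk mutant control must show a 1.5-fold higher per-cell ratio, and
finally the cluster-specific APOBEC1-YTHmut background is removed.

Because nonspecific deamination is not evenly distributed across clusters,
the background correction is cluster-aware on two levels:

* the cluster's average mutant editing - both the pooled editing rate of
  its E-YTHmut cells and the per-site mean mutant ratio - defines a
  cluster-specific null;
* each retained site in a YTH cell must carry editing that (a) exceeds the
  per-site mutant mean (positive adjusted ratio, which is recorded) and
  (b) remains significant when re-tested against the cluster null with BH
  control within the cell.

With a zero background both requirements reduce to the original per-cell
call, so the correction is the identity on clean clusters; with a uniform
background it coincides with a global correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation_io import SiteCountTable, SnpMask
from .bulk_calling import MergedSite
from .edit_detection import (EditSite, EditThresholds, SiteKey, bh_qvalues,
                             call_candidate_edits, site_pvalue)

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

CELL_COUNT_COLUMNS = ["barcode", "condition", "cluster",
                      "chrom", "pos", "strand", "ref", "m", "k"]


@dataclass
class CellEditMatrix:
    """Sparse per-cell (m, k) pairs at candidate cytidine sites.

    ``cells``: one row per cell (barcode, condition, cluster);
    ``counts``: long form (barcode, chrom, pos, strand, ref, m, k), k > 0.
    """

    cells: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self):
        if self.cells.barcode.duplicated().any():
            raise ValueError("duplicate cell barcodes")
        if "cluster" not in self.cells.columns:
            self.cells = self.cells.assign(cluster=UNASSIGNED)
        self.cells = self.cells.fillna({"cluster": UNASSIGNED}).reset_index(drop=True)
        bad = self.counts.index[(self.counts.m < 0) |
                                (self.counts.m > self.counts.k) |
                                (self.counts.k <= 0)]
        if len(bad):
            raise ValueError(f"invalid (m,k) at counts row {bad[0]}")
        unknown = set(self.counts.barcode) - set(self.cells.barcode)
        if unknown:
            raise ValueError(f"counts for unlisted barcodes: {sorted(unknown)[:3]}")

    def subset(self, condition: str) -> "CellEditMatrix":
        cells = self.cells[self.cells.condition == condition]
        counts = self.counts[self.counts.barcode.isin(cells.barcode)]
        return CellEditMatrix(cells.copy(), counts.copy())

    def cluster_of(self) -> dict[str, str]:
        return dict(zip(self.cells.barcode, self.cells.cluster.astype(str)))

    def write(self, counts_path, clusters_path) -> None:
        meta = self.cells.set_index("barcode")
        out = self.counts.copy()
        out.insert(1, "condition", out.barcode.map(meta.condition))
        out.insert(2, "cluster", out.barcode.map(meta.cluster))
        out[CELL_COUNT_COLUMNS].to_csv(counts_path, sep="\t", index=False)
        self.cells.to_csv(clusters_path, sep="\t", index=False)


def read_cell_matrix(counts_path, clusters_path=None) -> CellEditMatrix:
    counts = pd.read_csv(counts_path, sep="\t", dtype={"chrom": str})
    if clusters_path is not None:
        cells = pd.read_csv(clusters_path, sep="\t", dtype=str)
    else:
        cells = counts[["barcode", "condition"]].drop_duplicates()
        cells["cluster"] = UNASSIGNED
    keep = [c for c in ("barcode", "condition", "cluster", "cell_type")
            if c in cells.columns]
    return CellEditMatrix(cells[keep].copy(),
                          counts[["barcode", "chrom", "pos", "strand",
                                  "ref", "m", "k"]].copy())


# ---------------------------------------------------------------------------
# Per-cell candidate calling
# ---------------------------------------------------------------------------

def call_cell_edits(mat: CellEditMatrix,
                    thr: EditThresholds = EditThresholds(),
                    mask: SnpMask | None = None,
                    error_rate: float | None = None,
                    ) -> dict[str, dict[SiteKey, EditSite]]:
    """Bulk thresholds applied independently within each cell (the FDR
    family is the single cell; no replicate-intersection rule)."""
    out: dict[str, dict[SiteKey, EditSite]] = {
        bc: {} for bc in mat.cells.barcode}
    for barcode, sub in mat.counts.groupby("barcode", sort=False):
        table = SiteCountTable(str(barcode), "YTH", str(barcode),
                               sub[["chrom", "pos", "strand", "ref", "m", "k"]])
        out[str(barcode)] = call_candidate_edits(table, thr, mask,
                                                 error_rate=error_rate)
    return out


def remove_bulk_background_sc(cells: dict[str, dict[SiteKey, EditSite]],
                              wt: set[SiteKey] | dict,
                              apobec: set[SiteKey] | dict,
                              bulk_mut: dict[SiteKey, MergedSite],
                              fold_min: float = 1.5,
                              ) -> dict[str, dict[SiteKey, EditSite]]:
    """Drop per-cell sites seen in bulk WT/APOBEC1 controls; sites present in
    the bulk mutant control are kept only at >= fold_min times its merged
    ratio."""
    drop = set(wt) | set(apobec)
    out = {}
    for barcode, sites in cells.items():
        kept = {}
        for key, site in sites.items():
            if key in drop:
                continue
            mut_site = bulk_mut.get(key)
            if mut_site is not None and mut_site.m > 0:
                # exact rational "1.5-fold over bulk mutant" comparison
                if site.m * mut_site.k < fold_min * mut_site.m * site.k:
                    continue
            kept[key] = site
        out[barcode] = kept
    return out


# ---------------------------------------------------------------------------
# Cluster-specific mutant background
# ---------------------------------------------------------------------------

@dataclass
class ClusterBackground:
    """Average E-YTHmut editing per cluster.

    ``per_site[cluster][key]`` holds (mean ratio, mean edited count, n cells
    contributing at coverage >= k_min). ``pooled_rate[cluster]`` is the
    cluster's overall mutant editing rate (sum m / sum k over unmasked
    sites), the scalar "average C-to-U editing" of the cluster.
    """

    per_site: dict[str, dict[SiteKey, tuple[float, float, int]]]
    pooled_rate: dict[str, float]
    n_cells: dict[str, int]
    global_rate: float
    global_per_site: dict[SiteKey, tuple[float, float, int]]
    empty_clusters: set[str] = field(default_factory=set)

    def rate(self, cluster: str) -> float:
        if cluster in self.empty_clusters or cluster not in self.pooled_rate:
            return self.global_rate
        return self.pooled_rate[cluster]

    def site_mean(self, cluster: str, key: SiteKey) -> float:
        if cluster in self.empty_clusters or cluster not in self.per_site:
            entry = self.global_per_site.get(key)
        else:
            entry = self.per_site[cluster].get(key)
        return entry[0] if entry is not None else 0.0


def cluster_background_profile(mut_cells: CellEditMatrix,
                               k_min: int = 10,
                               mask: SnpMask | None = None,
                               exclude: set[SiteKey] | None = None,
                               ) -> ClusterBackground:
    """Per-(cluster, site) mean mutant editing ratio/count and per-cluster
    pooled editing rate over the E-YTHmut cells.

    Cells contribute to a site's mean only at coverage >= k_min. The pooled
    rate estimates the cluster's *uniform* nonspecific editing, so masked
    positions (known variants) and ``exclude``d sites (e.g. bulk-control
    background already removed site-wise) do not contribute to it. Clusters
    without mutant cells are flagged; downstream the global mutant average
    is used for them.
    """
    counts = mut_cells.counts.copy()
    meta = mut_cells.cluster_of()
    counts["cluster"] = counts.barcode.map(meta).astype(str)

    unmasked = counts
    if mask is not None and len(mask) > 0:
        sel = ~np.fromiter(((c, p) in mask
                            for c, p in zip(counts.chrom, counts.pos)),
                           bool, count=len(counts))
        unmasked = counts[sel]
    if exclude:
        sel = ~np.fromiter(
            (((c, int(p), s) in exclude)
             for c, p, s in zip(unmasked.chrom, unmasked.pos, unmasked.strand)),
            bool, count=len(unmasked))
        unmasked = unmasked[sel]

    pooled, per_site = {}, {}
    for cluster, sub in unmasked.groupby("cluster"):
        pooled[cluster] = float(sub.m.sum() / sub.k.sum()) if sub.k.sum() else 0.0
    covered = counts[counts.k >= k_min]
    covered = covered.assign(ratio=covered.m / covered.k)
    for cluster, sub in covered.groupby("cluster"):
        agg = sub.groupby(["chrom", "pos", "strand"]).agg(
            r=("ratio", "mean"), c=("m", "mean"), n=("m", "size"))
        per_site[cluster] = {(c, int(p), s): (float(r.r), float(r.c), int(r.n))
                             for (c, p, s), r in agg.iterrows()}

    total_k = unmasked.k.sum()
    global_rate = float(unmasked.m.sum() / total_k) if total_k else 0.0
    gagg = covered.groupby(["chrom", "pos", "strand"]).agg(
        r=("ratio", "mean"), c=("m", "mean"), n=("m", "size"))
    global_per_site = {(c, int(p), s): (float(r.r), float(r.c), int(r.n))
                       for (c, p, s), r in gagg.iterrows()}

    all_clusters = set(mut_cells.cells.cluster.astype(str))
    n_cells = mut_cells.cells.groupby(
        mut_cells.cells.cluster.astype(str)).size().to_dict()
    empty = {c for c in all_clusters if n_cells.get(c, 0) == 0}
    for c in empty:
        logger.warning("cluster %s has no mutant cells; global background "
                       "fallback will apply", c)
    return ClusterBackground(per_site, pooled, n_cells, global_rate,
                             global_per_site, empty)


# ---------------------------------------------------------------------------
# Cluster background subtraction
# ---------------------------------------------------------------------------

@dataclass
class CellSiteRecord:
    m: int
    k: int
    ratio: float
    adjusted_ratio: float
    background: float


@dataclass
class CellM6AProfile:
    barcode: str
    cluster: str
    sites: dict[SiteKey, CellSiteRecord]

    @property
    def n_sites(self) -> int:
        return len(self.sites)


def subtract_cluster_background(yth_cells: dict[str, dict[SiteKey, EditSite]],
                                bg: ClusterBackground,
                                clusters: dict[str, str],
                                thr: EditThresholds = EditThresholds(),
                                error_rate: float | None = None,
                                ) -> list[CellM6AProfile]:
    """Remove the cluster-specific mutant background from each YTH cell.

    For a cell in cluster c, a called site survives iff

    * its per-cell ratio exceeds the per-site mutant mean of the cluster
      (adjusted ratio = ratio - mean > 0, recorded on the output), and
    * it stays significant against the cluster null rate
      max(e, pooled mutant rate of c, per-site mutant mean), with BH
      control (q < fdr_max) across the cell's sites.

    Cells whose cluster is unknown, or whose cluster has no mutant cells,
    fall back to the global mutant background (logged by the profile step).
    Retained sites keep their raw m and k; the adjustment is recorded.
    """
    e = error_rate if error_rate is not None else thr.error_rate
    profiles = []
    for barcode, sites in yth_cells.items():
        cluster = clusters.get(barcode, UNASSIGNED)
        if cluster == UNASSIGNED:
            rate = bg.global_rate
        else:
            rate = bg.rate(cluster)
        keys, pvals, adj, bgs = [], [], [], []
        for key, site in sites.items():
            r_site = (bg.site_mean(cluster, key) if cluster != UNASSIGNED
                      else (bg.global_per_site.get(key, (0.0,))[0]))
            a = site.ratio - r_site
            if a <= 0:
                continue
            null = min(max(e, rate, r_site), 1.0 - 1e-12)
            keys.append(key)
            pvals.append(float(site_pvalue(site.m, site.k, null)))
            adj.append(a)
            bgs.append(r_site)
        kept: dict[SiteKey, CellSiteRecord] = {}
        if keys:
            order = np.argsort(pvals, kind="stable")
            q = np.empty(len(pvals))
            q[order] = bh_qvalues(np.asarray(pvals)[order])
            for i, key in enumerate(keys):
                if q[i] < thr.fdr_max:
                    s = sites[key]
                    kept[key] = CellSiteRecord(s.m, s.k, s.ratio, adj[i], bgs[i])
        profiles.append(CellM6AProfile(barcode, cluster, kept))
    return profiles


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def summarize_counts(profiles: list[CellM6AProfile],
                     cell_types: dict[str, str] | None = None,
                     ) -> dict[str, pd.DataFrame]:
    """Mean/median/total m6A sites per cell, grouped by cluster and
    (optionally) by cell type, plus a per-cell table."""
    rows = [(p.barcode, p.cluster, p.n_sites) for p in profiles]
    per_cell = pd.DataFrame(rows, columns=["barcode", "cluster", "n_sites"])
    if cell_types:
        per_cell["cell_type"] = per_cell.barcode.map(cell_types)
    out = {"per_cell": per_cell}
    for grouping in ("cluster", "cell_type"):
        if grouping not in per_cell.columns:
            continue
        g = per_cell.groupby(grouping).n_sites.agg(
            mean="mean", median="median", total="sum", n_cells="size")
        out[f"per_{grouping}"] = g.reset_index()
    return out


def profiles_to_frame(profiles: list[CellM6AProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        for (chrom, pos, strand), rec in sorted(p.sites.items()):
            rows.append((p.barcode, p.cluster, chrom, pos, strand,
                         rec.m, rec.k, rec.ratio, rec.adjusted_ratio,
                         rec.background))
    return pd.DataFrame(rows, columns=["barcode", "cluster", "chrom", "pos",
                                       "strand", "m", "k", "ratio",
                                       "adjusted_ratio", "background"])
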