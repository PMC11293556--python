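"""Bulk m6A calling: replicate intersection and control elimination.

The APOBEC1-YTH ("YTH") replicates are intersected (site present in at
least ``min_rep`` replicates, counts summed over the supporting
replicates), sites seen in WT or APOBEC1-only controls are removed, and
surviving sites must show editing at least ``fold_min`` (default 1.5,
inclusive) times the replicate-merged ratio of the binding-dead
APOBEC1-YTHmut control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .edit_detection import EditSite, SiteKey


@dataclass(frozen=True)
class M6ACall:
    chrom: str
    pos: int
    strand: str
    m: int                      # summed over supporting YTH replicates
    k: int
    n_replicates_support: int
    fold_over_mut: float        # math.inf when absent from the mutant control
    passed_wt: bool = True
    passed_apobec: bool = True
    passed_fold: bool = True
    gene_id: str | None = None

    @property
    def ratio(self) -> float:
        return self.m / self.k

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.strand)

    @property
    def provenance(self) -> str:
        fold = "inf" if math.isinf(self.fold_over_mut) else f"{self.fold_over_mut:.2f}"
        return f"rep{self.n_replicates_support}|fold{fold}"


@dataclass
class MergedSite:
    """A replicate-merged edit: counts summed over supporting replicates."""
    chrom: str
    pos: int
    strand: str
    m: int
    k: int
    n_support: int

    @property
    def ratio(self) -> float:
        return self.m / self.k

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.strand)


def intersect_replicates(reps: list[dict[SiteKey, EditSite]],
                         min_rep: int = 2) -> dict[SiteKey, MergedSite]:
    """Sites present in >= min_rep replicate edit sets; m and k are summed
    over the supporting replicates and the ratio recomputed from the sums."""
    if min_rep > len(reps):
        raise ValueError(f"min_rep={min_rep} exceeds number of replicate sets "
                         f"({len(reps)})")
    merged: dict[SiteKey, MergedSite] = {}
    for rep in reps:
        for key, site in rep.items():
            if key in merged:
                ms = merged[key]
                ms.m += site.m
                ms.k += site.k
                ms.n_support += 1
            else:
                merged[key] = MergedSite(*key, site.m, site.k, 1)
    return {k: v for k, v in merged.items() if v.n_support >= min_rep}


def union_replicates(reps: list[dict[SiteKey, EditSite]]) -> set[SiteKey]:
    """Union of site keys over replicate sets (background controls are
    removed maximally conservatively)."""
    keys: set[SiteKey] = set()
    for rep in reps:
        keys |= set(rep)
    return keys


def subtract_background(yth: dict[SiteKey, MergedSite],
                        wt: set[SiteKey] | dict,
                        apobec: set[SiteKey] | dict) -> dict[SiteKey, MergedSite]:
    """yth minus (wt union apobec), matched on (chrom, pos, strand)."""
    drop = set(wt) | set(apobec)
    return {k: v for k, v in yth.items() if k not in drop}


def fold_filter(yth: dict[SiteKey, MergedSite],
                mut: dict[SiteKey, MergedSite],
                fold_min: float = 1.5) -> dict[SiteKey, M6ACall]:
    """Keep sites absent from the mutant control (fold = inf) or edited at
    >= fold_min times the mutant's merged ratio."""
    out: dict[SiteKey, M6ACall] = {}
    for key, site in yth.items():
        mut_site = mut.get(key)
        if mut_site is None or mut_site.m == 0:
            fold = math.inf
            keep = True
        else:
            fold = site.ratio / mut_site.ratio
            # exact rational comparison: m_y/k_y >= fold_min * m_mut/k_mut
            keep = site.m * mut_site.k >= fold_min * mut_site.m * site.k
        if keep:
            out[key] = M6ACall(*key, site.m, site.k, site.n_support, fold)
    return out


@dataclass
class BulkAudit:
    """Counts surviving each named stage of the bulk pipeline."""
    stages: list[tuple[str, int]] = field(default_factory=list)

    def record(self, stage: str, n: int) -> None:
        self.stages.append((stage, int(n)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_sites"])


def call_bulk_m6a(yth_reps: list[dict[SiteKey, EditSite]],
                  mut_reps: list[dict[SiteKey, EditSite]],
                  wt_reps: list[dict[SiteKey, EditSite]],
                  apobec_reps: list[dict[SiteKey, EditSite]],
                  min_rep: int = 2,
                  fold_min: float = 1.5,
                  ) -> tuple[dict[SiteKey, M6ACall], BulkAudit]:
    """End-to-end bulk composition with a stagewise audit log.

    Controls: WT and APOBEC1-only backgrounds are each the union over their
    replicates; the mutant control is replicate-intersected like YTH so the
    fold comparison uses merged ratios on both sides.
    """
    for name, reps in (("YTH", yth_reps), ("YTHmut", mut_reps),
                       ("WT", wt_reps), ("APOBEC1", apobec_reps)):
        if not reps:
            raise ValueError(f"missing condition: {name}")

    audit = BulkAudit()
    yth = intersect_replicates(yth_reps, min_rep=min_rep)
    audit.record("yth_replicate_intersection", len(yth))
    mut = intersect_replicates(mut_reps, min_rep=min(min_rep, len(mut_reps)))
    audit.record("mut_replicate_intersection", len(mut))
    wt_keys = union_replicates(wt_reps)
    ap_keys = union_replicates(apobec_reps)
    no_bg = subtract_background(yth, wt_keys, ap_keys)
    audit.record("after_wt_apobec_removal", len(no_bg))
    calls = fold_filter(no_bg, mut, fold_min=fold_min)
    audit.record("after_fold_filter", len(calls))
    return calls, audit


def calls_to_frame(calls: dict[SiteKey, M6ACall]) -> pd.DataFrame:
    rows = [(c.chrom, c.pos, c.strand, c.m, c.k, c.ratio,
             c.n_replicates_support, c.fold_over_mut)
            for c in sorted(calls.values(), key=lambda c: c.key)]
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "m", "k",
                                       "ratio", "n_replicates_support",
                                       "fold_over_mut"])
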