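"""Scoring pipeline output against planted synthetic truth.

Shared by the analysis drivers, the test suite and the acceptance script so
every reported recall / precision / false-positive figure comes from one
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation_io import SiteCountTable
from .edit_detection import SiteKey
from .sc_calling import CellM6AProfile
from .simulate import SyntheticScenario


@dataclass
class BulkScore:
    recall: float            # over recoverable planted sites (coverage-aware)
    precision: float
    n_recoverable: int
    n_called: int
    n_true_positive: int
    snps_in_calls: int
    artifacts_in_calls: int


def recoverable_m6a_keys(scenario: SyntheticScenario,
                         yth_tables: list[SiteCountTable],
                         k_min: int = 20, min_rep: int = 2) -> set[SiteKey]:
    """Planted m6A sites with coverage >= k_min in >= min_rep YTH
    replicates (the sites the sequencing depth can support)."""
    truth_keys = scenario.truth.m6a_keys()
    support: dict[SiteKey, int] = {}
    for table in yth_tables:
        df = table.df
        ok = df[df.k >= k_min]
        for key in zip(ok.chrom, ok.pos, ok.strand):
            key = (key[0], int(key[1]), key[2])
            if key in truth_keys:
                support[key] = support.get(key, 0) + 1
    return {k for k, n in support.items() if n >= min_rep}


def score_bulk_calls(calls: dict, scenario: SyntheticScenario,
                     yth_tables: list[SiteCountTable],
                     k_min: int = 20, min_rep: int = 2) -> BulkScore:
    truth = scenario.truth
    m6a = truth.m6a_keys()
    recoverable = recoverable_m6a_keys(scenario, yth_tables, k_min, min_rep)
    called = set(calls)
    tp = called & m6a
    return BulkScore(
        recall=len(called & recoverable) / len(recoverable) if recoverable else float("nan"),
        precision=len(tp) / len(called) if called else float("nan"),
        n_recoverable=len(recoverable),
        n_called=len(called),
        n_true_positive=len(tp),
        snps_in_calls=len(called & truth.snp_keys()),
        artifacts_in_calls=len(called & truth.artifact_keys()),
    )


def stratum_recovery(tables: list[SiteCountTable],
                     scenario: SyntheticScenario,
                     min_k: int = 10) -> pd.DataFrame:
    """Mean observed m/k per planted-stoichiometry stratum, with the
    binomial standard error sqrt(pi (1 - pi) / k_bar) / sqrt(n)."""
    truth = scenario.truth.m6a.set_index(["chrom", "pos", "strand"])
    frames = []
    for t in tables:
        df = t.df[t.df.k >= min_k].copy()
        df = df.join(truth[["pi"]], on=["chrom", "pos", "strand"], how="inner")
        frames.append(df)
    obs = pd.concat(frames, ignore_index=True)
    obs["ratio"] = obs.m / obs.k
    rows = []
    for pi, grp in obs.groupby("pi"):
        n = len(grp)
        k_bar = grp.k.mean()
        se = np.sqrt(pi * (1 - pi) / k_bar) / np.sqrt(n) if n else np.nan
        rows.append((pi, n, grp.ratio.mean(), k_bar, se,
                     abs(grp.ratio.mean() - pi)))
    return pd.DataFrame(rows, columns=["pi", "n_obs", "mean_ratio", "k_bar",
                                       "se", "abs_error"])


def fp_rates_by_cluster(per_cell_sites: dict[str, set[SiteKey] | dict],
                        clusters: dict[str, str],
                        scenario: SyntheticScenario,
                        covered: dict[str, set[SiteKey]] | None = None,
                        ) -> pd.DataFrame:
    """False-positive site rate per cluster: called sites that are neither
    planted m6A nor SNPs nor artifact sites, per cell (and per covered null
    site when coverage sets are supplied)."""
    truth = scenario.truth
    planted = truth.m6a_keys() | truth.snp_keys() | truth.artifact_keys()
    rows = []
    for barcode, sites in per_cell_sites.items():
        fp = {k for k in set(sites) if k not in planted}
        n_cov = len(covered[barcode] - planted) if covered else np.nan
        rows.append((barcode, clusters.get(barcode, "unassigned"),
                     len(fp), n_cov))
    df = pd.DataFrame(rows, columns=["barcode", "cluster", "n_fp", "n_null_covered"])
    agg = df.groupby("cluster").agg(mean_fp=("n_fp", "mean"),
                                    n_cells=("n_fp", "size"),
                                    mean_null_covered=("n_null_covered", "mean"))
    agg["fp_rate"] = agg.mean_fp / agg.mean_null_covered
    return agg.reset_index()


def profiles_site_sets(profiles: list[CellM6AProfile]) -> dict[str, set]:
    return {p.barcode: set(p.sites) for p in profiles}


def covered_null_sets(mat, k_min: int = 10) -> dict[str, set]:
    """Per cell, the site keys covered at >= k_min reads."""
    out: dict[str, set] = {}
    cov = mat.counts[mat.counts.k >= k_min]
    for barcode, grp in cov.groupby("barcode"):
        out[str(barcode)] = {(c, int(p), s) for c, p, s in
                             zip(grp.chrom, grp.pos, grp.strand)}
    for bc in mat.cells.barcode:
        out.setdefault(str(bc), set())
    return out
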