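"""End-to-end orchestration: configuration, bulk and single-cell runs.

``RunConfig`` aggregates every published threshold (FDR < 0.01, m >= 2,
k >= 10, m/k > 5%, 2-of-3 replicates, 1.5-fold over mutant, homogeneity
5 / 0.9 / 10, metagene window 500 nt) and round-trips losslessly through a
YAML config file. All randomness used by a run flows from ``seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation_io import (SiteCountTable, SnpMask, load_snp_mask,
                            load_transcript_models, read_site_counts,
                            write_calls_bed)
from .bulk_calling import BulkAudit, call_bulk_m6a, calls_to_frame
from .edit_detection import EditThresholds, call_candidate_edits
from .metagene import map_sites, region_pie, stop_codon_profile
from .sc_calling import (CellEditMatrix, call_cell_edits,
                         cluster_background_profile, profiles_to_frame,
                         read_cell_matrix, remove_bulk_background_sc,
                         subtract_cluster_background, summarize_counts)
from .stoichiometry import (find_homogeneous_sites, mk_histogram,
                            records_from_profiles)
from .bulk_calling import intersect_replicates, union_replicates

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    # per-site filters
    fdr_max: float = 0.01
    m_min: int = 2
    k_min: int = 10
    ratio_min: float = 0.05
    error_rate: float = 1e-3
    # replicate / control rules
    min_rep: int = 2
    fold_min: float = 1.5
    # homogeneity heuristic
    homog_n_other: int = 5
    homog_ratio_below: float = 0.9
    homog_k_min: int = 10
    # metagene
    metagene_window: int = 500
    metagene_bin: int = 25
    # run plumbing
    seed: int = 42
    outdir: str = "results/run"
    # input paths (optional; filled by CLI or caller)
    gtf: str | None = None
    snp_mask: list[str] = field(default_factory=list)
    yth: list[str] = field(default_factory=list)
    mut: list[str] = field(default_factory=list)
    wt: list[str] = field(default_factory=list)
    apobec: list[str] = field(default_factory=list)
    yth_cells: str | None = None
    mut_cells: str | None = None
    clusters: str | None = None

    def thresholds(self) -> EditThresholds:
        return EditThresholds(self.fdr_max, self.m_min, self.k_min,
                              self.ratio_min, self.error_rate)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _load_edit_sets(paths, thr, mask):
    sets = []
    for path in paths:
        for table in read_site_counts(path):
            sets.append(call_candidate_edits(table, thr, mask))
    return sets


@dataclass
class BulkResult:
    calls: dict
    audit: BulkAudit
    region_fractions: pd.DataFrame | None = None
    profile: pd.DataFrame | None = None
    peak_offset: float | None = None


def run_bulk_from_tables(yth_tables: list[SiteCountTable],
                         mut_tables: list[SiteCountTable],
                         wt_tables: list[SiteCountTable],
                         apobec_tables: list[SiteCountTable],
                         config: RunConfig,
                         mask: SnpMask | None = None,
                         ts=None) -> BulkResult:
    """Library entry point for the bulk pipeline on in-memory tables."""
    thr = config.thresholds()
    yth = [call_candidate_edits(t, thr, mask) for t in yth_tables]
    mut = [call_candidate_edits(t, thr, mask) for t in mut_tables]
    wt = [call_candidate_edits(t, thr, mask) for t in wt_tables]
    ap = [call_candidate_edits(t, thr, mask) for t in apobec_tables]
    calls, audit = call_bulk_m6a(yth, mut, wt, ap, min_rep=config.min_rep,
                                 fold_min=config.fold_min)
    result = BulkResult(calls, audit)
    if ts is not None:
        positions = map_sites(calls.keys(), ts,
                              downstream_window=config.metagene_window)
        result.region_fractions = region_pie(positions)
        profile = stop_codon_profile(positions, window=config.metagene_window,
                                     bin_width=config.metagene_bin)
        result.profile = profile.to_frame()
        result.peak_offset = profile.peak_offset
    return result


def run_bulk(config: RunConfig) -> BulkResult:
    """File-driven bulk run; writes calls BED, audit TSV and metagene
    tables under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask = load_snp_mask(config.snp_mask) if config.snp_mask else None
    ts = load_transcript_models(config.gtf) if config.gtf else None

    def tables(paths):
        out = []
        for p in paths:
            out.extend(read_site_counts(p))
        return out

    result = run_bulk_from_tables(tables(config.yth), tables(config.mut),
                                  tables(config.wt), tables(config.apobec),
                                  config, mask, ts)
    write_calls_bed(result.calls, outdir / "m6a_calls.bed")
    calls_to_frame(result.calls).to_csv(outdir / "m6a_calls.tsv", sep="\t",
                                        index=False)
    result.audit.to_frame().to_csv(outdir / "audit.tsv", sep="\t", index=False)
    if result.region_fractions is not None:
        result.region_fractions.to_csv(outdir / "region_fractions.tsv",
                                       sep="\t", index=False)
        result.profile.to_csv(outdir / "stop_codon_profile.tsv", sep="\t",
                              index=False)
    _write_run_log(outdir, config)
    return result


@dataclass
class ScResult:
    profiles: list
    summaries: dict[str, pd.DataFrame]
    homogeneous: object
    histogram: pd.DataFrame
    candidates_per_cell: dict | None = None
    after_bulk_controls: dict | None = None


def run_sc_from_data(yth_cells: CellEditMatrix, mut_cells: CellEditMatrix,
                     mut_tables: list[SiteCountTable],
                     wt_tables: list[SiteCountTable],
                     apobec_tables: list[SiteCountTable],
                     config: RunConfig,
                     mask: SnpMask | None = None) -> ScResult:
    """Single-cell pipeline: per-cell calling, bulk-control removal,
    cluster-specific mutant background subtraction, summaries and the
    homogeneous-site heuristic."""
    thr = config.thresholds()
    candidates = call_cell_edits(yth_cells, thr, mask)

    bulk_mut_sets = [call_candidate_edits(t, thr, mask) for t in mut_tables]
    bulk_mut = intersect_replicates(
        bulk_mut_sets, min_rep=min(config.min_rep, len(bulk_mut_sets)))
    wt_keys = union_replicates(
        [call_candidate_edits(t, thr, mask) for t in wt_tables])
    ap_keys = union_replicates(
        [call_candidate_edits(t, thr, mask) for t in apobec_tables])
    cleaned = remove_bulk_background_sc(candidates, wt_keys, ap_keys,
                                        bulk_mut, fold_min=config.fold_min)

    bg = cluster_background_profile(mut_cells, k_min=config.k_min, mask=mask,
                                    exclude=set(wt_keys) | set(ap_keys))
    profiles = subtract_cluster_background(cleaned, bg,
                                           yth_cells.cluster_of(), thr)

    cell_types = None
    if "cell_type" in yth_cells.cells.columns:
        cell_types = dict(zip(yth_cells.cells.barcode,
                              yth_cells.cells.cell_type))
    summaries = summarize_counts(profiles, cell_types)
    records = records_from_profiles(profiles)
    homogeneous = find_homogeneous_sites(records,
                                         n_other_min=config.homog_n_other,
                                         ratio_below=config.homog_ratio_below,
                                         k_min=config.homog_k_min)
    hist = mk_histogram(records, min_ratio=config.ratio_min,
                        min_k=config.k_min)
    return ScResult(profiles, summaries, homogeneous, hist,
                    candidates_per_cell=candidates,
                    after_bulk_controls=cleaned)


def run_sc(config: RunConfig) -> ScResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mask = load_snp_mask(config.snp_mask) if config.snp_mask else None
    yth_cells = read_cell_matrix(config.yth_cells, config.clusters)
    mut_cells = read_cell_matrix(config.mut_cells, config.clusters)

    def tables(paths):
        out = []
        for p in paths:
            out.extend(read_site_counts(p))
        return out

    result = run_sc_from_data(yth_cells, mut_cells, tables(config.mut),
                              tables(config.wt), tables(config.apobec),
                              config, mask)
    profiles_to_frame(result.profiles).to_csv(outdir / "cell_calls.tsv",
                                              sep="\t", index=False)
    for name, df in result.summaries.items():
        df.to_csv(outdir / f"summary_{name}.tsv", sep="\t", index=False)
    result.homogeneous.to_frame().to_csv(outdir / "homogeneous_sites.tsv",
                                         sep="\t", index=False)
    result.histogram.to_csv(outdir / "mk_histogram.tsv", sep="\t", index=False)
    _write_run_log(outdir, config)
    return result


def _write_run_log(outdir: Path, config: RunConfig) -> None:
    log = {"dartcall_version": __version__,
           "config_hash": config.config_hash(),
           "seed": config.seed}
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
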