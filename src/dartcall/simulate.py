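"""Ground-truthed synthetic DART-seq count data.

The generator emulates the statistical structure the calling pipeline
assumes: a small multi-exon transcriptome, m6A sites planted near the stop
codon (offset ~ Normal(+118, 30) nt by default) with per-site stoichiometry
pi, germline SNPs (edited-looking with ratio ~1 in every condition),
condition-independent deamination-prone "artifact" sites that reproduce the
WT/APOBEC1 background calls, a uniform nonspecific editing rate for every
APOBEC1-bearing condition (scaled per cluster in single-cell mode), and
negative-binomial coverage.

Counts at a site are drawn as k ~ NegBin(mu, phi) and m ~ Binomial(k, p)
with

    p = clamp(e + b_cond + [YTH] * pi * eta)   at planted m6A sites,
    p = 1 - e                                  at SNPs (every condition),
    p = clamp(e + b_cond + rate)               at artifact sites,
    p = e + b_cond                             elsewhere,

where e is the sequencing error rate, b_cond the condition's nonspecific
editing rate (0 for WT) and eta the editing efficiency. In single-cell mode
b is scaled by the cluster's multiplier lambda, and at a planted m6A site a
cell is "homogeneous" with probability h (then p = 1 - e, so m = k up to
sequencing error) and heterogeneous otherwise.

Everything is reproducible from (parameters, seed) alone; all derived
random streams use integer seed sequences below 2**31.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import (CONDITIONS, SiteCountTable, TranscriptModel,
                            TranscriptSet, write_fasta, write_gtf,
                            write_snp_vcf)
from .sc_calling import CellEditMatrix

_COND_CODE = {c: i for i, c in enumerate(CONDITIONS)}

DEFAULT_E = 1e-3        # per-base sequencing error (Q30 scale)
DEFAULT_B_BG = 5e-3     # nonspecific deamination of APOBEC1-bearing constructs
DEFAULT_MU = 50.0       # negative-binomial coverage mean
DEFAULT_PHI = 0.5       # negative-binomial dispersion (size parameter)
# Deamination-prone background sites must be detectable in every control
# sample at typical coverage (that is what makes them background *calls*);
# 0.25 keeps them comfortably above the m >= 2 / ratio > 5% floor at k ~ 10.
DEFAULT_ARTIFACT_RATE = 0.25


# ---------------------------------------------------------------------------
# Transcriptome generation
# ---------------------------------------------------------------------------

@dataclass
class TranscriptomeParams:
    n_genes: int = 80
    isoforms_per_gene: int = 1
    utr5_range: tuple[int, int] = (100, 250)
    cds_codons: tuple[int, int] = (200, 500)
    utr3_range: tuple[int, int] = (600, 1200)
    exons_range: tuple[int, int] = (1, 4)
    intron_range: tuple[int, int] = (100, 400)
    intergenic_range: tuple[int, int] = (200, 500)
    n_chroms: int = 2

    def __post_init__(self):
        for lo, hi in (self.utr5_range, self.cds_codons, self.utr3_range,
                       self.exons_range, self.intron_range,
                       self.intergenic_range):
            if not (0 < lo <= hi):
                raise ValueError("infeasible length parameters")
        if self.n_genes <= 0 or self.isoforms_per_gene <= 0:
            raise ValueError("n_genes and isoforms_per_gene must be positive")


def generate_transcriptome(params: TranscriptomeParams | None = None,
                           seed: int = 0,
                           ) -> tuple[TranscriptSet, dict[str, str]]:
    """Random multi-exon coding transcripts on both strands.

    Extra isoforms share the primary structure with a truncated 3'UTR, so
    mature lengths differ and the longest-isoform rule is exercised.
    Returns the transcript set and the genome sequences (chrom -> str).
    """
    p = params or TranscriptomeParams()
    rng = np.random.default_rng([seed, 1])
    models: list[TranscriptModel] = []
    chrom_parts: dict[str, list[str]] = {f"chr{i+1}": [] for i in range(p.n_chroms)}
    cursors = {c: 0 for c in chrom_parts}
    bases = np.array(list("ACGT"))

    for g in range(p.n_genes):
        chrom = f"chr{(g % p.n_chroms) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        utr5 = int(rng.integers(*p.utr5_range, endpoint=True))
        cds_len = 3 * int(rng.integers(*p.cds_codons, endpoint=True))
        utr3 = int(rng.integers(*p.utr3_range, endpoint=True))
        mature = utr5 + cds_len + utr3
        n_exons = int(rng.integers(*p.exons_range, endpoint=True))
        # mature breakpoints -> exon block lengths
        if n_exons > 1:
            cuts = np.sort(rng.choice(np.arange(1, mature), n_exons - 1,
                                      replace=False))
            blocks = np.diff(np.concatenate([[0], cuts, [mature]])).tolist()
        else:
            blocks = [mature]
        introns = [int(rng.integers(*p.intron_range, endpoint=True))
                   for _ in range(n_exons - 1)]

        gap = int(rng.integers(*p.intergenic_range, endpoint=True))
        gene_start = cursors[chrom] + gap
        # genomic exon layout; for "-" the first mature block is rightmost
        genomic_blocks = blocks if strand == "+" else blocks[::-1]
        genomic_introns = introns if strand == "+" else introns[::-1]
        exons = []
        pos = gene_start
        for i, b in enumerate(genomic_blocks):
            exons.append((pos, pos + b))
            pos += b
            if i < len(genomic_introns):
                pos += genomic_introns[i]
        gene_end = pos
        cursors[chrom] = gene_end
        chrom_parts[chrom].append("".join(
            rng.choice(bases, size=gap + gene_end - gene_start)))

        gene_id = f"gene{g + 1:04d}"
        shell = TranscriptModel(f"{gene_id}.t1", gene_id, chrom, strand,
                                tuple(exons))
        c0, c1 = utr5, utr5 + cds_len
        g0 = shell.mature_to_genomic(c0)
        g1 = shell.mature_to_genomic(c1 - 1)
        cds_start, cds_end = min(g0, g1), max(g0, g1) + 1
        models.append(TranscriptModel(f"{gene_id}.t1", gene_id, chrom, strand,
                                      tuple(exons), cds_start, cds_end))

        for iso in range(2, p.isoforms_per_gene + 1):
            trim = int(rng.integers(1, max(2, utr3 - 10)))
            new_mature = mature - trim
            if new_mature <= c1:
                continue
            # drop trimmed tail from the 3'-most exon(s) in mature order
            kept, acc = [], 0
            for b in blocks:
                if acc + b <= new_mature:
                    kept.append(b)
                    acc += b
                else:
                    if new_mature - acc > 0:
                        kept.append(new_mature - acc)
                        acc = new_mature
                    break
            if strand == "+":
                # trimming shortens the last kept mature block in place
                exons2 = []
                for i, b in enumerate(kept):
                    start = exons[i][0]
                    exons2.append((start, start + b))
            else:
                # mature tail is at the genomic left; rebuild right-aligned
                kept_rev = kept[::-1]
                offset = len(blocks) - len(kept)
                exons2 = []
                for i, b in enumerate(kept_rev):
                    s, e = exons[offset + i]
                    exons2.append((e - b, e))
            models.append(TranscriptModel(f"{gene_id}.t{iso}", gene_id, chrom,
                                          strand, tuple(sorted(exons2)),
                                          cds_start, cds_end))

    # pad chromosome ends so downstream-window lookups stay in bounds
    genome = {c: "".join(parts) + "".join(rng.choice(bases, size=600))
              for c, parts in chrom_parts.items()}
    return TranscriptSet(models), genome


def transcript_strand_base(genome: dict[str, str], chrom: str, pos: int,
                           strand: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    b = genome[chrom][pos]
    return b if strand == "+" else comp[b]


def enumerate_c_sites(ts: TranscriptSet, genome: dict[str, str]) -> pd.DataFrame:
    """All exonic transcript-strand cytidine positions, deduplicated on
    (chrom, pos, strand)."""
    seen = set()
    rows = []
    for tid in sorted(ts.transcripts):
        tm = ts[tid]
        seq = genome[tm.chrom]
        want = "C" if tm.strand == "+" else "G"
        for s, e in tm.exons:
            for pos in range(s, e):
                if seq[pos] == want:
                    key = (tm.chrom, pos, tm.strand)
                    if key not in seen:
                        seen.add(key)
                        rows.append(key)
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


# ---------------------------------------------------------------------------
# Truth planting
# ---------------------------------------------------------------------------

@dataclass
class CoverageModel:
    mu: float = DEFAULT_MU
    phi: float = DEFAULT_PHI


@dataclass
class TruthTable:
    """Planted ground truth against which calls are scored."""

    m6a: pd.DataFrame       # chrom pos strand gene_id transcript_id offset pi h
    snps: pd.DataFrame      # chrom pos strand
    artifacts: pd.DataFrame  # chrom pos strand rate
    e: float = DEFAULT_E
    b_cond: dict[str, float] = field(default_factory=lambda: {
        "YTH": DEFAULT_B_BG, "YTHmut": DEFAULT_B_BG,
        "APOBEC1": DEFAULT_B_BG, "WT": 0.0})
    lambda_cluster: dict[str, float] = field(default_factory=dict)
    eta: float = 1.0
    coverage: CoverageModel = field(default_factory=CoverageModel)
    seed: int = 0

    def m6a_keys(self) -> set[tuple[str, int, str]]:
        return {(r.chrom, int(r.pos), r.strand)
                for r in self.m6a.itertuples()}

    def snp_keys(self) -> set[tuple[str, int, str]]:
        return {(r.chrom, int(r.pos), r.strand)
                for r in self.snps.itertuples()}

    def artifact_keys(self) -> set[tuple[str, int, str]]:
        return {(r.chrom, int(r.pos), r.strand)
                for r in self.artifacts.itertuples()}


@dataclass
class SyntheticScenario:
    ts: TranscriptSet
    genome: dict[str, str]
    truth: TruthTable
    c_sites: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gtf(self.ts, outdir / "transcripts.gtf")
        write_fasta(self.genome, outdir / "genome.fa")
        self.truth.m6a.to_csv(outdir / "truth_m6a.tsv", sep="\t", index=False)
        self.truth.snps.to_csv(outdir / "truth_snps.tsv", sep="\t", index=False)
        self.truth.artifacts.to_csv(outdir / "truth_artifacts.tsv", sep="\t",
                                    index=False)
        write_snp_vcf([(r.chrom, int(r.pos)) for r in self.truth.snps.itertuples()],
                      outdir / "snp_mask.vcf")


def plant_truth(ts: TranscriptSet, genome: dict[str, str],
                n_m6a: int = 200,
                offset_mean: float = 118.0, offset_sd: float = 30.0,
                pi_dist=None,
                n_snps: int = 50,
                n_artifacts: int = 0,
                artifact_rate: float = DEFAULT_ARTIFACT_RATE,
                background_offset_frac: float = 0.0,
                homogeneity: list[tuple[int, float, float]] | None = None,
                window_radius: int = 0,
                seed: int = 0,
                **model_kwargs) -> TruthTable:
    """Plant m6A sites, SNPs and artifact sites on the transcriptome.

    m6A offsets from the stop codon are sampled from Normal(offset_mean,
    offset_sd) and snapped to the nearest transcript-strand C on the gene's
    longest isoform; a ``background_offset_frac`` fraction is instead placed
    uniformly along the mature transcript (sites outside the 3' region).
    ``pi_dist(rng, n)`` draws stoichiometries (default Uniform(0.2, 1]).
    ``homogeneity`` is a list of (count, h, pi) groups assigning a
    homogeneous-cell fraction h to that many planted sites (single-cell
    mode); remaining sites get h = 0. ``window_radius`` > 0 additionally
    plants the same site at neighboring Cs within the radius (stress tests).
    """
    rng = np.random.default_rng([seed, 3])
    if pi_dist is None:
        pi_dist = lambda r, n: r.uniform(0.2, 1.0, n)

    genes = [g for g in sorted(ts.genes) if ts.longest_isoform(g).is_coding]
    if not genes:
        raise ValueError("no coding genes to plant on")
    used: set[tuple[str, int, str]] = set()
    rows = []
    attempts = 0
    while len(rows) < n_m6a:
        attempts += 1
        if attempts > 50 * n_m6a:
            raise RuntimeError("m6A placement exhausted; use a larger "
                               "transcriptome or fewer sites")
        gene = genes[int(rng.integers(len(genes)))]
        tm = ts.longest_isoform(gene)
        c0, c1 = tm.cds_mature_interval()
        if rng.random() < background_offset_frac:
            target = int(rng.integers(tm.mature_length))
        else:
            target = c1 + int(round(rng.normal(offset_mean, offset_sd)))
        target = int(np.clip(target, 0, tm.mature_length - 1))
        t_site = _nearest_c(tm, genome, target)
        if t_site is None:
            continue
        gpos = tm.mature_to_genomic(t_site)
        key = (tm.chrom, gpos, tm.strand)
        if key in used:
            continue
        used.add(key)
        rows.append((tm.chrom, gpos, tm.strand, gene, tm.transcript_id,
                     t_site - c1))
        if window_radius > 0:
            for dt in range(-window_radius, window_radius + 1):
                t2 = t_site + dt
                if dt == 0 or not (0 <= t2 < tm.mature_length):
                    continue
                if _is_c(tm, genome, t2):
                    g2 = tm.mature_to_genomic(t2)
                    key2 = (tm.chrom, g2, tm.strand)
                    if key2 not in used:
                        used.add(key2)
                        rows.append((tm.chrom, g2, tm.strand, gene,
                                     tm.transcript_id, t2 - c1))

    m6a = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "gene_id",
                                      "transcript_id", "offset"])
    m6a["pi"] = pi_dist(rng, len(m6a))
    m6a["h"] = 0.0
    if homogeneity:
        idx = 0
        order = rng.permutation(len(m6a))
        for count, h, pi in homogeneity:
            take = order[idx:idx + count]
            idx += count
            m6a.loc[m6a.index[take], "h"] = h
            m6a.loc[m6a.index[take], "pi"] = pi

    snps = _plant_uniform(ts, genome, n_snps, used, rng)
    artifacts = _plant_uniform(ts, genome, n_artifacts, used, rng)
    artifacts["rate"] = artifact_rate
    return TruthTable(m6a, snps, artifacts, seed=seed, **model_kwargs)


def _is_c(tm: TranscriptModel, genome, t: int) -> bool:
    return transcript_strand_base(genome, tm.chrom, tm.mature_to_genomic(t),
                                  tm.strand) == "C"


def _nearest_c(tm: TranscriptModel, genome, target: int) -> int | None:
    for d in range(0, tm.mature_length):
        for t in (target - d, target + d) if d else (target,):
            if 0 <= t < tm.mature_length and _is_c(tm, genome, t):
                return t
    return None


def _plant_uniform(ts, genome, n, used, rng) -> pd.DataFrame:
    genes = sorted(ts.genes)
    rows = []
    attempts = 0
    while len(rows) < n:
        attempts += 1
        if attempts > 200 * max(n, 1):
            raise RuntimeError("uniform placement exhausted")
        tm = ts.longest_isoform(genes[int(rng.integers(len(genes)))])
        t = int(rng.integers(tm.mature_length))
        if not _is_c(tm, genome, t):
            continue
        key = (tm.chrom, tm.mature_to_genomic(t), tm.strand)
        if key in used:
            continue
        used.add(key)
        rows.append(key)
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand"])


# ---------------------------------------------------------------------------
# Count simulation
# ---------------------------------------------------------------------------

def _negbin(rng: np.random.Generator, mu: float, phi: float, size: int):
    return rng.negative_binomial(phi, phi / (phi + mu), size)


def _site_probs(scenario: SyntheticScenario, condition: str,
                sites: pd.DataFrame, lam: float = 1.0,
                pi_override: np.ndarray | None = None) -> np.ndarray:
    """Per-site editing probability for one condition (bulk semantics)."""
    truth = scenario.truth
    e = truth.e
    b = truth.b_cond.get(condition, 0.0) * lam
    p = np.full(len(sites), e + b)

    index = {(c, int(q), s): i for i, (c, q, s) in
             enumerate(zip(sites.chrom, sites.pos, sites.strand))}
    if condition == "YTH":
        for j, r in enumerate(truth.m6a.itertuples()):
            i = index.get((r.chrom, int(r.pos), r.strand))
            if i is not None:
                pi = (pi_override[j] if pi_override is not None else r.pi)
                p[i] = e + b + pi * truth.eta
    for r in truth.artifacts.itertuples():
        i = index.get((r.chrom, int(r.pos), r.strand))
        if i is not None:
            p[i] = e + b + r.rate
    for r in truth.snps.itertuples():
        i = index.get((r.chrom, int(r.pos), r.strand))
        if i is not None:
            p[i] = 1.0 - e
    return np.clip(p, 0.0, 1.0)


def simulate_bulk_sample(scenario: SyntheticScenario, condition: str,
                         replicate: int,
                         sites: pd.DataFrame | None = None) -> SiteCountTable:
    """One bulk replicate: NegBin coverage and binomial editing at every
    candidate C site (rows with zero coverage are dropped)."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    truth = scenario.truth
    sites = scenario.c_sites if sites is None else sites
    rng = np.random.default_rng(
        [truth.seed % (2**31), 5, _COND_CODE[condition], replicate])
    p = _site_probs(scenario, condition, sites)
    k = _negbin(rng, truth.coverage.mu, truth.coverage.phi, len(sites))
    m = rng.binomial(k, p)
    df = sites.copy()
    df["ref"] = "C"
    df["m"] = m
    df["k"] = k
    df = df[df.k > 0].reset_index(drop=True)
    sample_id = f"{condition}_rep{replicate}"
    return SiteCountTable(sample_id, condition, replicate,
                          df[["chrom", "pos", "strand", "ref", "m", "k"]])


@dataclass
class ClusterSpec:
    name: str
    lam: float = 1.0          # background multiplier for this cluster
    n_yth: int = 30
    n_mut: int = 30
    active: set | None = None  # m6A site keys methylated here (None = all)


@dataclass
class ClusterPlan:
    clusters: list[ClusterSpec]
    mu_cell: float = DEFAULT_MU
    phi_cell: float = DEFAULT_PHI
    n_null_sites: int = 600


def simulate_cells(scenario: SyntheticScenario, plan: ClusterPlan,
                   seed: int | None = None) -> CellEditMatrix:
    """Per-cell counts over a restricted site universe (planted sites, SNPs,
    artifacts, and a random subset of null cytidines).

    YTH and YTHmut cells share cluster labels. At an active m6A site a YTH
    cell is homogeneous (p = 1 - e) with probability h and heterogeneous
    (p = e + lam * b + pi * eta) otherwise.
    """
    truth = scenario.truth
    seed = truth.seed if seed is None else seed
    seed = seed % (2**31)
    rng_univ = np.random.default_rng([seed, 11])

    planted = pd.concat([truth.m6a[["chrom", "pos", "strand"]],
                         truth.snps[["chrom", "pos", "strand"]],
                         truth.artifacts[["chrom", "pos", "strand"]]],
                        ignore_index=True)
    planted_keys = set(map(tuple, planted.to_numpy()))
    null_pool = scenario.c_sites[
        ~scenario.c_sites.apply(tuple, axis=1).isin(planted_keys)]
    n_null = min(plan.n_null_sites, len(null_pool))
    null_sites = null_pool.iloc[
        np.sort(rng_univ.choice(len(null_pool), n_null, replace=False))]
    sites = pd.concat([planted, null_sites], ignore_index=True)
    sites = sites.drop_duplicates().reset_index(drop=True)
    n_sites = len(sites)

    index = {(c, int(q), s): i for i, (c, q, s) in
             enumerate(zip(sites.chrom, sites.pos, sites.strand))}
    m6a_idx = np.array([index[(r.chrom, int(r.pos), r.strand)]
                        for r in truth.m6a.itertuples()], dtype=int)
    m6a_pi = truth.m6a.pi.to_numpy()
    m6a_h = truth.m6a.h.to_numpy()
    snp_idx = np.array([index[k] for k in truth.snp_keys()], dtype=int)
    art_idx = np.array([index[(r.chrom, int(r.pos), r.strand)]
                        for r in truth.artifacts.itertuples()], dtype=int)
    art_rate = truth.artifacts.rate.to_numpy() if len(truth.artifacts) else np.array([])

    e, eta = truth.e, truth.eta
    cell_rows, count_frames = [], []
    for ci, cl in enumerate(plan.clusters):
        b = truth.b_cond["YTH"] * cl.lam
        active = np.ones(len(m6a_idx), dtype=bool)
        if cl.active is not None:
            keys = [(r.chrom, int(r.pos), r.strand)
                    for r in truth.m6a.itertuples()]
            active = np.array([k in cl.active for k in keys])
        for condition, n_cells in (("YTH", cl.n_yth), ("YTHmut", cl.n_mut)):
            for j in range(n_cells):
                barcode = f"{condition}_{cl.name}_c{j:03d}"
                cell_rows.append((barcode, condition, cl.name))
                rng = np.random.default_rng(
                    [seed, 13, ci, _COND_CODE[condition], j])
                p = np.full(n_sites, e + b)
                if condition == "YTH" and len(m6a_idx):
                    homog = rng.random(len(m6a_idx)) < m6a_h
                    p_site = np.where(homog & active, 1.0 - e,
                                      np.where(active,
                                               e + b + m6a_pi * eta, e + b))
                    p[m6a_idx] = p_site
                if len(art_idx):
                    p[art_idx] = e + b + art_rate
                if len(snp_idx):
                    p[snp_idx] = 1.0 - e
                p = np.clip(p, 0.0, 1.0)
                k = _negbin(rng, plan.mu_cell, plan.phi_cell, n_sites)
                m = rng.binomial(k, p)
                nz = k > 0
                df = sites.loc[nz].copy()
                df.insert(0, "barcode", barcode)
                df["ref"] = "C"
                df["m"] = m[nz]
                df["k"] = k[nz]
                count_frames.append(df)

    cells = pd.DataFrame(cell_rows, columns=["barcode", "condition", "cluster"])
    counts = pd.concat(count_frames, ignore_index=True)
    return CellEditMatrix(cells, counts[["barcode", "chrom", "pos", "strand",
                                         "ref", "m", "k"]])


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def bulk_basic(seed: int = 42) -> tuple[SyntheticScenario,
                                        dict[str, list[SiteCountTable]]]:
    """Bulk study conditions: 200 planted m6A (pi ~ U[0.2, 1], ~80% in the
    3' region), 50 SNPs, 100 condition-independent background sites, three
    replicates of each of YTH / YTHmut / APOBEC1 / WT at mu = 50 coverage."""
    seed = seed % (2**31)
    ts, genome = generate_transcriptome(TranscriptomeParams(n_genes=80),
                                        seed=seed)
    truth = plant_truth(ts, genome, n_m6a=200, n_snps=50, n_artifacts=100,
                        background_offset_frac=0.2, seed=seed)
    scenario = SyntheticScenario(ts, genome, truth, enumerate_c_sites(ts, genome))
    samples = {cond: [simulate_bulk_sample(scenario, cond, rep)
                      for rep in (1, 2, 3)] for cond in CONDITIONS}
    return scenario, samples


def sc_clusters(seed: int = 42) -> tuple[SyntheticScenario, CellEditMatrix,
                                         ClusterPlan,
                                         dict[str, list[SiteCountTable]]]:
    """Single-cell study conditions: four clusters (one with a 5x nonspecific
    background), 30 YTH + 30 YTHmut cells each; 60 planted m6A of which 15
    are homogeneous-in-some-cells (h = 0.3, pi = 0.5) and 10 SNP-mimics
    (h = 1); 50 masked SNPs and 30 artifact sites; bulk control replicates
    simulated on the same site universe."""
    seed = seed % (2**31)
    ts, genome = generate_transcriptome(TranscriptomeParams(n_genes=40),
                                        seed=seed)
    truth = plant_truth(
        ts, genome, n_m6a=60, n_snps=50, n_artifacts=30,
        pi_dist=lambda r, n: r.uniform(0.3, 0.85, n),
        homogeneity=[(15, 0.3, 0.5), (10, 1.0, 0.5)],
        seed=seed)
    scenario = SyntheticScenario(ts, genome, truth, enumerate_c_sites(ts, genome))
    plan = ClusterPlan(
        clusters=[ClusterSpec("c1", 1.0), ClusterSpec("c2", 1.0),
                  ClusterSpec("c3", 1.0), ClusterSpec("c4", 5.0)])
    cells = simulate_cells(scenario, plan)
    cell_sites = cells.counts[["chrom", "pos", "strand"]].drop_duplicates()
    cell_sites = cell_sites.reset_index(drop=True)
    controls = {cond: [simulate_bulk_sample(scenario, cond, rep,
                                            sites=cell_sites)
                       for rep in (1, 2, 3)]
                for cond in ("YTHmut", "APOBEC1", "WT")}
    return scenario, cells, plan, controls


def ko_contrast(seed: int = 42) -> tuple[SyntheticScenario, SyntheticScenario,
                                         dict[str, list[SiteCountTable]],
                                         dict[str, list[SiteCountTable]]]:
    """Stoichiometry study: 300 sites on a pi grid {0.1, ..., 1.0} (30 per
    stratum) with e = 0, b = 0 and eta = 1 so observed m/k isolates binomial
    sampling of the stoichiometry; the METTL3-KO counterpart loses half the
    sites (pi -> 0) and halves pi at the rest."""
    seed = seed % (2**31)
    ts, genome = generate_transcriptome(TranscriptomeParams(n_genes=80),
                                        seed=seed)
    grid = np.repeat(np.round(np.arange(0.1, 1.01, 0.1), 1), 30)

    def pi_grid(rng, n):
        if n != len(grid):
            raise ValueError("grid size mismatch")
        return grid.copy()

    b0 = {c: 0.0 for c in CONDITIONS}
    truth_wt = plant_truth(ts, genome, n_m6a=len(grid), n_snps=0,
                           n_artifacts=0, pi_dist=pi_grid, seed=seed,
                           e=0.0, b_cond=b0)
    wt = SyntheticScenario(ts, genome, truth_wt, enumerate_c_sites(ts, genome))

    rng = np.random.default_rng([seed, 17])
    lost = rng.random(len(truth_wt.m6a)) < 0.5
    ko_m6a = truth_wt.m6a.copy()
    ko_m6a["pi"] = np.where(lost, 0.0, ko_m6a.pi * 0.5)
    truth_ko = TruthTable(ko_m6a, truth_wt.snps, truth_wt.artifacts,
                          e=0.0, b_cond=b0, seed=(seed + 1) % (2**31))
    ko = SyntheticScenario(ts, genome, truth_ko, wt.c_sites)

    planted = truth_wt.m6a[["chrom", "pos", "strand"]].reset_index(drop=True)
    wt_samples = {"YTH": [simulate_bulk_sample(wt, "YTH", r, sites=planted)
                          for r in (1, 2, 3)]}
    ko_samples = {"YTH": [simulate_bulk_sample(ko, "YTH", r, sites=planted)
                          for r in (1, 2, 3)]}
    return wt, ko, wt_samples, ko_samples


def metagene_sites(seed: int = 42, n_sites: int = 500,
                   offset_mean: float = 118.0, offset_sd: float = 30.0,
                   ) -> tuple[SyntheticScenario, pd.DataFrame]:
    """Site-level planting (no counts) for metagene geometry checks."""
    seed = seed % (2**31)
    ts, genome = generate_transcriptome(TranscriptomeParams(n_genes=150),
                                        seed=seed)
    truth = plant_truth(ts, genome, n_m6a=n_sites, n_snps=0, n_artifacts=0,
                        offset_mean=offset_mean, offset_sd=offset_sd,
                        seed=seed)
    scenario = SyntheticScenario(ts, genome, truth,
                                 pd.DataFrame(columns=["chrom", "pos", "strand"]))
    return scenario, truth.m6a
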