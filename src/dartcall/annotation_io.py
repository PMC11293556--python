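"""Transcript models, SNP masks and site-count I/O.

Everything downstream works in 0-based, half-open genomic coordinates.
VCF input is converted from its native 1-based convention on load; BED
output is written 0-based half-open.

The canonical interchange object is the :class:`SiteCountTable`: per-site,
per-sample stranded mismatch counts (``m`` deaminated reads out of ``k``
covering reads at a transcript-strand cytidine). Tables can be produced by
:func:`pileup_site_counts` from alignments, read from TSV, or generated
synthetically (:mod:`dartcall.simulate`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONDITIONS = ("YTH", "YTHmut", "APOBEC1", "WT")

#: TSV column order for site-count tables.
SITE_COUNT_COLUMNS = ["sample_id", "condition", "replicate",
                      "chrom", "pos", "strand", "ref", "m", "k"]


# ---------------------------------------------------------------------------
# Transcript models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript: ordered exons plus an optional CDS.

    ``exons`` are 0-based half-open genomic intervals sorted by start and
    pairwise non-overlapping. ``cds_start``/``cds_end`` (genomic, half-open
    over the CDS footprint) are ``None`` for noncoding transcripts.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"bad exon ({s},{e}) in {self.transcript_id}")
            if s < prev_end:
                raise ValueError(f"exons overlap/unsorted in {self.transcript_id}")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start/cds_end must be set together")
        if self.cds_start is not None:
            if not (self.span[0] <= self.cds_start < self.cds_end <= self.span[1]):
                raise ValueError(f"CDS outside exon span in {self.transcript_id}")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    # -- spliced-coordinate arithmetic ------------------------------------
    # Mature coordinates run 5'->3' along the transcript: position 0 is the
    # first transcribed nucleotide regardless of genomic strand.

    def genomic_to_mature(self, pos: int) -> int | None:
        """Spliced transcript coordinate of genomic ``pos``; None if intronic
        or outside the transcript span."""
        cum = 0
        for s, e in self.exons:
            if s <= pos < e:
                plus_coord = cum + (pos - s)
                if self.strand == "+":
                    return plus_coord
                return self.mature_length - 1 - plus_coord
            cum += e - s
        return None

    def mature_to_genomic(self, t: int) -> int:
        if not (0 <= t < self.mature_length):
            raise IndexError(f"mature coordinate {t} outside [0,{self.mature_length})")
        plus_coord = t if self.strand == "+" else self.mature_length - 1 - t
        cum = 0
        for s, e in self.exons:
            if plus_coord < cum + (e - s):
                return s + (plus_coord - cum)
            cum += e - s
        raise AssertionError("unreachable")

    def cds_mature_interval(self) -> tuple[int, int] | None:
        """CDS as a half-open interval in mature coordinates, or None."""
        if not self.is_coding:
            return None
        a = self.genomic_to_mature(self.cds_start)
        b = self.genomic_to_mature(self.cds_end - 1)
        if a is None or b is None:
            raise ValueError(f"CDS boundary intronic in {self.transcript_id}")
        lo, hi = min(a, b), max(a, b)
        return lo, hi + 1

    def three_prime_end(self) -> int:
        """Genomic position of the last transcribed base."""
        return self.exons[-1][1] - 1 if self.strand == "+" else self.exons[0][0]


class TranscriptSet:
    """Transcripts indexed by id, with gene->transcripts and per-gene
    longest-isoform lookup (ties broken by lexicographic transcript_id)."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.transcripts: dict[str, TranscriptModel] = {}
        self.gene_to_transcripts: dict[str, list[str]] = {}
        for tm in transcripts:
            if tm.transcript_id in self.transcripts:
                raise ValueError(f"duplicate transcript_id {tm.transcript_id}")
            self.transcripts[tm.transcript_id] = tm
            self.gene_to_transcripts.setdefault(tm.gene_id, []).append(tm.transcript_id)
        self._longest: dict[str, str] = {}
        for gene, tids in self.gene_to_transcripts.items():
            self._longest[gene] = min(
                tids, key=lambda t: (-self.transcripts[t].mature_length, t))

    def __len__(self):
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def __getitem__(self, transcript_id: str) -> TranscriptModel:
        return self.transcripts[transcript_id]

    @property
    def genes(self) -> list[str]:
        return list(self.gene_to_transcripts)

    def longest_isoform(self, gene_id: str) -> TranscriptModel:
        if gene_id not in self._longest:
            raise KeyError(f"unknown gene {gene_id!r}")
        return self.transcripts[self._longest[gene_id]]


def select_longest_isoform(ts: TranscriptSet, gene_id: str) -> TranscriptModel:
    """The gene's longest mature isoform (lexicographic id on ties)."""
    return ts.longest_isoform(gene_id)


def load_transcript_models(gtf_path: str | Path) -> TranscriptSet:
    """Build a :class:`TranscriptSet` from a GTF with exon/CDS features.

    Transcripts without exon features are skipped with a warning.
    """
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(gtf_path), ":memory:",
            force=True, keep_order=True, merge_strategy="create_unique",
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
    except EmptyInputError:
        return TranscriptSet([])
    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes["gene_id"][0]
        except KeyError:
            logger.warning("feature without transcript_id/gene_id skipped: %s", feat)
            continue
        rec = per_tx.setdefault(tid, {"gene": gid, "chrom": feat.seqid,
                                      "strand": feat.strand, "exons": [], "cds": []})
        iv = (feat.start - 1, feat.end)  # GTF is 1-based inclusive
        rec["exons" if feat.featuretype == "exon" else "cds"].append(iv)

    models = []
    for tid, rec in per_tx.items():
        if not rec["exons"]:
            logger.warning("transcript %s has no exon features; skipped", tid)
            continue
        exons = tuple(sorted(rec["exons"]))
        cds_start = cds_end = None
        if rec["cds"]:
            cds_start = min(s for s, _ in rec["cds"])
            cds_end = max(e for _, e in rec["cds"])
        try:
            models.append(TranscriptModel(tid, rec["gene"], rec["chrom"],
                                          rec["strand"], exons, cds_start, cds_end))
        except ValueError as exc:
            logger.warning("transcript %s invalid (%s); skipped", tid, exc)
    return TranscriptSet(models)


# ---------------------------------------------------------------------------
# SNP mask
# ---------------------------------------------------------------------------

class SnpMask:
    """Set of (chrom, 0-based position) pairs excluded from edit calling."""

    def __init__(self, positions: Iterable[tuple[str, int]] = ()):
        self._set = frozenset((c, int(p)) for c, p in positions)
        if any(p < 0 for _, p in self._set):
            raise ValueError("negative position in SNP mask")

    def __contains__(self, item) -> bool:
        # Accept (chrom, pos) or (chrom, pos, strand) keys.
        if len(item) == 3:
            item = (item[0], item[1])
        return (item[0], int(item[1])) in self._set

    def __len__(self):
        return len(self._set)

    def __or__(self, other: "SnpMask") -> "SnpMask":
        return SnpMask(self._set | other._set)


def load_snp_mask(vcf_paths: str | Path | Iterable[str | Path]) -> SnpMask:
    """Union SNP mask from one or more VCFs (1-based POS converted to 0-based)."""
    from cyvcf2 import VCF

    if isinstance(vcf_paths, (str, Path)):
        vcf_paths = [vcf_paths]
    positions: set[tuple[str, int]] = set()
    for path in vcf_paths:
        vcf = VCF(str(path))
        try:
            for rec in vcf:
                try:
                    positions.add((rec.CHROM, rec.POS - 1))
                except Exception as exc:  # malformed row
                    logger.warning("skipping malformed VCF row in %s: %s", path, exc)
        finally:
            vcf.close()
    return SnpMask(positions)


def write_snp_vcf(positions: Iterable[tuple[str, int]], path: str | Path,
                  ref: str = "C", alt: str = "T") -> None:
    """Write a minimal VCF (0-based inputs -> 1-based POS) usable as a mask."""
    rows = sorted(set(positions))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dartcall\n")
        chroms = sorted({c for c, _ in rows})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos in rows:
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# Site-count tables
# ---------------------------------------------------------------------------

@dataclass
class SiteCountTable:
    """Per-sample stranded mismatch counts at cytidine positions.

    ``df`` columns: chrom (str), pos (int, 0-based), strand, ref, m, k.
    ``replicate`` is an integer for bulk samples or a cell barcode string.
    """

    sample_id: str
    condition: str
    replicate: int | str
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        self.df = self.df.reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = {"chrom", "pos", "strand", "ref", "m", "k"} - set(df.columns)
        if missing:
            raise ValueError(f"missing columns {missing}")
        bad = df.index[(df.m < 0) | (df.m > df.k) | (df.k <= 0)]
        if len(bad):
            raise ValueError(f"invalid counts (need 0 <= m <= k, k > 0) at row {bad[0]}")
        bad = df.index[df.ref != "C"]
        if len(bad):
            raise ValueError(f"non-C reference base at row {bad[0]}")
        if df.duplicated(["chrom", "pos", "strand"]).any():
            raise ValueError("duplicate (chrom,pos,strand) rows")

    def __len__(self):
        return len(self.df)


def read_site_counts(path: str | Path) -> list[SiteCountTable]:
    """Read a site-count TSV; one table per (sample_id) in file order."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "replicate": str})
    missing = set(SITE_COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    tables = []
    for sample_id, sub in df.groupby("sample_id", sort=False):
        cond = sub.condition.iloc[0]
        rep_raw = sub.replicate.iloc[0]
        rep: int | str = int(rep_raw) if str(rep_raw).isdigit() else str(rep_raw)
        tables.append(SiteCountTable(
            str(sample_id), cond, rep,
            sub[["chrom", "pos", "strand", "ref", "m", "k"]].copy()))
    return tables


def write_site_counts(tables: SiteCountTable | Iterable[SiteCountTable],
                      path: str | Path) -> None:
    if isinstance(tables, SiteCountTable):
        tables = [tables]
    frames = []
    for t in tables:
        d = t.df.copy()
        d.insert(0, "sample_id", t.sample_id)
        d.insert(1, "condition", t.condition)
        d.insert(2, "replicate", t.replicate)
        frames.append(d[SITE_COUNT_COLUMNS])
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_calls_bed(calls, path: str | Path) -> None:
    """Write calls as BED6: 0-based half-open, name = gene|provenance,
    score = round(1000 * m/k)."""
    rows = []
    for key, call in sorted(calls.items()):
        chrom, pos, strand = key
        gene = getattr(call, "gene_id", None) or "."
        prov = getattr(call, "provenance", "") or "edit"
        rows.append((chrom, pos, pos + 1, f"{gene}|{prov}",
                     int(round(1000 * call.ratio)), strand))
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(map(str, r)) + "\n")


# ---------------------------------------------------------------------------
# Pileup from alignments (optional input path)
# ---------------------------------------------------------------------------

@dataclass
class PileupConfig:
    min_base_quality: int = 20   # matches the <Q20 trimming convention
    min_mapping_quality: int = 10
    sample_id: str = "sample"
    condition: str = "YTH"
    replicate: int | str = 1


def pileup_site_counts(alignments: str | Path, reference: str | Path,
                       config: PileupConfig | None = None,
                       ts: TranscriptSet | None = None) -> SiteCountTable:
    """Count deaminated reads per reference cytidine from a coordinate-sorted,
    indexed BAM.

    Editing is counted on the transcript strand: genomic C with T reads on
    "+", genomic G with A reads on "-". When a transcript set is given, only
    annotated strands are evaluated at each position; otherwise both strands
    are emitted where covered. Duplicate-flagged, secondary and QC-fail reads
    are excluded (pysam pileup defaults).
    """
    import pysam

    config = config or PileupConfig()
    fasta = pysam.FastaFile(str(reference))
    bam = pysam.AlignmentFile(str(alignments))

    annotated: dict[str, set[str]] | None = None
    if ts is not None:
        annotated = {}
        for tm in ts:
            for s, e in tm.exons:
                for p in range(s, e):
                    annotated.setdefault(f"{tm.chrom}:{p}", set()).add(tm.strand)

    rows = []
    for contig in bam.references:
        if contig not in fasta.references:
            raise ValueError(f"contig {contig!r} absent from reference FASTA")
        seq = fasta.fetch(contig).upper()
        for col in bam.pileup(contig,
                              min_base_quality=config.min_base_quality,
                              min_mapping_quality=config.min_mapping_quality,
                              truncate=False, stepper="all"):
            pos = col.reference_pos
            ref = seq[pos] if pos < len(seq) else "N"
            strands = []
            if ref == "C":
                strands.append(("+", "T"))
            if ref == "G":
                strands.append(("-", "A"))
            if not strands:
                continue
            if annotated is not None:
                allowed = annotated.get(f"{contig}:{pos}")
                if allowed is not None:
                    strands = [sd for sd in strands if sd[0] in allowed]
            bases = [b.upper() for b in
                     col.get_query_sequences(add_indels=False) if b]
            k = len(bases)
            if k == 0:
                continue
            for strand, edited_base in strands:
                m = sum(1 for b in bases if b == edited_base)
                rows.append((contig, pos, strand, "C", m, k))
    bam.close()
    fasta.close()
    df = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "ref", "m", "k"])
    return SiteCountTable(config.sample_id, config.condition, config.replicate, df)


def write_gtf(ts: TranscriptSet, path: str | Path, source: str = "dartcall") -> None:
    """Write exon and CDS features (GTF, 1-based inclusive)."""
    with open(path, "w") as fh:
        for tid in sorted(ts.transcripts):
            tm = ts[tid]
            attrs = f'gene_id "{tm.gene_id}"; transcript_id "{tm.transcript_id}";'
            for s, e in tm.exons:
                fh.write(f"{tm.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                         f"{tm.strand}\t.\t{attrs}\n")
            if tm.is_coding:
                for s, e in tm.exons:
                    cs, ce = max(s, tm.cds_start), min(e, tm.cds_end)
                    if cs < ce:
                        fh.write(f"{tm.chrom}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t"
                                 f"{tm.strand}\t0\t{attrs}\n")


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
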