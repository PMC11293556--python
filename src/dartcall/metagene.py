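"""Transcript meta-coordinates: region labels, stop-codon profiles, overlaps.

Sites are mapped onto the longest isoform of the gene whose exons contain
them (spliced coordinates, introns excluded). Offset 0 is the first
nucleotide 3' of the stop codon's last base; negative offsets lie inside
the CDS/5'UTR, positive offsets in the 3'UTR. Sites up to ``window`` nt
downstream of an annotated 3' end (genomic, strand-aware) are classified
``TTS_downstream`` and included in profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation_io import TranscriptModel, TranscriptSet
from .edit_detection import SiteKey

logger = logging.getLogger(__name__)

REGIONS = ("5'UTR", "CDS", "3'UTR", "ncRNA", "TTS_downstream")


@dataclass(frozen=True)
class MetaPosition:
    key: SiteKey
    transcript_id: str
    gene_id: str
    region: str
    offset_from_stop: int | None      # None for ncRNA
    scaled_position: float | None     # [0,3): 5'UTR/CDS/3'UTR thirds


class TranscriptLocator:
    """Chromosome interval index over transcript exon spans (plus a
    downstream margin for TTS classification)."""

    def __init__(self, ts: TranscriptSet, downstream: int = 500):
        self.ts = ts
        self.downstream = downstream
        self._trees: dict[str, IntervalTree] = {}
        for tm in ts:
            tree = self._trees.setdefault(tm.chrom, IntervalTree())
            s, e = tm.span
            if tm.strand == "+":
                tree.addi(s, e + downstream, tm.transcript_id)
            else:
                tree.addi(max(0, s - downstream), e, tm.transcript_id)

    def candidates(self, chrom: str, pos: int, strand: str | None = None
                   ) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self.ts[iv.data] for iv in tree.at(pos)]
        if strand is not None:
            hits = [tm for tm in hits if tm.strand == strand]
        return hits


def map_to_transcript(key: SiteKey, ts: TranscriptSet,
                      locator: TranscriptLocator | None = None,
                      downstream_window: int = 500) -> MetaPosition | None:
    """Meta-coordinates of a genomic site, or None for intergenic sites.

    Among transcripts whose exons contain the site, the longest isoform is
    chosen (ties by lexicographic id). A site that is intronic in every
    containing isoform is classified ``intronic`` (excluded from profiles);
    one that only falls in a downstream margin becomes ``TTS_downstream``.
    """
    chrom, pos, strand = key
    locator = locator or TranscriptLocator(ts, downstream=downstream_window)
    cands = locator.candidates(chrom, pos, strand)
    if not cands:
        return None

    exonic = [tm for tm in cands if tm.genomic_to_mature(pos) is not None]
    if exonic:
        tm = min(exonic, key=lambda t: (-t.mature_length, t.transcript_id))
        t = tm.genomic_to_mature(pos)
        return _meta_from_mature(key, tm, t)

    spanned = [tm for tm in cands if tm.span[0] <= pos < tm.span[1]]
    if spanned:
        tm = min(spanned, key=lambda t: (-t.mature_length, t.transcript_id))
        logger.debug("site %s intronic in all containing isoforms", key)
        return MetaPosition(key, tm.transcript_id, tm.gene_id, "intronic",
                            None, None)

    # downstream margin only
    def downstream_dist(tm: TranscriptModel) -> int:
        end = tm.three_prime_end()
        return pos - end if tm.strand == "+" else end - pos

    past = [tm for tm in cands if downstream_dist(tm) > 0]
    if not past:
        return None
    tm = min(past, key=lambda t: (-t.mature_length, t.transcript_id))
    d = downstream_dist(tm)
    cds = tm.cds_mature_interval()
    if cds is None:
        return MetaPosition(key, tm.transcript_id, tm.gene_id, "ncRNA",
                            None, None)
    offset = (tm.mature_length - cds[1]) + d
    return MetaPosition(key, tm.transcript_id, tm.gene_id, "TTS_downstream",
                        int(offset), None)


def _meta_from_mature(key: SiteKey, tm: TranscriptModel, t: int) -> MetaPosition:
    cds = tm.cds_mature_interval()
    if cds is None:
        return MetaPosition(key, tm.transcript_id, tm.gene_id, "ncRNA",
                            None, None)
    c0, c1 = cds
    offset = t - c1
    if t < c0:
        region = "5'UTR"
        scaled = t / c0 if c0 > 0 else 0.0
    elif t < c1:
        region = "CDS"
        scaled = 1.0 + (t - c0) / (c1 - c0)
    else:
        region = "3'UTR"
        utr3 = tm.mature_length - c1
        scaled = 2.0 + (t - c1) / utr3 if utr3 > 0 else 2.0
    return MetaPosition(key, tm.transcript_id, tm.gene_id, region,
                        int(offset), float(min(scaled, 3.0 - 1e-9)))


def map_sites(keys: Iterable[SiteKey], ts: TranscriptSet,
              downstream_window: int = 500) -> list[MetaPosition]:
    locator = TranscriptLocator(ts, downstream=downstream_window)
    out = []
    for key in keys:
        mp = map_to_transcript(key, ts, locator,
                               downstream_window=downstream_window)
        if mp is not None:
            out.append(mp)
    return out


def region_pie(positions: Iterable[MetaPosition]) -> pd.DataFrame:
    """Fraction of mapped sites per region (classified sites only; the
    fractions sum to 1)."""
    counts: dict[str, int] = {}
    for mp in positions:
        if mp.region == "intronic":
            continue
        counts[mp.region] = counts.get(mp.region, 0) + 1
    total = sum(counts.values())
    rows = [(r, n, n / total) for r, n in sorted(counts.items())] if total else []
    return pd.DataFrame(rows, columns=["region", "n_sites", "fraction"])


@dataclass
class MetageneProfile:
    bin_edges: np.ndarray
    counts: np.ndarray
    normalized: np.ndarray
    peak_offset: float | None
    n_in_window: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_start": self.bin_edges[:-1].astype(int),
            "bin_end": self.bin_edges[1:].astype(int),
            "count": self.counts,
            "normalized": self.normalized,
        })


def stop_codon_profile(positions: Iterable[MetaPosition],
                       window: int = 500, bin_width: int = 25,
                       ) -> MetageneProfile:
    """Binned site density over [-window, +window] nt around the stop codon
    (offset 0 = first nt 3' of the stop). ncRNA/intronic sites are excluded.
    ``peak_offset`` is the midpoint of the modal bin (smallest offset wins
    ties); counts are also max-normalized for overlaying groups."""
    offsets = np.array([mp.offset_from_stop for mp in positions
                        if mp.offset_from_stop is not None
                        and mp.region not in ("ncRNA", "intronic")])
    edges = np.arange(-window, window + bin_width, bin_width)
    if len(offsets):
        in_win = offsets[(offsets >= -window) & (offsets < edges[-1])]
        counts, _ = np.histogram(in_win, bins=edges)
    else:
        in_win = offsets
        counts = np.zeros(len(edges) - 1, dtype=int)
    maxc = counts.max() if len(counts) else 0
    normalized = counts / maxc if maxc > 0 else counts.astype(float)
    peak = None
    if maxc > 0:
        i = int(np.argmax(counts))
        peak = float((edges[i] + edges[i + 1]) / 2)
    return MetageneProfile(edges, counts, normalized, peak, int(len(in_win)))


# ---------------------------------------------------------------------------
# Gene-level set overlaps
# ---------------------------------------------------------------------------

def _genes_of_set(items, ts: TranscriptSet, locator: TranscriptLocator) -> set[str]:
    """Reduce a set of site keys or (chrom, start, end[, strand]) regions to
    the genes they touch (regions: any overlap with a gene's exon span)."""
    genes: set[str] = set()
    for item in items:
        if len(item) == 3 and isinstance(item[2], str):      # site key
            chrom, pos, strand = item
            for tm in locator.candidates(chrom, pos, strand):
                if tm.span[0] <= pos < tm.span[1]:
                    genes.add(tm.gene_id)
        else:                                                # region
            chrom, start, end = item[0], int(item[1]), int(item[2])
            strand = item[3] if len(item) > 3 else None
            for p in (start, end - 1):
                for tm in locator.candidates(chrom, p, strand):
                    genes.add(tm.gene_id)
            tree = locator._trees.get(chrom)
            if tree is not None:
                for iv in tree.overlap(start, end):
                    tm = ts[iv.data]
                    if strand is None or tm.strand == strand:
                        genes.add(tm.gene_id)
    return genes


def gene_level_overlap(sets: dict[str, Iterable], ts: TranscriptSet
                       ) -> pd.DataFrame:
    """Venn-ready gene-set intersection counts for named site/region sets.

    Each input set is reduced to the genes containing its sites (or
    overlapping its regions); every non-empty combination of set names is
    reported with its exclusive and cumulative intersection counts.
    """
    locator = TranscriptLocator(ts, downstream=0)
    gene_sets = {name: _genes_of_set(items, ts, locator)
                 for name, items in sets.items()}
    names = list(gene_sets)
    rows = []
    from itertools import combinations
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inter = set.intersection(*(gene_sets[n] for n in combo))
            outside = set().union(*(gene_sets[n] for n in names
                                    if n not in combo)) if r < len(names) else set()
            rows.append(("&".join(combo), len(inter), len(inter - outside)))
    return pd.DataFrame(rows, columns=["sets", "n_genes", "n_exclusive"])
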