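"""Statistical detection of candidate C-to-U editing sites.

Each site is tested one-sided against a background per-base error rate with
a binomial upper tail, followed by Benjamini-Hochberg FDR control across
the sample and the hard count/coverage/ratio filters:

1. SNP-masked positions are discarded;
2. coverage k >= k_min (default 10);
3. edited reads m >= m_min (default 2);
4. binomial upper-tail p-value P[X >= m], X ~ Bin(k, e);
5. BH FDR across the sample's surviving sites, keep q < fdr_max (0.01);
6. editing ratio m/k > ratio_min (default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation_io import SiteCountTable, SnpMask

logger = logging.getLogger(__name__)

SiteKey = tuple[str, int, str]  # (chrom, pos, strand)


@dataclass(frozen=True)
class EditSite:
    chrom: str
    pos: int
    strand: str
    m: int
    k: int
    pvalue: float
    qvalue: float

    @property
    def ratio(self) -> float:
        return self.m / self.k

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.strand)


@dataclass(frozen=True)
class EditThresholds:
    """Per-site filter thresholds. Defaults follow the published criteria:
    FDR < 0.01, m >= 2, k >= 10, m/k > 5%."""

    fdr_max: float = 0.01
    m_min: int = 2
    k_min: int = 10
    ratio_min: float = 0.05
    error_rate: float = 1e-3

    def __post_init__(self):
        if not (0 < self.fdr_max <= 1):
            raise ValueError("fdr_max out of range")
        if self.m_min < 0 or self.k_min <= 0:
            raise ValueError("count thresholds out of range")
        if not (0 <= self.ratio_min < 1):
            raise ValueError("ratio_min out of range")
        if not (0 < self.error_rate < 1):
            raise ValueError("error_rate out of range")


ERROR_RATE_FLOOR = 1e-5
ERROR_RATE_CEIL = 0.05


def estimate_error_rate(table: SiteCountTable, default: float = 1e-3) -> float:
    """Pooled mismatch fraction at non-deamination positions, clamped to
    [1e-5, 0.05].

    Retained site-count rows carry only transcript-strand cytidines, so the
    sequencing-error proxy comes from optional rows whose reference base is
    not C (kept in ``table.df.attrs['other_mismatches']`` as an (m, k)
    aggregate, or supplied as extra columns ``err_m``/``err_k``). When no
    such information exists the configured default is returned with a
    warning.
    """
    df = table.df
    if "err_m" in df.columns and "err_k" in df.columns:
        m = int(df.err_m.sum())
        k = int(df.err_k.sum())
    else:
        agg = df.attrs.get("other_mismatches")
        if agg is None:
            logger.warning("no non-deamination mismatch data in %s; "
                           "using default error rate %g", table.sample_id, default)
            return default
        m, k = int(agg[0]), int(agg[1])
    if k <= 0:
        logger.warning("empty non-deamination pool in %s; using default %g",
                       table.sample_id, default)
        return default
    return float(np.clip(m / k, ERROR_RATE_FLOOR, ERROR_RATE_CEIL))


def site_pvalue(m, k, e: float):
    """Upper-tail binomial probability P[X >= m] for X ~ Binomial(k, e).

    Accepts scalars or arrays; inclusive tail, so m = 0 gives 1.0.
    """
    return stats.binom.sf(np.asarray(m) - 1, np.asarray(k), e)[()]


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    if len(pvalues) == 0:
        return np.asarray(pvalues, dtype=float)
    return multipletests(pvalues, method="fdr_bh")[1]


def call_candidate_edits(table: SiteCountTable,
                         thr: EditThresholds = EditThresholds(),
                         mask: SnpMask | None = None,
                         error_rate: float | None = None,
                         ) -> dict[SiteKey, EditSite]:
    """Apply the per-site filter cascade to one sample (or one cell).

    The FDR family is the sample's own surviving sites; the ratio filter is
    applied after FDR so the multiple-testing burden reflects only sites
    that are testable on counts alone.
    """
    e = error_rate if error_rate is not None else thr.error_rate
    df = table.df
    if len(df) == 0:
        return {}

    keep = np.ones(len(df), dtype=bool)
    if mask is not None and len(mask) > 0:
        masked = np.fromiter(((c, p) in mask for c, p in zip(df.chrom, df.pos)),
                             bool, count=len(df))
        keep &= ~masked
    keep &= df.k.to_numpy() >= thr.k_min
    keep &= df.m.to_numpy() >= thr.m_min
    sub = df.loc[keep]
    if len(sub) == 0:
        return {}

    pvals = site_pvalue(sub.m.to_numpy(), sub.k.to_numpy(), e)
    pvals = np.atleast_1d(pvals)
    # stable order by (p, chrom, pos) for deterministic BH ties
    order = np.lexsort((sub.pos.to_numpy(), sub.chrom.to_numpy(), pvals))
    qvals = np.empty_like(pvals)
    qvals[order] = bh_qvalues(pvals[order])

    ratio = sub.m.to_numpy() / sub.k.to_numpy()
    final = (qvals < thr.fdr_max) & (ratio > thr.ratio_min)

    out: dict[SiteKey, EditSite] = {}
    rows = sub.loc[final]
    for (_, row), p, q in zip(rows.iterrows(), pvals[final], qvals[final]):
        site = EditSite(row.chrom, int(row.pos), row.strand,
                        int(row.m), int(row.k), float(p), float(q))
        out[site.key] = site
    return out


def edits_to_frame(edits: dict[SiteKey, EditSite]) -> pd.DataFrame:
    rows = [(s.chrom, s.pos, s.strand, s.m, s.k, s.ratio, s.pvalue, s.qvalue)
            for s in sorted(edits.values(), key=lambda s: s.key)]
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "m", "k",
                                       "ratio", "pvalue", "qvalue"])
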