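"""Independent naive reference implementations used to cross-check the
pipeline. Deliberately written one-site-at-a-time with plain Python
arithmetic, sharing no code with the package internals."""

import math


def naive_binom_sf(m: int, k: int, e: float) -> float:
    """P[X >= m], X ~ Binomial(k, e), by explicit term summation."""
    total = 0.0
    for i in range(m, k + 1):
        total += math.comb(k, i) * (e ** i) * ((1 - e) ** (k - i))
    return min(total, 1.0)


def naive_bh(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values (sorted-rank oracle)."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        q = pvalues[i] * n / rank_from_top
        running_min = min(running_min, q)
        adjusted[i] = running_min
    return adjusted


def naive_call(rows, mask=None, fdr_max=0.01, m_min=2, k_min=10,
               ratio_min=0.05, error_rate=1e-3):
    """One-site-at-a-time candidate-edit calling.

    rows: list of (chrom, pos, strand, m, k). Returns dict key -> (m, k, p, q).
    """
    mask = mask or set()
    surviving = []
    for chrom, pos, strand, m, k in rows:
        if (chrom, pos) in mask:
            continue
        if k < k_min or m < m_min:
            continue
        surviving.append((chrom, pos, strand, m, k,
                          naive_binom_sf(m, k, error_rate)))
    qvals = naive_bh([s[5] for s in surviving])
    out = {}
    for (chrom, pos, strand, m, k, p), q in zip(surviving, qvals):
        if q < fdr_max and (m / k) > ratio_min:
            out[(chrom, pos, strand)] = (m, k, p, q)
    return out


def naive_intersect(rep_sets, min_rep=2):
    """rep_sets: list of dict key -> (m, k). Returns key -> (m, k, n)."""
    keys = set()
    for r in rep_sets:
        keys |= set(r)
    out = {}
    for key in keys:
        hits = [r[key] for r in rep_sets if key in r]
        if len(hits) >= min_rep:
            out[key] = (sum(h[0] for h in hits), sum(h[1] for h in hits),
                        len(hits))
    return out


def naive_subtract(yth, wt, apobec):
    return {k: v for k, v in yth.items() if k not in wt and k not in apobec}


def naive_fold(yth, mut, fold_min=1.5):
    """yth/mut: dict key -> (m, k, ...). Returns kept keys -> fold."""
    out = {}
    for key, v in yth.items():
        if key not in mut or mut[key][0] == 0:
            out[key] = math.inf
        else:
            my, ky = v[0], v[1]
            mm, km = mut[key][0], mut[key][1]
            # inclusive threshold checked on integer cross-products
            if my * km >= fold_min * mm * ky:
                out[key] = (my / ky) / (mm / km)
    return out


def naive_bulk_compose(yth_reps, mut_reps, wt_sets, apobec_sets,
                       min_rep=2, fold_min=1.5):
    """Full bulk composition over plain dicts; returns kept keys -> fold."""
    yth = naive_intersect(yth_reps, min_rep)
    mut = naive_intersect(mut_reps, min(min_rep, len(mut_reps)))
    wt = set().union(*[set(s) for s in wt_sets]) if wt_sets else set()
    ap = set().union(*[set(s) for s in apobec_sets]) if apobec_sets else set()
    clean = naive_subtract(yth, wt, ap)
    return naive_fold(clean, mut, fold_min)
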