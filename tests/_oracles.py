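"""Independent from-definition reimplementations used as test oracles.

Each function recomputes a published quantity straight from its printed
definition, deliberately sharing no code with the package (plain loops and
textbook formulas), so agreement is evidence of formula fidelity rather
than of shared bugs.
"""

import math

import numpy as np


def oracle_relative_occupancy(N, s, g, gr):
    """O = N / ((146*s)/(g*gr)), evaluated literally."""
    return N / ((146.0 * s) / (g * gr))


def oracle_ndr(positions, values):
    """NDR = (max(+1,-1) - center) / (max(all) - min(all)).

    +1: max over [+50, +250); -1: max over [-250, -50);
    center: mean over [-50, +50); all: the whole profile.
    """
    plus1 = max(v for p, v in zip(positions, values) if 50 <= p < 250)
    minus1 = max(v for p, v in zip(positions, values) if -250 <= p < -50)
    center_vals = [v for p, v in zip(positions, values) if -50 <= p < 50]
    center = sum(center_vals) / len(center_vals)
    rng = max(values) - min(values)
    if rng == 0:
        return 0.0
    return (max(plus1, minus1) - center) / rng


def oracle_pos(positions, values, lag=10, span=1000, bin_width=50):
    """POS = Pearson cor of 50-bp-binned profile vs its 10-bp-lagged copy."""
    def binned(start):
        out = []
        for b0 in range(start, start + span, bin_width):
            vals = [v for p, v in zip(positions, values)
                    if b0 <= p < b0 + bin_width]
            out.append(sum(vals) / len(vals))
        return out

    vi, vj = binned(0), binned(lag)
    return _pearson(vi, vj)


def _pearson(x, y):
    n = len(x)
    mx, my = sum(x) / n, sum(y) / n
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    if sxx == 0 or syy == 0:
        return 0.0
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    return sxy / math.sqrt(sxx * syy)


def oracle_dft_peak(values, resolution, band):
    """Explicit-sum DFT; period and |X|/n of the strongest band component."""
    v = [x - sum(values) / len(values) for x in values]
    n = len(v)
    best = (None, 0.0)
    for k in range(1, n // 2 + 1):
        period = n * resolution / k
        if not band[0] <= period <= band[1]:
            continue
        re = sum(v[t] * math.cos(2 * math.pi * k * t / n) for t in range(n))
        im = sum(v[t] * math.sin(2 * math.pi * k * t / n) for t in range(n))
        mag = math.hypot(re, im)
        if mag > best[1]:
            best = (period, mag)
    return best[0], best[1] / n


def oracle_enrichment_ratio(regions, elements, genome_size):
    """observed/expected overlap via per-bp set membership (small genomes)."""
    region_bp = set()
    for chrom, s, e in regions:
        region_bp |= {(chrom, p) for p in range(s, e)}
    element_bp = set()
    for chrom, s, e in elements:
        element_bp |= {(chrom, p) for p in range(s, e)}
    observed = len(region_bp & element_bp) / len(region_bp)
    expected = len(element_bp) / genome_size
    return observed / expected


def oracle_zga_enrichment(genes_with_motif, zga, all_genes):
    obs = len(genes_with_motif & zga) / len(genes_with_motif)
    exp = len(zga) / len(all_genes)
    return obs / exp


def oracle_partial_correlation_closed_form(x, y, z):
    """(r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2))."""
    r_xy = _pearson(list(x), list(y))
    r_xz = _pearson(list(x), list(z))
    r_yz = _pearson(list(y), list(z))
    return (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz ** 2) * (1 - r_yz ** 2))


def oracle_anova_f(groups):
    """One-way ANOVA F from explicit sums of squares."""
    allv = [v for g in groups for v in g]
    grand = sum(allv) / len(allv)
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def oracle_midpoint_histogram(fragments, chrom_sizes, bin_width):
    """Brute-force per-bin fragment midpoint counts (146-bp window rule)."""
    counts = {}
    for chrom, start, end in fragments:
        mid = (start + end) // 2
        a = min(max(mid - 73, 0), chrom_sizes[chrom])
        b = min(max(mid + 73, 0), chrom_sizes[chrom])
        wmid = (a + b) // 2
        key = (chrom, wmid // bin_width)
        counts[key] = counts.get(key, 0) + 1
    return counts


def oracle_bh(pvalues):
    """Benjamini-Hochberg step-up adjusted p-values, by hand."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvalues[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def random_profile(rng, upstream=2000, downstream=2000, resolution=10):
    """A seeded random nonnegative profile on the standard grid."""
    n = (upstream + downstream) // resolution
    base = rng.gamma(2.0, 1.0, size=n)
    k = max(3, int(rng.integers(3, 12)))
    kernel = np.ones(k) / k
    return np.convolve(base, kernel, mode="same")
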