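"""Quality control: fragment lengths, genome coverage, replicate pooling.

The fragment-length distribution (computed on a random 1 M-pair subsample)
separates mono-nucleosomal protection (~147 bp) from sub-nucleosomal
contamination (5-50 bp, characteristic of sperm packaging structures).
Genome coverage is the fraction of consecutive 200-bp bins touched by at
least one nucleosome window; it doubles as the occupied-genome fraction
``gr`` in the occupancy model.  Biological replicates are pooled when their
promoter-occupancy Pearson correlation exceeds 0.8 (strict inequality).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import NUC_WIDTH, FragmentSet, _centered_intervals

log = logging.getLogger(__name__)

SHORT_RANGE = (5, 50)
MONO_RANGE = (120, 180)
MAX_HIST_LENGTH = 1000
POOL_THRESHOLD = 0.8


@dataclass
class QCReport:
    length_histogram: dict[int, float] = field(default_factory=dict)
    modal_length: int | None = None
    short_fraction: float = 0.0
    mono_fraction: float = 0.0
    coverage_fraction: float | None = None
    replicate_correlations: dict[tuple[str, str], float] = field(default_factory=dict)
    n_sampled: int = 0

    def to_dict(self) -> dict:
        return {
            "modal_length": self.modal_length,
            "short_fraction": self.short_fraction,
            "mono_fraction": self.mono_fraction,
            "coverage_fraction": self.coverage_fraction,
            "n_sampled": self.n_sampled,
            "replicate_correlations": {
                f"{a}|{b}": r for (a, b), r in self.replicate_correlations.items()
            },
        }


def fragment_length_distribution(fragset: FragmentSet, sample_n: int = 1_000_000,
                                 seed: int = 0) -> QCReport:
    """Length histogram over a seeded random subsample of fragments.

    Lengths above 1000 bp are lumped into the 1000-bp bin (logged).  The
    modal length is the histogram argmax, ties resolved to the smallest
    length.  Short (5-50 bp) and mono-nucleosomal (120-180 bp) fractions
    are inclusive on both ends.
    """
    if sample_n <= 0:
        raise ValueError("sample_n must be positive")
    if len(fragset) == 0:
        raise ValueError("no fragments")
    lengths = fragset.lengths
    if len(lengths) > sample_n:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(lengths), size=int(sample_n), replace=False)
        lengths = lengths[idx]
    n_long = int(np.count_nonzero(lengths > MAX_HIST_LENGTH))
    if n_long:
        log.info("lumped %d fragments longer than %d bp", n_long, MAX_HIST_LENGTH)
    clipped = np.minimum(lengths, MAX_HIST_LENGTH)
    counts = np.bincount(clipped, minlength=MAX_HIST_LENGTH + 1)[1:]
    freqs = counts / len(lengths)
    hist = {int(l + 1): float(f) for l, f in enumerate(freqs) if f > 0}
    modal = int(np.argmax(freqs)) + 1
    short = float(freqs[SHORT_RANGE[0] - 1: SHORT_RANGE[1]].sum())
    mono = float(freqs[MONO_RANGE[0] - 1: MONO_RANGE[1]].sum())
    return QCReport(length_histogram=hist, modal_length=modal,
                    short_fraction=short, mono_fraction=mono,
                    n_sampled=len(lengths))


def genome_coverage_fraction(fragset: FragmentSet, bin_width: int = 200) -> float:
    """Fraction of ``bin_width`` bins overlapped by >= 1 nucleosome window.

    Each fragment contributes its 146-bp midpoint-centered window.  This is
    the occupied-genome fraction ``gr`` used to normalize occupancy.
    """
    if not fragset.chrom_sizes:
        raise ValueError("coverage requires chrom_sizes")
    covered = total = 0
    df = fragset.fragments
    for chrom, size in fragset.chrom_sizes.items():
        n_bins = -(-size // bin_width)
        total += n_bins
        sub = df[df["chrom"] == chrom]
        if len(sub) == 0:
            continue
        a, b = _centered_intervals(sub["start"].to_numpy(), sub["end"].to_numpy(),
                                   NUC_WIDTH, size)
        hit = np.zeros(n_bins + 1, dtype=np.int64)
        # window [a, b) touches bins a//w .. (b-1)//w inclusive
        np.add.at(hit, a // bin_width, 1)
        np.add.at(hit, np.minimum((b - 1) // bin_width + 1, n_bins), -1)
        covered += int(np.count_nonzero(np.cumsum(hit[:-1]) > 0))
    return covered / total


def replicate_correlation(occ_a: np.ndarray, occ_b: np.ndarray) -> float:
    """Pearson correlation of promoter occupancy between two replicates.

    Returns NaN (with a warning) when either vector has zero variance.
    """
    occ_a, occ_b = np.asarray(occ_a, float), np.asarray(occ_b, float)
    if occ_a.shape != occ_b.shape or occ_a.size < 3:
        raise ValueError("replicate vectors must have equal length >= 3")
    if np.std(occ_a) == 0 or np.std(occ_b) == 0:
        warnings.warn("zero variance in replicate vector; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(occ_a, occ_b)[0])


def pool_decision(r: float, threshold: float = POOL_THRESHOLD) -> str:
    """``"pool"`` iff r > threshold (strictly); NaN keeps replicates separate."""
    if np.isnan(r):
        return "keep_separate"
    return "pool" if r > threshold else "keep_separate"


def promoter_occupancy(bin_table, anchors, flank: int = 2000) -> np.ndarray:
    """Mean relative occupancy O over each +/-``flank`` promoter window.

    Promoter windows are read off the occupancy bin table at its native
    (1-kb) granularity; bins overlapping the window are averaged.
    """
    df = bin_table.bins
    w = bin_table.bin_width
    per_chrom = {c: sub.set_index(sub["start"] // w)["O"]
                 for c, sub in df.groupby("chrom", sort=False)}
    out = np.zeros(len(anchors.anchors))
    for i, row in enumerate(anchors.anchors.itertuples(index=False)):
        series = per_chrom.get(row.chrom)
        if series is None:
            continue
        lo = max(0, (row.position - flank)) // w
        hi = (row.position + flank - 1) // w
        vals = series.reindex(range(lo, hi + 1), fill_value=0.0)
        out[i] = float(vals.mean())
    return out
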