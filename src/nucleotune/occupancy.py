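"""Normalized nucleosome occupancy over consecutive genome bins.

The genome is split into consecutive 1-kb bins (a coarse resolution suited
to the sparseness of ultra-low-input samples).  For a bin with
depth-normalized fragment count N, the relative occupancy is

    O = N / ((146 * s) / (g * gr))

where ``s`` is the normalized sequencing depth (5e8 read pairs), ``g`` the
genome size, and ``gr`` the fraction of the genome occupied by nucleosomes
(sample-specific, estimated from 200-bp coverage).  O is the ratio of
observed to expected nucleosome fragments under uniform placement over the
occupied part of the genome.  Bins with O > 0.3 are called occupied; bins
with O > 3 in a gamete sample are called gamete-retained.  A bin is "newly
established" at a stage when it is occupied there but in none of the
previous stages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import qc
from .fragments import DEFAULT_TARGET_DEPTH, NUC_WIDTH, FragmentSet

log = logging.getLogger(__name__)

OCCUPANCY_CUTOFF = 0.3
RETAINED_CUTOFF = 3.0


@dataclass
class GenomeBinTable:
    """Consecutive fixed-width bins with counts, occupancy and calls.

    ``bins`` has columns ``chrom``, ``start``, ``N`` and, once
    :func:`relative_occupancy` has run, ``O`` and ``occupied``.
    """

    bins: pd.DataFrame
    bin_width: int = 1000
    s: float = DEFAULT_TARGET_DEPTH
    g: float = 0.0
    gr: float | None = None
    sample_id: str = ""
    stage_label: str = ""

    def occupied_fraction(self) -> float:
        return float(self.bins["occupied"].mean())

    def same_layout(self, other: "GenomeBinTable") -> bool:
        return (self.bin_width == other.bin_width
                and len(self.bins) == len(other.bins)
                and (self.bins["chrom"].values == other.bins["chrom"].values).all()
                and (self.bins["start"].values == other.bins["start"].values).all())


@dataclass
class StageSeries:
    """Ordered stages of one parental origin sharing a bin layout."""

    labels: list[str]
    tables: list[GenomeBinTable]
    parental_origin: str = "NA"

    def __post_init__(self):
        if len(self.labels) != len(self.tables):
            raise ValueError("labels and tables must align")
        for t in self.tables[1:]:
            if not self.tables[0].same_layout(t):
                raise ValueError("inconsistent bin layouts across stages")


def assign_counts(fragset: FragmentSet, bin_width: int = 1000,
                  target_depth: float = DEFAULT_TARGET_DEPTH) -> GenomeBinTable:
    """Count fragments per bin (midpoint rule), scaled to ``target_depth``.

    Each fragment lands in exactly one bin -- the bin holding the midpoint
    of its 146-bp nucleosome window -- so total counts are conserved:
    the N column sums to ``target_depth``.
    """
    if not fragset.chrom_sizes:
        raise ValueError("binning requires chrom_sizes")
    if len(fragset) == 0:
        raise ValueError("no fragments")
    scale = target_depth / len(fragset)
    frames = []
    df = fragset.fragments
    for chrom, size in fragset.chrom_sizes.items():
        n_bins = -(-size // bin_width)
        starts = np.arange(n_bins, dtype=np.int64) * bin_width
        sub = df[df["chrom"] == chrom]
        counts = np.zeros(n_bins)
        if len(sub):
            mids = (sub["start"].to_numpy() + sub["end"].to_numpy()) // 2
            # midpoint of the clipped nucleosome window
            half = NUC_WIDTH // 2
            a = np.clip(mids - half, 0, size)
            b = np.clip(mids + half, 0, size)
            wmid = (a + b) // 2
            counts = np.bincount(wmid // bin_width, minlength=n_bins).astype(float)
        frames.append(pd.DataFrame({"chrom": chrom, "start": starts,
                                    "N": counts * scale}))
    bins = pd.concat(frames, ignore_index=True)
    return GenomeBinTable(bins=bins, bin_width=bin_width, s=target_depth,
                          g=fragset.genome_size, sample_id=fragset.sample_id,
                          stage_label=fragset.stage_label)


def estimate_gr(fragset: FragmentSet, bin_width: int = 200) -> float:
    """Occupied-genome fraction ``gr``: 200-bp coverage of the sample."""
    return qc.genome_coverage_fraction(fragset, bin_width=bin_width)


def relative_occupancy(table: GenomeBinTable, gr: float | None = None,
                       s: float | None = None, g: float | None = None,
                       cutoff: float = OCCUPANCY_CUTOFF) -> GenomeBinTable:
    """Fill the O column: O = N / ((146*s)/(g*gr)); call occupied bins.

    O is the observed/expected fragment ratio; the default call cutoff
    (O > 0.3) is the model's operating point and absorbs the per-bin scale.
    """
    s = table.s if s is None else s
    g = table.g if g is None else g
    gr = table.gr if gr is None else gr
    if gr is None:
        raise ValueError("gr must be supplied or set on the table")
    if gr <= 0:
        raise ValueError("empty-genome occupancy: gr must be > 0")
    if s <= 0 or g <= 0:
        raise ValueError("s and g must be positive")
    expected = (NUC_WIDTH * s) / (g * gr)
    bins = table.bins.copy()
    bins["O"] = bins["N"] / expected
    bins["occupied"] = bins["O"] > cutoff
    return GenomeBinTable(bins=bins, bin_width=table.bin_width, s=s, g=g, gr=gr,
                          sample_id=table.sample_id, stage_label=table.stage_label)


def occupancy_from_fragments(fragset: FragmentSet, bin_width: int = 1000,
                             target_depth: float = DEFAULT_TARGET_DEPTH,
                             gr: float | None = None,
                             cutoff: float = OCCUPANCY_CUTOFF) -> GenomeBinTable:
    """Convenience: counts + gr estimate + relative occupancy in one call."""
    table = assign_counts(fragset, bin_width=bin_width, target_depth=target_depth)
    if gr is None:
        gr = estimate_gr(fragset)
    return relative_occupancy(table, gr=gr, cutoff=cutoff)


def classify_regions(series: StageSeries, cutoff: float = OCCUPANCY_CUTOFF,
                     retained_cutoff: float = RETAINED_CUTOFF,
                     gamete_stage: int | None = None) -> pd.DataFrame:
    """Label newly-established (and optionally gamete-retained) bins.

    A bin is newly established at stage t when O > cutoff at t and
    O <= cutoff at every previous stage; the first stage's occupied bins
    are its own newly-established set.  With ``gamete_stage`` given,
    bins with O > ``retained_cutoff`` (strictly) at that stage are flagged
    retained.  Returns one boolean column per stage plus layout columns.
    """
    if not series.tables:
        raise ValueError("empty stage series")
    out = series.tables[0].bins[["chrom", "start"]].copy()
    occ = np.column_stack([
        (t.bins["O"] > cutoff).to_numpy() for t in series.tables
    ])
    prev_any = np.zeros(len(out), dtype=bool)
    for j, label in enumerate(series.labels):
        out[f"newly_established_{label}"] = occ[:, j] & ~prev_any
        prev_any |= occ[:, j]
    if gamete_stage is not None:
        gt = series.tables[gamete_stage]
        out["retained"] = (gt.bins["O"] > retained_cutoff).to_numpy()
    return out


def _merge_intervals(intervals):
    """Merge overlapping (chrom, start, end) intervals; sorted output."""
    merged = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], end)
        else:
            merged.append([chrom, start, end])
    return [tuple(m) for m in merged]


def _overlap_length(a, b):
    """Total overlap between two merged, sorted interval lists."""
    total = 0
    j = 0
    for chrom, s, e in a:
        while j < len(b) and (b[j][0], b[j][2]) <= (chrom, s):
            j += 1
        k = j
        while k < len(b) and b[k][0] == chrom and b[k][1] < e:
            total += max(0, min(e, b[k][2]) - max(s, b[k][1]))
            k += 1
    return total


def element_enrichment(regions, elements, genome_size: float) -> float:
    """Observed/expected overlap of nucleosome regions with genomic elements.

    observed = overlap(regions, elements) / total region length;
    expected = total element length / genome size.  Both interval lists are
    merged before measuring.
    """
    regions = _merge_intervals(regions)
    elements = _merge_intervals(elements)
    if not regions:
        raise ValueError("empty region set")
    if not elements:
        warnings.warn("empty element set; enrichment is 0")
        return 0.0
    region_len = sum(e - s for _, s, e in regions)
    element_len = sum(e - s for _, s, e in elements)
    observed = _overlap_length(regions, elements) / region_len
    expected = element_len / genome_size
    return observed / expected


def bins_to_intervals(table: GenomeBinTable, mask) -> list[tuple[str, int, int]]:
    """Convert a boolean bin mask into merged (chrom, start, end) intervals."""
    df = table.bins[np.asarray(mask, bool)]
    ivals = [(r.chrom, int(r.start), int(r.start) + table.bin_width)
             for r in df.itertuples(index=False)]
    return _merge_intervals(ivals)
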