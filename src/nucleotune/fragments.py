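"""Fragment, anchor and signal-track handling for MNase-seq analysis.

Paired-end MNase-seq fragments mark nucleosome-protected DNA.  Every
coordinate in this package is 0-based half-open (BED convention); 1-based
inputs are converted at the boundary.  A sequenced fragment is converted to
a nucleosome-sized interval by taking its midpoint and extending to 146 bp
(the core-particle footprint); for sharper visual profiles only the middle
74 bp are piled.  Per-base pileups are depth-normalized so that every sample
is on the scale of a fixed total read count (500 million by default),
making tracks comparable between samples of very different depth.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: width of the nucleosome core-particle footprint used for occupancy pileups
NUC_WIDTH = 146
#: central sub-fragment width used for visualization pileups
VISUAL_WIDTH = 74
#: default depth-normalization target (read pairs)
DEFAULT_TARGET_DEPTH = 5e8
#: mouse genome size, the default when chromosome sizes are not supplied
MOUSE_GENOME_SIZE = 2.7e9

_FRAG_COLS = ["chrom", "start", "end"]


def _opener(path):
    path = str(path)
    return gzip.open(path, "rt") if path.endswith(".gz") else open(path, "rt")


def read_chrom_sizes(path) -> dict[str, int]:
    """Read a two-column ``chrom<TAB>length`` table into a dict."""
    sizes = {}
    with _opener(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {i}: expected 'chrom<TAB>length'")
            sizes[parts[0]] = int(parts[1])
    return sizes


@dataclass
class FragmentSet:
    """A per-sample collection of paired-end fragment intervals.

    Parameters
    ----------
    fragments
        DataFrame with columns ``chrom``, ``start``, ``end`` (0-based
        half-open), sorted by (chrom, start).
    chrom_sizes
        Mapping chromosome name -> length in bp.
    genome_size
        Effective genome size ``g`` used for occupancy normalization.
        Defaults to the sum of ``chrom_sizes`` when given, otherwise the
        mouse genome size 2.7e9.
    """

    fragments: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    sample_id: str = ""
    stage_label: str = ""
    genome_size: float | None = None

    def __post_init__(self):
        df = self.fragments
        if not all(c in df.columns for c in _FRAG_COLS):
            raise ValueError(f"fragments must have columns {_FRAG_COLS}")
        if self.genome_size is None:
            self.genome_size = (
                float(sum(self.chrom_sizes.values()))
                if self.chrom_sizes
                else MOUSE_GENOME_SIZE
            )
        self.validate()

    def validate(self):
        df = self.fragments
        if len(df) and not (df["start"] < df["end"]).all():
            bad = df.index[~(df["start"] < df["end"])][0]
            raise ValueError(f"fragment {bad}: start must be < end")
        if len(df) and (df["start"] < 0).any():
            raise ValueError("negative fragment start")
        if self.chrom_sizes:
            for chrom, sub in df.groupby("chrom", sort=False):
                if chrom not in self.chrom_sizes:
                    raise ValueError(f"fragment on unknown chromosome {chrom!r}")
                if (sub["end"] > self.chrom_sizes[chrom]).any():
                    raise ValueError(f"fragment beyond end of {chrom}")

    def __len__(self) -> int:
        return len(self.fragments)

    @property
    def lengths(self) -> np.ndarray:
        return (self.fragments["end"] - self.fragments["start"]).to_numpy()

    def sorted(self) -> "FragmentSet":
        df = self.fragments.sort_values(["chrom", "start", "end"], kind="mergesort")
        return replace(self, fragments=df.reset_index(drop=True))

    @classmethod
    def pool(cls, sets: list["FragmentSet"], sample_id: str = "pooled") -> "FragmentSet":
        """Concatenate replicate fragment lists into one sample."""
        if not sets:
            raise ValueError("no fragment sets to pool")
        df = pd.concat([s.fragments[_FRAG_COLS] for s in sets], ignore_index=True)
        out = cls(
            fragments=df,
            chrom_sizes=sets[0].chrom_sizes,
            sample_id=sample_id,
            stage_label=sets[0].stage_label,
            genome_size=sets[0].genome_size,
        )
        return out.sorted()


def nucleosome_interval(start: int, end: int, chrom_length: int | None = None):
    """Map a fragment to the 146-bp window centered on its midpoint.

    The midpoint of an odd-length fragment uses floor division.  Windows
    crossing a chromosome edge are clipped, not dropped.
    """
    mid = (start + end) // 2
    a, b = mid - NUC_WIDTH // 2, mid + NUC_WIDTH // 2
    return _clip(a, b, chrom_length)


def central_interval(start: int, end: int, width: int = VISUAL_WIDTH,
                     chrom_length: int | None = None):
    """Map a fragment to the ``width``-bp window centered on its midpoint."""
    mid = (start + end) // 2
    a, b = mid - width // 2, mid + width - width // 2
    return _clip(a, b, chrom_length)


def _clip(a: int, b: int, chrom_length: int | None):
    if a < 0:
        a = 0
    if chrom_length is not None and b > chrom_length:
        b = chrom_length
    return a, b


def _centered_intervals(starts, ends, width: int, chrom_length: int):
    """Vectorized midpoint-centered windows, clipped at chromosome edges."""
    mids = (starts + ends) // 2
    a = mids - width // 2
    b = a + width
    n_clip = int(np.count_nonzero((a < 0) | (b > chrom_length)))
    if n_clip:
        log.info("clipped %d windows at chromosome edges", n_clip)
    return np.clip(a, 0, chrom_length), np.clip(b, 0, chrom_length)


def read_fragments(path, format: str = "bed", chrom_sizes: dict | None = None,
                   sample_id: str = "", stage_label: str = "",
                   min_mapq: int = 10) -> FragmentSet:
    """Read paired-end fragments from BED3+ or a paired-end BAM/SAM.

    BED input is assumed pre-filtered; BAM records are kept only when both
    mates are mapped, the pair is proper, and MAPQ >= ``min_mapq``.  One
    fragment is emitted per template, spanning leftmost mate start to
    rightmost mate end.  Output is sorted by (chrom, start).
    """
    if format == "bed":
        df = _read_bed3(path)
    elif format in ("bam", "sam"):
        df = _read_bam(path, min_mapq=min_mapq)
    else:
        raise ValueError(f"unknown fragment format {format!r}")
    fs = FragmentSet(df, chrom_sizes=chrom_sizes or {}, sample_id=sample_id,
                     stage_label=stage_label)
    return fs.sorted()


def _read_bed3(path) -> pd.DataFrame:
    rows = []
    with _opener(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {i}: BED needs >= 3 columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}: line {i}: malformed BED line") from exc
    return pd.DataFrame(rows, columns=_FRAG_COLS)


def _read_bam(path, min_mapq: int = 10) -> pd.DataFrame:
    import pysam

    mode = "r" if str(path).endswith(".sam") else "rb"
    rows, skipped = [], 0
    with pysam.AlignmentFile(str(path), mode) as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mate_is_unmapped or not rec.is_proper_pair:
                skipped += 1
                continue
            if rec.mapping_quality < min_mapq:
                continue
            # count each template once, from its leftmost read
            if rec.template_length <= 0:
                continue
            rows.append((rec.reference_name, rec.reference_start,
                         rec.reference_start + rec.template_length))
    if skipped:
        log.info("skipped %d records with unmapped mates", skipped)
    return pd.DataFrame(rows, columns=_FRAG_COLS)


@dataclass
class SignalTrack:
    """Per-base nucleosome coverage, depth-normalized to a stated total.

    ``values`` maps chromosome -> float array of length chrom size /
    ``resolution``.  The integral of the track equals
    ``piled width * target_depth`` for clipping-free input.
    """

    values: dict[str, np.ndarray]
    resolution: int = 1
    target_depth: float = DEFAULT_TARGET_DEPTH
    n_fragments: int = 0
    piled_width: int = NUC_WIDTH

    def total(self) -> float:
        return float(sum(v.sum() for v in self.values.values())) * self.resolution

    @property
    def genome_size(self) -> int:
        return sum(len(v) * self.resolution for v in self.values.values())

    def mean(self) -> float:
        """Genome-wide mean signal per bp (used for profile normalization)."""
        return self.total() / self.genome_size

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.values[chrom][start // self.resolution: end // self.resolution]


def pileup(fragset: FragmentSet, mode: str = "occupancy",
           target_depth: float = DEFAULT_TARGET_DEPTH,
           min_length: int | None = None,
           max_length: int | None = None) -> SignalTrack:
    """Pile midpoint-centered windows of every fragment into a genome track.

    ``mode`` chooses the piled width: ``"occupancy"`` (alias
    ``"occupancy_146"``) uses the 146-bp nucleosome window, ``"visual"``
    (alias ``"visual_74"``) the middle 74 bp.  Coverage is multiplied by
    ``target_depth / n_fragments`` so all samples sit on a common depth
    scale.  ``min_length``/``max_length`` optionally drop fragments outside
    a length range (off by default; sub-nucleosomal contamination is piled
    unless explicitly filtered).
    """
    widths = {"occupancy": NUC_WIDTH, "occupancy_146": NUC_WIDTH,
              "visual": VISUAL_WIDTH, "visual_74": VISUAL_WIDTH}
    if mode not in widths:
        raise ValueError(f"unknown pileup mode {mode!r}")
    width = widths[mode]
    if not fragset.chrom_sizes:
        raise ValueError("pileup requires chrom_sizes")
    df = fragset.fragments
    if min_length is not None or max_length is not None:
        lens = df["end"] - df["start"]
        keep = pd.Series(True, index=df.index)
        if min_length is not None:
            keep &= lens >= min_length
        if max_length is not None:
            keep &= lens <= max_length
        log.info("length filter kept %d/%d fragments", int(keep.sum()), len(df))
        df = df[keep]
    if len(df) == 0:
        raise ValueError("no fragments")
    scale = target_depth / len(df)
    values = {}
    for chrom, size in fragset.chrom_sizes.items():
        diff = np.zeros(size + 1)
        sub = df[df["chrom"] == chrom]
        if len(sub):
            a, b = _centered_intervals(sub["start"].to_numpy(),
                                       sub["end"].to_numpy(), width, size)
            np.add.at(diff, a, 1.0)
            np.add.at(diff, b, -1.0)
        values[chrom] = np.cumsum(diff[:-1]) * scale
    return SignalTrack(values=values, resolution=1, target_depth=target_depth,
                       n_fragments=len(df), piled_width=width)


def write_bedgraph(track: SignalTrack, path):
    """Write a track as bedGraph (0-based half-open), gzip-transparent.

    Zero-valued runs are skipped, as is conventional for bedGraph.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for chrom in track.values:
            v = track.values[chrom]
            change = np.flatnonzero(np.diff(v)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(v)]))
            for s, e in zip(starts, ends):
                if v[s] != 0.0:
                    fh.write(f"{chrom}\t{s * track.resolution}"
                             f"\t{e * track.resolution}\t{v[s]:.10g}\n")


def read_bedgraph(path, chrom_sizes: dict[str, int],
                  resolution: int = 1) -> SignalTrack:
    values = {c: np.zeros(size // resolution) for c, size in chrom_sizes.items()}
    with _opener(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}: line {i}: bedGraph needs 4 columns")
            chrom, s, e, v = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            values[chrom][s // resolution: e // resolution] = v
    return SignalTrack(values=values, resolution=resolution)


@dataclass
class AnchorSet:
    """Oriented genomic anchor points (TSSs, motif centers, region centers).

    ``anchors`` has columns ``chrom``, ``position``, ``strand``, ``name``,
    ``score``.  Motif-center sets are expected to be truncated to the
    top-K sites by descending motif score before profiling.
    """

    anchors: pd.DataFrame
    kind: str = "TSS"

    _COLS = ["chrom", "position", "strand", "name", "score"]

    def __post_init__(self):
        for c in self._COLS:
            if c not in self.anchors.columns:
                raise ValueError(f"anchor table missing column {c!r}")

    def __len__(self) -> int:
        return len(self.anchors)

    def top_by_score(self, k: int = 10000) -> "AnchorSet":
        """Keep the top-``k`` anchors by descending score (stable ties)."""
        df = self.anchors.sort_values(
            ["score", "chrom", "position"], ascending=[False, True, True],
            kind="mergesort").head(k)
        return AnchorSet(df.reset_index(drop=True), kind=self.kind)


def read_anchors(path, kind: str = "TSS") -> AnchorSet:
    """Read anchors from BED6 (or BED6+score for motifs).

    For ``kind="TSS"`` the anchor is the strand-aware 5' end of the
    interval; for motif/region kinds it is the interval midpoint.
    """
    rows = []
    with _opener(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {i}: BED needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"anchor{i}"
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else 0.0
            strand = parts[5] if len(parts) > 5 else "+"
            if kind == "TSS":
                pos = start if strand == "+" else end - 1
            else:
                pos = (start + end) // 2
            rows.append((chrom, pos, strand, name, score))
    df = pd.DataFrame(rows, columns=AnchorSet._COLS)
    return AnchorSet(df, kind=kind)
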