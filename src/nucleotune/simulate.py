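"""Synthetic MNase-seq data with planted nucleosome architecture.

The generator emulates, at desk scale, the conditions of a pronuclear
nucleosome-remodeling experiment: a small genome (3 chromosomes x 2 Mb) is
observed over an ordered series of stages whose occupied-genome fraction
grows from sperm-like sparseness (0.15) through an intermediate state (0.5)
to near-complete occupancy (0.8), mirroring the protamine-to-histone
transition of the paternal genome.  Occupied territory is nested across
stages; anchor neighbourhoods (see below) are occupied whenever their
structure is active, and the remaining territory is filled in order of
descending GC content, planting the GC preference of early nucleosome
establishment.

Anchors (gene TSSs and TF motif sites) live at the centers of disjoint
5-kb slots, so their +/-2 kb profile windows never overlap.  From its onset
stage, each gene promoter carries a nucleosome-depleted region of
controllable depth flanked by a phased array: placement density is
suppressed by the NDR depth within +/-100 bp of the TSS, and Gaussian bumps
(sd 20 bp) mark the -1 nucleosome at -150 bp and a downstream lattice at
+150, +150+R, ... with repeat length R (190 bp, 10 nucleosomes by default).
TF motif sites follow one of three dynamic classes: ``closed`` (a
nucleosome bump sits on the site at every stage), ``open`` (depleted center
with a phased array at every stage), and ``rising`` (closed before an onset
stage, open afterwards).

Fragment centers are drawn by inverse-CDF sampling from the explicit
per-bp placement density; mono-nucleosomal lengths are truncated-normal
(147 +/- 15, bounded to [100, 200]) and a per-stage contamination fraction
of sub-nucleosomal fragments draws lengths uniformly from 5-50 bp.  Every
planted parameter is recorded in an emitted truth file, and the same seed
reproduces byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import AnchorSet, FragmentSet

log = logging.getLogger(__name__)

DEFAULT_GENOME = [("chr1", 2_000_000), ("chr2", 2_000_000), ("chr3", 2_000_000)]
DEFAULT_STAGES = ["sperm", "pn_1h", "pn_6h"]
DEFAULT_OCCUPIED = (0.15, 0.5, 0.8)
DEFAULT_SHORT = (0.2, 0.0, 0.0)
NDR_DEPTH_GROUPS = (0.0, 0.3, 0.6)
BUMP_SD = 20.0
BUMP_AMPLITUDE = 2.0
NDR_HALF_WIDTH = 100
FLANK_OFFSET = 150
OPEN_DEPTH = 0.8
SLOT_BINS = 5
EXPRESSION_STAGES = ["oocyte", "zygote", "early_2cell", "late_2cell"]


@dataclass
class ArchitectureSpec:
    """Planted architecture of a synthetic fragment dataset."""

    genome: list[tuple[str, int]] = field(
        default_factory=lambda: list(DEFAULT_GENOME))
    stages: list[str] = field(default_factory=lambda: list(DEFAULT_STAGES))
    occupied_fraction: tuple[float, ...] = DEFAULT_OCCUPIED
    short_fraction: tuple[float, ...] = DEFAULT_SHORT
    fragments_per_stage: int = 50_000
    bin_width: int = 1000
    n_genes: int = 300
    ndr_depths: tuple[float, ...] = NDR_DEPTH_GROUPS
    gene_onset_stage: int = 1
    repeat_length: int = 190
    array_n: int = 10
    n_tfs_per_class: int = 2
    sites_per_tf: int = 80
    tf_rising_onset: int | None = None  # default: last stage
    bump_amplitude: float = BUMP_AMPLITUDE
    open_depth: float = OPEN_DEPTH
    mono_mean: float = 147.0
    mono_sd: float = 15.0
    mono_bounds: tuple[int, int] = (100, 200)
    gc_linked: bool = True
    seed: int = 7

    def __post_init__(self):
        n = len(self.stages)
        if len(self.occupied_fraction) != n or len(self.short_fraction) != n:
            raise ValueError("per-stage parameters must match the stage list")
        if not all(0 < f <= 1 for f in self.occupied_fraction):
            raise ValueError("occupied fractions must lie in (0, 1]")
        slot_bp = SLOT_BINS * self.bin_width
        n_slots = sum(l // slot_bp for _, l in self.genome)
        if self.n_anchors > n_slots:
            raise ValueError("infeasible spec: more anchors than 5-kb slots")
        span = FLANK_OFFSET + (self.array_n - 1) * self.repeat_length
        if span + 3 * BUMP_SD > slot_bp // 2:
            raise ValueError("infeasible spec: phased array exceeds its slot")

    @property
    def n_anchors(self) -> int:
        return self.n_genes + 3 * self.n_tfs_per_class * self.sites_per_tf


@dataclass
class SyntheticData:
    """In-memory fixture: fragments, annotations, and the planted truth."""

    spec: ArchitectureSpec
    fragments: dict[str, FragmentSet]
    tss: AnchorSet
    genes: pd.DataFrame
    tf_sites: dict[str, AnchorSet]
    tf_classes: dict[str, str]
    occupied_bins: dict[str, np.ndarray]  # stage -> bool per genome bin
    bin_index: pd.DataFrame  # chrom, start per genome bin
    gc_per_bin: np.ndarray
    fpkm: pd.DataFrame
    zga_genes: set[str]
    chrom_sizes: dict[str, int]

    def planted_occupied_fraction(self, stage: str) -> float:
        return float(self.occupied_bins[stage].mean())

    def tss_subset(self, depth: float) -> AnchorSet:
        """Anchors of the genes planted with one NDR depth group."""
        names = set(self.genes.loc[self.genes["ndr_depth"] == depth, "name"])
        df = self.tss.anchors[self.tss.anchors["name"].isin(names)]
        return AnchorSet(df.reset_index(drop=True), kind="TSS")


def _bump(weight: np.ndarray, center: int, amplitude: float, sd: float = BUMP_SD):
    lo = max(0, int(center - 3 * sd))
    hi = min(len(weight), int(center + 3 * sd) + 1)
    x = np.arange(lo, hi)
    weight[lo:hi] += amplitude * np.exp(-0.5 * ((x - center) / sd) ** 2)


def _lattice_offsets(repeat: int, array_n: int) -> list[int]:
    """Oriented bump offsets: -1 nucleosome plus the downstream array."""
    return [-FLANK_OFFSET] + [FLANK_OFFSET + k * repeat for k in range(array_n)]


@dataclass
class _Anchor:
    chrom: str
    pos: int
    sign: int  # +1 / -1: direction of the downstream array
    kind: str  # "gene" or a TF class
    depth: float = 0.0  # NDR suppression depth when open
    onset: int = 0  # first stage index at which the anchor is active


def _anchor_state(anchor: _Anchor, stage_idx: int) -> str | None:
    """None (inactive), "closed" (center nucleosome) or "open" (NDR+array)."""
    if anchor.kind == "gene":
        return "open" if stage_idx >= anchor.onset else None
    if anchor.kind == "closed":
        return "closed"
    if anchor.kind == "open":
        return "open"
    return "open" if stage_idx >= anchor.onset else "closed"


def _footprint_bins(anchor: _Anchor, state: str, spec: ArchitectureSpec,
                    bin_offset: int) -> range:
    """Global bin indices whose weight the anchor's structure touches."""
    pad = int(3 * BUMP_SD)
    if state == "closed":
        lo, hi = anchor.pos - pad, anchor.pos + pad
    else:
        span = FLANK_OFFSET + (spec.array_n - 1) * spec.repeat_length + pad
        back = max(FLANK_OFFSET + pad, NDR_HALF_WIDTH)
        if anchor.sign > 0:
            lo, hi = anchor.pos - back, anchor.pos + span
        else:
            lo, hi = anchor.pos - span, anchor.pos + back
    return range(bin_offset + lo // spec.bin_width,
                 bin_offset + (hi - 1) // spec.bin_width + 1)


def _sample_lengths(rng, n, spec: ArchitectureSpec, short_fraction: float):
    n_short = int(round(n * short_fraction))
    lo, hi = spec.mono_bounds
    a = (lo - spec.mono_mean) / spec.mono_sd
    b = (hi - spec.mono_mean) / spec.mono_sd
    mono = stats.truncnorm.ppf(rng.random(n - n_short), a, b,
                               loc=spec.mono_mean, scale=spec.mono_sd)
    mono = np.rint(mono).astype(int)
    short = rng.integers(5, 51, size=n_short)
    lengths = np.concatenate([mono, short])
    return lengths[rng.permutation(n)]


def generate(spec: ArchitectureSpec | None = None) -> SyntheticData:
    """Build a full synthetic dataset from an architecture spec."""
    spec = spec or ArchitectureSpec()
    rng = np.random.default_rng(spec.seed)
    chrom_sizes = dict(spec.genome)
    bw = spec.bin_width
    n_bins_per = [l // bw for _, l in spec.genome]
    total_bins = sum(n_bins_per)
    bin_offsets = dict(zip([c for c, _ in spec.genome],
                           np.concatenate(([0], np.cumsum(n_bins_per)[:-1]))))
    bin_chrom = np.concatenate([
        np.repeat(c, n) for (c, _), n in zip(spec.genome, n_bins_per)])
    bin_start = np.concatenate([
        np.arange(n, dtype=np.int64) * bw for n in n_bins_per])
    bin_index = pd.DataFrame({"chrom": bin_chrom, "start": bin_start})

    gc = np.clip(rng.normal(0.45, 0.08, size=total_bins), 0.25, 0.70)

    # disjoint 5-kb anchor slots; anchors at slot centers
    slot_bp = SLOT_BINS * bw
    slots = [(c, s) for c, l in spec.genome
             for s in range(0, l - slot_bp + 1, slot_bp)]
    chosen = rng.choice(len(slots), size=spec.n_anchors, replace=False)

    anchors: list[_Anchor] = []
    gene_rows = []
    for i in range(spec.n_genes):
        chrom, start = slots[chosen[i]]
        strand = "+" if rng.random() < 0.5 else "-"
        depth = spec.ndr_depths[i % len(spec.ndr_depths)]
        pos = start + slot_bp // 2
        anchors.append(_Anchor(chrom, pos, 1 if strand == "+" else -1,
                               "gene", depth, spec.gene_onset_stage))
        gene_rows.append((f"gene{i:04d}", chrom, pos, strand, depth))
    genes = pd.DataFrame(gene_rows,
                         columns=["name", "chrom", "tss", "strand", "ndr_depth"])
    tss = AnchorSet(pd.DataFrame({
        "chrom": genes["chrom"], "position": genes["tss"],
        "strand": genes["strand"], "name": genes["name"],
        "score": genes["ndr_depth"]}), kind="TSS")

    rising_onset = (len(spec.stages) - 1 if spec.tf_rising_onset is None
                    else spec.tf_rising_onset)
    tf_sites, tf_classes = {}, {}
    cursor = spec.n_genes
    for cls in ("closed", "open", "rising"):
        for j in range(spec.n_tfs_per_class):
            name = f"{cls}_tf{j}"
            rows = []
            for i in range(spec.sites_per_tf):
                chrom, start = slots[chosen[cursor]]
                cursor += 1
                pos = start + slot_bp // 2
                anchors.append(_Anchor(chrom, pos, 1, cls, spec.open_depth,
                                       rising_onset))
                rows.append((chrom, pos, "+", f"{name}_site{i}",
                             100.0 - 50.0 * i / max(1, spec.sites_per_tf - 1)))
            tf_sites[name] = AnchorSet(
                pd.DataFrame(rows, columns=AnchorSet._COLS), kind="motif_center")
            tf_classes[name] = cls

    # occupied masks: active anchor footprints, then GC-ranked filler,
    # nested across stages
    if spec.gc_linked:
        priority = np.argsort(-(gc + rng.normal(0, 0.01, size=total_bins)),
                              kind="stable")
    else:
        priority = rng.permutation(total_bins)
    occupied = {}
    prev = np.zeros(total_bins, dtype=bool)
    for si, (stage, f) in enumerate(zip(spec.stages, spec.occupied_fraction)):
        mask = prev.copy()
        for a in anchors:
            state = _anchor_state(a, si)
            if state is not None:
                fp = _footprint_bins(a, state, spec, bin_offsets[a.chrom])
                mask[fp.start: fp.stop] = True
        target = int(round(f * total_bins))
        if mask.sum() > target:
            raise ValueError("infeasible spec: anchor footprints exceed the "
                             f"occupied fraction at stage {stage!r}")
        filler = priority[~mask[priority]][: target - mask.sum()]
        mask[filler] = True
        occupied[stage] = mask
        prev = mask

    offsets = _lattice_offsets(spec.repeat_length, spec.array_n)
    fragments = {}
    for si, stage in enumerate(spec.stages):
        weights = {}
        off = 0
        for (chrom, length), n in zip(spec.genome, n_bins_per):
            weights[chrom] = np.repeat(
                occupied[stage][off: off + n].astype(float), bw)[:length]
            off += n
        for a in anchors:
            state = _anchor_state(a, si)
            if state is None:
                continue
            w = weights[a.chrom]
            if state == "closed":
                _bump(w, a.pos, spec.bump_amplitude)
                continue
            if a.depth > 0:
                w[max(0, a.pos - NDR_HALF_WIDTH):
                  a.pos + NDR_HALF_WIDTH] *= (1.0 - a.depth)
            for o in offsets:
                _bump(w, a.pos + a.sign * o, spec.bump_amplitude)

        totals = np.array([weights[c].sum() for c, _ in spec.genome])
        counts = rng.multinomial(spec.fragments_per_stage,
                                 totals / totals.sum())
        rows = []
        for (chrom, length), n in zip(spec.genome, counts):
            if n == 0:
                continue
            cdf = np.cumsum(weights[chrom])
            centers = np.searchsorted(cdf, rng.random(n) * cdf[-1],
                                      side="right")
            rows.append(pd.DataFrame({"chrom": chrom, "center": centers}))
        placed = pd.concat(rows, ignore_index=True)
        lengths = _sample_lengths(rng, len(placed), spec,
                                  spec.short_fraction[si])
        starts = placed["center"].to_numpy() - lengths // 2
        df = pd.DataFrame({"chrom": placed["chrom"],
                           "start": np.maximum(starts, 0),
                           "end": starts + lengths})
        for chrom, length in spec.genome:
            sel = df["chrom"] == chrom
            df.loc[sel, "end"] = np.minimum(df.loc[sel, "end"], length)
        fragments[stage] = FragmentSet(df, chrom_sizes=chrom_sizes,
                                       sample_id=stage,
                                       stage_label=stage).sorted()

    # expression: all TFs are zygotically expressed; the *_tf0 member of
    # each class is additionally maternal
    fpkm = pd.DataFrame(0.1, index=list(tf_sites), columns=EXPRESSION_STAGES)
    fpkm["zygote"] = 2.0
    maternal = [n for n in tf_sites if n.endswith("tf0")]
    fpkm.loc[maternal, "oocyte"] = 5.0

    # the deepest-NDR genes stand in for ZGA genes
    zga = (set(genes.loc[genes["ndr_depth"] == max(spec.ndr_depths), "name"])
           if len(genes) else set())

    return SyntheticData(spec=spec, fragments=fragments, tss=tss, genes=genes,
                         tf_sites=tf_sites, tf_classes=tf_classes,
                         occupied_bins=occupied, bin_index=bin_index,
                         gc_per_bin=gc, fpkm=fpkm, zga_genes=zga,
                         chrom_sizes=chrom_sizes)


def write_fixture(data: SyntheticData, out_dir, write_fasta: bool = True):
    """Write a generated dataset as plain-text pipeline inputs + truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec = data.spec
    for stage, fs in data.fragments.items():
        fs.fragments.to_csv(out / f"fragments_{stage}.bed", sep="\t",
                            header=False, index=False)
    with open(out / "chrom.sizes", "w") as fh:
        for c, l in spec.genome:
            fh.write(f"{c}\t{l}\n")
    with open(out / "tss.bed", "w") as fh:
        for g in data.genes.itertuples(index=False):
            fh.write(f"{g.chrom}\t{g.tss}\t{g.tss + 1}\t{g.name}"
                     f"\t{g.ndr_depth}\t{g.strand}\n")
    motif_dir = out / "motifs"
    motif_dir.mkdir(exist_ok=True)
    for name, sites in data.tf_sites.items():
        with open(motif_dir / f"{name}.bed", "w") as fh:
            for r in sites.anchors.itertuples(index=False):
                fh.write(f"{r.chrom}\t{r.position - 10}\t{r.position + 10}"
                         f"\t{r.name}\t{r.score:g}\t{r.strand}\n")
    data.fpkm.to_csv(out / "fpkm.tsv", sep="\t", index_label="gene")
    with open(out / "zga_genes.txt", "w") as fh:
        for g in sorted(data.zga_genes):
            fh.write(g + "\n")
    if write_fasta:
        _write_fasta(data, out / "genome.fa")
    truth = {
        "seed": spec.seed,
        "stages": spec.stages,
        "occupied_fraction_planted": list(spec.occupied_fraction),
        "occupied_fraction_exact": {
            s: data.planted_occupied_fraction(s) for s in spec.stages},
        "short_fraction": list(spec.short_fraction),
        "fragments_per_stage": spec.fragments_per_stage,
        "ndr_depth_groups": list(spec.ndr_depths),
        "repeat_length": spec.repeat_length,
        "array_n": spec.array_n,
        "gene_onset_stage": spec.gene_onset_stage,
        "tf_classes": data.tf_classes,
        "mono_length": [spec.mono_mean, spec.mono_sd, *spec.mono_bounds],
        "gc_linked": spec.gc_linked,
        "n_genes": spec.n_genes,
        "zga_genes": sorted(data.zga_genes),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return out


def _write_fasta(data: SyntheticData, path):
    """Sequence with the planted per-bin GC content (G/C vs A/T equiprobable)."""
    rng = np.random.default_rng(data.spec.seed + 1)
    bw = data.spec.bin_width
    with open(path, "w") as fh:
        offset = 0
        for chrom, length in data.spec.genome:
            n_bins = length // bw
            gc = np.repeat(data.gc_per_bin[offset: offset + n_bins], bw)[:length]
            offset += n_bins
            is_gc = rng.random(length) < gc
            half = rng.random(length) < 0.5
            seq = np.where(is_gc, np.where(half, "G", "C"),
                           np.where(half, "A", "T"))
            fh.write(f">{chrom}\n")
            s = "".join(seq)
            for i in range(0, length, 80):
                fh.write(s[i:i + 80] + "\n")


DEFAULT_TEMPLATES = {
    "closed": np.array([-0.25, -0.25, -0.25, -0.25, -0.25, -0.25]),
    "open": np.array([0.55, 0.55, 0.55, 0.55, 0.55, 0.55]),
    "rising": np.array([-0.25, -0.25, -0.1, 0.2, 0.45, 0.55]),
}


def make_score_fixture(templates: dict[str, np.ndarray] | None = None,
                       n_per_class: int = 10, noise_sd: float = 0.02,
                       seed: int = 0, stage_labels: list[str] | None = None):
    """Score-matrix fixture: class-template trajectories plus Gaussian noise.

    Returns ``(matrix, labels)`` where ``matrix`` is a row-per-member
    DataFrame and ``labels`` the planted class of each row.
    """
    templates = templates or DEFAULT_TEMPLATES
    if not templates:
        raise ValueError("need at least one class template")
    rng = np.random.default_rng(seed)
    n_stages = len(next(iter(templates.values())))
    stages = stage_labels or [f"stage{i}" for i in range(n_stages)]
    rows, names, labels = [], [], []
    for cls, tpl in templates.items():
        noise = rng.normal(0, noise_sd, size=(n_per_class, n_stages))
        rows.append(np.asarray(tpl)[None, :] + noise)
        names += [f"{cls}_{i}" for i in range(n_per_class)]
        labels += [cls] * n_per_class
    matrix = pd.DataFrame(np.vstack(rows), index=names, columns=stages)
    return matrix, pd.Series(labels, index=names)


def make_screening_panel(n_per_class: int = 10, noise_sd: float = 0.02,
                         seed: int = 0, n_genes: int = 1000, n_zga: int = 100,
                         n_with_motif: int = 100):
    """End-to-end screening fixture at the score-matrix level.

    Plants three TF classes (closed / open / rising trajectories); among the
    rising TFs, members 0-2 are ZGA-enriched and maternally expressed (the
    expected candidates), members 3-4 ZGA-enriched but not maternal, and the
    rest carry motifs at exactly the background ZGA rate.  Returns a dict
    with the NDR matrix, planted labels, per-TF motif-bearing promoter sets,
    gene sets, the expression table, and the expected candidate set.
    """
    rng = np.random.default_rng(seed)
    matrix, labels = make_score_fixture(n_per_class=n_per_class,
                                        noise_sd=noise_sd, seed=seed)
    all_genes = [f"g{i:05d}" for i in range(n_genes)]
    zga = set(rng.choice(all_genes, size=n_zga, replace=False))
    non_zga = [g for g in all_genes if g not in zga]
    zga_list = sorted(zga)

    n_zga_enriched = int(round(0.3 * n_with_motif))
    n_zga_null = int(round(n_with_motif * n_zga / n_genes))
    motif_map = {}
    for name in matrix.index:
        cls = labels[name]
        member = int(name.rsplit("_", 1)[1])
        enriched = cls == "rising" and member < 5
        k = n_zga_enriched if enriched else n_zga_null
        picked = set(rng.choice(zga_list, size=k, replace=False))
        picked |= set(rng.choice(non_zga, size=n_with_motif - k, replace=False))
        motif_map[name] = picked

    fpkm = pd.DataFrame(0.1, index=list(matrix.index),
                        columns=EXPRESSION_STAGES)
    fpkm["zygote"] = 2.0
    maternal = [n for n in matrix.index
                if labels[n] == "rising" and int(n.rsplit("_", 1)[1]) < 3]
    fpkm.loc[maternal, "oocyte"] = 5.0
    return {
        "ndr_matrix": matrix,
        "labels": labels,
        "motif_map": motif_map,
        "zga_genes": zga,
        "all_genes": set(all_genes),
        "fpkm": fpkm,
        "expected_candidates": set(maternal),
    }
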