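"""Regulator screening from nucleosome dynamics at TF binding motifs.

A transcription factor whose motif sites turn from nucleosome-occupied to
nucleosome-depleted across pronuclear stages is a candidate pioneer factor.
The screen (i) computes an NDR score per TF per stage on its top motif
sites, (ii) k-means clusters the TF trajectories into k=3 classes --
always-occupied, always-open, and closed-to-open -- (iii) tests each
closed-to-open TF's motif-bearing promoters for enrichment of zygotic
genome activation (ZGA) genes, and (iv) keeps candidates with maternal
expression (FPKM >= 1 in the oocyte), since a factor acting at pronuclear
stages must be maternally deposited.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from . import profiles
from .fragments import AnchorSet, SignalTrack

log = logging.getLogger(__name__)

TOP_SITES = 10000
FPKM_CUTOFF = 1.0
ENRICHMENT_ALPHA = 0.05
PROMOTER_FLANK = 2000


@dataclass
class TFEntry:
    """One TF: its motif sites, motif GC content, and expression by stage."""

    name: str
    sites: AnchorSet
    gc_content: float | None = None
    expression: dict[str, float] = field(default_factory=dict)


@dataclass
class TFClusterResult:
    ndr_matrix: pd.DataFrame
    assignments: pd.Series  # TF -> cluster label in 1..k
    centers: np.ndarray
    k: int
    seed: int

    def members(self, cluster: int) -> list[str]:
        return list(self.assignments.index[self.assignments == cluster])


def build_tf_ndr_matrix(panel: list[TFEntry],
                        tracks: dict[str, SignalTrack],
                        window=profiles.MOTIF_WINDOW,
                        resolution: int = profiles.DEFAULT_RESOLUTION,
                        normalize: bool = True) -> pd.DataFrame:
    """TF x stage matrix of NDR scores on each TF's motif sites."""
    if not panel:
        raise ValueError("empty TF panel")
    data = {}
    for stage, track in tracks.items():
        mean = track.mean() if normalize else None
        col = []
        for tf in panel:
            prof = profiles.anchor_profile(track, tf.sites, window=window,
                                           resolution=resolution)
            if normalize:
                prof = profiles.normalize_profile(prof, mean)
            col.append(profiles.ndr_score(prof))
        data[stage] = col
    return pd.DataFrame(data, index=[tf.name for tf in panel])


def _relabel_by_trajectory(matrix: np.ndarray, raw_labels: np.ndarray, k: int):
    """Deterministic cluster labels: the class with the largest first-to-last
    NDR gain becomes cluster k (the closed-to-open class); the remaining
    classes are numbered by ascending first-stage mean, so cluster 1 is the
    always-occupied class and cluster k-1 the always-open class."""
    first = np.array([matrix[raw_labels == c, 0].mean() for c in range(k)])
    change = np.array([(matrix[raw_labels == c, -1]
                        - matrix[raw_labels == c, 0]).mean() for c in range(k)])
    rising = int(np.argmax(change))
    rest = sorted((c for c in range(k) if c != rising), key=lambda c: first[c])
    order = rest + [rising]
    mapping = {raw: new + 1 for new, raw in enumerate(order)}
    return np.array([mapping[c] for c in raw_labels])


def cluster_tfs(ndr_matrix: pd.DataFrame, k: int = 3, seed: int = 0,
                n_init: int = 25, scale: bool = False) -> TFClusterResult:
    """Seeded k-means over TF NDR-score trajectories (raw rows by default).

    Rows are fitted in a deterministic sort order so that membership sets do
    not depend on the input TF order.  Labels follow the trajectory
    convention of :func:`_relabel_by_trajectory`.
    """
    if len(ndr_matrix) < k:
        raise ValueError("k exceeds the number of TFs")
    if ndr_matrix.isna().any().any():
        raise ValueError("NDR matrix contains missing cells")
    X = ndr_matrix.to_numpy(float)
    if scale:
        X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1, X.std(axis=0))
    order = np.argsort(np.asarray(ndr_matrix.index, str), kind="stable")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_sorted = km.fit_predict(X[order])
    raw = np.empty(len(X), dtype=int)
    raw[order] = raw_sorted
    labels = _relabel_by_trajectory(X, raw, k)
    Xraw = ndr_matrix.to_numpy(float)
    centers = np.vstack([Xraw[labels == c].mean(axis=0) for c in range(1, k + 1)])
    return TFClusterResult(ndr_matrix=ndr_matrix,
                           assignments=pd.Series(labels, index=ndr_matrix.index),
                           centers=centers, k=k, seed=seed)


def promoter_motif_map(sites: AnchorSet, tss: AnchorSet,
                       flank: int = PROMOTER_FLANK) -> set[str]:
    """Genes whose promoter (+/-``flank`` of the TSS) holds >= 1 site center."""
    out = set()
    by_chrom = {c: np.sort(sub["position"].to_numpy())
                for c, sub in sites.anchors.groupby("chrom", sort=False)}
    for row in tss.anchors.itertuples(index=False):
        pos = by_chrom.get(row.chrom)
        if pos is None:
            continue
        lo = np.searchsorted(pos, row.position - flank, side="left")
        hi = np.searchsorted(pos, row.position + flank, side="right")
        if hi > lo:
            out.add(row.name)
    return out


def zga_promoter_enrichment(genes_with_motif: set[str], zga_genes: set[str],
                            all_genes: set[str]):
    """Odds-ratio enrichment of ZGA promoters among motif-bearing promoters.

    ratio = (|ZGA with motif| / |with motif|) / (|ZGA| / |all genes|),
    with a one-sided hypergeometric p-value for over-representation.
    Returns (nan, nan) when no promoter carries the motif.
    """
    if not zga_genes or not all_genes:
        raise ValueError("gene sets must be nonempty")
    if not zga_genes <= all_genes:
        raise ValueError("ZGA genes must be a subset of all genes")
    with_motif = genes_with_motif & all_genes
    if not with_motif:
        warnings.warn("no promoters with motif; enrichment undefined")
        return float("nan"), float("nan")
    n_with = len(with_motif)
    n_zga_with = len(with_motif & zga_genes)
    observed = n_zga_with / n_with
    expected = len(zga_genes) / len(all_genes)
    p = float(stats.hypergeom.sf(n_zga_with - 1, len(all_genes),
                                 len(zga_genes), n_with))
    return observed / expected, p


def expression_filter(tf_names: list[str], fpkm: pd.DataFrame,
                      stages: list[str], cutoff: float = FPKM_CUTOFF,
                      require_all: bool = False) -> list[str]:
    """TFs with FPKM >= cutoff in any (default) or all of ``stages``.

    TFs missing from the expression table are excluded with a warning.
    """
    missing = [t for t in tf_names if t not in fpkm.index]
    if missing:
        warnings.warn(f"{len(missing)} TFs missing from expression table")
    present = [t for t in tf_names if t in fpkm.index]
    sub = fpkm.loc[present, stages] >= cutoff
    keep = sub.all(axis=1) if require_all else sub.any(axis=1)
    return [t for t in present if keep[t]]


def maternal_filter(tf_names: list[str], fpkm: pd.DataFrame,
                    oocyte_stage: str = "oocyte",
                    cutoff: float = FPKM_CUTOFF) -> list[str]:
    """TFs with maternal storage: FPKM >= cutoff in the oocyte."""
    return expression_filter(tf_names, fpkm, [oocyte_stage], cutoff=cutoff)


def motif_gc_content(sites: AnchorSet, fasta, width: int = 20) -> float:
    """Mean G/C fraction over site intervals (+/- ``width``/2 of the center).

    ``fasta`` is a pyfaidx.Fasta-like mapping; ambiguous bases (N) are
    excluded from the denominator.
    """
    gc = at = 0
    for row in sites.anchors.itertuples(index=False):
        seq = str(fasta[row.chrom][max(0, row.position - width // 2):
                                   row.position + width - width // 2]).upper()
        if not seq:
            raise ValueError(f"site at {row.chrom}:{row.position} outside genome")
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


def rank_candidates(cluster_result: TFClusterResult,
                    enrichment: pd.DataFrame,
                    fpkm: pd.DataFrame,
                    oocyte_stage: str = "oocyte",
                    alpha: float = ENRICHMENT_ALPHA) -> pd.DataFrame:
    """Rank closed-to-open TFs by ZGA-promoter enrichment and maternal storage.

    ``enrichment`` must have columns ``ratio`` and ``p`` indexed by TF.
    Candidates are cluster-k TFs with BH-adjusted enrichment p < ``alpha``;
    the ``maternal`` column separates the maternally stored tier from the
    rest (which are reported, not dropped).  Sorted by descending ratio.
    """
    cluster3 = cluster_result.members(cluster_result.k)
    if not cluster3:
        return pd.DataFrame(columns=["ratio", "p", "p_adj", "maternal"])
    sub = enrichment.loc[cluster3].copy()
    ok = sub["p"].notna()
    sub.loc[ok, "p_adj"] = profiles.bh_adjust(sub.loc[ok, "p"].to_numpy())
    sub = sub[sub["p_adj"] < alpha]
    maternal = set(maternal_filter(list(sub.index), fpkm, oocyte_stage))
    sub["maternal"] = [t in maternal for t in sub.index]
    return sub.sort_values(["maternal", "ratio"], ascending=[False, False])
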