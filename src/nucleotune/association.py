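"""Determinants of nucleosome establishment and promoter-NDR dynamics.

What drives where nucleosomes appear?  Candidate features (GC content, DNA
methylation, chromatin accessibility, histone marks) are related to
stage-resolved occupancy or promoter NDR scores while controlling for the
previous stage's state, using first-order partial correlation: regress both
the current-stage values and the feature on the previous-stage values
(ordinary least squares with intercept) and correlate the residuals.
Gene promoters are additionally grouped by the trajectory of their NDR
scores across stages (k-means, k=7), and a one-way ANOVA F-value per
feature measures how strongly the feature separates the clusters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

log = logging.getLogger(__name__)

GENE_CLUSTER_K = 7


def _residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """OLS residuals of y ~ 1 + x."""
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def partial_correlation(target, feature, confounder) -> float:
    """First-order partial correlation of target and feature given confounder.

    Computed the residual way (correlate the residuals of two simple linear
    regressions on the confounder), which equals the closed form
    (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).  A constant
    confounder falls back to the plain Pearson correlation with a warning;
    zero residual variance returns 0 with a warning.
    """
    t = np.asarray(target, float)
    f = np.asarray(feature, float)
    c = np.asarray(confounder, float)
    if not (t.shape == f.shape == c.shape) or t.ndim != 1 or t.size < 4:
        raise ValueError("need three equal-length 1-d vectors, n >= 4")
    if np.std(c) == 0:
        warnings.warn("constant confounder; falling back to plain Pearson")
        return float(stats.pearsonr(t, f)[0])
    rt, rf = _residuals(t, c), _residuals(f, c)
    if np.std(rt) < 1e-12 * max(1.0, np.std(t)) or \
       np.std(rf) < 1e-12 * max(1.0, np.std(f)):
        warnings.warn("zero residual variance; partial correlation set to 0")
        return 0.0
    return float(stats.pearsonr(rt, rf)[0])


def newly_established_association(values: pd.DataFrame, features: pd.DataFrame,
                                  stage: str | int,
                                  restrict_unoccupied_below: float | None = None
                                  ) -> pd.Series:
    """Per-feature partial correlation of stage values given the previous stage.

    ``values`` is a row-aligned (bin or gene) x stage matrix of occupancy or
    NDR scores, ``features`` a row-aligned feature table.  For occupancy,
    ``restrict_unoccupied_below`` limits the rows to bins whose
    previous-stage occupancy is <= the given cutoff, so the correlation
    describes *newly gained* occupancy.
    """
    cols = list(values.columns)
    j = cols.index(stage) if not isinstance(stage, int) else stage
    if j < 1:
        raise ValueError("the first stage has no previous stage")
    cur = values.iloc[:, j].to_numpy(float)
    prev = values.iloc[:, j - 1].to_numpy(float)
    mask = np.ones(len(cur), bool)
    if restrict_unoccupied_below is not None:
        mask = prev <= restrict_unoccupied_below
    out = {}
    for name in features.columns:
        out[name] = partial_correlation(cur[mask],
                                        features[name].to_numpy(float)[mask],
                                        prev[mask])
    return pd.Series(out, name=f"stage_{cols[j]}")


def stage_series_associations(values: pd.DataFrame, features: pd.DataFrame,
                              restrict_unoccupied_below: float | None = None
                              ) -> pd.DataFrame:
    """Partial correlations for every stage after the first (feature x stage)."""
    if values.shape[1] < 2:
        raise ValueError("need at least two stages")
    cols = [newly_established_association(
        values, features, j, restrict_unoccupied_below)
        for j in range(1, values.shape[1])]
    return pd.concat(cols, axis=1)


@dataclass
class GeneClusterResult:
    assignments: pd.Series  # gene -> cluster 1..k ("C1".."Ck")
    centroids: pd.DataFrame  # cluster x stage NDR trajectories
    k: int
    seed: int


def cluster_promoters(ndr_scores: pd.DataFrame, k: int = GENE_CLUSTER_K,
                      seed: int = 0, n_init: int = 25) -> GeneClusterResult:
    """Seeded k-means over per-gene promoter NDR trajectories.

    Clusters are labeled C1..Ck deterministically: by descending mean NDR,
    ties broken by the earlier stage of onset (first stage whose centroid
    exceeds 0).  Rows are fitted in gene-name order so membership does not
    depend on input order.
    """
    if ndr_scores.isna().any().any():
        raise ValueError("NDR matrix contains missing cells; impute upstream")
    if len(ndr_scores) < k:
        raise ValueError("k exceeds the number of genes")
    X = ndr_scores.to_numpy(float)
    order = np.argsort(np.asarray(ndr_scores.index, str), kind="stable")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw_sorted = km.fit_predict(X[order])
    raw = np.empty(len(X), dtype=int)
    raw[order] = raw_sorted
    cent = np.vstack([X[raw == c].mean(axis=0) for c in range(k)])
    onset = np.array([np.argmax(cent[c] > 0) if (cent[c] > 0).any() else cent.shape[1]
                      for c in range(k)])
    rank = sorted(range(k), key=lambda c: (-cent[c].mean(), onset[c]))
    mapping = {raw_c: new + 1 for new, raw_c in enumerate(rank)}
    labels = np.array([mapping[c] for c in raw])
    centroids = pd.DataFrame(cent[rank], index=[f"C{i+1}" for i in range(k)],
                             columns=ndr_scores.columns)
    return GeneClusterResult(
        assignments=pd.Series(labels, index=ndr_scores.index),
        centroids=centroids, k=k, seed=seed)


def anova_fvalues(assignments: pd.Series, features: pd.DataFrame) -> pd.Series:
    """One-way ANOVA F per feature across gene clusters.

    F = between-cluster mean square / within-cluster mean square; a feature
    constant everywhere yields F = 0.
    """
    clusters = assignments.unique()
    sizes = assignments.value_counts()
    if len(clusters) < 2 or (sizes < 2).any():
        raise ValueError("need >= 2 clusters with >= 2 members each")
    out = {}
    for name in features.columns:
        groups = [features.loc[assignments.index[assignments == c], name]
                  .to_numpy(float) for c in clusters]
        if np.std(np.concatenate(groups)) == 0:
            out[name] = 0.0
            continue
        out[name] = float(stats.f_oneway(*groups).statistic)
    return pd.Series(out, name="F")
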