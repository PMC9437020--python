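"""Anchor-centered nucleosome profiles and positioning scores.

An average profile is the mean depth-normalized nucleosome signal at
relative positions around a set of anchors (TSSs at +/-2 kb, motif centers
at +/-1 kb), binned at 10 bp with minus-strand anchors flipped so that
"downstream" always means the direction of transcription.

Two scalar scores summarize a profile.  The NDR (nucleosome depletion)
score contrasts the stronger of the -1/+1 nucleosome peaks with the signal
at the anchor itself,

    NDR = (max(+1, -1) - center) / (max(all) - min(all)),

where +1 is the profile maximum over [+50, +250) bp, -1 the maximum over
[-250, -50), and center the mean over [-50, +50).  NDR lies in [-1, 1];
positive values mean a canonical depleted center flanked by positioned
nucleosomes, negative values a nucleosome sitting on the anchor.  The POS
(phasing) score is the Pearson correlation between the 50-bp-binned profile
over [0, 1000) and the same binning shifted 10 bp downstream; a regular
nucleosome array keeps this lagged correlation high.  The dominant spacing
of an array is measured directly as the period of the strongest Fourier
component within the nucleosome-repeat band (120-300 bp).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.interpolate import make_smoothing_spline

from .fragments import AnchorSet, SignalTrack

log = logging.getLogger(__name__)

TSS_WINDOW = (2000, 2000)
MOTIF_WINDOW = (1000, 1000)
DEFAULT_RESOLUTION = 10
MOTIF_TOP_K = 10000
PERIOD_BAND = (120, 300)


@dataclass
class AverageProfile:
    """Mean nucleosome signal on a relative-coordinate grid around anchors.

    ``values[i]`` is the mean signal over the half-open 10-bp bin whose left
    edge is ``positions()[i]``; the grid runs from -upstream to
    +downstream - resolution.
    """

    values: np.ndarray
    upstream: int
    downstream: int
    resolution: int = DEFAULT_RESOLUTION
    n_anchors: int = 0
    anchor_kind: str = "TSS"
    normalized_by_mean: bool = False

    def positions(self) -> np.ndarray:
        return np.arange(-self.upstream, self.downstream, self.resolution)

    def __len__(self) -> int:
        return len(self.values)


def _anchor_matrix(track: SignalTrack, anchors: AnchorSet, window,
                   resolution: int, strand_flip: bool):
    """Per-anchor signal vectors at ``resolution``; out-of-bounds dropped."""
    up, down = window
    if up % resolution or down % resolution:
        raise ValueError("window must be a multiple of the resolution")
    if track.resolution != 1:
        raise ValueError("profiles require a per-bp track")
    rows, dropped = [], 0
    for row in anchors.anchors.itertuples(index=False):
        size = len(track.values[row.chrom])
        minus = strand_flip and row.strand == "-"
        lo, hi = (row.position - down, row.position + up) if minus else \
                 (row.position - up, row.position + down)
        if lo < 0 or hi > size:
            dropped += 1
            continue
        v = track.values[row.chrom][lo:hi]
        if minus:
            v = v[::-1]
        rows.append(v.reshape(-1, resolution).mean(axis=1))
    if dropped:
        log.info("dropped %d anchors with out-of-bounds windows", dropped)
    if not rows:
        raise ValueError("zero usable anchors")
    return np.asarray(rows)


def anchor_profile(track: SignalTrack, anchors: AnchorSet,
                   window=None, resolution: int = DEFAULT_RESOLUTION,
                   strand_flip: bool = True,
                   top_k: int | None = None) -> AverageProfile:
    """Average the per-anchor signal around an anchor set.

    Motif-center anchor sets are truncated to the top 10,000 sites by motif
    score before averaging (override with ``top_k``).
    """
    if window is None:
        window = MOTIF_WINDOW if anchors.kind == "motif_center" else TSS_WINDOW
    if anchors.kind == "motif_center":
        anchors = anchors.top_by_score(MOTIF_TOP_K if top_k is None else top_k)
    elif top_k is not None:
        anchors = anchors.top_by_score(top_k)
    mat = _anchor_matrix(track, anchors, window, resolution, strand_flip)
    return AverageProfile(values=mat.mean(axis=0), upstream=window[0],
                          downstream=window[1], resolution=resolution,
                          n_anchors=mat.shape[0], anchor_kind=anchors.kind)


def normalize_profile(profile: AverageProfile, sample_mean: float) -> AverageProfile:
    """Divide a profile by the sample-wide mean signal (per bp).

    Puts profiles from samples of different global signal level on a common
    scale so that 1.0 means "average nucleosome density".
    """
    if sample_mean <= 0:
        raise ValueError("sample mean signal must be positive")
    return replace(profile, values=profile.values / sample_mean,
                   normalized_by_mean=True)


def _window_slice(profile: AverageProfile, lo: int, hi: int) -> np.ndarray:
    """Profile values over relative positions [lo, hi) (half-open bins)."""
    pos = profile.positions()
    mask = (pos >= lo) & (pos < hi)
    return profile.values[mask]


def ndr_score(profile: AverageProfile) -> float:
    """Depletion score in [-1, 1]; 0 for a flat profile by convention."""
    if profile.upstream < 250 or profile.downstream < 250:
        raise ValueError("NDR score needs a window covering +/-250 bp")
    plus1 = _window_slice(profile, 50, 250).max()
    minus1 = _window_slice(profile, -250, -50).max()
    center = _window_slice(profile, -50, 50).mean()
    rng = profile.values.max() - profile.values.min()
    if rng == 0:
        return 0.0
    return float((max(plus1, minus1) - center) / rng)


def pos_score(profile: AverageProfile, lag: int = 10, span: int = 1000,
              bin_width: int = 50) -> float:
    """Phasing score: lagged correlation of the 50-bp-binned profile.

    Correlates the binned signal over [0, span) with the binned signal over
    [lag, span + lag); the default 10-bp lag follows the score's printed
    definition (an optional larger ``lag`` is an extension).  Returns 0
    (with a warning) when either binned vector is constant.
    """
    if profile.downstream < span + lag:
        raise ValueError(
            f"POS score needs downstream coverage of {span + lag} bp")
    if bin_width % profile.resolution or lag % profile.resolution:
        raise ValueError("bin width and lag must be multiples of the resolution")
    per = bin_width // profile.resolution
    vi = _window_slice(profile, 0, span).reshape(-1, per).mean(axis=1)
    vj = _window_slice(profile, lag, span + lag).reshape(-1, per).mean(axis=1)
    if np.std(vi) == 0 or np.std(vj) == 0:
        warnings.warn("constant profile; POS score set to 0")
        return 0.0
    return float(stats.pearsonr(vi, vj)[0])


def phasing_fft(profile: AverageProfile, period_band=PERIOD_BAND):
    """Dominant nucleosome repeat length and its spectral intensity.

    The mean-detrended profile is Fourier transformed; among frequency
    components whose period (in bp) falls inside ``period_band``, the one of
    maximum magnitude gives the periodicity, and its magnitude divided by
    the number of profile points gives the intensity (half the amplitude of
    a pure cosine).  A flat profile reports (nan, 0.0).
    """
    v = profile.values - profile.values.mean()
    n = len(v)
    spec = np.abs(np.fft.rfft(v))
    freqs = np.fft.rfftfreq(n, d=profile.resolution)
    with np.errstate(divide="ignore"):
        periods = np.where(freqs > 0, 1.0 / np.maximum(freqs, 1e-300), np.inf)
    mask = (periods >= period_band[0]) & (periods <= period_band[1])
    if not mask.any():
        raise ValueError("no Fourier component falls in the period band")
    if not np.any(v):
        return float("nan"), 0.0
    idx = np.flatnonzero(mask)[np.argmax(spec[mask])]
    return float(periods[idx]), float(spec[idx] / n)


def smooth_profile(profile: AverageProfile,
                   stiffness: float | None = None) -> AverageProfile:
    """Cubic smoothing-spline fit, for visualization only.

    The smoothing parameter is chosen by generalized cross-validation when
    ``stiffness`` is unset.  Scores are always computed on raw profiles.
    """
    if len(profile) < 10:
        raise ValueError("smoothing needs at least 10 points")
    x = profile.positions().astype(float)
    spl = make_smoothing_spline(x, profile.values, lam=stiffness)
    return replace(profile, values=spl(x))


def per_anchor_scores(track: SignalTrack, anchors: AnchorSet, window=None,
                      resolution: int = DEFAULT_RESOLUTION,
                      strand_flip: bool = True, score: str = "ndr") -> np.ndarray:
    """Score each anchor's own profile (for group comparisons)."""
    if window is None:
        window = MOTIF_WINDOW if anchors.kind == "motif_center" else TSS_WINDOW
    mat = _anchor_matrix(track, anchors, window, resolution, strand_flip)
    scorer = {"ndr": ndr_score, "pos": pos_score}[score]
    out = np.empty(mat.shape[0])
    for i, row in enumerate(mat):
        p = AverageProfile(values=row, upstream=window[0], downstream=window[1],
                           resolution=resolution, n_anchors=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out[i] = scorer(p)
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return stats.false_discovery_control(np.asarray(pvalues, float), method="bh")


def compare_profiles(scores_a, scores_b, alternative: str = "greater",
                     method: str = "auto"):
    """Compare per-anchor score distributions between two groups.

    Returns ``(delta, p)``: the difference of medians (A - B) and the
    one-sided Wilcoxon rank-sum p-value for A ``alternative`` B (``method``
    is passed through to the rank-sum test; "exact" enumerates the tail for
    small tie-free samples).  Adjust a batch of such p-values with
    :func:`bh_adjust`.
    """
    a, b = np.asarray(scores_a, float), np.asarray(scores_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 scores per group")
    delta = float(np.median(a) - np.median(b))
    p = float(stats.mannwhitneyu(a, b, alternative=alternative,
                                 method=method).pvalue)
    return delta, p
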