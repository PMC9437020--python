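# Methods

## Scope and data model

`nucleotune` analyzes paired-end MNase-seq fragments from ultra-low-input
chromatin samples — gametes and pronucleus-stage embryos are the motivating
case — and quantifies three things: where nucleosomes are (occupancy), how
they are arranged around regulatory anchors (depletion and phasing), and
which transcription factors' motif sites change from nucleosome-covered to
nucleosome-depleted across a developmental series (regulator screening).

All coordinates are 0-based half-open (BED convention) internally; 1-based
formats are converted at the boundary.  Alignment is upstream of this
package: input is aligned fragments (BED3+) or a paired-end BAM/SAM, from
which one fragment per template is taken (leftmost mate start to rightmost
mate end, proper pairs only, MAPQ ≥ 10 by default for BAM; BED is assumed
pre-filtered).

## Pileup and normalization

A fragment of any length is reduced to the 146-bp window centered on its
midpoint — the nucleosome core-particle footprint — before piling
(mid-point of an odd-length fragment uses floor division; windows crossing
a chromosome edge are clipped, not dropped, so counts are conserved).  For
sharper visual profiles only the middle 74 bp are piled.  Tracks are
multiplied by `target_depth / n_fragments` with `target_depth` = 5×10⁸
read pairs, putting all samples on one depth scale; one fragment counts as
one read pair.  Sub-nucleosomal fragments (5–50 bp, characteristic of
sperm-specific packaging) are piled unless an explicit length filter is
requested, since excluding them is an analysis decision, not a default.

## Quality control

* **Length spectrum**: computed on a seeded random subsample (10⁶ pairs by
  default); histogram support is 1–1000 bp with longer fragments lumped
  into the last bin.  The mono-nucleosomal band is 120–180 bp, the
  sub-nucleosomal band 5–50 bp (both inclusive).
* **Genome coverage**: the fraction of consecutive 200-bp bins touched by
  at least one 146-bp nucleosome window.  This statistic doubles as the
  occupied-genome fraction `gr` below.
* **Replicates**: Pearson correlation of mean relative occupancy over
  ±2-kb promoter windows (read off the 1-kb occupancy table; the window
  granularity is a package choice, as the underlying statistic is defined
  only as "normalized nucleosome occupancy").  Replicates are pooled —
  fragment lists concatenated, then re-normalized — when *r* > 0.8,
  strictly; a `--force-pool` escape hatch exists because very sparse
  samples (sperm-like) legitimately fail this bar through near-random
  nucleosome retention rather than technical failure.

## Relative occupancy

The genome is divided into consecutive 1-kb bins, a resolution matched to
the sparseness of low-input samples.  Each fragment is assigned to exactly
one bin, the one containing the midpoint of its nucleosome window
(midpoint assignment preserves total counts; overlap-weighted assignment
would not).  With `N` the depth-normalized count, the relative occupancy is

    O = N / ((146 * s) / (g * gr))

where `s` = 5×10⁸ (normalized depth), `g` the genome size and `gr` the
occupied-genome fraction estimated from the same sample at 200-bp
resolution (a user-supplied `gr` is accepted).  The denominator is the
expected per-base fragment coverage under uniform placement over the
occupied part of the genome, applied per bin exactly as written — no
per-kilobase rescaling — so the occupancy call cutoff (*O* > 0.3, strict)
is the model's operating point and absorbs the scale.  `gr` is estimated
from raw coverage before `N` is depth-normalized.  Classification over a
stage series, with stage order always taken from configuration:

* *occupied*: `O > 0.3`;
* *retained* (gamete stage): `O > 3`, strict;
* *newly established at stage t*: `O_t > 0.3` and `O_u <= 0.3` for every
  earlier stage `u`; the first stage's occupied bins are its own
  newly-established set.  A bin is therefore newly established at most
  once.

Element enrichment of a region set is observed/expected: (overlap length /
region length) / (element length / genome size), on merged intervals.

## Profiles and positioning scores

Average profiles are the mean per-anchor signal at relative positions
around an anchor set — ±2 kb for TSSs, ±1 kb for motif centers, 10-bp bins
(the granularity of the POS lag), minus-strand anchors flipped so
"downstream" is transcription direction.  Motif anchor sets are truncated
to the top 10,000 sites by motif score.  Anchors whose window leaves the
chromosome are dropped and counted.  For cross-sample comparison a profile
is divided by the sample-wide mean signal per bp.

* **NDR score** = (max(+1, −1) − center) / (max(all) − min(all)), where +1
  is the profile maximum over [+50, +250) bp, −1 the maximum over
  [−250, −50), center the mean over [−50, +50), and "all" the full window.
  All windows are half-open on the 10-bp grid (the inclusive/exclusive
  choice is unstated in the score's published form; half-open is fixed here
  for determinism).  The score lies in [−1, 1]; a flat profile returns 0 by
  convention.  Positive means a canonical depleted center; negative means
  the anchor itself is occupied.
* **POS score** = Pearson correlation between the 50-bp-binned profile
  over [0, 1000) and the same binning over [10, 1010).  Implemented
  verbatim.  Note the consequence: adjacent bins share 4/5 of their source
  points, so even white noise scores ≈ 0.8 — the score separates phased
  from unphased profiles in its upper range, not around 0.  An optional
  larger `lag` is provided as a clearly-marked extension.  Zero variance in
  either binned vector returns 0 with a warning, mirroring the flat-profile
  NDR convention.
* **Phasing periodicity/intensity**: the profile is mean-detrended and
  Fourier transformed; among components whose period falls in the
  nucleosome-repeat band (120–300 bp, configurable), the maximum-magnitude
  component gives the periodicity, and its magnitude divided by the number
  of profile points gives the intensity (half the amplitude for a pure
  cosine).  Scores are always computed on raw profiles; the cubic
  smoothing spline (generalized cross-validation when no stiffness is
  given) exists for visualization only.

Group comparisons of per-anchor scores use the one-sided Wilcoxon rank-sum
test with Benjamini–Hochberg adjustment across a batch.

## Regulator screening

For each TF (motif sites supplied as BED6+score, database-style; motif
scanning is out of scope) the NDR score of its site-averaged profile is
computed per stage, giving a TF × stage matrix.  Seeded k-means (k = 3,
25 restarts) on the raw rows — no z-scaling by default, since the rows are
already on the common [−1, 1] scale — is relabeled deterministically: the
cluster with the largest mean first-to-last NDR gain is cluster k (the
closed-to-open class), and the remaining clusters are numbered by ascending
first-stage mean, so cluster 1 is always-occupied and cluster 2 always-open.
Rows are fitted in name order, making membership independent of input
order.

ZGA-promoter enrichment of a TF is the odds ratio
(|ZGA promoters with motif| / |promoters with motif|) / (|ZGA genes| /
|all genes|), where a promoter "contains" a motif when at least one site
center lies within ±2 kb of the TSS.  Per-TF significance is a one-sided
hypergeometric test for over-representation, BH-adjusted across TFs (the
choice of test is the package's; cluster-level comparisons of ratio
distributions use the rank-sum machinery above).  Candidates are cluster-k
TFs with adjusted p < 0.05, split into a maternally-stored tier
(FPKM ≥ 1 in the oocyte, cutoff inclusive) and a reported non-maternal
tier, sorted by enrichment ratio.  Expression filtering keeps TFs with
FPKM ≥ 1 in any of the requested stages by default (`--all-stages`
switches to all, since either reading of "expressed at stages X–Z" is
defensible).

## Determinant analyses

First-order partial correlation is computed the residual way: ordinary
least squares (with intercept) of target and of feature on the confounder,
then Pearson correlation of the residuals — algebraically equal to the
closed form (r_xy − r_xz·r_yz)/√((1−r_xz²)(1−r_yz²)), which the tests
verify to 1e-10.  For stage series the confounder is the previous stage's
values; for occupancy, rows can be restricted to bins unoccupied at the
previous stage so the correlation describes newly gained occupancy (the
subset rule is the package's reading of an ambiguous published procedure).
Gene promoters are clustered by NDR trajectory (seeded k-means, k = 7),
labels C1..Ck ordered by descending mean NDR then earlier onset (first
stage whose centroid exceeds 0), and per-feature association with the
clusters is the one-way ANOVA F-value on per-gene signals.

## The synthetic-data generator

The generator emulates the study conditions at desk scale and is the
ground truth for every recovery test.

* **Genome**: 3 chromosomes × 2 Mb — ~6,000 1-kb bins, large enough for
  stable fraction estimates yet desk-sized.
* **Stages**: sperm → early PN → late PN with occupied fractions
  0.15 / 0.5 / 0.8, the trajectory of a paternal genome rebuilding
  nucleosomes after protamine removal (sperm-like sparseness, then
  near-complete occupancy).  Occupied territory is nested across stages.
* **Fragments**: 5×10⁴ per stage.  Mono-nucleosomal lengths are truncated
  normal (147 ± 15 bp on [100, 200]); the sperm stage carries 20%
  sub-nucleosomal contamination (uniform 5–50 bp), later stages none.
* **Anchors**: 300 gene TSSs and 6 TFs × 80 motif sites live at the
  centers of disjoint 5-kb slots, so ±2-kb windows never overlap.  NDR
  depths cycle through {0, 0.3, 0.6}; promoters activate at the second
  stage.  Phased arrays put Gaussian bumps (sd 20 bp, amplitude 2× the
  background) at −150 bp and at +150 + k·190 bp for k = 0..9; placement
  density within ±100 bp of an open anchor is multiplied by (1 − depth).
  TF classes: `closed` (center bump every stage), `open` (depleted center
  with array every stage), `rising` (closed until the last stage, then
  open).
* **Placement**: an explicit per-bp density (occupied-bin indicator, times
  suppression, plus bumps) sampled by inverse CDF — the generative model
  is inspectable and unit-testable.  Anchor footprint bins count toward
  the planted occupied fraction; remaining territory is filled in order of
  descending per-bin GC content (GC ~ clipped Normal(0.45, 0.08)), which
  plants the GC preference of early nucleosome establishment that the
  partial-correlation analysis is designed to detect.  The emitted FASTA
  realizes the per-bin GC values.
* **Determinism**: one `numpy` Generator seeded from the spec; identical
  seeds give byte-identical outputs, and every planted value is written to
  `truth.json`.

What the generator does **not** model: MNase digestion bias,
sequence-dependent nucleosome energetics, replication timing, or any
coupling between expression and chromatin beyond the planted labels.
Passing recovery tests therefore demonstrates that the estimators measure
what they claim on data matching their assumptions — not that real
embryonic chromatin satisfies those assumptions.

Score-matrix fixtures (`make_score_fixture`, `make_screening_panel`)
plant class-template trajectories plus Gaussian noise (σ = 0.02 standard),
with the screening panel additionally planting ZGA enrichment (30% of
motif promoters in the ZGA set vs 10% background, 1,000 genes) for five
rising TFs, of which three are maternally expressed — the expected
candidate set.

## Numerical conventions and limitations

* Midpoints use floor division; all score windows are half-open; cutoffs
  (0.3, 3, 0.8, FPKM 1) follow their published strict/inclusive forms
  exactly (0.3 and 3 strict, FPKM ≥ 1 inclusive).
* k-means is seeded with 25 restarts and fitted in deterministic row
  order; duplicated rows always co-cluster and membership is invariant to
  input permutation.
* The NDR score saturates: once the depleted center is the profile's
  global minimum, the denominator approaches the numerator and deep NDRs
  compress toward 1, so the contrast between two already-deep depths
  (e.g., planted 0.3 vs 0.6) is small relative to anchor-sampling noise at
  ~100 anchors per group.  The default fixture's depth ordering is strict
  at its standard seed; at arbitrary seeds the deepest two groups can
  occasionally swap.  This is a property of the published score, kept
  verbatim by design.
* POS is a 10-bp-lag autocorrelation of overlapping 50-bp bins and is high
  for any smooth profile (≈ 0.8 white-noise baseline); interpret it
  relative to that baseline.
* Flat-profile conventions: NDR = 0, POS = 0, FFT intensity 0 with
  periodicity undefined (NaN).
* Degenerate inputs fail loudly: empty fragment sets, zero-variance
  replicate vectors, gr = 0, windows too small for a score, k exceeding
  the number of rows.
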