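# nucleotune

Nucleosome occupancy, positioning and regulator screening from
ultra-low-input MNase-seq fragments.

MNase digestion protects nucleosome-wrapped DNA; paired-end sequencing of
the protected fragments (~147 bp for a mono-nucleosome) reads out where
nucleosomes sit.  In ultra-low-input settings — for example pronucleus-stage
mouse zygotes, where only 10–15 nuclei are available per reaction — the
resulting fragment sets are sparse and noisy, and standard peak-calling
approaches do not apply.  `nucleotune` implements a complete analysis stack
for such data, aimed at developmental epigenomics groups studying chromatin
remodeling after fertilization:

1. **Pileup & QC** — fragments are reduced to midpoint-centered 146-bp
   nucleosome windows (74 bp for sharper visualization), piled per base and
   depth-normalized to a common scale of *s* = 5×10⁸ read pairs; QC reports
   the fragment-length spectrum (mono-nucleosomal 120–180 bp vs
   sub-nucleosomal 5–50 bp contamination), 200-bp genome coverage, and
   replicate reproducibility (replicates pooled when promoter-occupancy
   Pearson *r* > 0.8).
2. **Occupancy** — the genome is split into 1-kb bins; a bin with
   depth-normalized count *N* gets a relative occupancy

   *O* = *N* / ((146 · *s*) / (*g* · *gr*)),

   the ratio of observed to expected nucleosome fragments given genome size
   *g* and the sample's occupied-genome fraction *gr*.  Bins with
   *O* > 0.3 are called occupied; *O* > 3 in a gamete sample marks retained
   nucleosomes; a bin occupied now but never before is *newly established*.
3. **Profiles & scores** — average nucleosome signal around anchors (TSSs
   at ±2 kb, motif centers at ±1 kb, 10-bp bins, strand-aware).  The NDR
   score, NDR = (max(+1, −1) − center) / (max(all) − min(all)), contrasts
   the −1/+1 nucleosome peaks with the anchor-center signal (positive =
   depleted center); the POS score is the Pearson correlation of the
   50-bp-binned downstream profile with its 10-bp-lagged copy; the
   nucleosome repeat length is the period of the strongest Fourier
   component in the 120–300 bp band.
4. **Screening & determinants** — a TF × stage matrix of NDR scores on each
   factor's top motif sites is k-means clustered (k = 3) into
   always-occupied, always-open, and closed-to-open classes; closed-to-open
   factors whose motif-bearing promoters are enriched for
   zygotic-genome-activation genes and that are maternally expressed
   (FPKM ≥ 1 in the oocyte) are ranked as candidate pioneer factors.
   Partial correlations (controlling for the previous stage) relate newly
   established occupancy or promoter NDRs to genomic features such as GC
   content, and genes are clustered by NDR-score trajectory (k = 7) with
   per-feature ANOVA F-values.

A first-class synthetic-data module generates fragment datasets with
planted architecture (occupied fractions, NDR depths, phased arrays, TF
dynamic classes, length contamination) so every stage of the pipeline is
testable without external data; every planted parameter lands in an emitted
`truth.json`.

## Worked example

```python
from nucleotune import simulate, occupancy, profiles, pileup

data = simulate.generate()                       # seed 7, 3 x 2 Mb, 5e4 fragments/stage
table = occupancy.occupancy_from_fragments(data.fragments["pn_6h"])
print(f"gr = {table.gr:.3f}, occupied fraction = {table.occupied_fraction():.3f}")

track = pileup(data.fragments["pn_6h"])          # 146-bp occupancy pileup, depth 5e8
prof = profiles.normalize_profile(
    profiles.anchor_profile(track, data.tss), track.mean())
print(f"NDR = {profiles.ndr_score(prof):.3f}, POS = {profiles.pos_score(prof):.3f}")
period, intensity = profiles.phasing_fft(prof)
print(f"repeat length = {period:.1f} bp (intensity {intensity:.3f})")
```

prints

```
gr = 0.801, occupied fraction = 0.800
NDR = 0.875, POS = 0.971
repeat length = 190.5 bp (intensity 0.056)
```

The synthetic sample planted 80% of 1-kb bins as occupied, and the
estimated occupied-genome fraction (`gr`) and called occupied fraction both
recover it.  The positive NDR score says promoters carry a depleted center
flanked by positioned −1/+1 nucleosomes; the high POS score and the
190.5-bp Fourier period recover the planted 190-bp nucleosome repeat
(190.5 bp is the nearest frequency bin of a ±2-kb window).

The same steps are available as a CLI:

```sh
nucleotune simulate --seed 7 -o fix/
nucleotune qc --fragments fix/fragments_sperm.bed --chrom-sizes fix/chrom.sizes -o qc/
nucleotune occupancy --fragments fix/fragments_pn_6h.bed --chrom-sizes fix/chrom.sizes -o occ
nucleotune pileup --fragments fix/fragments_pn_6h.bed --chrom-sizes fix/chrom.sizes -o t.bedgraph
nucleotune profile --track t.bedgraph --chrom-sizes fix/chrom.sizes --anchors fix/tss.bed -o p.tsv
nucleotune score --profile p.tsv -o scores.json
```

Every run writes a provenance record (parameters, package version, input
checksums) and is byte-reproducible for a fixed seed.

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator, the
numerical conventions and the known limitations in detail.
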