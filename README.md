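# epitype

Condition-specific transcription-factor binding sites, accessibility signal
matrices, and Type 1 / Type 2 enhancer classification over factor-withdrawal
time courses.

## The problem

Inducible expression systems make it possible to ask what a single
transcription factor does to chromatin: express the factor (e.g. Pax7 under
doxycycline control in myogenic precursors), map its binding and the
surrounding chromatin state, then withdraw the inducer and follow
accessibility (ATAC-seq) and enhancer histone marks (H3K4me1, H3K27ac) at
12 h, 24 h and 3 d. Two behaviours emerge at bound sites:

* **Type 1** — accessibility and enhancer marks collapse within the first
  withdrawal timepoint: open chromatin strictly depends on the factor.
* **Type 2** — accessibility persists for days after the factor is gone,
  typically with another factor (MyoD-like) bound a short distance away.

`epitype` implements the complete downstream analysis as a tested,
reproducible library:

* BED/bedGraph interval model (0-based half-open; ≥1-shared-base overlap);
* consensus site derivation: regions supported by ≥2 treatment replicates
  and absent from every control replicate;
* coverage tracks (3' fragment extension; ATAC +4/−5 Tn5 offset
  correction; reads-per-million normalisation), reference-point matrices
  (±1.5 kb around peak centres), metagene profiles and a flank/centre
  bimodality index;
* k-means classification of baseline-scaled accessibility profiles into
  Type 1 / Type 2, background-calibrated accessibility calls, and the
  Pearson chi-square test for accessibility change;
* enhancer-mark categories (H3K4me1 / H3K27ac / both / neither) and
  per-class retention after withdrawal;
* nearest-TSS distance classes (promoter ≤1 kb / distal >5 kb),
  centre-to-centre co-factor proximity, the ≥2-fold expression signature,
  and PCA of sample accessibility with optional restriction to bound sites;
* a ground-truthed synthetic-data generator so every stage is testable
  without downloads, and a pipeline runner with a reproducibility manifest.

## Worked example

`examples/` contains one short script per capability. Classifying sites on
the default synthetic study (`python examples/03_classify_site_types.py`):

```
     +Dox: 500/500 sites accessible (threshold 0.626 normalised units)
 -Dox_12h: 200/500 sites accessible (threshold 0.979 normalised units)
 -Dox_24h: 200/500 sites accessible (threshold 1.018 normalised units)
  -Dox_3d: 200/500 sites accessible (threshold 1.051 normalised units)
classified: 300 Type 1, 200 Type 2
agreement with simulated ground truth: 100.0%
accessibility loss +Dox -> 12h: chi-square = 428.6, p = 3.33e-95
```

All 500 simulated sites are open while the factor is expressed; by 12 h the
300 Type 1 sites have dropped below the accessibility threshold while the
200 Type 2 sites persist, the classifier recovers the planted labels from
the accessibility time course alone, and the chi-square test quantifies the
significance of the loss. The metagene companion script shows the
H3K27ac bimodality index at Type 1 sites falling monotonically
(6.11 → 1.99 → 1.59 → 1.18) across the withdrawal course — the collapse of
the flanking-nucleosome enhancer signature.

The same operations are available from a thin CLI
(`epitype run|simulate|consensus|matrix|classify|annotate|proximity|signature|pca`),
e.g.:

```bash
epitype consensus --treatment r1.bed --treatment r2.bed --treatment r3.bed \
    --control c1.bed --min-support 2 --out sites.bed
```

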