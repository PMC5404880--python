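# Methods

`epitype` re-implements, as a tested library, the computational analysis by
which condition-specific transcription-factor binding sites are derived from
replicate peak calls and classified into factor-dependent (Type 1) and
factor-independent (Type 2) enhancer classes over a factor-withdrawal time
course, together with the surrounding signal, annotation and expression
statistics. The motivating biology is an inducible myogenic system: Pax7 is
expressed under doxycycline control in ES-derived muscle precursors, and the
chromatin response to switching the factor off is followed by ATAC-seq and
histone-mark ChIP-seq at 12 h, 24 h and 3 d after withdrawal.

## Coordinate and overlap conventions

All intervals are 0-based half-open (BED convention). Overlap requires at
least one shared base; no reciprocal-fraction requirement is applied
anywhere, and abutting half-open intervals are *not* merged or counted as
overlapping. Peaks are treated as unstranded; strand is carried only for
reads and TSS records (a TSS is the strand-aware 5' end of its BED record).
Chromosome names are matched as exact strings. A peak's centre is
`floor((start + end) / 2)`.

## Consensus binding sites

The final site list applies two rules to per-replicate peak calls:
candidate regions are the merged union of all treatment-replicate peaks; a
candidate is kept when peaks from at least `min_treatment_support` distinct
treatment replicates overlap it (default 2) and removed whole when any
control-replicate peak overlaps it. Merged-union candidates make "found in
k replicates" well defined without summit information; subtraction removes
peaks, not base pairs. Output intervals keep merged-candidate coordinates,
sorted by (chrom, start, end), with the support count in the score column.

Note that the number of output intervals is not monotone in the number of
treatment replicates in full generality: a new replicate can contribute a
bridging peak that merges two previously distinct candidates. The
monotonicity property is exercised on non-bridging (slot-separated) inputs,
where it holds; control-replicate monotonicity (adding controls never
increases the output) holds unconditionally and is tested on unrestricted
random inputs.

## Signal tracks and matrices

ChIP-style coverage extends each read 3' by the library's mean fragment
length (configurable; typical values 150–250 bp). A minus-strand read
covers `[p − L + 1, p + 1)` so its 5' base is included and each read
contributes exactly L bases — mass is conserved exactly, and coverage
clipped at chromosome ends is accounted in `clipped_mass`. ATAC read 5'
ends are first shifted +4 bp (plus strand) / −5 bp (minus strand) onto the
Tn5 insertion centre; positions are clipped at zero rather than dropping
reads, preserving the read count. Reads on configurable mitochondrial
chromosome names (default `chrM`) are removed before ATAC analysis. Tracks
are normalised to reads per million.

Reference-point matrices sample the track in `[centre − w, centre + w)`
(default w = 1500 bp) in bins aggregated by mean per-base value (default
50 bp; the window must divide evenly). Bins extending past chromosome ends
are zero-filled. Site rows are never flipped (peak centres are
unoriented). The metagene profile is the column mean. The bimodality index
is the mean over flank bins spanning [−1000, −200) and [200, 1000) divided
by the mean over the centre bins [−200, 200) (+1e-9): values above 1
indicate the flanking-nucleosome configuration of active enhancers. The
flank/centre windows and the bin size are declared defaults of this
package, not reconstructions of any published parameterisation.

## Accessibility, classification and testing

Per-site accessibility at a timepoint is the mean normalised signal over
the centre ±250 bp. A site is called *accessible* when this scalar exceeds
`max(q-quantile of background, min_fold × median background)`, with
background scalars measured at random positions of the same track
(avoiding the site set), q = 0.75 and min_fold = 10 by default. The
fold-enrichment floor is essential: when genome-wide background is low, a
site retaining even 10% of a strong signal sits far above any background
quantile, so a pure quantile rule cannot express loss of accessibility;
a ~10-fold enrichment floor matches the order of enrichment of called
open-chromatin regions.

Sites are clustered by k-means (scikit-learn, k-means++ initialisation,
fixed seed, k = 2 by default) on accessibility profiles scaled by their
induced-condition baseline. Cluster labels — never per-site labels — are
assigned by the cluster's mean persistence ratio (first-withdrawal /
baseline signal): below 0.5 → Type 1, else Type 2. Sites with zero
baseline cannot be scaled and are reported `unassigned`. Classification is
invariant to site order and to global positive rescaling of the profiles.

Accessibility change between two conditions is tested with the Pearson
chi-square on the 2×2 accessible/inaccessible × condition table, one
degree of freedom, no continuity correction (the uncorrected form is the
default meaning of "chi-square test" and is verifiable against
Σ(O−E)²/E). Zero row or column totals are an error.

Enhancer signatures assign each site one of four mutually exclusive
categories from its overlap with H3K4me1 and H3K27ac peak sets (both /
either alone / neither); fractions are exact rationals over the site
count. Retention per type class is the fraction of sites carrying both
marks before withdrawal that still carry both after.

PCA mean-centres sites (features) across samples and projects samples on
the right singular vectors; explained-variance fractions are reported in
non-increasing order, and each component's sign is fixed so its
largest-magnitude loading is positive (reproducible output). An optional
restriction keeps only features overlapping a peak set — the contrast
between the all-sites projection (grouping by cell of origin) and the
bound-site projection (separating factor-expressing samples) is the
analysis's signature result.

## Annotation statistics

Nearest-TSS distances are measured centre-to-TSS on the same chromosome,
signed positive when the TSS lies downstream of the centre; ties go to the
smaller coordinate, then the lexicographically smaller gene name. Distance
classes: promoter ≤ 1 kb, distal > 5 kb, with the 1–5 kb band reported as
"intermediate" so the three classes always partition the site list.
Centre-to-centre proximity between two factors' peak sets reports each
A-peak's nearest B centre within `max_distance` (default 2000 bp, a local
search cap) and the median over matched peaks. The expression signature
keeps genes expressed in satellite cells (normalised count > 1 by
default) and splits them by a pseudocounted (±1) ratio between the induced
and withdrawn conditions at a 2-fold threshold; for thresholds ≥ 1 the up
and down lists are disjoint.

## The synthetic study

The generator emulates the structure the analysis assumes, not real
sequencing data. Defaults — which are the study conditions used by the
tests and the acceptance script — are: a 3 × 2 Mb genome; 500
non-overlapping sites of 300 bp placed one per equal slot; exactly 60%
Type 1; per-timepoint accessibility decay (1, 0.1, 0.05, 0.02) for Type 1
and (1, 0.9, 0.88, 0.85) for Type 2; three treatment and two control
replicates with 90% per-replicate sensitivity, ±10 bp edge jitter and 5
false peaks/Mb placed away from true sites (controls contain only false
peaks); 200 expected reads per site per track over a 0.01 reads/base
background. ATAC signal is a centre Gaussian (σ = 100 bp); H3K4me1/H3K27ac
are symmetric flank Gaussians at ±500 bp (σ = 150 bp) halved between the
flanks and decaying with the site's class; H3K4me3 sits at planted TSSs
only; H3K27me3 occupies 30 blocks of 20 kb kept disjoint from all sites
(asserted at generation). Counts are per-base Poisson draws from these
rate profiles. Co-factor peaks are placed at folded-normal centre offsets
(σ = 356 bp, median ≈ 240 bp) near Type 2 sites only. Mark-peak retention
after withdrawal is 20% (Type 1) vs 90% (Type 2). The expression table
plants a fold grid (4, 2.5, 2, 1, 0.5, 0.4, 0.25) on base counts floored
at 50 with 5% log-normal noise, so folds ≥ 2.5 are safely (≈3σ) above
the 2-fold threshold after pseudocounting; 80% of genes are
satellite-expressed. The accessibility panel for PCA uses the sample
layout of the motivating study (iPax7 time course, satellite cells, C2C12
myoblasts ± factor, myotubes), a strong per-origin batch effect (σ = 3.5)
on 2000 background sites and a bound-site contrast of 5 vs 1 units, so
batch dominates the unrestricted projection while factor status dominates
the restricted one. All stage streams derive from one seed via
`default_rng([seed, stage_id])`; identical config + seed reproduce
byte-identical outputs.

What the generator does *not* model — sequence content, mappability, GC
and fragment-size bias, replicate-specific depth, peak-width variation,
partially penetrant decay — bounds what passing tests show: they validate
the pipeline's logic, determinism and statistical behaviour under its own
assumptions, not performance on real libraries.

A deterministic synthetic stand-in (`reference_site_standin`) reproduces
the published binding-site supplement's *format and region count* (2455
BED records on mouse-named chromosomes) for parser testing; its
coordinates carry no biology.

## Numerical and degenerate-input choices

Background thresholds and k-means are seeded; k-means on fewer distinct
rows than clusters is accepted (a degenerate cluster, no crash).
Chi-square with an empty row/column, PCA with fewer than two
samples/features, metagenes of empty matrices, empty TSS annotations and
empty query sets for overlap fractions all raise errors rather than
returning sentinel values; proximity with no matched partner reports an
undefined (None) median. Matrix equality against per-base brute force is
exact to 1e-12; the chi-square closed form agrees to 1e-9 relative.

## Problem sizes

Tests and the acceptance script run the full default study (500 sites,
6 Mb genome, per-base Poisson tracks for two assays × four timepoints) in
seconds; randomized oracle checks use hundreds of instances of ≤50 peaks
or ≤50 kb chromosomes, sizes at which brute-force per-base oracles remain
exact and fast.

## Known limitations

Peak calling itself, read alignment, duplicate marking, motif discovery
and GO enrichment are out of scope (consumed upstream or omitted). BigWig
and BAM are not parsed; the text formats (BED, bedGraph, TSV) are the
interchange surface. The original study's headline counts (2455 sites,
41 kb median TSS distance, 337/236 bp proximity medians, the published
overlap percentages) derive from deposited sequencing data and are not
reproducible from scratch at desk scale; this package validates the
method's properties on ground-truthed synthetic data instead, and its
annotation statistics on the synthetic genome are on the genome's own
scale (medians of kilobases, not tens of kilobases).
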