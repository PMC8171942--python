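# Methods

`nucdyn` analyses nucleosome dynamics from MNase-seq mono-nucleosome
fragments alongside RNA-seq counts: it builds occupancy tracks, calls
nucleosome peaks per condition, tests matched peaks for differential
positioning, estimates the nucleosome repeat length from phasograms,
anchors per-gene occupancy profiles on the +1 nucleosome, clusters
differential profiles, runs a lightweight negative-binomial differential
expression analysis, and scores DEG/DPN-gene overlaps.  Every stage is
exercised end to end on synthetic data with planted ground truth.

## Fragment model and occupancy tracks

The sequenced unit is a mono-nucleosome fragment (0-based half-open BED
interval); its integer midpoint, `floor((start + end) / 2)`, approximates
the nucleosome dyad.  An occupancy track places one unit of mass per
fragment as a symmetric triangular kernel centred on the midpoint.

* **Kernel half-width** (`bandwidth`, default 36 bp ≈ a quarter
  nucleosome).  Smoothing width is not a property of the data model, so it
  is an exposed knob; mass is conserved exactly because kernels clipped at
  chromosome edges are re-normalised per fragment.
* **Depth normalisation** scales each library linearly to the mean library
  mass.  Linear scaling keeps mass arithmetic analytically checkable;
  quantile-style alternatives would change peak heights non-linearly and
  are out of scope.

## Peak calling and the three dynamics tests

Peaks are local maxima above a height threshold (default: twice the
genome-wide mean signal), selected greedily by height with a 120 bp
exclusion radius (ties: leftmost).  The peak interval is summit ± 73 bp,
clipped at midpoints to neighbouring summits.  Per-peak fuzziness is the
population SD of fragment midpoints inside the interval.

Peaks from the two conditions are paired by mutual nearest neighbours
within 90 bp; an unmatched peak is paired with a zero-occupancy
pseudo-peak spanning the same interval.  Each pair is scored on three
parameters:

* **occupancy** — exact conditional binomial test on the fragment counts
  of the two conditions inside the union interval, with the null success
  probability set by the library-depth ratio (the conditional form of the
  two-sample Poisson rate test).  Fragments of *both* conditions are
  counted in the interval even when only one condition has a called peak,
  so appearance/disappearance events are measured against the observed
  data rather than an assumed zero.
* **fuzziness** — two-sided variance-ratio (F) test on midpoints; needs
  ≥ 8 fragments per side, otherwise the pair is excluded from this family.
* **position** — Welch t test on midpoints; the position change is the
  difference of mean midpoints.  Skipped for pseudo-peak pairs.

These particular tests are a design choice: the three-parameter reporting
scheme is standard for nucleosome dynamics tools, but the internal
statistics are not canonical, so they sit behind a single scoring
interface and can be swapped.  P-values are Benjamini–Hochberg adjusted
*within each family separately*, and a pair is a differentially positioned
nucleosome (DPN) when any family q-value is below the FDR threshold
(default 0.01); the significant families label the DPN's categories.

Replicates are pooled per condition before calling; a replicate-aware
mixed model is a non-goal.

## Phasograms and repeat length

The phasogram is the histogram of pairwise midpoint distances on the same
chromosome (1 bp bins, default up to 1500 bp), computed exactly via
autocorrelation of the midpoint count histogram (identical to all-pairs
enumeration, verified against a brute-force oracle).  The histogram is
smoothed with a 31 bp moving average; local maxima at least 120 bp apart
and at distance ≥ 120 bp (excluding the self-adjacency artefact near zero)
are regressed on their rank.  The slope is the nucleosome repeat length in
bp per nucleosome; fewer than 3 peaks raises an "insufficient periodicity"
error.  Condition comparisons use a two-sided paired t test with the
chromosome as the pairing unit (replicate-level pairing is possible by
passing per-replicate slopes); identical slope lists return p = 1 rather
than a 0/0 t statistic.

Distances are midpoint-to-midpoint, matching the generator and the
coverage model; read-start phasograms would shift the intercept but not
the slope.

## Gene context

Regions are strand-aware, 0-based half-open: promoter = 1,000 bp upstream
of the TSS in the transcription direction, TSS region = 180 bp centred on
the TSS, body = TSS to TES, plus the promoter+body union.  A DPN is
assigned to a gene when its summit lies inside the selected region class
(default promoter+body); a DPN may hit several genes, and overlapping
genes on opposite strands both receive hits.

The +1 nucleosome is the first peak summit downstream of TSS − 50 within
[TSS − 50, TSS + 250] (transcription-oriented); the window is a
configurable choice since the data themselves do not define one.  Genes
without a +1 call are excluded from profiles and counted.  Metaprofiles
extract the track in a window around the +1 dyad (default −1000..+1500 bp,
10 bp bins, minus-strand genes reversed); differential profiles subtract
mock from treated after depth normalisation, pooling replicates per
condition before differencing.

Differential profiles are clustered with K-means (k = 6 by default,
k-means++ initialisation, best of 20 restarts, fixed seed) on the raw
binned values — profiles are deliberately not z-scaled per gene, because
the magnitude of the occupancy change is part of the pattern; a
standardised variant only needs pre-scaling the matrix.  Cluster ids are
relabelled 1..k by descending size so labels are stable.

## Differential expression

Size factors are median-of-ratios over genes with nonzero counts in all
samples, normalised to geometric mean 1.  Per-gene NB dispersion
(var = μ + αμ²) is method-of-moments pooled within conditions, shrunk 50%
toward the median dispersion of the gene's expression decile, floored at
1e-8.  Each gene gets a Wald test of the condition effect: group means are
NB maximum-likelihood estimates (Newton iterations on the score equation,
vectorised across genes, with size factors as offsets), the standard error
comes from the Fisher information at the estimates, and dispersions are
held fixed.  This is intentionally a minimal NB Wald pipeline, not a
re-creation of any specific package's shrinkage machinery; the default
design is condition-only (an additive replicate covariate is a non-goal of
the minimal fit and replicate structure enters only through the pooled
dispersion).  BH adjustment runs over all tested genes; all-zero genes are
excluded and reported.  Genes are induced when padj < 0.05 and fold change
> 1.5 on the ratio scale (2^log2FC > 1.5), repressed when < 1/1.5.

Overlaps between DEG classes and DPN-carrying genes use the upper-tail
hypergeometric test.  The overlap universe defaults to the genes in the
supplied annotation; for runs against the TAIR10 annotation a universe of
27,655 protein-coding genes is the documented convention.  The enrichment
conclusion is sensitive to this choice — for the deposited dataset's
induced-gene overlap the expected count crosses the observed one for
universes below roughly 27,000 — so the universe is an explicit config
value, never inferred.  Term enrichment is a one-sided Fisher test per
user-supplied term with BH across terms; genes missing from the term map
count as unannotated.

## Synthetic data generator

The generator emulates the study conditions, not the organism's sequence:

* **Genome and genes** — uniform-length chromosomes; non-overlapping gene
  bodies of 1–2 kb with 0.5–1 kb gaps, both strands, placed deterministically
  from a seed.  No sequence, no alignment.
* **Nucleosome landscape** — per gene, a phased array: +1 dyad 50–90 bp
  downstream of the TSS (random per-gene phase offset so arrays are not
  artificially coherent genome-wide), further dyads every 177 bp
  (Arabidopsis-like repeat) with 2 bp spacing jitter, tiling the body and
  the 1 kb promoter.  Each nucleosome has an occupancy weight (relative
  sampling probability) and a fuzziness SD (default 25 bp).
* **Planted effects** — per-gene classes: promoter/body occupancy
  depletion (negative magnitudes are gains), +1/+2/−1 occupancy gain, dyad
  shift (bp, transcription direction), fuzziness multiplier.  The treated
  landscape is a copy of mock with effects applied, so an empty plan gives
  an exact null.  The demo cycles induced genes through six archetypes
  (body loss, +2 loss, promoter loss, +2 gain, +1 gain, −1 gain) and gives
  repressed genes a gene-body gain, reproducing the qualitative
  differential-occupancy signatures of immune-activated chromatin; the
  archetype magnitudes (±0.5 to ±0.75) are free parameters of the demo,
  chosen to be detectable at ~30–40 fragments per nucleosome without being
  saturating.
* **Fragments** — each fragment picks a nucleosome ∝ weight, centres at
  dyad + Normal(0, fuzziness), draws a length from Normal(147, 10) clipped
  to [100, 200] bp (gel excision of the mono-nucleosome band).
* **Counts** — NB draws (var = μ + αμ²; α = 0 is Poisson) with log-normal
  baseline means around 100, dispersion 0.1, and planted log2 fold changes
  of ±2 for induced/repressed genes.

Every generator op draws from its own RNG stream keyed by (seed, op name),
so changing one stage never perturbs another and all outputs are byte-
reproducible for a seed.

What the generator does **not** emulate: MNase sequence bias, GC effects,
replicate batch effects, chromatin heterogeneity between cells, or
sub-nucleosomal particles.  Passing tests therefore demonstrate estimator
correctness and error-rate control under the stated generative model, not
robustness to those real-data artefacts.

## Numerical choices and degenerate inputs

* Integer bp grid throughout; midpoints floor; all intervals 0-based
  half-open; conversion to 1-based only at report rendering.
* Both-zero fragment counts: occupancy p = 1.  Identical midpoint
  multisets: fuzziness and position p = 1.  Zero-variance inputs to the F
  test return 1 (both zero) or 0 (one-sided degeneracy).
* BH families exclude NaN (untestable) entries; q-values are clipped to
  [0, 1] and monotone.
* K-means determinism: fixed random_state plus size-ordered relabelling.
* Newton iterations for NB group means start at ∑y/∑s, halve on negative
  steps, and stop at relative tolerance 1e-12.

## Problem sizes for the bundled studies

The calibration studies in `nucdyn.simulations` use a 2 Mb / 300-gene
genome with 5×10⁵ fragments for repeat-length recovery, twenty 0.5 Mb
null datasets at ~30 fragments per nucleosome for the DPN false-discovery
study, and ten 5,000-gene × (3+3) null count matrices (μ = 100, α = 0.1)
for the DE type-I study.  At these sizes the Monte Carlo standard errors
are an order of magnitude below the quantities being bounded and the full
set runs in about a minute on one core.

## Known limitations

* The occupancy test conditions on total counts and assumes fragments are
  independent draws; overdispersion between biological replicates is not
  modelled (replicates are pooled).
* The 3-vs-3 NB Wald test is slightly anti-conservative per gene at small
  n (raw p ≈ 0.08 at nominal 0.05 in null simulations); BH at the DEG
  threshold remains comfortably controlled, which is what the DEG calls
  rely on.
* Peak calling has no sub-nucleosome or overlapping-particle model; two
  true nucleosomes closer than the exclusion radius merge.
* `compare_phase` needs ≥ 3 pairing units, so single-chromosome runs log
  per-condition slopes without a paired test.
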