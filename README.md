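# nucdyn

Nucleosome dynamics from MNase-seq, integrated with RNA-seq differential
expression.

When chromatin is digested with micrococcal nuclease, the ~147 bp of DNA
wrapped around each histone octamer survives; sequencing those
mono-nucleosome fragments maps nucleosome positions genome-wide, and
comparing two conditions (e.g. mock vs elicitor-treated plants) reveals
which nucleosomes move, blur, or change occupancy when transcription is
reprogrammed.  `nucdyn` is for genomicists who have fragment intervals
(BED) and a gene-level count matrix and want the downstream statistics:

* **occupancy tracks** — per-bp midpoint density, triangular-kernel
  smoothed, depth-normalised;
* **differentially positioned nucleosomes (DPNs)** — per-condition peak
  calling, mutual-nearest-neighbour matching, and three tests per matched
  pair: occupancy (exact conditional binomial on fragment counts given the
  depth ratio), fuzziness (variance-ratio F on fragment midpoints,
  σ²₁/σ²₂), and position (Welch t on midpoints).  Each family is
  Benjamini–Hochberg adjusted separately and a pair is a DPN when
  min(q) < 0.01;
* **phasograms** — the histogram of pairwise midpoint distances; regressing
  its periodic peak positions on peak rank gives the nucleosome repeat
  length (bp/nucleosome) as the slope;
* **+1-anchored metaprofiles** — per-gene (differential) occupancy in
  transcription orientation around the +1 nucleosome dyad, with k-means
  clustering (k = 6) of the differential patterns;
* **NB differential expression** — median-of-ratios size factors, moment
  dispersion estimates with decile shrinkage, and a Wald test of the
  condition log2 fold change under var = μ + αμ²; genes are induced when
  padj < 0.05 and FC > 1.5;
* **overlap statistics** — upper-tail hypergeometric tests of DEG /
  DPN-gene overlaps and one-sided Fisher term enrichment.

A synthetic-data module generates genomes, phased nucleosome landscapes
with planted condition effects, fragment samples, and NB count matrices,
so the whole pipeline is testable against known truth without downloads.

## Worked example

Generate a synthetic dataset (2 Mb genome, 300 genes, 6×10⁵ fragments per
sample, two conditions × two replicates) and run every stage:

```sh
nucdyn demo demo/ --scale default --seed 42
nucdyn run-all --config demo/config.yaml
```

The run log prints one line per stage; with seed 42 the counts are:

```
stage profiles      {'n_fragments_mock': 1200000, 'n_fragments_treated': 1200000}
stage peaks         {'n_peaks_mock': 3428, 'n_peaks_treated': 3434}
stage dpns          {'n_pairs': 3453, 'n_dpns': 527}
stage phasing       {'slope_mock': 177.0, 'slope_treated': 177.17857142857142}
stage mapping       {'n_dpn_genes': 89, ...}
stage clustering    {'cluster_sizes': {'1': 30, '2': 24, '3': 11, '4': 9, '5': 8, '6': 7}}
stage de            {'n_induced': 41, 'n_repressed': 30, 'n_excluded': 0}
stage overlap       {'induced': 39, 'repressed': 28}
```

Reading these numbers: both conditions recover the generative 177 bp
repeat length from the phasogram; 527 of 3,453 matched nucleosome pairs
are DPNs at FDR < 0.01, concentrated in the 89 genes carrying planted
occupancy/position/fuzziness changes; the DE stage recovers the planted
induced and repressed genes (39 of the 41 called induced genes also carry
a DPN — the overlap the hypergeometric test scores, `overlap.json` has the
p-values).  All tables (peaks, DPN records with Δ/p/q per parameter,
metaprofile matrices, cluster assignments, DE results) are written as TSV
under `demo/results/`, along with `manifest.json` recording parameters,
seed, input checksums and per-stage record counts.

The same stages are callable as a library (`nucdyn.calling.call_dpns`,
`nucdyn.phasing.estimate_phase`, `nucdyn.expression.test_de`, ...) or as
individual CLI subcommands (`profiles`, `peaks`, `dpos`, `phase`, `map`,
`metaprofile`, `cluster`, `de`, `overlap`) that each run from the previous
stage's on-disk outputs.

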