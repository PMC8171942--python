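"""Calibration studies run on synthetic data with known truth.

These drive the package end to end under controlled conditions: repeat-
length recovery from phased fragment samples, the empirical false-discovery
rate of DPN calls on null data, and the type-I rate of the NB differential
expression stage on null counts.  Problem sizes are chosen so each study
runs in seconds to a couple of minutes on one core while keeping the Monte
Carlo error well below the quantities being checked.
"""

from __future__ import annotations

import numpy as np

from . import calling, expression, phasing, profiles, synthetic
from ._util import rng_for


def repeat_length_estimate(
    seed: int = 42,
    genome_length: int = 2_000_000,
    n_genes: int = 300,
    n_fragments: int = 500_000,
    max_dist: int = 1500,
) -> dict:
    """Fit the nucleosome repeat length on fragments from the demo landscape.

    Uses the generator defaults (177 bp spacing, 25 bp fuzziness) and the
    phasogram peak-rank regression; returns the fitted slope in bp per
    nucleosome along with fit diagnostics.
    """
    genome, genes = synthetic.make_genome(1, genome_length, n_genes, seed)
    mock, _ = synthetic.make_landscape(genome, genes, seed=seed)
    frags = synthetic.sample_fragments(mock, genome, n_fragments, seed=seed)
    fit = phasing.estimate_phase(phasing.phasogram(frags, max_dist))
    return {
        "slope": fit.slope,
        "r_squared": fit.r_squared,
        "n_peaks": len(fit.peaks),
        "n_fragments": n_fragments,
    }


def null_dpn_fraction(
    seed: int,
    genome_length: int = 500_000,
    n_genes: int = 70,
    fragments_per_nucleosome: int = 30,
    fdr: float = 0.01,
) -> float:
    """Fraction of nucleosome pairs flagged as DPN on one null dataset.

    Both conditions are sampled independently from the same nucleosome
    landscape, so every flagged pair is a false discovery.
    """
    genome, genes = synthetic.make_genome(1, genome_length, n_genes, seed=7)
    mock, _ = synthetic.make_landscape(genome, genes, seed=7)
    n_frag = fragments_per_nucleosome * len(mock)
    fa = synthetic.sample_fragments(mock, genome, n_frag, seed=seed, stream="null_a")
    fb = synthetic.sample_fragments(mock, genome, n_frag, seed=seed, stream="null_b")
    ta = profiles.midpoint_coverage(fa, genome.lengths)
    tb = profiles.midpoint_coverage(fb, genome.lengths)
    (ta, tb), _ = profiles.normalize_depth([ta, tb])
    pairs = calling.match_peaks(calling.call_peaks(ta), calling.call_peaks(tb))
    scored = calling.score_pairs(
        pairs,
        calling.FragmentIndex.from_fragments(fa),
        calling.FragmentIndex.from_fragments(fb),
    )
    dpns = calling.call_dpns(scored, fdr)
    return float(dpns["is_dpn"].mean())


def null_dpn_study(seed: int, n_seeds: int = 20, **kwargs) -> dict:
    """Mean null DPN fraction over independent datasets, with its MC error."""
    rng = rng_for(seed, "null_dpn_study")
    sub_seeds = rng.integers(0, 2**31 - 1, n_seeds)
    fracs = np.array([null_dpn_fraction(int(s), **kwargs) for s in sub_seeds])
    return {
        "mean_fraction": float(fracs.mean()),
        "mc_se": float(fracs.std(ddof=1) / np.sqrt(n_seeds)),
        "n_seeds": n_seeds,
    }


def null_de_rate(
    seed: int,
    n_seeds: int = 10,
    n_genes: int = 5000,
    mu: float = 100.0,
    alpha: float = 0.1,
    n_replicates: int = 3,
    padj: float = 0.05,
) -> dict:
    """Fraction of genes passing the DEG adjusted-p threshold on null counts.

    All true fold changes are 1, so the fraction should stay below the
    nominal BH level.
    """
    rng = rng_for(seed, "null_de_rate")
    sub_seeds = rng.integers(0, 2**31 - 1, n_seeds)
    fracs = []
    gene_ids = [f"g{i}" for i in range(n_genes)]
    for s in sub_seeds:
        truth = synthetic.CountTruth(
            gene_ids,
            np.full(n_genes, mu),
            np.full(n_genes, alpha),
            np.zeros(n_genes),
            n_replicates=n_replicates,
        )
        counts = synthetic.sample_counts(truth, seed=int(s))
        labels = [c.rsplit("_", 1)[0] for c in counts.columns]
        de = expression.test_de(counts, labels, padj_threshold=padj)
        fracs.append(float((de.table["padj"] < padj).mean()))
    fracs = np.array(fracs)
    return {
        "mean_fraction": float(fracs.mean()),
        "mc_se": float(fracs.std(ddof=1) / np.sqrt(n_seeds)),
        "n_seeds": n_seeds,
        "n_genes": n_genes,
    }
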