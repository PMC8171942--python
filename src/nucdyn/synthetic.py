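"""Synthetic MNase-seq / RNA-seq data with planted ground truth.

Generates a toy genome with gene models, phased nucleosome arrays per
condition (mock vs treated) with planted occupancy / fuzziness / position
effects, mono-nucleosome fragment samples, and negative-binomial gene
count matrices.  Every generator is a pure function of its parameters and
a seed, so downstream stages can be tested against known truth without
any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import rng_for

#: Canonical mono-nucleosome fragment length (bp of DNA around the octamer).
NUCLEOSOME_BP = 147

#: Default inter-dyad spacing, matching phased arrays in Arabidopsis seedlings.
DEFAULT_REPEAT_LENGTH = 177

#: Default positional dispersion of fragment midpoints around a dyad (bp).
DEFAULT_FUZZINESS_SD = 25.0

EFFECT_CLASSES = (
    "promoter_depletion",
    "body_depletion",
    "plus2_gain",
    "plus1_gain",
    "minus1_gain",
    "shift",
    "fuzz_change",
    "none",
)


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths of a synthetic genome."""

    chrom_names: tuple
    chrom_lengths: tuple
    seed: int

    def __post_init__(self):
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("chromosome names must be unique")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")

    @property
    def lengths(self) -> dict:
        return dict(zip(self.chrom_names, self.chrom_lengths))


@dataclass
class EffectPlan:
    """Planted per-gene treatment effects.

    ``nucleosome`` maps gene_id -> (effect_class, magnitude).  For the
    depletion/gain classes the magnitude is the fractional occupancy change
    (0.5 halves the weight; a negative depletion magnitude is a gain); for
    ``shift`` it is the dyad displacement in bp (transcription direction);
    for ``fuzz_change`` it is a multiplier on the fuzziness SD.
    ``expression`` maps gene_id -> log2 fold change (treated vs mock).
    """

    nucleosome: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)

    def __post_init__(self):
        for g, (cls, mag) in self.nucleosome.items():
            if cls not in EFFECT_CLASSES:
                raise ValueError(f"unknown effect class {cls!r} for gene {g}")
            if not np.isfinite(mag):
                raise ValueError(f"effect magnitude for gene {g} not finite")

    def effect_for(self, gene_id) -> tuple:
        return self.nucleosome.get(gene_id, ("none", 0.0))


@dataclass
class CountTruth:
    """Generative truth for an RNA-seq count matrix.

    NB parameterised as var = mu + alpha * mu^2; alpha == 0 is Poisson.
    """

    gene_ids: list
    base_means: np.ndarray
    dispersions: np.ndarray
    log2_fold_changes: np.ndarray  # treated vs mock
    n_replicates: int = 3

    def __post_init__(self):
        self.base_means = np.asarray(self.base_means, dtype=float)
        self.dispersions = np.asarray(self.dispersions, dtype=float)
        self.log2_fold_changes = np.asarray(self.log2_fold_changes, dtype=float)
        if np.any(self.base_means <= 0):
            raise ValueError("baseline means must be > 0")
        if np.any(self.dispersions < 0):
            raise ValueError("dispersions must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")


def make_genome(n_chrom: int, length: int, n_genes: int, seed: int):
    """Build a genome and non-overlapping gene models.

    Parameters
    ----------
    n_chrom, length : number of chromosomes, each of `length` bp.
    n_genes : total genes to place; requires ``n_genes * 3000 <= n_chrom * length``.

    Returns ``(GenomeSpec, genes)`` where `genes` is a DataFrame with columns
    gene_id, chrom, strand, tss, tes (0-based; tss > tes on the minus strand).
    Gene bodies are >= 1 kb and never overlap.
    """
    if n_genes * 3000 > n_chrom * length:
        raise ValueError(
            f"capacity exceeded: {n_genes} genes need {n_genes * 3}kb, "
            f"genome has {n_chrom * length // 1000}kb"
        )
    rng = rng_for(seed, "make_genome")
    names = tuple(f"chr{i + 1}" for i in range(n_chrom))
    genome = GenomeSpec(names, tuple([length] * n_chrom), seed)

    per_chrom_cap = max(0, (length - 2000) // 3000)
    if per_chrom_cap * n_chrom < n_genes:
        raise ValueError("capacity exceeded: genes do not fit with flanking margins")

    # spread genes evenly, spilling over when a chromosome is at capacity
    counts = [n_genes // n_chrom + (i < n_genes % n_chrom) for i in range(n_chrom)]
    for i in range(n_chrom):
        excess = counts[i] - per_chrom_cap
        if excess > 0:
            counts[i] = per_chrom_cap
            counts[(i + 1) % n_chrom] += excess

    records = []
    gid = 0
    for chrom, n_here in zip(names, counts):
        cursor = 1000
        for _ in range(n_here):
            body_len = int(rng.integers(1000, 2001))
            gap = int(rng.integers(500, 1001))
            g0 = cursor
            g1 = g0 + body_len
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                tss, tes = g0, g1
            else:
                tss, tes = g1 - 1, g0 - 1
            records.append((f"gene{gid:04d}", chrom, strand, tss, tes))
            gid += 1
            cursor = g1 + gap
    genes = pd.DataFrame(records, columns=["gene_id", "chrom", "strand", "tss", "tes"])
    # guarantee both strands are represented
    if n_genes >= 2 and genes["strand"].nunique() == 1:
        flip = {"+": "-", "-": "+"}[genes.loc[0, "strand"]]
        row = genes.iloc[0]
        lo = min(row.tss, row.tes + 1) if row.strand == "-" else row.tss
        hi = row.tes if row.strand == "+" else row.tss + 1
        if flip == "+":
            genes.loc[0, ["strand", "tss", "tes"]] = ["+", lo, hi]
        else:
            genes.loc[0, ["strand", "tss", "tes"]] = ["-", hi - 1, lo - 1]
    return genome, genes


def make_landscape(
    genome: GenomeSpec,
    genes: pd.DataFrame,
    effects: EffectPlan | None = None,
    repeat_length: int = DEFAULT_REPEAT_LENGTH,
    fuzziness_sd: float = DEFAULT_FUZZINESS_SD,
    spacing_jitter_sd: float = 2.0,
    seed: int = 0,
):
    """Nucleosome ground truth per condition.

    Each gene gets a phased array: a +1 nucleosome 50-90 bp downstream of
    the TSS (random per-gene phase offset), further dyads every
    ``repeat_length`` bp (with small spacing jitter) tiling the gene body,
    and upstream dyads tiling the 1 kb promoter.  The treated landscape is
    a copy of mock with the planted effects applied, so with an empty
    EffectPlan the two conditions are identical.

    Returns ``(mock, treated)`` DataFrames with columns
    chrom, dyad, weight, fuzziness_sd, gene_id, role.
    """
    if repeat_length <= 150:
        raise ValueError("repeat_length must exceed the 147 bp core particle")
    effects = effects or EffectPlan()
    rng = rng_for(seed, "make_landscape")
    lengths = genome.lengths

    rows = []
    for row in genes.itertuples(index=False):
        d = 1 if row.strand == "+" else -1
        chrom_len = lengths[row.chrom]
        body_lo = min(row.tss, row.tes + 1)
        body_hi = max(row.tes, row.tss + 1)
        offset = int(rng.integers(50, 91))
        plus1 = row.tss + d * offset
        # downstream array through the gene body
        k = 0
        pos = plus1
        while body_lo <= pos < body_hi and 0 <= pos < chrom_len:
            role = "plus1" if k == 0 else ("plus2" if k == 1 else "body")
            rows.append((row.chrom, int(pos), 1.0, float(fuzziness_sd), row.gene_id, role))
            k += 1
            pos = pos + d * (repeat_length + int(round(rng.normal(0, spacing_jitter_sd))))
        # upstream array through the 1 kb promoter
        k = 1
        pos = plus1 - d * (repeat_length + int(round(rng.normal(0, spacing_jitter_sd))))
        while abs(pos - row.tss) <= 1000 and 0 <= pos < chrom_len:
            role = "minus1" if k == 1 else "promoter"
            # only dyads genuinely upstream of the TSS count as promoter
            if (pos - row.tss) * d < 0:
                rows.append((row.chrom, int(pos), 1.0, float(fuzziness_sd), row.gene_id, role))
            k += 1
            pos = pos - d * (repeat_length + int(round(rng.normal(0, spacing_jitter_sd))))

    mock = pd.DataFrame(
        rows, columns=["chrom", "dyad", "weight", "fuzziness_sd", "gene_id", "role"]
    )
    mock = mock.sort_values(["chrom", "dyad"], kind="stable").reset_index(drop=True)

    treated = mock.copy()
    strand_of = dict(zip(genes["gene_id"], genes["strand"]))
    for gene_id, (cls, mag) in effects.nucleosome.items():
        idx = treated.index[treated["gene_id"] == gene_id]
        if cls == "none" or len(idx) == 0:
            continue
        roles = treated.loc[idx, "role"]
        if cls == "promoter_depletion":
            sel = idx[roles.isin(["minus1", "promoter"])]
            treated.loc[sel, "weight"] *= 1.0 - mag
        elif cls == "body_depletion":
            sel = idx[roles.isin(["plus2", "body"])]
            treated.loc[sel, "weight"] *= 1.0 - mag
        elif cls in ("plus1_gain", "plus2_gain", "minus1_gain"):
            role = {"plus1_gain": "plus1", "plus2_gain": "plus2", "minus1_gain": "minus1"}[cls]
            sel = idx[roles == role]
            treated.loc[sel, "weight"] *= 1.0 + mag
        elif cls == "shift":
            if abs(mag) >= repeat_length / 2:
                raise ValueError("shift magnitude must be < repeat_length / 2")
            d = 1 if strand_of[gene_id] == "+" else -1
            treated.loc[idx, "dyad"] += d * int(round(mag))
        elif cls == "fuzz_change":
            treated.loc[idx, "fuzziness_sd"] *= mag
    treated = treated.sort_values(["chrom", "dyad"], kind="stable").reset_index(drop=True)
    return mock, treated


def sample_fragments(
    truth: pd.DataFrame,
    genome: GenomeSpec,
    n_fragments: int,
    fragment_len_mean: float = float(NUCLEOSOME_BP),
    fragment_len_sd: float = 10.0,
    seed: int = 0,
    stream: str = "sample_fragments",
) -> pd.DataFrame:
    """Draw mono-nucleosome fragments from a nucleosome landscape.

    Each fragment picks a nucleosome with probability proportional to its
    occupancy weight, centres itself at dyad + Normal(0, fuzziness_sd), and
    draws a length from Normal(mean, sd) clipped to [100, 200] bp — the
    range a mono-nucleosome gel excision retains.  Returns a BED-like
    DataFrame (chrom, start, end; 0-based half-open) sorted by coordinate.
    """
    if len(truth) == 0:
        raise ValueError("empty nucleosome truth: nothing to sample from")
    if n_fragments <= 0:
        raise ValueError("n_fragments must be positive")
    rng = rng_for(seed, stream)
    w = truth["weight"].to_numpy(dtype=float)
    if not np.all(np.isfinite(w)) or np.any(w < 0):
        raise ValueError("occupancy weights must be finite and >= 0")
    p = w / w.sum()
    pick = rng.choice(len(truth), size=n_fragments, p=p)
    dyads = truth["dyad"].to_numpy()[pick]
    fuzz = truth["fuzziness_sd"].to_numpy(dtype=float)[pick]
    mids = dyads + np.round(rng.normal(0.0, 1.0, n_fragments) * fuzz).astype(int)
    lens = np.clip(
        np.round(rng.normal(fragment_len_mean, fragment_len_sd, n_fragments)), 100, 200
    ).astype(int)
    if fragment_len_sd == 0:
        lens = np.full(n_fragments, int(round(fragment_len_mean)))
    start = mids - lens // 2
    end = start + lens
    chroms = truth["chrom"].to_numpy()[pick]
    # shift fragments that spill over chromosome ends back inside
    lengths = np.array([genome.lengths[c] for c in chroms])
    shift_left = np.maximum(0, -start)
    shift_right = np.minimum(0, lengths - end)
    start = start + shift_left + shift_right
    end = end + shift_left + shift_right
    frags = pd.DataFrame({"chrom": chroms, "start": start, "end": end})
    return frags.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def sample_counts(truth: CountTruth, seed: int = 0) -> pd.DataFrame:
    """NB-distributed count matrix: genes x (mock/treated replicates).

    Genes with log2 fold change 0 have the same generative distribution in
    both conditions.  Columns are mock_1.. mock_n, treated_1.. treated_n.
    """
    rng = rng_for(seed, "sample_counts")
    n = truth.n_replicates
    mu_mock = truth.base_means
    mu_treat = truth.base_means * np.exp2(truth.log2_fold_changes)
    cols = {}
    for cond, mu in (("mock", mu_mock), ("treated", mu_treat)):
        for r in range(1, n + 1):
            cols[f"{cond}_{r}"] = _nb_draw(rng, mu, truth.dispersions)
    counts = pd.DataFrame(cols, index=pd.Index(truth.gene_ids, name="gene_id"))
    return counts


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """One NB sample per gene; alpha == 0 falls back to Poisson."""
    out = np.empty(mu.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    nb = ~pois
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def write_fragments_bed(frags: pd.DataFrame, path) -> None:
    frags[["chrom", "start", "end"]].to_csv(path, sep="\t", header=False, index=False)


def write_gene_models(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)
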