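"""Lightweight negative-binomial differential expression and set overlap.

Counts are normalised with median-of-ratios size factors, per-gene NB
dispersions are estimated by a shrunken method of moments, and each gene
gets a Wald test of the condition log2 fold change under an NB model with
fixed dispersion.  Genes are classified as induced (BH-adjusted p < 0.05
and fold change > 1.5), repressed (< 1/1.5) or ns — the standard DEG
thresholds.  Gene-set overlaps are scored with the upper-tail
hypergeometric test and term enrichment with one-sided Fisher tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._util import bh_adjust

DEFAULT_PADJ = 0.05
DEFAULT_FC = 1.5
DISPERSION_FLOOR = 1e-8


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    return counts


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, normalised to geometric mean 1.

    Only genes with nonzero counts in every sample enter the reference
    geometric means.
    """
    X = counts.to_numpy(dtype=float)
    nz = (X > 0).all(axis=1)
    if not nz.any():
        raise ValueError("no gene with nonzero counts in all samples")
    logX = np.log(X[nz])
    log_gm = logX.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logX - log_gm, axis=0))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(
    counts: pd.DataFrame, sf: pd.Series, conditions: pd.Series
) -> pd.Series:
    """Per-gene NB dispersion alpha (var = mu + alpha mu^2).

    Method of moments on size-factor-normalised counts pooled within
    conditions, then shrunk 50% toward the median dispersion of genes in
    the same expression decile; floored at 1e-8.
    """
    X = counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    cond = np.asarray(conditions)
    mu = X.mean(axis=1)
    num = np.zeros(X.shape[0])
    dof = 0
    for c in np.unique(cond):
        sub = X[:, cond == c]
        if sub.shape[1] < 2:
            raise ValueError("need >= 2 replicates per condition")
        num += sub.var(axis=1, ddof=1) * (sub.shape[1] - 1)
        dof += sub.shape[1] - 1
    s2 = num / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = np.where(mu > 0, np.maximum(0.0, (s2 - mu) / mu**2), 0.0)
    # decile-trend shrinkage
    alpha = alpha_raw.copy()
    expressed = mu > 0
    if expressed.sum() >= 10:
        deciles = pd.qcut(mu[expressed], 10, labels=False, duplicates="drop")
        med = pd.Series(alpha_raw[expressed]).groupby(deciles).transform("median")
        alpha[expressed] = 0.5 * alpha_raw[expressed] + 0.5 * med.to_numpy()
    return pd.Series(np.maximum(alpha, DISPERSION_FLOOR), index=counts.index, name="alpha")


def _nb_group_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Vectorised NB MLE of the per-unit-size-factor group mean.

    Solves sum_j (y_j - s_j mu) / (1 + alpha s_j mu) = 0 per gene by
    Newton iteration (score equation of the NB log-likelihood with log
    link and offset log s_j).  With alpha = 0 this is sum(y)/sum(s).
    """
    mu = y.sum(axis=1) / s.sum()
    for _ in range(50):
        denom = 1.0 + alpha[:, None] * s[None, :] * mu[:, None]
        f = ((y - s[None, :] * mu[:, None]) / denom).sum(axis=1)
        fp = -((s[None, :] * (1.0 + alpha[:, None] * y)) / denom**2).sum(axis=1)
        step = f / fp
        new = mu - step
        new = np.where(new <= 0, mu / 2.0, new)
        if np.allclose(new, mu, rtol=1e-12, atol=1e-15):
            mu = new
            break
        mu = new
    return mu


@dataclass
class DEResult:
    table: pd.DataFrame  # baseMean, log2FC, p, padj, status
    n_excluded: int  # all-zero genes removed before testing
    padj_threshold: float
    fc_threshold: float

    @property
    def induced(self) -> list:
        return self.table.index[self.table["status"] == "induced"].tolist()

    @property
    def repressed(self) -> list:
        return self.table.index[self.table["status"] == "repressed"].tolist()


def test_de(
    counts: pd.DataFrame,
    conditions: pd.Series | list,
    padj_threshold: float = DEFAULT_PADJ,
    fc_threshold: float = DEFAULT_FC,
    reference: str = "mock",
) -> DEResult:
    """NB Wald test of the condition effect, gene by gene.

    ``conditions`` labels each column; the non-reference level is treated.
    The Wald statistic is the difference of group log-means over its
    standard error from the Fisher information, with dispersions held
    fixed at their shrunken estimates.  P-values are BH-adjusted over all
    tested genes; all-zero genes are excluded and reported.
    """
    cond = pd.Series(np.asarray(conditions), index=counts.columns)
    levels = pd.unique(cond)
    if len(levels) != 2:
        raise ValueError("exactly two conditions required")
    treated_level = [l for l in levels if l != reference]
    if reference not in set(levels) or len(treated_level) != 1:
        raise ValueError(f"reference level {reference!r} not found")
    treated_level = treated_level[0]

    nonzero = counts.sum(axis=1) > 0
    n_excluded = int((~nonzero).sum())
    sub = counts.loc[nonzero]
    sf = size_factors(counts)
    alpha = estimate_dispersion(sub, sf, cond).to_numpy()

    Y = sub.to_numpy(dtype=float)
    s = sf.to_numpy()
    mask_m = (cond == reference).to_numpy()
    mask_t = ~mask_m
    mu_m = _nb_group_mean(Y[:, mask_m], s[mask_m], alpha)
    mu_t = _nb_group_mean(Y[:, mask_t], s[mask_t], alpha)

    def info(mu, s_g):
        return (s_g[None, :] * mu[:, None] / (1.0 + alpha[:, None] * s_g[None, :] * mu[:, None])).sum(axis=1)

    degenerate = (mu_m <= 0) | (mu_t <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mu_t / mu_m)
        se = np.sqrt(1.0 / info(mu_m, s[mask_m]) + 1.0 / info(mu_t, s[mask_t]))
        z = (np.log(mu_t) - np.log(mu_m)) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(degenerate, 1.0, p)
    base_mean = (Y / s[None, :]).mean(axis=1)

    padj = bh_adjust(p)
    fc = np.exp2(lfc)
    status = np.where(
        (padj < padj_threshold) & (fc > fc_threshold),
        "induced",
        np.where((padj < padj_threshold) & (fc < 1.0 / fc_threshold), "repressed", "ns"),
    )
    status = np.where(degenerate, "ns", status)
    table = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": lfc,
            "p": p,
            "padj": padj,
            "status": status,
            "degenerate": degenerate,
        },
        index=sub.index,
    )
    return DEResult(table, n_excluded, padj_threshold, fc_threshold)


@dataclass
class OverlapResult:
    universe: int
    set_size: int  # K, e.g. DEG-class genes
    draw_size: int  # n, e.g. genes with a DPN
    overlap: int  # k
    expected: float
    p_value: float


def classify_overlap(deg_set, dpn_gene_set, universe_size: int) -> OverlapResult:
    """Upper-tail hypergeometric test of a gene-set overlap.

    p = P(X >= k) for X ~ Hypergeom(N = universe, K = |deg_set|,
    n = |dpn_gene_set|); k = 0 returns p = 1.
    """
    K, n = len(set(deg_set)), len(set(dpn_gene_set))
    k = len(set(deg_set) & set(dpn_gene_set))
    if K > universe_size or n > universe_size:
        raise ValueError("set sizes exceed the universe")
    if k > min(K, n):
        raise ValueError("overlap exceeds set sizes")
    p = float(stats.hypergeom.sf(k - 1, universe_size, K, n))
    expected = n * K / universe_size
    return OverlapResult(universe_size, K, n, k, expected, min(p, 1.0))


def term_enrichment(gene_set, universe, term_map: pd.DataFrame) -> pd.DataFrame:
    """One-sided Fisher enrichment of user-supplied terms in a gene set.

    ``term_map`` has columns gene_id, term_id; genes in the universe
    missing from the map simply count as unannotated.  Returns one row per
    term with the 2x2 counts, p, and BH q.
    """
    if len(term_map) == 0:
        raise ValueError("empty term map")
    universe = set(universe)
    gene_set = set(gene_set) & universe
    rows = []
    for term, sub in term_map.groupby("term_id"):
        members = set(sub["gene_id"]) & universe
        a = len(gene_set & members)
        b = len(gene_set) - a
        c = len(members) - a
        d = len(universe) - a - b - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((term, a, len(members), float(p)))
    out = pd.DataFrame(rows, columns=["term_id", "overlap", "term_size", "p"])
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)
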