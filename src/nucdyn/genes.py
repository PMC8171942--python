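"""Gene-centric context: regions, DPN-to-gene mapping, +1 anchoring,
metaprofiles, and K-means pattern clustering.

Regions follow the standard strand-aware conventions: the promoter is the
1,000 bp upstream of the TSS in the direction of transcription, the TSS
region is the 180 bp centred on the TSS, and the gene body runs from TSS
to TES.  Metaprofiles are anchored on the dyad of the +1 nucleosome (the
first positioned nucleosome downstream of the TSS) and oriented in the
direction of transcription.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .profiles import OccupancyTrack

PROMOTER_BP = 1000
TSS_HALFWIDTH = 90
PLUS1_WINDOW = (-50, 250)  # search window around the TSS, transcription direction
DEFAULT_WINDOW = (-1000, 1500)
DEFAULT_BIN = 10
DEFAULT_K = 6

REGION_CLASSES = ("promoter", "tss_region", "body", "promoter_plus_body")


def read_gene_models(path) -> pd.DataFrame:
    """Read the tab-separated gene model table (gene_id, chrom, strand, tss, tes)."""
    genes = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    required = {"gene_id", "chrom", "strand", "tss", "tes"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene model table missing columns: {sorted(missing)}")
    return genes


def read_gff3_genes(path) -> pd.DataFrame:
    """Minimal GFF3 reader: gene features -> gene model table.

    Converts GFF3 1-based closed coordinates to the package's 0-based
    convention (minus-strand TSS is the last base of the feature).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            chrom, _, _, start, end, _, strand, _, attrs = parts[:9]
            gene_id = None
            for field in attrs.split(";"):
                if field.startswith("ID="):
                    gene_id = field[3:]
            if gene_id is None:
                continue
            s, e = int(start) - 1, int(end)  # to 0-based half-open
            if strand == "+":
                tss, tes = s, e
            else:
                tss, tes = e - 1, s - 1
            rows.append((gene_id, chrom, strand, tss, tes))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss", "tes"])


def _validate_genes(genes: pd.DataFrame) -> None:
    plus = genes["strand"] == "+"
    bad = (plus & (genes["tss"] >= genes["tes"])) | (~plus & (genes["tss"] <= genes["tes"]))
    if bad.any():
        raise ValueError(f"invalid gene models: {genes.loc[bad, 'gene_id'].tolist()[:5]}")


def assign_regions(
    genes: pd.DataFrame,
    chrom_lengths: dict | None = None,
    promoter_bp: int = PROMOTER_BP,
    tss_halfwidth: int = TSS_HALFWIDTH,
) -> pd.DataFrame:
    """Strand-aware promoter / TSS / body / promoter+body intervals per gene.

    Returns a long-format DataFrame (gene_id, chrom, strand, region, start,
    end) with 0-based half-open genomic intervals, clipped at chromosome
    edges when ``chrom_lengths`` is given.
    """
    _validate_genes(genes)
    rows = []
    for g in genes.itertuples(index=False):
        if g.strand == "+":
            promoter = (g.tss - promoter_bp, g.tss)
            tss_region = (g.tss - tss_halfwidth, g.tss + tss_halfwidth)
            body = (g.tss, g.tes)
            prom_body = (g.tss - promoter_bp, g.tes)
        else:
            promoter = (g.tss + 1, g.tss + 1 + promoter_bp)
            tss_region = (g.tss + 1 - tss_halfwidth, g.tss + 1 + tss_halfwidth)
            body = (g.tes + 1, g.tss + 1)
            prom_body = (g.tes + 1, g.tss + 1 + promoter_bp)
        limit = None if chrom_lengths is None else chrom_lengths[g.chrom]
        if limit is not None and not (0 <= g.tss < limit):
            raise ValueError(f"TSS of {g.gene_id} outside chromosome {g.chrom}")
        for region, (s, e) in zip(
            REGION_CLASSES, (promoter, tss_region, body, prom_body)
        ):
            s = max(s, 0)
            if limit is not None:
                e = min(e, limit)
            rows.append((g.gene_id, g.chrom, g.strand, region, int(s), int(e)))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "region", "start", "end"]
    )


def map_dpns_to_genes(
    dpns: pd.DataFrame,
    regions: pd.DataFrame,
    mode: str = "promoter_plus_body",
) -> pd.DataFrame:
    """Assign each DPN to every gene whose selected region contains its summit.

    ``dpns`` needs chrom and summit columns (``summit_a`` is used when a
    plain ``summit`` is absent).  A DPN may hit several genes; the result is
    one row per (gene, DPN) with the DPN row index in ``dpn_index``.
    """
    if mode not in REGION_CLASSES:
        raise ValueError(f"unknown region mode {mode!r}")
    summit_col = "summit" if "summit" in dpns.columns else "summit_a"
    chrom_col = "chrom" if "chrom" in dpns.columns else "chrom_a"
    sel = regions[regions["region"] == mode]
    rows = []
    for chrom, reg in sel.groupby("chrom", sort=False):
        sub = dpns[dpns[chrom_col] == chrom]
        if not len(sub):
            continue
        summits = sub[summit_col].to_numpy()
        idx = sub.index.to_numpy()
        for r in reg.itertuples(index=False):
            inside = (summits >= r.start) & (summits < r.end)
            for i in idx[inside]:
                rows.append((r.gene_id, i))
    return pd.DataFrame(rows, columns=["gene_id", "dpn_index"])


def count_dpns_by_region(dpns: pd.DataFrame, regions: pd.DataFrame) -> dict:
    """Number of distinct DPNs whose summit falls in each region class."""
    return {
        mode: int(map_dpns_to_genes(dpns, regions, mode)["dpn_index"].nunique())
        for mode in REGION_CLASSES
    }


def find_plus1(peaks: pd.DataFrame, gene, window: tuple = PLUS1_WINDOW):
    """Dyad (summit) of the +1 nucleosome for a gene, or None.

    The +1 is the first peak summit downstream of TSS - 50 in the direction
    of transcription, within [TSS - 50, TSS + 250] (transcription-oriented
    coordinates).  Peaks should come from the reference (mock) condition.
    """
    sub = peaks[peaks["chrom"] == gene.chrom]
    s = sub["summit"].to_numpy()
    if gene.strand == "+":
        lo, hi = gene.tss + window[0], gene.tss + window[1]
        cand = s[(s >= lo) & (s <= hi)]
        return int(cand.min()) if cand.size else None
    lo, hi = gene.tss - window[1], gene.tss - window[0]
    cand = s[(s >= lo) & (s <= hi)]
    return int(cand.max()) if cand.size else None


def locate_plus1(peaks: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """+1 dyad per gene (NaN when undefined); indexed by gene_id."""
    out = {}
    for g in genes.itertuples(index=False):
        p1 = find_plus1(peaks, g)
        out[g.gene_id] = np.nan if p1 is None else p1
    return pd.Series(out, name="plus1")


@dataclass
class MetaProfileMatrix:
    """Genes x relative-position matrix anchored on the +1 dyad."""

    gene_ids: list
    positions: np.ndarray  # bin-centre offsets from the +1 dyad, bp
    values: np.ndarray  # (n_genes, n_bins)
    bin_size: int
    n_excluded: int = 0  # genes without a +1 call

    @property
    def mean_profile(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.gene_ids, name="gene_id"),
            columns=self.positions,
        )


def metaprofile(
    track: OccupancyTrack,
    genes: pd.DataFrame,
    anchors: pd.Series,
    window: tuple = DEFAULT_WINDOW,
    bin_size: int = DEFAULT_BIN,
) -> MetaProfileMatrix:
    """Per-gene occupancy around the +1 dyad, transcription-oriented.

    Each row is the track signal in ``[anchor + window[0], anchor +
    window[1])`` (with minus-strand genes reversed so positive offsets run
    into the gene body), binned by the mean.  Genes without an anchor are
    excluded; positions outside the chromosome are NaN.
    """
    lo, hi = window
    span = hi - lo
    if span % bin_size:
        raise ValueError("window span must be a multiple of bin_size")
    n_bins = span // bin_size
    rows, ids = [], []
    n_excluded = 0
    for g in genes.itertuples(index=False):
        anchor = anchors.get(g.gene_id, np.nan)
        if anchor is None or (isinstance(anchor, float) and np.isnan(anchor)):
            n_excluded += 1
            continue
        anchor = int(anchor)
        sig = track.signal[g.chrom]
        out = np.full(span, np.nan)
        if g.strand == "+":
            s, e = anchor + lo, anchor + hi
            cs, ce = max(s, 0), min(e, sig.size)
            if ce > cs:
                out[cs - s : ce - s] = sig[cs:ce]
        else:
            # transcription-oriented offset x maps to genomic anchor - x
            s, e = anchor - hi + 1, anchor - lo + 1
            cs, ce = max(s, 0), min(e, sig.size)
            if ce > cs:
                rev = sig[cs:ce][::-1]
                off = (anchor - lo + 1) - ce  # leading NaNs after reversal
                out[off : off + rev.size] = rev
        rows.append(np.nanmean(out.reshape(n_bins, bin_size), axis=1))
        ids.append(g.gene_id)
    positions = np.arange(lo, hi, bin_size) + bin_size // 2
    values = np.vstack(rows) if rows else np.empty((0, n_bins))
    return MetaProfileMatrix(ids, positions, values, bin_size, n_excluded)


def differential_metaprofile(
    track_treated: OccupancyTrack,
    track_mock: OccupancyTrack,
    genes: pd.DataFrame,
    anchors: pd.Series,
    window: tuple = DEFAULT_WINDOW,
    bin_size: int = DEFAULT_BIN,
) -> MetaProfileMatrix:
    """Occupancy difference (treated - mock) per gene around the +1 dyad.

    Tracks must already be depth-normalised; identical tracks give an
    all-zero matrix.
    """
    mp_t = metaprofile(track_treated, genes, anchors, window, bin_size)
    mp_m = metaprofile(track_mock, genes, anchors, window, bin_size)
    return MetaProfileMatrix(
        mp_t.gene_ids, mp_t.positions, mp_t.values - mp_m.values, bin_size, mp_t.n_excluded
    )


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series  # gene_id -> cluster id in 1..k, ordered by size
    centroids: np.ndarray  # (k, n_bins), same ordering
    inertia: float
    seed: int


def cluster_profiles(
    matrix: MetaProfileMatrix, k: int = DEFAULT_K, seed: int = 0, n_init: int = 20
) -> ClusterResult:
    """K-means (k-means++ init, best of ``n_init`` restarts) on profile rows.

    Rows are clustered on the raw binned values; cluster ids are relabelled
     1..k by descending cluster size so the labelling is stable for a seed.
    """
    X = np.nan_to_num(matrix.values, nan=0.0)
    if X.shape[0] < k:
        raise ValueError(f"{X.shape[0]} profiles cannot form {k} clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, random_state=seed)
    raw = km.fit_predict(X)
    sizes = np.bincount(raw, minlength=k)
    # descending size; ties broken by original label for determinism
    order = np.lexsort((np.arange(k), -sizes))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    assignments = pd.Series(relabel[raw], index=matrix.gene_ids, name="cluster")
    centroids = km.cluster_centers_[order]
    return ClusterResult(k, assignments, centroids, float(km.inertia_), seed)
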