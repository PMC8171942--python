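"""Nucleosome peak calling and differential positioning tests.

Peaks are greedy local maxima on a smoothed occupancy track.  Matched
cross-condition peak pairs are scored on three dynamics parameters —
occupancy (exact conditional binomial on fragment counts), fuzziness
(variance-ratio F test on fragment midpoints) and position (Welch t on
fragment midpoints) — each adjusted by Benjamini-Hochberg within its own
family.  A pair is a differentially positioned nucleosome (DPN) when any
of the three q-values falls below the FDR threshold (default 0.01).
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from ._util import bh_adjust
from .profiles import OccupancyTrack, fragment_midpoints

#: half-width of a nucleosome footprint used for peak intervals
HALF_NUC = 73

#: minimum fragments per side for the fuzziness and position tests
MIN_FRAGMENTS_FOR_TEST = 8

DEFAULT_FDR = 0.01
DEFAULT_MIN_DISTANCE = 120
DEFAULT_MAX_SHIFT = 90


def call_peaks(
    track: OccupancyTrack,
    min_height: float | None = None,
    min_distance: int = DEFAULT_MIN_DISTANCE,
) -> pd.DataFrame:
    """Call nucleosome peaks as greedy height-ranked local maxima.

    Local maxima above ``min_height`` are selected greedily by height
    (ties: leftmost wins) with an exclusion radius of ``min_distance`` bp.
    Each peak's interval is summit +/- 73 bp, clipped at the midpoints to
    neighbouring selected summits and at chromosome ends.  When
    ``min_height`` is None it defaults to twice the genome-wide mean
    signal.
    """
    if min_height is None:
        total_len = sum(len(v) for v in track.signal.values())
        min_height = 2.0 * track.total_mass / max(total_len, 1)
    rows = []
    for chrom, x in track.signal.items():
        if x.size == 0:
            continue
        cand, _ = sps.find_peaks(x, height=min_height)
        if cand.size == 0:
            continue
        order = np.lexsort((cand, -x[cand]))
        chosen: list[int] = []
        for i in order:
            pos = int(cand[i])
            j = bisect_left(chosen, pos)
            left_ok = j == 0 or pos - chosen[j - 1] >= min_distance
            right_ok = j == len(chosen) or chosen[j] - pos >= min_distance
            if left_ok and right_ok:
                insort(chosen, pos)
        summits = np.array(chosen)
        for i, s in enumerate(summits):
            lo = 0 if i == 0 else (summits[i - 1] + s) // 2
            hi = x.size if i == len(summits) - 1 else (s + summits[i + 1]) // 2
            start = int(max(s - HALF_NUC, lo, 0))
            end = int(min(s + HALF_NUC + 1, hi, x.size))
            rows.append(
                (chrom, start, end, int(s), float(x[s]), float(x[start:end].sum()))
            )
    peaks = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "summit", "summit_height", "occupancy"]
    )
    return peaks.sort_values(["chrom", "summit"], kind="stable").reset_index(drop=True)


@dataclass
class FragmentIndex:
    """Sorted midpoints per chromosome, for fast interval queries."""

    midpoints: dict  # chrom -> sorted int ndarray
    n_total: int

    @classmethod
    def from_fragments(cls, frags: pd.DataFrame) -> "FragmentIndex":
        mids = {}
        for chrom, sub in frags.groupby("chrom", sort=False):
            mids[str(chrom)] = np.sort(fragment_midpoints(sub))
        return cls(mids, len(frags))

    def in_interval(self, chrom: str, start: int, end: int) -> np.ndarray:
        m = self.midpoints.get(chrom)
        if m is None:
            return np.empty(0, dtype=int)
        return m[np.searchsorted(m, start) : np.searchsorted(m, end)]


def peak_fuzziness(mids: np.ndarray) -> float:
    """Population SD (bp) of fragment midpoints within a peak; NaN if < 2."""
    if mids.size < 2:
        return float("nan")
    return float(np.std(mids))


def annotate_peaks(peaks: pd.DataFrame, frag_index: FragmentIndex) -> pd.DataFrame:
    """Attach per-peak fragment count and fuzziness from a fragment index."""
    n, fuzz = [], []
    for row in peaks.itertuples(index=False):
        mids = frag_index.in_interval(row.chrom, row.start, row.end)
        n.append(mids.size)
        fuzz.append(peak_fuzziness(mids))
    out = peaks.copy()
    out["n_fragments"] = n
    out["fuzziness"] = fuzz
    return out


def match_peaks(
    peaks_a: pd.DataFrame,
    peaks_b: pd.DataFrame,
    max_shift: int = DEFAULT_MAX_SHIFT,
) -> pd.DataFrame:
    """Mutual-nearest-neighbour peak pairing within ``max_shift`` bp.

    Unmatched peaks are paired with a zero-occupancy pseudo-peak spanning
    the same interval (appearance / disappearance events).  Returns one row
    per pair with suffixes ``_a`` / ``_b`` and a ``status`` column in
    {matched, only_a, only_b}.
    """
    cols = ["chrom", "start", "end", "summit", "summit_height", "occupancy"]
    rows = []
    chroms = sorted(set(peaks_a["chrom"]) | set(peaks_b["chrom"]))
    for chrom in chroms:
        a = peaks_a[peaks_a["chrom"] == chrom].reset_index(drop=True)
        b = peaks_b[peaks_b["chrom"] == chrom].reset_index(drop=True)
        sa = a["summit"].to_numpy()
        sb = b["summit"].to_numpy()
        matched_a = np.full(len(a), -1)
        matched_b = np.full(len(b), -1)
        if len(a) and len(b):
            # nearest b for each a
            j = np.clip(np.searchsorted(sb, sa), 0, len(sb) - 1)
            j_alt = np.clip(j - 1, 0, len(sb) - 1)
            nearest_ab = np.where(
                np.abs(sb[j] - sa) <= np.abs(sb[j_alt] - sa), j, j_alt
            )
            i = np.clip(np.searchsorted(sa, sb), 0, len(sa) - 1)
            i_alt = np.clip(i - 1, 0, len(sa) - 1)
            nearest_ba = np.where(
                np.abs(sa[i] - sb) <= np.abs(sa[i_alt] - sb), i, i_alt
            )
            for ia in range(len(a)):
                ib = nearest_ab[ia]
                if nearest_ba[ib] == ia and abs(sa[ia] - sb[ib]) <= max_shift:
                    matched_a[ia] = ib
                    matched_b[ib] = ia
        for ia in range(len(a)):
            ib = matched_a[ia]
            ra = a.loc[ia, cols]
            if ib >= 0:
                rb = b.loc[ib, cols]
                rows.append([*ra, *rb, "matched"])
            else:
                pseudo = [chrom, ra["start"], ra["end"], ra["summit"], 0.0, 0.0]
                rows.append([*ra, *pseudo, "only_a"])
        for ib in range(len(b)):
            if matched_b[ib] < 0:
                rb = b.loc[ib, cols]
                pseudo = [chrom, rb["start"], rb["end"], rb["summit"], 0.0, 0.0]
                rows.append([*pseudo, *rb, "only_b"])
    out = pd.DataFrame(
        rows, columns=[f"{c}_a" for c in cols] + [f"{c}_b" for c in cols] + ["status"]
    )
    return out.sort_values(["chrom_a", "summit_a"], kind="stable").reset_index(drop=True)


def test_occupancy(n_a: int, n_b: int, depth_a: float, depth_b: float) -> float:
    """Exact two-sample Poisson rate test on fragment counts.

    Conditional on the total, n_a ~ Binomial(n_a + n_b, depth_a /
    (depth_a + depth_b)); returns the two-sided exact binomial p-value.
    """
    total = n_a + n_b
    if total == 0:
        return 1.0
    p0 = depth_a / (depth_a + depth_b)
    return float(stats.binomtest(n_a, total, p0).pvalue)


def test_fuzziness(mids_a: np.ndarray, mids_b: np.ndarray) -> float:
    """Two-sided variance-ratio (F) test on fragment midpoint dispersion."""
    if mids_a.size < MIN_FRAGMENTS_FOR_TEST or mids_b.size < MIN_FRAGMENTS_FOR_TEST:
        return float("nan")
    va = np.var(mids_a, ddof=1)
    vb = np.var(mids_b, ddof=1)
    if va == 0 and vb == 0:
        return 1.0
    if vb == 0 or va == 0:
        return 0.0
    f = va / vb
    dfn, dfd = mids_a.size - 1, mids_b.size - 1
    cdf = stats.f.cdf(f, dfn, dfd)
    return float(min(1.0, 2 * min(cdf, 1 - cdf)))


def test_position(mids_a: np.ndarray, mids_b: np.ndarray) -> tuple:
    """Welch t test on fragment midpoints; returns (delta_bp, p).

    delta is mean(b) - mean(a), i.e. the summit displacement of the second
    condition relative to the first.
    """
    if mids_a.size < MIN_FRAGMENTS_FOR_TEST or mids_b.size < MIN_FRAGMENTS_FOR_TEST:
        return float("nan"), float("nan")
    delta = float(np.mean(mids_b) - np.mean(mids_a))
    if np.var(mids_a) == 0 and np.var(mids_b) == 0:
        return delta, (1.0 if delta == 0 else 0.0)
    res = stats.ttest_ind(mids_b, mids_a, equal_var=False)
    return delta, float(res.pvalue)


def score_pairs(
    pairs: pd.DataFrame,
    frags_a: FragmentIndex,
    frags_b: FragmentIndex,
) -> pd.DataFrame:
    """Compute the three dynamics tests for every matched pair.

    Fragment counts and midpoints for both conditions are taken over the
    union of the two peak intervals, so appearance/disappearance events are
    still measured against the other condition's actual fragments.  The
    fuzziness and position tests only apply to matched pairs with enough
    fragments on both sides.
    """
    depth_a, depth_b = frags_a.n_total, frags_b.n_total
    recs = []
    for row in pairs.itertuples(index=False):
        chrom = row.chrom_a
        start = int(min(row.start_a, row.start_b))
        end = int(max(row.end_a, row.end_b))
        ma = frags_a.in_interval(chrom, start, end)
        mb = frags_b.in_interval(chrom, start, end)
        p_occ = test_occupancy(ma.size, mb.size, depth_a, depth_b)
        if row.status == "matched":
            p_fuzz = test_fuzziness(ma, mb)
            d_pos, p_pos = test_position(ma, mb)
        else:
            p_fuzz, d_pos, p_pos = float("nan"), float("nan"), float("nan")
        d_occ = row.occupancy_b - row.occupancy_a
        d_fuzz = peak_fuzziness(mb) - peak_fuzziness(ma)
        recs.append((ma.size, mb.size, d_occ, d_fuzz, d_pos, p_occ, p_fuzz, p_pos))
    scored = pairs.copy()
    scored[
        [
            "n_frag_a",
            "n_frag_b",
            "delta_occupancy",
            "delta_fuzziness",
            "delta_position",
            "p_occupancy",
            "p_fuzziness",
            "p_position",
        ]
    ] = pd.DataFrame(recs, index=pairs.index)
    return scored


def call_dpns(scored: pd.DataFrame, fdr: float = DEFAULT_FDR) -> pd.DataFrame:
    """BH-adjust each test family separately and flag DPNs.

    A pair is a DPN when any of its three q-values is below ``fdr``; the
    ``categories`` column lists the significant families.
    """
    out = scored.copy()
    for fam in ("occupancy", "fuzziness", "position"):
        out[f"q_{fam}"] = bh_adjust(out[f"p_{fam}"].to_numpy())
    qs = out[["q_occupancy", "q_fuzziness", "q_position"]].to_numpy()
    with np.errstate(invalid="ignore"):
        sig = qs < fdr
    out["is_dpn"] = sig.any(axis=1)
    labels = np.array(["occupancy", "fuzziness", "position"])
    out["categories"] = [",".join(labels[s]) for s in sig]
    return out


def dpns_to_bed(dpns: pd.DataFrame) -> pd.DataFrame:
    """BED6-style view of flagged DPNs; score is -log10 of the min q-value."""
    flagged = dpns[dpns["is_dpn"]].reset_index(drop=True)
    qmin = flagged[["q_occupancy", "q_fuzziness", "q_position"]].min(axis=1)
    return pd.DataFrame(
        {
            "chrom": flagged["chrom_a"],
            "start": flagged[["start_a", "start_b"]].min(axis=1).astype(int),
            "end": flagged[["end_a", "end_b"]].max(axis=1).astype(int),
            "name": [f"dpn{i:06d}" for i in range(len(flagged))],
            "score": -np.log10(np.maximum(qmin, 1e-300)),
            "strand": ".",
        }
    )
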