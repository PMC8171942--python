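"""Peak calling, peak matching, and the three nucleosome dynamics tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nucdyn import calling, profiles
from nucdyn._util import bh_adjust
from nucdyn.profiles import OccupancyTrack

from conftest import make_fragments


def track_from_signal(sig):
    return OccupancyTrack(
        {"chr1": np.asarray(sig, float)}, 0, 0, 1.0, {"chr1": len(sig)}
    )


def gaussian_bump(length, centers, heights, sd=20.0):
    x = np.arange(length)
    sig = np.zeros(length)
    for c, h in zip(centers, heights):
        sig += h * np.exp(-0.5 * ((x - c) / sd) ** 2)
    return sig


class TestCallPeaks:
    def test_flat_zero_track_gives_no_peaks(self):
        assert len(calling.call_peaks(track_from_signal(np.zeros(1000)), 0.1)) == 0

    def test_two_clean_bumps_found_at_their_modes(self):
        sig = gaussian_bump(1200, [500, 680], [3.0, 2.0])
        peaks = calling.call_peaks(track_from_signal(sig), min_height=0.5)
        assert len(peaks) == 2
        # oracle: the argmax of each generated bump
        assert abs(peaks["summit"][0] - 500) <= 5
        assert abs(peaks["summit"][1] - 680) <= 5
        assert (peaks["occupancy"] >= peaks["summit_height"]).all()
        assert ((peaks["end"] - peaks["start"]) <= 250).all()

    def test_exclusion_radius_keeps_the_taller(self):
        sig = gaussian_bump(1200, [500, 560], [3.0, 2.0])
        peaks = calling.call_peaks(track_from_signal(sig), 0.5, min_distance=120)
        assert len(peaks) == 1
        # greedy-selection oracle: taller candidate survives
        cand = np.flatnonzero(
            (sig[1:-1] > sig[:-2]) & (sig[1:-1] >= sig[2:])
        ) + 1
        tallest = cand[np.argmax(sig[cand])]
        assert peaks["summit"][0] == tallest


class TestFuzziness:
    def test_identical_midpoints_have_zero_spread(self):
        assert calling.peak_fuzziness(np.array([500, 500, 500])) == 0.0

    def test_population_sd_formula(self):
        assert calling.peak_fuzziness(np.array([498, 500, 502])) == pytest.approx(
            np.sqrt(8 / 3)
        )

    def test_sampling_recovers_generative_sd(self):
        rng = np.random.default_rng(1)
        mids = np.round(rng.normal(0, 20, 10_000))
        assert 19 <= calling.peak_fuzziness(mids) <= 21

    def test_undefined_below_two_fragments(self):
        assert np.isnan(calling.peak_fuzziness(np.array([5])))


def peaks_at(summits, height=1.0):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "start": [s - 73 for s in summits],
            "end": [s + 74 for s in summits],
            "summit": summits,
            "summit_height": height,
            "occupancy": 10.0,
        }
    )


class TestMatchPeaks:
    def test_identical_lists_pair_with_zero_shift(self):
        pk = peaks_at([100, 300, 900])
        pairs = calling.match_peaks(pk, pk)
        assert (pairs["status"] == "matched").all()
        assert (pairs["summit_a"] == pairs["summit_b"]).all()

    def test_lone_peak_gets_pseudo_zero_partner(self):
        pairs = calling.match_peaks(peaks_at([100]), peaks_at([], height=[]))
        assert list(pairs["status"]) == ["only_a"]
        assert pairs.loc[0, "occupancy_b"] == 0.0
        assert pairs.loc[0, "start_b"] == pairs.loc[0, "start_a"]

    def test_mixed_pairing_matches_exhaustive_oracle(self):
        pairs = calling.match_peaks(peaks_at([100, 300]), peaks_at([110, 500]))
        by_status = pairs.groupby("status")["summit_a"].apply(list).to_dict()
        assert by_status == {"matched": [100], "only_a": [300], "only_b": [500]}
        matched = pairs[pairs["status"] == "matched"].iloc[0]
        assert (matched["summit_a"], matched["summit_b"]) == (100, 110)


class TestOccupancyTest:
    def test_balanced_counts_are_null(self):
        assert calling.test_occupancy(100, 100, 1e6, 1e6) == pytest.approx(1.0)
        assert calling.test_occupancy(0, 0, 1e6, 1e6) == 1.0

    def test_matches_brute_force_binomial_sum(self):
        # two-sided exact binomial: sum of outcome probabilities <= P(obs)
        n, total, p0 = 100, 300, 0.5
        pmf = stats.binom.pmf(np.arange(total + 1), total, p0)
        oracle = pmf[pmf <= pmf[n] * (1 + 1e-12)].sum()
        assert calling.test_occupancy(100, 200, 1e6, 1e6) == pytest.approx(oracle)

    def test_depth_imbalance_shifts_the_null(self):
        # doubled depth in condition a makes 200 vs 100 the expected outcome
        assert calling.test_occupancy(200, 100, 2e6, 1e6) == pytest.approx(1.0, abs=0.1)


class TestFuzzinessAndPositionTests:
    def test_identical_samples_are_null(self):
        mids = np.arange(500, 540)
        assert calling.test_fuzziness(mids, mids.copy()) == pytest.approx(1.0)
        delta, p = calling.test_position(mids, mids.copy())
        assert delta == 0.0
        assert p == pytest.approx(1.0)

    def test_variance_ratio_detects_fuzz_change(self):
        rng = np.random.default_rng(2)
        a = rng.normal(500, 5, 200)
        b = rng.normal(500, 25, 200)
        assert calling.test_fuzziness(a, b) < 1e-6

    def test_welch_detects_shift(self):
        rng = np.random.default_rng(3)
        a = rng.normal(500, 15, 200)
        b = rng.normal(530, 15, 200)
        delta, p = calling.test_position(a, b)
        assert p < 1e-6
        assert delta == pytest.approx(30, abs=5)

    def test_small_samples_excluded(self):
        a = np.array([1.0, 2.0, 3.0])
        assert np.isnan(calling.test_fuzziness(a, a))
        delta, p = calling.test_position(a, a)
        assert np.isnan(p)


class TestCallDpns:
    def _null_scored(self, m, p_hit=None):
        scored = pd.DataFrame(
            {
                "p_occupancy": np.ones(m),
                "p_fuzziness": np.ones(m),
                "p_position": np.ones(m),
            }
        )
        if p_hit is not None:
            scored.loc[0, "p_occupancy"] = p_hit
        return scored

    def test_identical_conditions_give_zero_dpns(self, null_landscape):
        genome, _, mock, _ = null_landscape
        from nucdyn import synthetic

        frags = synthetic.sample_fragments(mock, genome, 20_000, seed=4)
        track = profiles.midpoint_coverage(frags, genome.lengths)
        peaks = calling.call_peaks(track)
        idx = calling.FragmentIndex.from_fragments(frags)
        pairs = calling.match_peaks(peaks, peaks)
        dpns = calling.call_dpns(calling.score_pairs(pairs, idx, idx))
        assert len(dpns) > 50
        assert dpns["is_dpn"].sum() == 0

    def test_bh_single_hit_hand_computation(self):
        m = 50
        dpns = calling.call_dpns(self._null_scored(m, p_hit=1e-12), fdr=0.01)
        assert dpns.loc[0, "q_occupancy"] == pytest.approx(1e-12 * m)
        assert dpns.loc[0, "is_dpn"]
        assert dpns.loc[0, "categories"] == "occupancy"
        assert dpns["is_dpn"].sum() == 1

    def test_bh_matches_hand_computation_on_mixed_family(self):
        p = np.array([0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216])
        # hand-computed BH (step-up, monotone from the top)
        expected = np.array(
            [0.01, 0.04, 0.084, 0.084, 0.084, 0.1, 0.105714285714, 0.24, 0.24, 0.216]
        )
        expected = np.minimum.accumulate(expected[::-1])[::-1]
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-9)

    def test_label_swap_symmetry(self, null_landscape):
        genome, _, mock, _ = null_landscape
        from nucdyn import synthetic

        fa = synthetic.sample_fragments(mock, genome, 15_000, seed=5, stream="a")
        fb = synthetic.sample_fragments(mock, genome, 15_000, seed=5, stream="b")
        ta = profiles.midpoint_coverage(fa, genome.lengths)
        tb = profiles.midpoint_coverage(fb, genome.lengths)
        pa, pb = calling.call_peaks(ta), calling.call_peaks(tb)
        ia = calling.FragmentIndex.from_fragments(fa)
        ib = calling.FragmentIndex.from_fragments(fb)
        fwd = calling.score_pairs(calling.match_peaks(pa, pb), ia, ib)
        rev = calling.score_pairs(calling.match_peaks(pb, pa), ib, ia)
        f = fwd[fwd["status"] == "matched"].sort_values("summit_a").reset_index(drop=True)
        r = rev[rev["status"] == "matched"].sort_values("summit_b").reset_index(drop=True)
        assert len(f) == len(r)
        np.testing.assert_allclose(f["delta_occupancy"], -r["delta_occupancy"], atol=1e-9)
        np.testing.assert_allclose(f["delta_position"], -r["delta_position"], atol=1e-9)
        np.testing.assert_allclose(f["p_occupancy"], r["p_occupancy"], atol=1e-12)
        np.testing.assert_allclose(f["p_position"], r["p_position"], atol=1e-9)
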