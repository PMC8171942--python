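"""Regions, DPN-to-gene mapping, +1 anchoring, metaprofiles, clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from nucdyn import genes as gc
from nucdyn.profiles import OccupancyTrack

L = 10_000


def gene_row(gene_id="g1", chrom="chr1", strand="+", tss=5000, tes=7000):
    return pd.DataFrame(
        [(gene_id, chrom, strand, tss, tes)],
        columns=["gene_id", "chrom", "strand", "tss", "tes"],
    )


def region(regions, name):
    r = regions[regions["region"] == name].iloc[0]
    return (r.start, r.end)


class TestAssignRegions:
    def test_plus_strand_definitions(self):
        regions = gc.assign_regions(gene_row(), {"chr1": L})
        assert region(regions, "promoter") == (4000, 5000)
        assert region(regions, "tss_region") == (4910, 5090)
        assert region(regions, "body") == (5000, 7000)
        assert region(regions, "promoter_plus_body") == (4000, 7000)

    def test_minus_strand_definitions(self):
        regions = gc.assign_regions(gene_row(strand="-", tss=7000, tes=5000), {"chr1": L})
        assert region(regions, "promoter") == (7001, 8001)
        assert region(regions, "body") == (5001, 7001)

    def test_strand_flip_mirror_oracle(self):
        # a minus-strand gene is the mirror image of a plus-strand gene
        plus = gc.assign_regions(gene_row(strand="+", tss=5000, tes=7000), {"chr1": L})
        minus = gc.assign_regions(
            gene_row(strand="-", tss=L - 1 - 5000, tes=L - 1 - 7000), {"chr1": L}
        )
        for name in gc.REGION_CLASSES:
            s, e = region(plus, name)
            ms, me = region(minus, name)
            assert (ms, me) == (L - e, L - s)

    def test_promoter_clipped_at_chromosome_start(self):
        regions = gc.assign_regions(gene_row(tss=300, tes=2000), {"chr1": L})
        assert region(regions, "promoter") == (0, 300)

    def test_promoter_and_body_disjoint(self):
        regions = gc.assign_regions(gene_row(strand="-", tss=7000, tes=5000), {"chr1": L})
        ps, pe = region(regions, "promoter")
        bs, be = region(regions, "body")
        assert min(pe, be) <= max(ps, bs)  # no shared bp

    def test_tss_outside_chromosome_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            gc.assign_regions(gene_row(tss=50_000, tes=52_000), {"chr1": L})


class TestMapDpns:
    def dpns_at(self, summits):
        return pd.DataFrame({"chrom": "chr1", "summit": summits})

    def test_summit_in_promoter_is_assigned(self):
        regions = gc.assign_regions(gene_row(), {"chr1": L})
        hits = gc.map_dpns_to_genes(self.dpns_at([4500]), regions, "promoter")
        assert hits["gene_id"].tolist() == ["g1"]

    def test_half_open_boundary_at_tss(self):
        regions = gc.assign_regions(gene_row(), {"chr1": L})
        at_tss = self.dpns_at([5000])
        assert len(gc.map_dpns_to_genes(at_tss, regions, "promoter")) == 0
        assert len(gc.map_dpns_to_genes(at_tss, regions, "body")) == 1

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(8)
        genes = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(50)],
                "chrom": "chr1",
                "strand": np.where(rng.random(50) < 0.5, "+", "-"),
                "tss": rng.integers(2000, 90_000, 50),
            }
        )
        genes["tes"] = np.where(
            genes["strand"] == "+", genes["tss"] + 1500, genes["tss"] - 1500
        )
        regions = gc.assign_regions(genes, {"chr1": 100_000})
        dpns = self.dpns_at(rng.integers(0, 100_000, 1000))
        fast = gc.map_dpns_to_genes(dpns, regions, "promoter_plus_body")
        sel = regions[regions["region"] == "promoter_plus_body"]
        brute = {
            (r.gene_id, i)
            for r in sel.itertuples(index=False)
            for i, s in dpns["summit"].items()
            if r.start <= s < r.end
        }
        assert set(map(tuple, fast.to_numpy())) == brute


class TestFindPlus1:
    def peaks_at(self, summits):
        return pd.DataFrame({"chrom": "chr1", "summit": summits})

    def test_first_downstream_summit_wins(self):
        g = gene_row().iloc[0]
        assert gc.find_plus1(self.peaks_at([5020, 5200]), g) == 5020

    def test_no_summit_in_window_is_undefined(self):
        g = gene_row().iloc[0]
        assert gc.find_plus1(self.peaks_at([4000, 6000]), g) is None

    def test_minus_strand_mirror(self):
        gp = gene_row().iloc[0]
        gm = gene_row(strand="-", tss=L - 1 - 5000, tes=L - 1 - 7000).iloc[0]
        for summit_offset in (20, 200, -40):
            p_plus = gc.find_plus1(self.peaks_at([5000 + summit_offset]), gp)
            p_minus = gc.find_plus1(
                self.peaks_at([L - 1 - (5000 + summit_offset)]), gm
            )
            if p_plus is None:
                assert p_minus is None
            else:
                assert p_minus == L - 1 - p_plus


class TestMetaprofile:
    def constant_track(self, c=3.0):
        return OccupancyTrack({"chr1": np.full(L, c)}, 0, 0, 1.0, {"chr1": L})

    def test_constant_track_gives_flat_matrix(self):
        genes = gene_row()
        anchors = pd.Series({"g1": 5060})
        mp = gc.metaprofile(self.constant_track(), genes, anchors, (-100, 100), 10)
        assert mp.values.shape == (1, 20)
        np.testing.assert_allclose(mp.values, 3.0)
        np.testing.assert_allclose(mp.mean_profile, 3.0)

    def test_row_equals_track_slice(self):
        sig = np.arange(L, dtype=float)
        track = OccupancyTrack({"chr1": sig}, 0, 0, 1.0, {"chr1": L})
        mp = gc.metaprofile(
            track, gene_row(), pd.Series({"g1": 5000}), (-10, 10), 1
        )
        np.testing.assert_array_equal(mp.values[0], sig[4990:5010])

    def test_minus_strand_mirror_oracle(self):
        rng = np.random.default_rng(9)
        sig = rng.random(L)
        track = OccupancyTrack({"chr1": sig}, 0, 0, 1.0, {"chr1": L})
        mirrored = OccupancyTrack({"chr1": sig[::-1].copy()}, 0, 0, 1.0, {"chr1": L})
        anchor = 5000
        mp_plus = gc.metaprofile(
            track, gene_row(), pd.Series({"g1": anchor}), (-200, 300), 10
        )
        mp_minus = gc.metaprofile(
            mirrored,
            gene_row(strand="-", tss=L - 1 - 5000, tes=L - 1 - 7000),
            pd.Series({"g1": L - 1 - anchor}),
            (-200, 300),
            10,
        )
        np.testing.assert_allclose(mp_minus.values, mp_plus.values)

    def test_identical_tracks_difference_is_zero(self):
        t = self.constant_track()
        dmp = gc.differential_metaprofile(
            t, t, gene_row(), pd.Series({"g1": 5060}), (-100, 100), 10
        )
        np.testing.assert_allclose(dmp.values, 0.0)

    def test_gene_without_anchor_excluded(self):
        mp = gc.metaprofile(
            self.constant_track(), gene_row(), pd.Series({"g1": np.nan}), (-100, 100), 10
        )
        assert mp.values.shape[0] == 0
        assert mp.n_excluded == 1


class TestClusterProfiles:
    def two_pattern_matrix(self, n=40, bins=30):
        rows = np.zeros((n, bins))
        rows[: n // 2, :10] = 5.0
        rows[n // 2 :, 20:] = -5.0
        return gc.MetaProfileMatrix([f"g{i}" for i in range(n)], np.arange(bins), rows, 1)

    def test_two_patterns_perfectly_separated(self):
        mp = self.two_pattern_matrix()
        res = gc.cluster_profiles(mp, k=2, seed=0)
        truth = [0] * 20 + [1] * 20
        assert adjusted_rand_score(truth, res.assignments.to_numpy()) == 1.0

    def test_duplicate_rows_share_assignment(self):
        mp = self.two_pattern_matrix()
        doubled = gc.MetaProfileMatrix(
            [f"g{i}" for i in range(80)],
            mp.positions,
            np.vstack([mp.values, mp.values]),
            1,
        )
        res = gc.cluster_profiles(doubled, k=2, seed=1)
        a = res.assignments.to_numpy()
        np.testing.assert_array_equal(a[:40], a[40:])

    def test_deterministic_for_seed_and_sizes_ordered(self):
        rng = np.random.default_rng(10)
        rows = rng.normal(size=(60, 25))
        rows[:30] += 4
        mp = gc.MetaProfileMatrix([f"g{i}" for i in range(60)], np.arange(25), rows, 1)
        r1 = gc.cluster_profiles(mp, k=4, seed=7)
        r2 = gc.cluster_profiles(mp, k=4, seed=7)
        pd.testing.assert_series_equal(r1.assignments, r2.assignments)
        np.testing.assert_allclose(r1.centroids, r2.centroids)
        sizes = r1.assignments.value_counts().sort_index().to_numpy()
        assert (np.diff(sizes) <= 0).all()

    def test_k_exceeding_rows_rejected(self):
        mp = self.two_pattern_matrix(n=4)
        with pytest.raises(ValueError, match="clusters"):
            gc.cluster_profiles(mp, k=6)
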