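import numpy as np
import pytest

from bgrd import (
    GeneModel,
    SignalTrack,
    compute_pausing_stats,
    eligibility_filter,
    motif_fold_enrichment,
    motif_track,
    pausing_index,
    ptb_ratio,
    scaled_body_profile,
    tss_profile,
)
from bgrd.profiles import rank_slices


def uniform_track(value=2.0, n=100_000, step=1):
    return SignalTrack({"chr1": np.full(n, value)}, step=step)


class TestTssProfile:
    def test_uniform_track_constant_mean(self):
        genes = [
            GeneModel("a", "chr1", "+", 50_000, 60_000),
            GeneModel("b", "chr1", "-", 20_000, 30_000),
        ]
        pm = tss_profile(uniform_track(3.0), genes, flank=1000, bin=100)
        assert np.allclose(pm.mean_profile, 3.0)

    def test_strand_symmetry(self):
        """Mirror-image signal around two TSSs gives identical oriented rows."""
        arr = np.zeros(10_000)
        arr[5000:5100] = 7.0  # downstream of + TSS at 5000
        arr[1900:2000] = 7.0  # downstream (leftward) of - TSS at 2000
        track = SignalTrack({"chr1": arr}, step=1)
        plus = GeneModel("p", "chr1", "+", 5000, 6000)
        minus = GeneModel("m", "chr1", "-", 1000, 2000)
        pm = tss_profile(track, [plus, minus], flank=500, bin=100)
        np.testing.assert_array_equal(pm.values[0], pm.values[1])

    def test_out_of_bounds_positions_contribute_zero(self):
        g = GeneModel("a", "chr1", "+", 100, 2000)
        pm = tss_profile(uniform_track(1.0, n=5000), [g], flank=1000, bin=100)
        # the first 900 bp of the upstream flank fall before the chromosome
        assert pm.values[0, :9].sum() == 0 and np.all(pm.values[0, 10:] == 1.0)

    def test_genome_reversal_invariance(self):
        """Reversing the genome (coordinates and strands) preserves profiles."""
        rng = np.random.default_rng(0)
        n = 20_000
        arr = rng.uniform(0, 5, n)
        track = SignalTrack({"chr1": arr}, step=1)
        genes = [
            GeneModel("a", "chr1", "+", 5000, 9000),
            GeneModel("b", "chr1", "-", 12_000, 15_000),
        ]
        flip = {"+": "-", "-": "+"}
        rev_track = SignalTrack({"chr1": arr[::-1].copy()}, step=1)
        rev_genes = [
            GeneModel(g.gene_id, "chr1", flip[g.strand], n - g.end, n - g.start)
            for g in genes
        ]
        pm = tss_profile(track, genes, flank=2000, bin=100)
        pm_rev = tss_profile(rev_track, rev_genes, flank=2000, bin=100)
        np.testing.assert_allclose(pm.values, pm_rev.values)


class TestScaledBodyProfile:
    def test_uniform_signal_flat_profile(self):
        g = GeneModel("a", "chr1", "+", 10_000, 25_000)
        pm = scaled_body_profile(uniform_track(2.0), [g], n_body_bins=20)
        assert np.allclose(pm.values, 2.0)

    @pytest.mark.parametrize("length", [10_000, 33_000])
    def test_half_on_half_off_any_length(self, length):
        arr = np.zeros(100_000)
        start = 20_000
        arr[start : start + length // 2] = 1.0
        track = SignalTrack({"chr1": arr}, step=1)
        g = GeneModel("a", "chr1", "+", start, start + length)
        pm = scaled_body_profile(track, [g], n_body_bins=10)
        assert np.all(pm.values[0, :4] > 0.99) and np.all(pm.values[0, 6:] < 0.01)

    def test_matches_per_bp_averaging_oracle(self):
        rng = np.random.default_rng(5)
        arr = rng.uniform(0, 3, 50_000)
        track = SignalTrack({"chr1": arr}, step=1)
        g = GeneModel("a", "chr1", "+", 7000, 19_337)
        pm = scaled_body_profile(track, [g], n_body_bins=7)
        body = arr[7000:19_337]
        edges = np.linspace(0, len(body), 8).astype(int)
        oracle = [body[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
        np.testing.assert_allclose(pm.values[0], oracle)

    def test_too_short_gene_skipped(self, caplog):
        track = SignalTrack({"chr1": np.ones(1000)}, step=100)
        g = GeneModel("tiny", "chr1", "+", 0, 500)
        with caplog.at_level("WARNING"):
            pm = scaled_body_profile(track, [g], n_body_bins=10)
        assert pm.gene_ids == []


class TestPausingAndPtb:
    def test_uniform_density_window_arithmetic(self):
        g = GeneModel("a", "chr1", "+", 10_000, 13_300)
        assert pausing_index(uniform_track(0.5), g) == pytest.approx(330 / 3000)

    def test_ptb_uniform_30kb_gene(self):
        g = GeneModel("a", "chr1", "+", 40_000, 70_000)
        assert ptb_ratio(uniform_track(1.0), g) == pytest.approx(6000 / 27_000)

    def test_promoter_only_signal_undefined(self):
        arr = np.zeros(50_000)
        arr[9970:10_300] = 5.0
        track = SignalTrack({"chr1": arr}, step=1)
        g = GeneModel("a", "chr1", "+", 10_000, 20_000)
        assert np.isnan(pausing_index(track, g))

    def test_matches_per_bp_summation_oracle(self):
        rng = np.random.default_rng(7)
        arr = rng.uniform(0, 2, 100_000)
        track = SignalTrack({"chr1": arr}, step=1)
        g = GeneModel("a", "chr1", "-", 30_000, 80_000)  # TSS at 80_000
        prom = arr[80_000 - 300 : 80_000 + 30].sum()
        body = arr[30_000 : 80_000 - 300].sum()
        assert pausing_index(track, g) == pytest.approx(prom / body)
        prom3k = arr[80_000 - 3000 : 80_000 + 3000].sum()
        body3k = arr[30_000 : 80_000 - 3000].sum()
        assert ptb_ratio(track, g) == pytest.approx(prom3k / body3k)

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        arr = rng.uniform(0.1, 2, 50_000)
        g = GeneModel("a", "chr1", "+", 10_000, 40_000)
        t1 = SignalTrack({"chr1": arr}, step=1)
        t2 = SignalTrack({"chr1": arr * 37.0}, step=1)
        assert pausing_index(t1, g) == pytest.approx(pausing_index(t2, g))
        assert ptb_ratio(t1, g) == pytest.approx(ptb_ratio(t2, g))

    def test_eligibility_strict_floor(self):
        def track_with(prom_density, body_density):
            arr = np.zeros(50_000)
            arr[9970:10_300] = prom_density
            arr[10_300:40_000] = body_density
            return SignalTrack({"chr1": arr}, step=1)

        g = GeneModel("a", "chr1", "+", 10_000, 40_000)
        k27 = uniform_track(1.0)
        kept = compute_pausing_stats(track_with(0.02, 0.02), k27, [g])
        assert eligibility_filter(kept)  # both above the floor
        dropped = compute_pausing_stats(track_with(0.02, 0.005), k27, [g])
        assert not eligibility_filter(dropped)  # body below the floor
        boundary = compute_pausing_stats(track_with(0.01, 0.02), k27, [g])
        assert not eligibility_filter(boundary)  # exactly 0.01 fails (strict >)


class TestMotifs:
    def test_overlapping_occurrences_no_double_count(self):
        track = motif_track([("chr1", 0, 10), ("chr1", 5, 15)], {"chr1": 20})
        expected = np.array([1.0] * 15 + [0.0] * 5)
        np.testing.assert_array_equal(track.values["chr1"], expected)

    def test_no_occurrences_all_zero(self):
        track = motif_track([], {"chr1": 50})
        assert track.values["chr1"].sum() == 0

    def test_matches_per_bp_membership_oracle(self):
        rng = np.random.default_rng(9)
        occs = []
        for _ in range(30):
            s = int(rng.integers(0, 900))
            occs.append(("chr1", s, s + int(rng.integers(1, 80))))
        track = motif_track(occs, {"chr1": 1000})
        oracle = np.zeros(1000)
        for _, s, e in occs:
            oracle[s:e] = 1.0
        np.testing.assert_array_equal(track.values["chr1"], oracle)

    def test_identical_groups_fold_one(self):
        track = motif_track([("chr1", 0, 50_000)], {"chr1": 100_000})
        genes = [GeneModel("a", "chr1", "+", 10_000, 30_000)]
        assert motif_fold_enrichment(track, genes, genes) == 1.0

    def test_planted_motif_inside_bgrd_bodies(self):
        rng = np.random.default_rng(10)
        bgrd = [GeneModel("b1", "chr1", "+", 10_000, 60_000)]
        ctrl = [GeneModel("c1", "chr1", "+", 100_000, 150_000)]
        occs = [("chr1", int(s), int(s) + 20) for s in rng.integers(10_000, 60_000, 200)]
        occs += [("chr1", int(s), int(s) + 20) for s in rng.integers(100_000, 150_000, 20)]
        track = motif_track(occs, {"chr1": 200_000})
        assert motif_fold_enrichment(track, bgrd, ctrl) > 1.5

    def test_uniform_random_placement_fold_near_one(self):
        rng = np.random.default_rng(11)
        occs = [("chr1", int(s), int(s) + 10) for s in rng.integers(0, 500_000, 5000)]
        track = motif_track(occs, {"chr1": 500_100})
        bgrd = [GeneModel("b", "chr1", "+", 50_000, 150_000)]
        ctrl = [GeneModel("c", "chr1", "+", 300_000, 400_000)]
        assert motif_fold_enrichment(track, bgrd, ctrl) == pytest.approx(1.0, abs=0.15)


def test_rank_slices_top_median_bottom():
    values = {f"g{i:03d}": float(i) for i in range(100)}
    slices = rank_slices(values, slice_size=10)
    assert slices["top"][0] == "g099" and slices["bottom"][-1] == "g000"
    assert len(slices["median"]) == 10
    assert set(slices["median"]) < set(values) - set(slices["top"]) - set(slices["bottom"])
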