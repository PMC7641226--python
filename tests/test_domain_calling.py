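import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgrd import (
    GeneModel,
    GeneSet,
    Peak,
    SignalTrack,
    SyntheticSpec,
    assign_gene_groups,
    call_peaks_from_signal,
    choose_planted,
    classify_domains,
    compute_gene_peak_stats,
    coverage_boundary,
    find_turning_point,
    intron_fraction,
    make_genome,
    make_sample,
)
from bgrd.domain_calling import DegenerateCurveError, NoBoundaryError, TurningPoint


def brute_force_stats(genes, peaks, clip=False):
    """Exhaustive all-pairs overlap oracle."""
    out = {}
    for g in genes:
        ws, hm = 0, 0.0
        for p in peaks:
            if p.chrom == g.chrom and p.start < g.end and p.end > g.start:
                ws += (min(p.end, g.end) - max(p.start, g.start)) if clip else p.width
                hm = max(hm, p.height)
        out[g.gene_id] = (ws, hm)
    return out


class TestGenePeakStats:
    def test_direct_sum_and_max(self):
        g = GeneModel("a", "chr1", "+", 0, 100)
        peaks = [Peak("chr1", 10, 20, 2.0), Peak("chr1", 50, 90, 5.0)]
        (s,) = compute_gene_peak_stats([g], peaks)
        assert (s.width_sum, s.height_max, s.coverage) == (50, 5.0, 0.5)

    def test_clipping_semantics(self):
        g = GeneModel("a", "chr1", "+", 0, 100)
        peaks = [Peak("chr1", -50, 150, 1.0)]
        (unclipped,) = compute_gene_peak_stats([g], peaks, clip=False)
        (clipped,) = compute_gene_peak_stats([g], peaks, clip=True)
        assert unclipped.width_sum == 200 and clipped.width_sum == 100

    def test_gene_without_peaks_gets_zero(self):
        g = GeneModel("a", "chr9", "+", 0, 100)
        (s,) = compute_gene_peak_stats([g], [Peak("chr1", 0, 10, 1.0)])
        assert s.width_sum == 0 and s.height_max == 0.0

    @pytest.mark.parametrize("clip", [False, True])
    @pytest.mark.parametrize("n_genes,n_peaks,seed", [(3, 5, 0), (100, 200, 1)])
    def test_matches_brute_force_oracle(self, clip, n_genes, n_peaks, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(n_genes):
            s = int(rng.integers(0, 10000))
            genes.append(
                GeneModel(f"g{i}", f"chr{rng.integers(1, 3)}", "+", s, s + int(rng.integers(1, 500)))
            )
        peaks = []
        for _ in range(n_peaks):
            s = int(rng.integers(0, 10000))
            peaks.append(
                Peak(f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(1, 300)), float(rng.uniform(0, 5)))
            )
        oracle = brute_force_stats(genes, peaks, clip)
        for s in compute_gene_peak_stats(genes, peaks, clip=clip):
            assert (s.width_sum, s.height_max) == oracle[s.gene_id]


class TestTurningPoint:
    def test_perfect_right_angle(self):
        values = [0.0] * 199 + [50000.0]
        tp = find_turning_point(values)
        assert tp.rank_index == 198 and tp.width_at_turn == 0.0

    def test_cutoff_is_multiplier_times_turn_width(self):
        tp = TurningPoint.from_width(60500.0, multiplier=2.0)
        assert tp.cutoff == 121000.0

    def test_matches_exhaustive_distance_scan(self):
        rng = np.random.default_rng(3)
        values = np.sort(rng.uniform(0, 1, 200)) ** 4 * 1e5  # convex curve
        tp = find_turning_point(values)
        v = np.sort(values)
        n = len(v)
        y = (v - v[0]) / (v[-1] - v[0]) * (n - 1)
        d2 = [(n - 1 - i) ** 2 + y[i] ** 2 for i in range(n)]
        best = max(i for i in range(n) if d2[i] == min(d2))
        assert tp.rank_index == best

    def test_degenerate_flat_curve_errors(self):
        with pytest.raises(DegenerateCurveError):
            find_turning_point([5.0, 5.0, 5.0, 5.0])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 1000),
        shift=st.floats(0, 1e6),
        seed=st.integers(0, 10),
    )
    def test_affine_invariance(self, scale, shift, seed):
        """Knee index is unchanged by affine rescaling; cutoff follows the data."""
        rng = np.random.default_rng(seed)
        values = np.concatenate([rng.uniform(0, 10, 50), rng.uniform(100, 1000, 10)])
        tp1 = find_turning_point(values)
        tp2 = find_turning_point(values * scale + shift)
        assert tp1.rank_index == tp2.rank_index
        assert tp2.width_at_turn == pytest.approx(tp1.width_at_turn * scale + shift)


class TestClassifyDomains:
    def _stats(self, widths, heights=None):
        from bgrd.domain_calling import GeneDomainStats

        heights = heights or [0.0] * len(widths)
        return [
            GeneDomainStats(gene_id=f"g{i}", width_sum=w, height_max=h)
            for i, (w, h) in enumerate(zip(widths, heights))
        ]

    def test_widest_genes_above_cutoff(self):
        stats = self._stats([10, 20, 30, 40, 50, 60, 70, 80, 90, 100])
        tp = TurningPoint.from_width(30.0, multiplier=2.0)  # cutoff 60
        out, _ = classify_domains(stats, tp, n_top=3)
        bgrd = {s.gene_id for s in out if s.domain_class == "BGRD"}
        assert bgrd == {"g7", "g8", "g9"}

    def test_cutoff_bites_below_n_top(self):
        stats = self._stats([10, 20, 30, 40, 50, 60, 70, 80, 90, 100])
        tp = TurningPoint.from_width(45.0, multiplier=2.0)  # cutoff 90
        out, _ = classify_domains(stats, tp, n_top=3)
        assert {s.gene_id for s in out if s.domain_class == "BGRD"} == {"g8", "g9"}

    def test_bgrd_takes_precedence_over_fgrd(self):
        stats = self._stats([100, 1, 1, 1], heights=[9.0, 5.0, 3.0, 1.0])
        tp = TurningPoint.from_width(10.0)
        out, _ = classify_domains(stats, tp, n_top=1)
        classes = {s.gene_id: s.domain_class for s in out}
        assert classes["g0"] == "BGRD" and classes["g1"] == "FGRD"

    def test_sets_disjoint_and_control_from_remainder(self):
        stats = self._stats(list(range(20)), heights=list(range(20, 0, -1)))
        tp = TurningPoint.from_width(1.0)
        out, control = classify_domains(stats, tp, n_top=5, seed=3)
        bgrd = {s.gene_id for s in out if s.domain_class == "BGRD"}
        fgrd = {s.gene_id for s in out if s.domain_class == "FGRD"}
        assert not bgrd & fgrd
        assert len(control) == 5 and not control.gene_ids & (bgrd | fgrd)

    def test_n_top_larger_than_universe_rejected(self):
        with pytest.raises(ValueError):
            classify_domains(self._stats([1, 2]), TurningPoint.from_width(0.5), n_top=3)

    def test_planted_recovery_on_dense_genome(self):
        """1000 genes, 400 planted broad domains: >= 95% recovered at n_top=400.

        Gene lengths are kept comparable (narrow log-normal) so the planted
        widths form one block well separated from background noise; with a
        dense planted fraction a wide length spread would put the curve's
        knee inside the planted arm rather than at the noise boundary.
        """
        spec = SyntheticSpec(
            seed=5, n_genes=1000, chrom_length=120_000_000, gene_len_sigma=0.25,
            frac_bgrd=0.4, frac_fgrd=0.1, bgrd_min_gene_length=20_000,
        )
        genes = make_genome(spec)
        pb, pf = choose_planted(genes, spec)
        peaks, _ = make_sample(genes, spec, pb, pf, with_track=False)
        stats = compute_gene_peak_stats(genes, peaks)
        tp = find_turning_point([s.width_sum for s in stats])
        out, _ = classify_domains(stats, tp, n_top=400)
        called = {s.gene_id for s in out if s.domain_class == "BGRD"}
        assert len(called & pb.gene_ids) / len(pb) >= 0.95


class TestCoverageBoundary:
    def test_bimodal_mixture_valley(self):
        rng = np.random.default_rng(0)
        cov = np.concatenate(
            [rng.normal(0.05, 0.01, 500), rng.normal(0.6, 0.05, 500)]
        )
        b = coverage_boundary(cov[cov > 0])
        assert 0.1 <= b <= 0.4

    def test_two_separated_clusters(self):
        cov = [0.1] * 50 + [0.101] * 50 + [0.9] * 50 + [0.899] * 50
        b = coverage_boundary(cov)
        assert 0.101 < b < 0.899

    def test_single_value_errors(self):
        with pytest.raises(NoBoundaryError):
            coverage_boundary([0.5] * 100)

    def test_unimodal_reports_mode(self):
        rng = np.random.default_rng(1)
        with pytest.raises(NoBoundaryError) as err:
            coverage_boundary(rng.normal(0.5, 0.05, 400))
        assert 0.3 < err.value.mode < 0.7


class TestGeneGroups:
    def _setup(self):
        genes = [
            GeneModel("bg1", "chr1", "+", 0, 101_000),
            GeneModel("bg2", "chr1", "+", 200_000, 350_000),
            GeneModel("long_lo", "chr1", "+", 400_000, 520_000),  # cov below boundary
            GeneModel("long_hi", "chr1", "+", 600_000, 720_000),  # cov above boundary
            GeneModel("short", "chr1", "+", 800_000, 810_000),
        ]
        from bgrd.domain_calling import GeneDomainStats

        stats = [
            GeneDomainStats("bg1", coverage=0.9),
            GeneDomainStats("bg2", coverage=0.8),
            GeneDomainStats("long_lo", coverage=0.05),
            GeneDomainStats("long_hi", coverage=0.7),
            GeneDomainStats("short", coverage=0.9),
        ]
        return genes, stats

    def test_min_bgrd_length_splits_groups(self):
        genes, stats = self._setup()
        out = assign_gene_groups(
            stats, genes, GeneSet("bgrd", {"bg1", "bg2"}), boundary=0.14
        )
        groups = {s.gene_id: s.group for s in out}
        # L* = 101 kb (shortest BGRD gene)
        assert groups == {
            "bg1": "a1", "bg2": "a1", "long_lo": "b", "long_hi": "a2", "short": "c",
        }

    def test_groups_partition_universe(self):
        genes, stats = self._setup()
        out = assign_gene_groups(stats, genes, GeneSet("b", {"bg1"}), boundary=0.14)
        assert all(s.group in ("a1", "a2", "b", "c") for s in out)

    def test_empty_bgrd_rejected(self):
        genes, stats = self._setup()
        with pytest.raises(ValueError):
            assign_gene_groups(stats, genes, GeneSet("b", set()), boundary=0.14)


class TestIntronFraction:
    def test_single_exon_spanning_gene(self):
        g = GeneModel("a", "chr1", "+", 0, 100, exons=((0, 100),))
        assert intron_fraction(g) == 0.0

    def test_partial_exons(self):
        g = GeneModel("a", "chr1", "+", 0, 100, exons=((0, 10), (50, 60)))
        assert intron_fraction(g) == pytest.approx(0.8)

    def test_no_exons_undefined(self):
        with pytest.raises(ValueError):
            intron_fraction(GeneModel("a", "chr1", "+", 0, 100))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_matches_per_bp_labeling_oracle(self, seed):
        rng = np.random.default_rng(seed)
        length = int(rng.integers(10, 500))
        cuts = np.sort(rng.choice(np.arange(1, length), size=min(6, length - 1), replace=False))
        bounds = [0, *cuts.tolist(), length]
        exons = tuple(
            (bounds[i], bounds[i + 1]) for i in range(0, len(bounds) - 1, 2)
        )
        g = GeneModel("a", "chr1", "+", 0, length, exons=exons)
        per_bp = np.zeros(length, dtype=bool)
        for s, e in exons:
            per_bp[s:e] = True
        assert intron_fraction(g) == pytest.approx(1 - per_bp.sum() / length)


class TestPeakCallingPlumbing:
    def test_flat_zero_track_no_peaks(self):
        track = SignalTrack({"chr1": np.zeros(100)}, step=10)
        assert call_peaks_from_signal(track, threshold=1.0) == []

    def test_rectangular_pulse(self):
        arr = np.zeros(100)
        arr[20:70] = 4.0
        track = SignalTrack({"chr1": arr}, step=100)
        (p,) = call_peaks_from_signal(track, threshold=1.0)
        assert (p.start, p.end, p.height) == (2000, 7000, 4.0)

    def test_merge_gap_joins_nearby_runs(self):
        arr = np.zeros(100)
        arr[10:20] = 2.0
        arr[21:30] = 3.0  # 100 bp gap at step 100
        track = SignalTrack({"chr1": arr}, step=100)
        peaks = call_peaks_from_signal(track, threshold=1.0, merge_gap=200)
        assert len(peaks) == 1 and peaks[0].height == 3.0
        assert len(call_peaks_from_signal(track, threshold=1.0, merge_gap=50)) == 2

    def test_min_width_drops_narrow_runs(self):
        arr = np.zeros(100)
        arr[10:11] = 5.0
        arr[50:80] = 2.0
        track = SignalTrack({"chr1": arr}, step=100)
        peaks = call_peaks_from_signal(track, threshold=1.0, min_width=500)
        assert len(peaks) == 1 and peaks[0].start == 5000
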