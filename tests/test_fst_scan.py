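"""Wright Fst arithmetic, window averaging, and candidate-window pruning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from deltafst import (
    FstTrack,
    WindowScore,
    breed_allele_frequencies,
    pairwise_fst,
    select_top_windows,
    window_delta_fst,
    wright_fst,
)
from deltafst.datasets import BREED_CT, BREED_NSD, BREED_SB, CANDIDATE_SNPS

from conftest import make_panel


def closed_form_fst(p1, p2):
    """Independent arithmetic oracle: (p1-p2)^2 / (4 pbar (1-pbar))."""
    pbar = (p1 + p2) / 2
    denom = 4 * pbar * (1 - pbar)
    return (p1 - p2) ** 2 / denom if denom > 0 else 0.0


class TestWrightFst:
    def test_equal_frequencies_give_zero(self):
        assert wright_fst(0.3, 0.3) == 0.0

    def test_fixed_difference_gives_one(self):
        assert wright_fst(1.0, 0.0) == 1.0

    def test_matches_closed_form_on_random_pairs(self, rng):
        p1 = rng.uniform(0, 1, 1000)
        p2 = rng.uniform(0, 1, 1000)
        expected = np.array([closed_form_fst(a, b) for a, b in zip(p1, p2)])
        assert np.allclose(wright_fst(p1, p2), expected, atol=1e-12, rtol=0)

    def test_reported_focal_snp_frequencies(self):
        """T allele 0.80 vs 0.15 and 0.80 vs 0.75 at the chr22 focal SNP."""
        assert wright_fst(0.80, 0.15) == pytest.approx(0.4225 / 0.9975, abs=1e-10)
        assert wright_fst(0.80, 0.75) == pytest.approx(0.0025 / 0.6975, abs=1e-10)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_symmetric_and_label_invariant(self, p1, p2):
        f = wright_fst(p1, p2)
        assert 0.0 <= f <= 1.0
        assert f == pytest.approx(wright_fst(p2, p1), abs=1e-12)
        assert f == pytest.approx(wright_fst(1 - p1, 1 - p2), abs=1e-12)

    def test_candidate_snps_separate_draught_from_trotters(self):
        """Reported top-SNP frequencies: draught-pair Fst far above the
        trotter-pair Fst at every candidate."""
        for snp in CANDIDATE_SNPS:
            f = snp["freqs"]
            fst_b = wright_fst(f[BREED_CT], f[BREED_NSD])
            fst_a = wright_fst(f[BREED_CT], f[BREED_SB])
            assert fst_b > 5 * fst_a


class TestBreedAlleleFrequencies:
    def test_fixation(self):
        panel = make_panel(np.full((10, 1), 2))
        freqs = breed_allele_frequencies(panel)
        assert freqs.freq_b.iloc[0, 0] == 1.0

    def test_direct_counting(self):
        calls = np.array([[2]] * 8 + [[1]] * 2)
        freqs = breed_allele_frequencies(make_panel(calls))
        assert freqs.freq_b.iloc[0, 0] == pytest.approx(0.9)
        assert freqs.n_called.iloc[0, 0] == 10

    def test_no_calls_flagged_undefined(self):
        from deltafst import MISSING
        panel = make_panel(np.full((4, 1), MISSING))
        freqs = breed_allele_frequencies(panel)
        assert np.isnan(freqs.freq_b.iloc[0, 0])

    def test_survey_scale_estimate_within_binomial_interval(self, rng):
        """n=183 trotters simulated at the surveyed T frequency 0.70."""
        truth, n = 0.70, 183
        half_width = 1.96 * np.sqrt(truth * (1 - truth) / (2 * n))
        inside = 0
        for _ in range(20):
            calls = rng.binomial(2, truth, size=(n, 1))
            freqs = breed_allele_frequencies(make_panel(calls))
            inside += abs(freqs.freq_b.iloc[0, 0] - truth) < half_width
        assert inside >= 16  # nominal coverage 95%


def _track(fst_values, pair=("x", "y"), chrom=None, positions=None):
    m = len(fst_values)
    chrom = chrom if chrom is not None else np.array(["1"] * m)
    positions = positions if positions is not None else np.arange(m) * 1000 + 1
    return FstTrack(
        pair=pair,
        marker_ids=[f"m{j}" for j in range(m)],
        chromosome=np.asarray(chrom),
        position_bp=np.asarray(positions),
        fst=np.asarray(fst_values, dtype=float),
    )


class TestWindowDeltaFst:
    def test_constant_tracks(self):
        tb = _track([0.4] * 9)
        ta = _track([0.1] * 9)
        windows = window_delta_fst(tb, ta)
        assert len(windows) == 5
        assert all(w.mean_delta_fst == pytest.approx(0.3) for w in windows)

    def test_self_contrast_is_zero(self, rng):
        vals = rng.uniform(0, 1, 20)
        windows = window_delta_fst(_track(vals), _track(vals))
        assert all(w.mean_delta_fst == 0.0 for w in windows)

    def test_toy_window_mean_and_top_marker(self):
        tb = _track([0.1, 0.5, 0.2, 0.3, 0.4])
        ta = _track([0.0] * 5)
        (w,) = window_delta_fst(tb, ta)
        assert w.mean_delta_fst == pytest.approx(0.3)
        assert w.top_marker_id == "m1"
        assert w.top_marker_delta_fst == pytest.approx(0.5)

    def test_windows_never_span_chromosomes(self):
        chrom = np.array(["1"] * 6 + ["2"] * 6)
        tb = _track([0.2] * 12, chrom=chrom)
        ta = _track([0.1] * 12, chrom=chrom)
        windows = window_delta_fst(tb, ta)
        assert len(windows) == 4  # 2 per 6-marker chromosome
        assert all(len(set(w.marker_ids) & set(f"m{j}" for j in range(6))) in
                   (0, 5) for w in windows)

    def test_short_chromosome_yields_no_windows(self):
        windows = window_delta_fst(_track([0.5] * 3), _track([0.1] * 3))
        assert windows == []

    def test_top_marker_delta_at_least_window_mean(self, rng):
        tb = _track(rng.uniform(0, 1, 50))
        ta = _track(rng.uniform(0, 1, 50))
        for w in window_delta_fst(tb, ta):
            assert w.top_marker_delta_fst >= w.mean_delta_fst - 1e-12

    def test_delta_bounded_by_unit_interval(self, rng):
        tb = _track(rng.uniform(0, 1, 100))
        ta = _track(rng.uniform(0, 1, 100))
        for w in window_delta_fst(tb, ta):
            assert -1.0 <= w.mean_delta_fst <= 1.0

    def test_mismatched_tracks_rejected(self):
        with pytest.raises(ValueError):
            window_delta_fst(_track([0.1] * 6), _track([0.1] * 5))


def _window(chrom, start, mean, end=None):
    return WindowScore(
        chromosome=chrom,
        marker_ids=tuple(f"w{start}_{k}" for k in range(5)),
        start_bp=start,
        end_bp=end if end is not None else start + 4000,
        mean_delta_fst=mean,
        top_marker_id=f"w{start}_0",
        top_marker_delta_fst=mean,
    )


def greedy_reference(windows, n_top, prune_bp):
    """Brute-force restatement of the selection rule, kept independent."""
    chosen = []
    for w in sorted(windows, key=lambda w: (-w.mean_delta_fst, w.chromosome,
                                            w.start_bp)):
        if len(chosen) == n_top:
            break
        ok = True
        for s in chosen:
            if s.chromosome != w.chromosome:
                continue
            gap = max(s.start_bp - w.end_bp, w.start_bp - s.end_bp)
            if gap <= prune_bp:
                ok = False
        if ok:
            chosen.append(w)
    return chosen


class TestSelectTopWindows:
    def test_single_window(self):
        w = _window("1", 1000, 0.4)
        assert select_top_windows([w]) == [w]

    def test_overlapping_windows_keep_highest(self):
        w1 = _window("1", 1000, 0.30)
        w2 = _window("1", 2000, 0.28)
        assert select_top_windows([w1, w2]) == [w1]

    def test_implanted_cluster_contributes_one_window(self, rng):
        windows = []
        for chrom in "123":
            for k in range(6):
                windows.append(
                    _window(chrom, 100_000 + k * 300_000,
                            float(rng.uniform(0, 0.1)))
                )
        # high-delta cluster of overlapping windows on chromosome 2
        cluster = [_window("2", 5_000_000 + k * 1000, 0.5 + 0.01 * k)
                   for k in range(4)]
        selected = select_top_windows(windows + cluster, n_top=5)
        in_cluster = [w for w in selected if w in cluster]
        assert len(in_cluster) == 1
        assert in_cluster[0].mean_delta_fst == pytest.approx(0.53)

    def test_matches_brute_force_reference(self, rng):
        windows = [
            _window(str(rng.integers(1, 4)), int(rng.integers(0, 20) * 500_000),
                    float(rng.uniform(-0.2, 0.6)))
            for _ in range(20)
        ]
        mine = select_top_windows(windows, n_top=5, prune_distance_bp=1_000_000)
        ref = greedy_reference(windows, 5, 1_000_000)
        assert mine == ref

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_top_windows([])


class TestPairwiseFstTrack:
    def test_tracks_from_panel_are_symmetric_in_pair(self, rng):
        calls = rng.binomial(2, rng.uniform(0.1, 0.9, 30), (20, 30))
        panel = make_panel(calls, breeds=["b1"] * 10 + ["b2"] * 10)
        freqs = breed_allele_frequencies(panel)
        t12 = pairwise_fst(freqs, ("b1", "b2"))
        t21 = pairwise_fst(freqs, ("b2", "b1"))
        assert np.allclose(t12.fst, t21.fst)

    def test_monomorphic_marker_scores_zero(self):
        calls = np.zeros((10, 2), dtype=int)
        calls[:5, 1] = 2  # marker 1 differentiates the breeds
        panel = make_panel(calls, breeds=["b1"] * 5 + ["b2"] * 5)
        track = pairwise_fst(breed_allele_frequencies(panel), ("b1", "b2"))
        assert track.fst[0] == 0.0
        assert track.fst[1] == 1.0
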