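"""Anchor profiles, NDR/POS scores, phasing FFT, smoothing, comparisons."""

import numpy as np
import pandas as pd
import pytest

from nucleotune import profiles
from nucleotune.fragments import AnchorSet, SignalTrack
from nucleotune.profiles import (
    AverageProfile,
    anchor_profile,
    bh_adjust,
    compare_profiles,
    ndr_score,
    normalize_profile,
    phasing_fft,
    pos_score,
    smooth_profile,
)

import _oracles


def _profile(values, upstream=2000, downstream=2000, resolution=10):
    return AverageProfile(values=np.asarray(values, float), upstream=upstream,
                          downstream=downstream, resolution=resolution)


def _anchors(rows, kind="TSS"):
    return AnchorSet(pd.DataFrame(rows, columns=AnchorSet._COLS), kind=kind)


class TestAnchorProfile:
    def test_delta_signal_maps_to_relative_position(self):
        v = np.zeros(100_000)
        v[5100:5110] = 3.0
        track = SignalTrack(values={"chr1": v})
        anchors = _anchors([("chr1", 5000, "+", "a", 0.0)])
        prof = anchor_profile(track, anchors, window=(2000, 2000))
        pos = prof.positions()
        assert prof.values[pos.tolist().index(100)] == pytest.approx(3.0)
        assert prof.values.sum() == pytest.approx(3.0)

    def test_strand_flip_mirrors(self):
        v = np.zeros(100_000)
        v[5100:5110] = 2.0   # +100 for a plus anchor at 5000
        v[19890:19900] = 2.0  # +100 for a minus anchor at 20000
        track = SignalTrack(values={"chr1": v})
        both = _anchors([("chr1", 5000, "+", "a", 0.0),
                         ("chr1", 20000, "-", "b", 0.0)])
        prof = anchor_profile(track, both, window=(2000, 2000))
        single = anchor_profile(track, _anchors([("chr1", 5000, "+", "a", 0.0)]),
                                window=(2000, 2000))
        np.testing.assert_allclose(prof.values, single.values)

    def test_mean_equals_bruteforce(self):
        rng = np.random.default_rng(6)
        v = rng.gamma(2, 1, size=50_000)
        track = SignalTrack(values={"chr1": v})
        positions = [5000, 9000, 21000]
        anchors = _anchors([("chr1", p, "+", f"a{p}", 0.0) for p in positions])
        prof = anchor_profile(track, anchors, window=(1000, 1000), resolution=10)
        manual = np.mean([v[p - 1000:p + 1000].reshape(-1, 10).mean(axis=1)
                          for p in positions], axis=0)
        np.testing.assert_allclose(prof.values, manual)

    def test_out_of_bounds_anchors_dropped(self):
        track = SignalTrack(values={"chr1": np.ones(5000)})
        anchors = _anchors([("chr1", 100, "+", "edge", 0.0),
                            ("chr1", 2500, "+", "mid", 0.0)])
        prof = anchor_profile(track, anchors, window=(2000, 2000))
        assert prof.n_anchors == 1
        with pytest.raises(ValueError, match="zero usable"):
            anchor_profile(track, _anchors([("chr1", 10, "+", "x", 0.0)]),
                           window=(2000, 2000))

    def test_motif_top_k_truncation(self):
        track = SignalTrack(values={"chr1": np.ones(100_000)})
        rows = [("chr1", 5000 + 3000 * i, "+", f"s{i}", float(i))
                for i in range(20)]
        anchors = _anchors(rows, kind="motif_center")
        prof = anchor_profile(track, anchors, window=(1000, 1000), top_k=5)
        assert prof.n_anchors == 5


class TestNormalizeProfile:
    def test_flat_profile_at_sample_mean_becomes_ones(self):
        prof = _profile(np.full(400, 3.5))
        out = normalize_profile(prof, 3.5)
        np.testing.assert_allclose(out.values, 1.0)
        assert out.normalized_by_mean

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        v = rng.gamma(2, 1, 400)
        a = normalize_profile(_profile(v), 2.0)
        b = normalize_profile(_profile(5 * v), 10.0)
        np.testing.assert_allclose(a.values, b.values)

    def test_zero_mean_errors(self):
        with pytest.raises(ValueError):
            normalize_profile(_profile(np.ones(400)), 0.0)


class TestNdrScore:
    def test_hand_constructed_depleted_profile(self):
        """max(+1)=10, max(-1)=8, center=2, range 10-1 -> 0.8889."""
        v = np.ones(400)
        pos = np.arange(-2000, 2000, 10)
        v[(pos >= 50) & (pos < 250)] = 5.0
        v[pos.tolist().index(100)] = 10.0
        v[(pos >= -250) & (pos < -50)] = 8.0
        v[(pos >= -50) & (pos < 50)] = 2.0
        assert ndr_score(_profile(v)) == pytest.approx((10 - 2) / 9)

    def test_flat_profile_is_zero(self):
        assert ndr_score(_profile(np.full(400, 2.0))) == 0.0

    def test_occupied_center_is_negative(self):
        v = np.ones(400)
        pos = np.arange(-2000, 2000, 10)
        v[(pos >= -50) & (pos < 50)] = 10.0
        v[(pos >= 50) & (pos < 250)] = 2.0
        v[(pos >= -250) & (pos < -50)] = 2.0
        assert ndr_score(_profile(v)) == pytest.approx((2 - 10) / 9)

    def test_window_too_small_errors(self):
        with pytest.raises(ValueError):
            ndr_score(_profile(np.ones(40), upstream=200, downstream=200))


class TestPosScore:
    def test_cosine_equals_lagged_cosine_similarity(self):
        """POS of a 200-bp cosine ~ cos(2*pi*10/200) = 0.951."""
        pos = np.arange(-2000, 2000, 10)
        v = np.cos(2 * np.pi * pos / 200.0)
        assert pos_score(_profile(v + 2)) == pytest.approx(
            np.cos(2 * np.pi * 10 / 200), abs=0.01)

    def test_constant_profile_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert pos_score(_profile(np.ones(400))) == 0.0

    def test_white_noise_baseline_below_phased_cosine(self):
        """The 10-bp lag makes adjacent 50-bp bins share 4/5 of their
        points, so even white noise correlates at ~0.8; a phased array must
        still clearly exceed that baseline."""
        rng = np.random.default_rng(12)
        vals = [pos_score(_profile(rng.normal(5, 1, 400))) for _ in range(100)]
        assert np.mean(vals) == pytest.approx(0.8, abs=0.05)
        pos = np.arange(-2000, 2000, 10)
        cosine = pos_score(_profile(2 + np.cos(2 * np.pi * pos / 200)))
        assert cosine > np.max(vals)

    def test_insufficient_downstream_errors(self):
        prof = _profile(np.ones(200), upstream=1000, downstream=1000)
        with pytest.raises(ValueError):
            pos_score(prof)


class TestScoreInvariants:
    def test_scores_match_oracles_on_random_profiles(self):
        rng = np.random.default_rng(42)
        pos = np.arange(-2000, 2000, 10)
        for _ in range(100):
            v = _oracles.random_profile(rng)
            prof = _profile(v)
            assert ndr_score(prof) == pytest.approx(
                _oracles.oracle_ndr(pos, v), abs=1e-12)
            assert pos_score(prof) == pytest.approx(
                _oracles.oracle_pos(pos, v), abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            v = _oracles.random_profile(rng)
            a = float(rng.uniform(0.1, 10))
            b = float(rng.uniform(0, 5))
            p1, p2 = _profile(v), _profile(a * v + b)
            assert ndr_score(p1) == pytest.approx(ndr_score(p2), abs=1e-9)
            assert pos_score(p1) == pytest.approx(pos_score(p2), abs=1e-9)

    def test_scores_bounded(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            v = _oracles.random_profile(rng)
            prof = _profile(v)
            assert -1.0 <= ndr_score(prof) <= 1.0
            assert -1.0 <= pos_score(prof) <= 1.0


class TestPhasingFFT:
    @pytest.mark.parametrize("period", [180, 200, 220])
    def test_pure_cosine_period_recovered(self, period):
        pos = np.arange(-2000, 2000, 10)
        amp = 3.0
        v = 5 + amp * np.cos(2 * np.pi * pos / period)
        got_p, got_i = phasing_fft(_profile(v))
        freq_bin = 4000 / np.floor(4000 / period)
        prev_bin = 4000 / (np.floor(4000 / period) + 1)
        assert prev_bin - 1 <= got_p <= freq_bin + 1
        # intensity approximates half the cosine amplitude (leakage aside)
        assert got_i == pytest.approx(amp / 2, rel=0.15)

    def test_flat_profile(self):
        p, i = phasing_fft(_profile(np.full(400, 2.0)))
        assert np.isnan(p) and i == 0.0

    def test_noisy_cosine_period_190(self):
        rng = np.random.default_rng(3)
        pos = np.arange(-2000, 2000, 10)
        hits = 0
        for _ in range(100):
            v = np.cos(2 * np.pi * pos / 190) + rng.normal(0, 0.2, len(pos))
            p, _ = phasing_fft(_profile(v))
            hits += abs(p - 190) <= 15
        assert hits >= 95

    def test_matches_explicit_dft(self):
        rng = np.random.default_rng(21)
        v = _oracles.random_profile(rng, upstream=500, downstream=500)
        got = phasing_fft(_profile(v, upstream=500, downstream=500))
        ref = _oracles.oracle_dft_peak(list(v), 10, (120, 300))
        assert got[0] == pytest.approx(ref[0])
        assert got[1] == pytest.approx(ref[1], abs=1e-9)

    def test_empty_band_errors(self):
        with pytest.raises(ValueError):
            phasing_fft(_profile(np.arange(400.0)), period_band=(1, 2))


class TestSmoothing:
    def test_polynomial_fidelity(self):
        pos = np.arange(-2000, 2000, 10).astype(float)
        v = 1e-6 * pos ** 2 + 1.0
        out = smooth_profile(_profile(v))
        assert np.max(np.abs(out.values - v)) < 0.01 * (v.max() - v.min())

    def test_mean_preserved(self):
        rng = np.random.default_rng(2)
        v = _oracles.random_profile(rng)
        out = smooth_profile(_profile(v))
        assert out.values.mean() == pytest.approx(v.mean(), rel=0.01)

    def test_large_stiffness_approaches_line(self):
        rng = np.random.default_rng(5)
        v = _oracles.random_profile(rng)
        out = smooth_profile(_profile(v), stiffness=1e18)
        x = np.arange(len(v), dtype=float)
        resid = out.values - np.polyval(np.polyfit(x, out.values, 1), x)
        assert np.max(np.abs(resid)) < 1e-2 * (v.max() - v.min())


class TestComparisons:
    def test_identical_groups(self):
        v = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        delta, p = compare_profiles(v, v)
        assert delta == 0.0
        assert p >= 0.5

    def test_fully_separated_exact_tail(self):
        a = np.arange(10, 20, dtype=float)
        b = np.arange(0, 10, dtype=float)
        _, p = compare_profiles(a, b, alternative="greater", method="exact")
        from math import comb
        assert p == pytest.approx(1 / comb(20, 10), rel=1e-6)

    def test_bh_stepup_by_hand(self):
        adj = bh_adjust([0.01, 0.02, 0.04])
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.04])
        rng = np.random.default_rng(13)
        ps = rng.uniform(0, 1, 25)
        np.testing.assert_allclose(bh_adjust(ps), _oracles.oracle_bh(list(ps)),
                                   atol=1e-12)

    def test_small_groups_error(self):
        with pytest.raises(ValueError):
            compare_profiles([1.0, 2.0], [1.0, 2.0, 3.0])


class TestPlantedProfileRecovery:
    def test_planted_ndr_depths_are_ordered(self, default_fixture,
                                            final_stage_track):
        track = final_stage_track
        scores = []
        for depth in default_fixture.spec.ndr_depths:
            prof = anchor_profile(track, default_fixture.tss_subset(depth))
            prof = normalize_profile(prof, track.mean())
            scores.append(ndr_score(prof))
        assert scores == sorted(scores)
        assert scores[0] < scores[-1]

    def test_planted_repeat_length_recovered(self, default_fixture,
                                             final_stage_track):
        prof = anchor_profile(final_stage_track, default_fixture.tss)
        period, intensity = phasing_fft(prof)
        planted = default_fixture.spec.repeat_length
        assert abs(period - planted) <= 4000 / 20 - 4000 / 21 + 0.5
        assert intensity > 0

    def test_zga_genes_score_higher(self, default_fixture, final_stage_track):
        """Deep-NDR (ZGA-like) promoters beat depth-0 promoters significantly."""
        track = final_stage_track
        zga = profiles.per_anchor_scores(track, default_fixture.tss_subset(0.6))
        flat = profiles.per_anchor_scores(track, default_fixture.tss_subset(0.0))
        delta, p = compare_profiles(zga, flat, alternative="greater")
        assert delta > 0
        assert p < 0.05
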