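"""Chung-Kennedy filtering, molecular brightness, stoichiometry, bleach decay."""

import numpy as np
import pytest

import spottrack as sp
from conftest import make_track


class TestChungKennedy:
    def test_constant_series_unchanged(self):
        x = np.full(30, 5.0)
        np.testing.assert_allclose(sp.chung_kennedy(x), x)

    def test_noiseless_step_preserved(self):
        x = np.concatenate([np.full(20, 100.0), np.full(20, 40.0)])
        y = sp.chung_kennedy(x, window=10)
        np.testing.assert_allclose(y, x, atol=1e-6)

    def test_variance_reduction_on_flat_noise(self, rng):
        x = rng.normal(50, 5, size=500)
        y = sp.chung_kennedy(x, window=10)
        assert y.var() <= x.var() / 2

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            sp.chung_kennedy([1.0])


class TestCharacteristicBrightness:
    def _decay_track(self, track_id, k, b, rng, n=25, noise=4.0):
        """k-mer bleaching to a terminal single-fluorophore plateau at b."""
        levels = np.maximum(k - rng.poisson(0.35, size=n).cumsum(), 1)
        intensities = levels * b + rng.normal(0, noise, size=n)
        pos = np.tile([20.0, 20.0], (n, 1))
        return make_track(track_id, positions=pos, intensities=intensities)

    def test_exact_terminal_levels(self):
        tracks = [make_track(i, positions=np.tile([10, 10], (12, 1)),
                             intensities=np.linspace(300, 100, 12))
                  for i in range(12)]
        est = sp.estimate_characteristic_brightness(tracks)
        assert est.brightness == pytest.approx(100.0, abs=2.0)

    def test_mode_picks_majority_level(self, rng):
        tracks = []
        for i in range(100):
            level = 200.0 if i % 11 == 0 else 100.0  # ~10:1 abundance
            vals = np.full(15, level) + rng.normal(0, 3, 15)
            tracks.append(make_track(i, positions=np.tile([10, 10], (15, 1)),
                                     intensities=vals))
        est = sp.estimate_characteristic_brightness(tracks)
        # brute-force histogram oracle over the same terminal levels
        terms = [sp.terminal_intensity(t) for t in tracks]
        counts, edges = np.histogram(terms, bins=np.arange(50, 300, 10))
        oracle = (edges[:-1] + edges[1:])[np.argmax(counts)] / 2
        assert est.brightness == pytest.approx(100.0, abs=10.0)
        assert est.brightness == pytest.approx(oracle, abs=10.0)

    def test_simulated_singles_recovery(self, rng):
        b_true = 76.0
        tracks = [self._decay_track(i, 1, b_true, rng, noise=6.0)
                  for i in range(80)]
        est = sp.estimate_characteristic_brightness(tracks)
        assert est.brightness == pytest.approx(b_true, rel=0.10)
        assert est.se > 0

    def test_brightness_unbiased_across_seeds(self):
        b_true = 76.0
        errs, ses = [], []
        for seed in range(5):
            r = np.random.default_rng(seed)
            tracks = [self._decay_track(i, r.integers(1, 4), b_true, r)
                      for i in range(60)]
            est = sp.estimate_characteristic_brightness(tracks, rng=r)
            errs.append(est.brightness - b_true)
            ses.append(est.se)
        assert abs(np.mean(errs)) < 2 * np.mean(ses)

    def test_too_few_tracks_advises_pooling(self):
        tracks = [make_track(i, positions=np.tile([10, 10], (5, 1)))
                  for i in range(3)]
        with pytest.raises(ValueError, match="pool"):
            sp.estimate_characteristic_brightness(tracks)


class TestInitialIntensity:
    def test_constant_track(self):
        t = make_track(0, positions=np.tile([10, 10], (6, 1)),
                       intensities=np.full(6, 240.0))
        assert sp.initial_track_intensity(t) == pytest.approx(240.0)

    def test_linear_vs_exponential_backprojection(self):
        tau = 120.0  # frames, >> the 5-frame window
        frames = np.arange(2, 10)
        vals = 500.0 * np.exp(-frames / tau)
        t = make_track(0, positions=np.tile([10, 10], (8, 1)),
                       intensities=vals, frames=frames)
        i0 = sp.initial_track_intensity(t)
        assert i0 == pytest.approx(500.0, rel=0.05)

    def test_exponential_backprojection_exact_on_exponential(self):
        tau = 25.0
        frames = np.arange(3, 11)
        vals = 400.0 * np.exp(-frames / tau)
        t = make_track(0, positions=np.tile([10, 10], (8, 1)),
                       intensities=vals, frames=frames)
        i0 = sp.initial_track_intensity(t, method="exponential",
                                        decay_tau_frames=tau)
        assert i0 == pytest.approx(400.0, rel=1e-9)

    def test_positive_slope_falls_back_to_mean(self):
        vals = np.array([100.0, 110.0, 120.0, 130.0])
        t = make_track(0, positions=np.tile([10, 10], (4, 1)), intensities=vals)
        assert sp.initial_track_intensity(t) == pytest.approx(vals.mean())

    def test_short_track_rejected(self):
        t = make_track(0, positions=np.tile([10, 10], (2, 1)))
        with pytest.raises(ValueError):
            sp.initial_track_intensity(t)


class TestStoichiometry:
    def test_unit_ratio(self):
        t = make_track(0, positions=np.tile([10, 10], (5, 1)),
                       intensities=np.full(5, 76.0))
        assert sp.stoichiometry(t, 76.0) == pytest.approx(1.0)

    def test_gain_invariance(self):
        vals = np.array([800.0, 760.0, 720.0, 680.0, 640.0])
        for gain in (1.0, 0.6, 2.7):
            t = make_track(0, positions=np.tile([10, 10], (5, 1)),
                           intensities=vals * gain)
            assert sp.stoichiometry(t, 100.0 * gain) == pytest.approx(
                sp.stoichiometry(make_track(0, positions=np.tile([10, 10], (5, 1)),
                                            intensities=vals), 100.0))

    def test_late_start_flagged(self):
        t = make_track(0, positions=np.tile([10, 10], (5, 1)),
                       intensities=np.full(5, 76.0), frames=np.arange(30, 35))
        sp.stoichiometry(t, 76.0, decay_time_frames=40.0)
        assert "late_start" in t.flags

    def test_invalid_brightness(self):
        t = make_track(0, positions=np.tile([10, 10], (5, 1)))
        with pytest.raises(ValueError):
            sp.stoichiometry(t, 0.0)

    def test_simulated_dimer_mode(self, rng):
        b = 100.0
        svals = []
        for i in range(300):
            # two fluorophores, occasional early bleach of one
            start = 2 * b if rng.random() > 0.15 else b
            decay = start * np.exp(-np.arange(8) / 30.0)
            t = make_track(i, positions=np.tile([10, 10], (8, 1)),
                           intensities=decay + rng.normal(0, 5, 8))
            svals.append(sp.stoichiometry(t, b))
        counts, edges = np.histogram(svals, bins=np.arange(0.25, 4, 0.5))
        mode = (edges[:-1] + edges[1:])[np.argmax(counts)] / 2
        assert mode == pytest.approx(2.0, abs=0.3)


class TestPhotobleachDecayTime:
    def test_exact_exponential(self):
        t = np.arange(200)
        y = 1000.0 * np.exp(-t / 20.0) + 50.0
        assert sp.photobleach_decay_time(y) == pytest.approx(20.0, abs=0.1)

    def test_matches_bleach_probability(self, rng):
        p_b = 0.05
        n_fluor = 20000
        bf = rng.geometric(p_b, size=n_fluor)
        frames = np.arange(80)
        y = np.array([(bf > t).sum() * 76.0 for t in frames])
        tau = sp.photobleach_decay_time(y)
        assert tau == pytest.approx(-1.0 / np.log(1 - p_b), rel=0.10)

    def test_returns_ms_when_interval_given(self):
        y = 500.0 * np.exp(-np.arange(100) / 10.0)
        tau_frames, tau_ms = sp.photobleach_decay_time(y, frame_interval_ms=10.0)
        assert tau_ms == pytest.approx(tau_frames * 10.0)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            sp.photobleach_decay_time(np.full(50, 10.0))
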