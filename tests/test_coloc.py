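"""Two-colour registration, overlap events and random-coincidence statistics."""

import numpy as np
import pytest

import spottrack as sp
from conftest import make_track


class TestRegisterChannels:
    def test_identity(self, rng):
        pts = rng.uniform(0, 100, size=(10, 2))
        tf = sp.register_channels(pts, pts)
        np.testing.assert_allclose(tf.matrix, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(tf.offset, 0.0, atol=1e-7)
        assert tf.residual < 1e-9

    def test_known_similarity_recovered(self, rng):
        pts = rng.uniform(0, 100, size=(12, 2))
        theta, scale, shift = 0.05, 1.02, np.array([3.1, -1.7])
        rot = scale * np.array([[np.cos(theta), -np.sin(theta)],
                                [np.sin(theta), np.cos(theta)]])
        mapped = pts @ rot.T + shift
        tf = sp.register_channels(pts, mapped)
        assert tf.residual < 0.05
        np.testing.assert_allclose(tf.apply(pts), mapped, atol=1e-6)

    def test_noisy_beads_residual_scale(self, rng):
        pts = rng.uniform(0, 100, size=(40, 2))
        noisy = pts + rng.normal(0, 0.1, size=pts.shape)
        tf = sp.register_channels(pts, noisy)
        assert 0.03 < tf.residual < 0.2

    def test_collinear_or_few_rejected(self):
        line = np.column_stack([np.arange(5.0), np.arange(5.0)])
        with pytest.raises(ValueError):
            sp.register_channels(line, line)
        with pytest.raises(ValueError):
            sp.register_channels(line[:2], line[:2])


class TestSelectLocusCandidates:
    def _track(self, i, d, s, i0):
        t = make_track(i, positions=np.tile([10, 10], (4, 1)))
        t.diffusivity, t.stoichiometry, t.initial_intensity = d, s, i0
        return t

    def test_eight_brightest_kept(self, rng):
        tracks = [self._track(i, 0.1, 20, i0) for i, i0 in
                  enumerate(rng.uniform(100, 1000, size=10))]
        kept = sp.select_locus_candidates(tracks, d_max=0.2, s_min=12)
        assert len(kept) == 8
        i0s = sorted((t.initial_intensity for t in tracks), reverse=True)[:8]
        assert sorted(t.initial_intensity for t in kept) == sorted(i0s)

    def test_none_qualifying(self):
        tracks = [self._track(0, 0.5, 20, 100), self._track(1, 0.1, 5, 100)]
        assert sp.select_locus_candidates(tracks, 0.2, 12) == []

    def test_matches_brute_force_oracle(self, rng):
        tracks = [self._track(i, rng.uniform(0, 0.5), rng.uniform(0, 30),
                              rng.uniform(10, 1000)) for i in range(40)]
        kept = sp.select_locus_candidates(tracks, 0.2, 12, k_brightest=8)
        oracle = sorted((t for t in tracks
                         if t.diffusivity <= 0.2 and t.stoichiometry > 12),
                        key=lambda t: -t.initial_intensity)[:8]
        assert [t.id for t in kept] == [t.id for t in oracle]


class TestOverlapFraction:
    def test_coincident_unity(self):
        a = make_track(0, positions=[[10, 10]]).foci[0]
        assert sp.overlap_fraction(a, a) == pytest.approx(1.0)

    def test_half_overlap_near_three_pixels(self):
        from conftest import make_focus
        a = make_focus(0, 10.0, 10.0, sigma=1.6)
        b = make_focus(0, 13.0, 10.0, sigma=1.6)
        # at sigma 1.6 px, 50% overlap corresponds to ~2.7 px separation
        assert sp.overlap_fraction(a, b) == pytest.approx(0.5, abs=0.1)

    def test_symmetry(self):
        from conftest import make_focus
        a = make_focus(0, 10.0, 11.0, sigma=1.2)
        b = make_focus(0, 12.5, 10.0, sigma=1.9)
        assert sp.overlap_fraction(a, b) == sp.overlap_fraction(b, a)


class TestColocalise:
    def test_identical_tracks_full_span_event(self):
        pos = np.column_stack([np.linspace(10, 14, 6), np.full(6, 20.0)])
        a = make_track(0, positions=pos)
        b = make_track(1, positions=pos)
        events = sp.colocalise([a], [b], sp.ColocParams(frame_interval=20.0))
        assert len(events) == 1
        e = events[0]
        assert e.mean_overlap == pytest.approx(1.0)
        assert e.n_frames == 6
        assert e.residence_time_ms == pytest.approx(6 * 20.0)

    def test_two_frame_coincidence_rejected(self):
        a = make_track(0, positions=np.tile([10, 10], (2, 1)))
        b = make_track(1, positions=np.tile([10, 10], (2, 1)))
        assert sp.colocalise([a], [b]) == []

    def test_distance_gate(self):
        pos_a = np.tile([10.0, 10.0], (5, 1))
        pos_b = np.tile([19.0, 10.0], (5, 1))  # 9 px > 7 px gate
        events = sp.colocalise([make_track(0, positions=pos_a)],
                               [make_track(1, positions=pos_b)])
        assert events == []

    def test_interrupted_overlap_splits_runs(self):
        pos_a = np.tile([10.0, 10.0], (9, 1))
        pos_b = pos_a.copy()
        pos_b[4] = [30.0, 30.0]  # breaks the run at frame 4
        events = sp.colocalise([make_track(0, positions=pos_a)],
                               [make_track(1, positions=pos_b)])
        assert len(events) == 2
        assert {e.n_frames for e in events} == {4}

    def test_symmetric_in_channels(self):
        rng = np.random.default_rng(3)
        pos = np.cumsum(rng.normal(0, 0.3, (8, 2)), axis=0) + 20
        a = make_track(0, positions=pos)
        b = make_track(1, positions=pos + rng.normal(0, 0.2, pos.shape))
        e_ab = sp.colocalise([a], [b])
        e_ba = sp.colocalise([b], [a])
        assert len(e_ab) == len(e_ba)
        if e_ab:
            assert e_ab[0].mean_overlap == pytest.approx(e_ba[0].mean_overlap)


class TestRandomCoincidence:
    def test_zero_density(self):
        assert sp.random_coincidence_probability(0.0, 0.35) == 0.0

    def test_first_order_series(self):
        lam, r = 1e-4, 0.35
        p = sp.random_coincidence_probability(lam, r)
        assert p == pytest.approx(lam * np.pi * r ** 2, rel=1e-3)

    def test_monte_carlo_uniform_points(self, rng):
        lam, r = 0.5, 0.35  # per µm², µm
        box = 40.0
        hits = []
        for _ in range(150):
            n = rng.poisson(lam * box * box)
            pts = rng.uniform(0, box, size=(n, 2))
            probe = rng.uniform(r, box - r, size=2)
            d = np.hypot(*(pts - probe).T).min() if n else np.inf
            hits.append(d <= r)
        p_emp = np.mean(hits)
        se = np.sqrt(p_emp * (1 - p_emp) / len(hits))
        expected = sp.random_coincidence_probability(lam, r)
        assert abs(p_emp - expected) < 3 * se + 1e-6

    def test_event_rate_matches_poisson_model(self, rng):
        """Independent static channels coincide at the closed-form rate."""
        box, n_a, n_b, n_frames = 100.0, 40, 40, 3
        px_um = 0.1  # 100 nm pixels
        r_px = 3.0
        hits = trials = 0
        for trial in range(60):
            pa = rng.uniform(10, box - 10, size=(n_a, 2))
            pb = rng.uniform(10, box - 10, size=(n_b, 2))
            ta = [make_track(i, positions=np.tile(p, (n_frames, 1)))
                  for i, p in enumerate(pa)]
            tb = [make_track(i, positions=np.tile(p, (n_frames, 1)))
                  for i, p in enumerate(pb)]
            params = sp.ColocParams(overlap_threshold=
                                    float(np.exp(-r_px ** 2 / (2 * (1.4 ** 2 + 1.4 ** 2)))),
                                    max_distance=r_px, min_frames=3)
            events = sp.colocalise(ta, tb, params)
            hits += len({e.track_a for e in events})
            trials += n_a
        p_emp = hits / trials
        lam = n_b / ((box - 20) * px_um) ** 2
        expected = sp.random_coincidence_probability(lam, r_px * px_um)
        se = np.sqrt(expected * (1 - expected) / trials)
        assert abs(p_emp - expected) < 4 * se + 0.01


class TestPrescanAugmentation:
    def test_blank_prescan_adds_nothing(self):
        live = [make_track(0, positions=np.tile([10, 10], (4, 1)))]
        out = sp.augment_with_prescan(live, [])
        assert len(out) == 1

    def test_new_static_track_appended(self):
        live = [make_track(0, positions=np.tile([10, 10], (4, 1)))]
        static = [make_track(0, positions=np.tile([40, 40], (4, 1)))]
        out = sp.augment_with_prescan(live, static)
        assert len(out) == 2
        assert "prescan" in out[1].flags
        assert out[1].id != out[0].id

    def test_duplicate_deduplicated(self):
        live = [make_track(0, positions=np.tile([10, 10], (4, 1)))]
        dup = [make_track(0, positions=np.tile([10.4, 10.3], (4, 1)))]
        out = sp.augment_with_prescan(live, dup)
        assert len(out) == 1

    def test_prescan_stack_shape(self):
        best = np.ones((32, 32))
        stack = sp.make_prescan_stack(5, best)
        assert stack.shape == (5, 32, 32)
        with pytest.raises(ValueError):
            sp.make_prescan_stack(5, np.ones((2, 32, 32)))


class TestPartitionByStoichiometry:
    def _event(self, a, b, s_b):
        return sp.ColocEvent(track_a=a, track_b=b, start_frame=0, end_frame=3,
                             mean_overlap=0.9, residence_time_ms=40.0,
                             stoichiometry_b=s_b)

    def test_hand_tallied_table(self):
        loci = [make_track(i, positions=np.tile([10, 10], (4, 1)))
                for i in range(5)]
        events = [self._event(0, 100, 10.0), self._event(1, 101, 3.0),
                  self._event(2, 102, 8.0)]
        table = sp.partition_by_stoichiometry(loci, events, s_threshold=6.0)
        np.testing.assert_array_equal(table, [[2, 1], [0, 2]])

    def test_all_colocalised_above_threshold(self):
        loci = [make_track(i, positions=np.tile([10, 10], (4, 1)))
                for i in range(3)]
        events = [self._event(i, 100 + i, 20.0) for i in range(3)]
        table = sp.partition_by_stoichiometry(loci, events, 6.0)
        assert table[0, 1] == 0 and table[1, 0] == 0
        assert table[0, 0] == 3
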