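"""Cropping, projections, flat-field estimation and drift correction."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from smor import preprocess as pre
from smor.preprocess import DriftTrack, FlatFieldError, MovieStack, Projection
from smor.simulate import SimConfig, illumination_profile, render_movie


def stack(frames, dt=0.1):
    return MovieStack(np.asarray(frames, dtype=float), dt)


class TestCrop:
    def test_512_to_300_keeps_central_window(self):
        movie = stack(np.zeros((1, 512, 512)))
        out = pre.crop_center(movie, 300)
        assert out.shape == (1, 300, 300)
        assert out.origin == (106, 106)

    def test_identity_when_size_matches(self):
        movie = stack(np.random.default_rng(0).random((2, 10, 10)))
        out = pre.crop_center(movie, 10)
        assert np.array_equal(out.frames, movie.frames)

    def test_10_to_4_window(self):
        movie = stack(np.arange(100, dtype=float).reshape(1, 10, 10))
        out = pre.crop_center(movie, 4)
        assert out.origin == (3, 3)
        assert np.array_equal(out.frames[0], movie.frames[0, 3:7, 3:7])

    @given(dim=st.integers(4, 64), size=st.integers(1, 64))
    @settings(max_examples=40, deadline=None)
    def test_center_matches_brute_force(self, dim, size):
        """Crop window equals the brute-force centered-window computation."""
        if size > dim:
            return
        movie = stack(np.arange(dim * dim, dtype=float).reshape(1, dim, dim))
        out = pre.crop_center(movie, size)
        # brute force: minimize |left margin - right margin|; on a tie the
        # extra pixel stays on the high-index side (smaller start wins)
        best = min(range(dim - size + 1),
                   key=lambda s: (abs(s - (dim - size - s)), s))
        assert out.origin == (best, best)

    def test_oversized_crop_rejected(self):
        with pytest.raises(ValueError):
            pre.crop_center(stack(np.zeros((1, 8, 8))), 9)


class TestProjections:
    def test_single_frame_projections_equal_frame(self):
        frame = np.random.default_rng(1).random((6, 6))
        movie = stack(frame[None])
        assert np.allclose(pre.project(movie, "max").image, frame)
        assert np.allclose(pre.project(movie, "min").image, frame)

    def test_max_geq_min_pixelwise(self):
        movie = stack(np.random.default_rng(2).random((20, 16, 16)))
        assert np.all(pre.project(movie, "max").image
                      >= pre.project(movie, "min").image)

    def test_crop_and_project_commute(self):
        movie = stack(np.random.default_rng(3).random((5, 12, 12)))
        a = pre.project(pre.crop_center(movie, 6), "max").image
        b = pre.crop_center(
            stack(pre.project(movie, "max").image[None]), 6).frames[0]
        assert np.allclose(a, b)

    def test_stuck_site_appears_in_min_projection(self):
        cfg = SimConfig(image_size=48, n_frames=30, n_sites=1, stuck_fraction=1.0,
                        shot_noise=False, read_noise_sd=0.0, background_rate=0.0,
                        camera_offset=10.0, illumination_sigma=np.inf,
                        tau_bound=1e5, bleach_tau=1e9, multimer_fraction=0.0,
                        edge_margin=15.0, seed=4)
        movie, truth = render_movie(cfg)
        mx = pre.project(movie, "max").image
        mn = pre.project(movie, "min").image
        x, y = truth.positions[0].round().astype(int)
        assert mn[y, x] > 10.0 + 1.0          # PSF present in the minimum
        assert mx[y, x] == pytest.approx(mn[y, x], rel=1e-6)

    def test_transient_site_absent_from_min_projection(self):
        cfg = SimConfig(image_size=48, n_frames=200, n_sites=1, tau_bound=0.3,
                        tau_unbound=3.0, stuck_fraction=0.0, shot_noise=False,
                        read_noise_sd=0.0, background_rate=0.0, camera_offset=10.0,
                        illumination_sigma=np.inf, multimer_fraction=0.0,
                        edge_margin=15.0, seed=5)
        movie, truth = render_movie(cfg)
        mx = pre.project(movie, "max").image
        mn = pre.project(movie, "min").image
        x, y = truth.positions[0].round().astype(int)
        assert mx[y, x] > 10.0 + 5.0
        assert mn[y, x] == pytest.approx(10.0, abs=0.5)


def synthetic_carpet_projection(size=300, spacing=5, amp=200.0, sigma_illum=150.0):
    """Centered Gaussian illumination times a dense carpet of equal spots."""
    illum = illumination_profile(size, sigma_illum)
    spots = np.zeros((size, size))
    spots[2::spacing, 2::spacing] = amp
    from scipy.ndimage import gaussian_filter

    spots = gaussian_filter(spots, 1.0, mode="constant")
    return Projection("max", spots * illum), illum


class TestFlatField:
    def test_uniform_projection_gives_unit_filter(self):
        filt = pre.build_flatfield(Projection("max", np.full((60, 60), 7.0)))
        assert np.allclose(filt.filter_image, 1.0)

    def test_known_illumination_recovered_within_5_percent(self):
        proj, illum = synthetic_carpet_projection()
        filt = pre.build_flatfield(proj, bin_size=20)
        mask = proj.image > pre.signal_mask_threshold(proj.image)
        ratio = filt.filter_image / (illum / illum.mean())
        rms = np.sqrt(np.mean((ratio[mask] - 1.0) ** 2))
        assert rms < 0.05

    def test_filter_has_unit_mean(self):
        proj, _ = synthetic_carpet_projection()
        filt = pre.build_flatfield(proj)
        assert filt.filter_image.mean() == pytest.approx(1.0, abs=1e-9)
        assert np.all(filt.filter_image > 0)

    def test_bin_grid_shape(self):
        """A 300 px image on a 20 px grid yields a 15 x 15 bin image."""
        img = np.random.default_rng(6).random((300, 300)) + 1.0
        bins = pre.bin_means(img, 20)
        assert bins.shape == (15, 15)

    def test_identity_filter_is_identity(self):
        movie = stack(np.random.default_rng(7).random((3, 40, 40)) + 5.0)
        filt = pre.FlatFieldFilter(np.ones((40, 40)), 20, 10.0, 0.0)
        out = pre.apply_flatfield(movie, filt)
        assert np.allclose(out.frames, movie.frames)

    def test_offset_is_not_warped_by_correction(self):
        """The camera offset is subtracted before dividing and re-added."""
        field = np.linspace(0.5, 1.5, 40)[None, :] * np.ones((40, 1))
        field /= field.mean()
        frames = 100.0 + 50.0 * field[None]
        movie = stack(frames)
        filt = pre.FlatFieldFilter(field, 20, 10.0, 0.0)
        out = pre.apply_flatfield(movie, filt, camera_offset=100.0)
        assert np.allclose(out.frames, 150.0, rtol=1e-6)

    def test_correction_preserves_spatial_mean_within_1_percent(self):
        proj, illum = synthetic_carpet_projection(size=100, spacing=5)
        movie = stack(np.tile(proj.image[None], (3, 1, 1)) + 10.0)
        filt = pre.build_flatfield(pre.project(movie, "max"), bin_size=20)
        out = pre.apply_flatfield(movie, filt)
        for f in range(3):
            assert out.frames[f].mean() == pytest.approx(
                movie.frames[f].mean(), rel=0.01)

    def test_blank_image_raises_explicit_error(self):
        noise = np.random.default_rng(8).normal(0.0, 1e-12, (40, 40)) + 5.0
        with pytest.raises(FlatFieldError, match="spots"):
            pre.build_flatfield(Projection("max", noise))

    def test_shape_mismatch_rejected(self):
        movie = stack(np.zeros((2, 10, 10)))
        filt = pre.FlatFieldFilter(np.ones((8, 8)), 4, 2.0, 0.0)
        with pytest.raises(ValueError):
            pre.apply_flatfield(movie, filt)


class TestDrift:
    def test_zero_drift_movie_yields_null_track(self):
        cfg = SimConfig(image_size=128, n_frames=200, n_sites=40, tau_bound=2.0,
                        tau_unbound=6.0, min_separation=5.0,
                        multimer_fraction=0.0, stuck_fraction=0.0, seed=9)
        movie, _ = render_movie(cfg)
        track = pre.estimate_drift(movie, segment_len=50)
        assert np.abs(track.offsets).max() < 0.2

    def test_linear_drift_recovered(self):
        cfg = SimConfig(image_size=200, n_frames=1000, n_sites=60, tau_bound=2.0,
                        tau_unbound=6.0, drift_velocity=(0.02, 0.0),
                        multimer_fraction=0.0, stuck_fraction=0.0,
                        edge_margin=25.0, seed=10)
        movie, truth = render_movie(cfg)
        track = pre.estimate_drift(movie, segment_len=50)
        assert abs(track.offsets[-1, 0] - truth.drift_track[-1, 0]) < 0.5
        assert abs(track.offsets[-1, 1]) < 0.5

    def test_pure_noise_movie_warns_and_returns_zero(self):
        movie = stack(np.full((120, 32, 32), 5.0))
        with pytest.warns(UserWarning, match="featureless"):
            track = pre.estimate_drift(movie, segment_len=50)
        assert np.all(track.offsets == 0.0)

    def test_zero_track_is_identity(self):
        movie = stack(np.random.default_rng(11).random((4, 16, 16)))
        track = DriftTrack(np.zeros((4, 2)))
        out = pre.apply_drift(movie, track)
        assert np.array_equal(out.frames, movie.frames)

    def test_shift_unshift_round_trip(self):
        """Shifting a smooth frame and shifting it back is near-lossless."""
        cfg = SimConfig(image_size=64, n_frames=2, n_sites=4, stuck_fraction=1.0,
                        tau_bound=1e5, bleach_tau=1e9, shot_noise=False,
                        read_noise_sd=0.0, background_rate=0.0, camera_offset=0.0,
                        illumination_sigma=np.inf, monomer_amplitude=500.0,
                        multimer_fraction=0.0, edge_margin=20.0, seed=12)
        movie, _ = render_movie(cfg)
        d = np.array([[0.0, 0.0], [1.3, -0.7]])
        shifted = pre.apply_drift(movie, DriftTrack(-d))     # impose drift
        restored = pre.apply_drift(shifted, DriftTrack(d))   # correct it
        interior = (slice(None), slice(5, -5), slice(5, -5))
        peak = movie.frames.max()
        err = np.abs(restored.frames[interior] - movie.frames[interior]).max()
        assert err < 0.01 * peak

    def test_track_length_mismatch_rejected(self):
        movie = stack(np.zeros((4, 8, 8)))
        with pytest.raises(ValueError):
            pre.apply_drift(movie, DriftTrack(np.zeros((3, 2))))

    def test_track_must_start_at_zero(self):
        with pytest.raises(ValueError):
            DriftTrack(np.ones((5, 2)))
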