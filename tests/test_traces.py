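"""Trace extraction, pooled double-Gaussian emission model, HMM idealization."""

import itertools
import warnings

import numpy as np
import pytest

from smor import traces as tr
from smor.preprocess import MovieStack
from smor.peaks import Peak
from smor.simulate import BOUND, occupancy_per_frame, sample_state_trajectory
from smor.traces import DegenerateFitError, IntensityModel, Trace
from conftest import nearest_site
from oracle_helpers import make_trace, path_log_prob


class TestExtract:
    def test_constant_movie_gives_constant_trace(self):
        movie = MovieStack(np.full((7, 12, 12), 42.0), 0.1)
        trace = tr.extract_trace(movie, Peak(6, 6, 0.0, 0.0))
        assert len(trace) == 7
        assert np.allclose(trace.intensities, 42.0)

    def test_footprint_mean_is_exact(self):
        rng = np.random.default_rng(0)
        movie = MovieStack(rng.random((3, 9, 9)), 0.1)
        trace = tr.extract_trace(movie, Peak(4, 3, 0.0, 0.0))
        expected = movie.frames[:, 2:5, 3:6].mean(axis=(1, 2))
        assert np.allclose(trace.intensities, expected)

    def test_border_peak_rejected(self):
        movie = MovieStack(np.zeros((2, 8, 8)), 0.1)
        with pytest.raises(ValueError):
            tr.extract_trace(movie, Peak(0, 4, 0.0, 0.0))


class TestDoubleGaussian:
    def test_recovers_well_separated_components(self):
        """Means of N(100,5) + N(300,10) recovered within 2 counts."""
        rng = np.random.default_rng(1)
        sample = np.concatenate([rng.normal(100, 5, 5000),
                                 rng.normal(300, 10, 5000)])
        model = tr.fit_double_gaussian(sample)
        assert model.mu_unbound == pytest.approx(100.0, abs=2.0)
        assert model.mu_bound == pytest.approx(300.0, abs=2.0)
        assert model.weight_unbound == pytest.approx(0.5, abs=0.05)

    def test_identical_values_are_degenerate(self):
        with pytest.raises(DegenerateFitError):
            tr.fit_double_gaussian(np.full(500, 7.0))

    def test_single_mode_is_degenerate(self):
        rng = np.random.default_rng(2)
        with pytest.raises(DegenerateFitError):
            tr.fit_double_gaussian(rng.normal(100, 5, 5000))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            tr.fit_double_gaussian(np.arange(50, dtype=float))

    def test_simulator_bound_level_recovered(self, analysis_products):
        """mu_bound lands within 10% of the rendered full spot level."""
        model = analysis_products["model"]
        cfg = analysis_products["config"]
        truth = analysis_products["truth"]
        # oracle: per-site expected 3x3 footprint mean at full occupancy,
        # computed from the pixel-integrated PSF at the true subpixel center
        from scipy.special import erf

        def footprint_mass(fx, fy, sigma):
            def axis_mass(f):
                edges = np.array([-1.5, 1.5]) - f
                a, b = 0.5 * (1 + erf(edges / (sigma * np.sqrt(2))))
                return b - a
            return axis_mass(fx) * axis_mass(fy)

        masses = []
        for x, y in truth.positions:
            masses.append(footprint_mass(x - round(x), y - round(y), cfg.psf_sigma))
        # flat-field correction normalizes brightness to the unit-mean
        # illumination, i.e. each site ends up at amplitude * mean(illum)
        from smor.simulate import illumination_profile

        mean_illum = illumination_profile(cfg.image_size,
                                          cfg.illumination_sigma).mean()
        expected = (cfg.camera_offset + cfg.background_rate * mean_illum
                    + cfg.monomer_amplitude * mean_illum * np.mean(masses) / 9.0)
        assert model.mu_bound == pytest.approx(expected, rel=0.10)


class TestHMM:
    MODEL = IntensityModel(100.0, 5.0, 200.0, 5.0, 0.8)

    def test_noiseless_two_level_trace_recovered_exactly(self):
        values = [100.0, 200, 200, 100, 100, 200, 100]
        fit = tr.fit_hmm(make_trace(values), self.MODEL)
        assert list(fit.state_path) == [0, 1, 1, 0, 0, 1, 0]
        assert fit.rmsd == pytest.approx(0.0, abs=1e-9)

    def test_pure_noise_trace_is_all_unbound(self):
        rng = np.random.default_rng(3)
        values = rng.normal(100, 5, 400)
        fit = tr.fit_hmm(make_trace(values), self.MODEL)
        assert not fit.state_path.any()
        assert fit.rmsd == pytest.approx(5.0, rel=0.15)

    def test_high_snr_state_accuracy(self):
        """Per-frame accuracy >= 99% at SNR >= 5 vs ground-truth states."""
        rng = np.random.default_rng(4)
        n, dt = 1500, 0.1
        correct = total = 0
        for _ in range(5):
            traj = sample_state_trajectory(0.8, 3.0, n * dt, rng)
            occ = occupancy_per_frame(traj, n, dt)
            true_states = occ > 0.5
            values = 100.0 + 100.0 * occ + rng.normal(0, 5.0, n)
            fit = tr.fit_hmm(make_trace(values), self.MODEL)
            correct += (fit.state_path.astype(bool) == true_states).sum()
            total += n
        assert correct / total >= 0.99

    def test_rmsd_invariant_under_common_offset(self):
        rng = np.random.default_rng(5)
        values = 100.0 + 100.0 * (rng.random(300) > 0.7) + rng.normal(0, 5, 300)
        f1 = tr.fit_hmm(make_trace(values), self.MODEL)
        shifted = IntensityModel(150.0, 5.0, 250.0, 5.0, 0.8)
        f2 = tr.fit_hmm(make_trace(values + 50.0), shifted)
        assert f1.rmsd == pytest.approx(f2.rmsd, abs=1e-6)

    def test_viterbi_matches_exhaustive_enumeration(self):
        """Viterbi path is the argmax over all 2^T paths (T <= 12)."""
        rng = np.random.default_rng(6)
        for case in range(25):
            n = int(rng.integers(3, 13))
            sep = rng.uniform(15, 60)
            model = IntensityModel(100.0, 5.0, 100.0 + sep, rng.uniform(4, 10),
                                   rng.uniform(0.3, 0.9))
            values = rng.uniform(90, 110 + sep, n)
            fit = tr.fit_hmm(make_trace(values), model, max_iter=0,
                             shared_sigma=False)
            best = max(itertools.product([0, 1], repeat=n),
                       key=lambda p: path_log_prob(model, 0.95, values, p))
            lp_vit = path_log_prob(model, 0.95, values, list(fit.state_path))
            lp_best = path_log_prob(model, 0.95, values, list(best))
            assert lp_vit == pytest.approx(lp_best, abs=1e-9), f"case {case}"

    def test_em_loglikelihood_is_nondecreasing(self):
        rng = np.random.default_rng(7)
        values = 100.0 + 100.0 * (rng.random(500) > 0.8) + rng.normal(0, 5, 500)
        fit = tr.fit_hmm(make_trace(values), self.MODEL)
        hist = np.asarray(fit.ll_history)
        assert len(hist) >= 2
        # allow float-level noise at the converged fixed point
        assert np.all(np.diff(hist) >= -1e-6 * np.maximum(1.0, np.abs(hist[:-1])))


class TestRmsdFilter:
    def test_identical_rmsds_reject_nothing(self):
        fits = [tr.TraceFit(make_trace([1.0]), np.zeros(1, np.int8),
                            np.eye(2), 3.0, 0.0) for _ in range(10)]
        fits = tr.filter_traces_by_rmsd(fits)
        assert all(f.accepted for f in fits)

    def test_outlier_rmsd_rejected(self):
        rng = np.random.default_rng(8)
        fits = [tr.TraceFit(make_trace([1.0]), np.zeros(1, np.int8), np.eye(2),
                            5.0 + rng.normal(0, 0.3), 0.0) for _ in range(40)]
        bad = tr.TraceFit(make_trace([1.0]), np.zeros(1, np.int8), np.eye(2),
                          20.0, 0.0)
        fits.append(bad)
        fits = tr.filter_traces_by_rmsd(fits)
        assert not bad.accepted
        assert bad.peak.status == "rejected_rmsd"
        assert sum(f.accepted for f in fits) == 40

    def test_homogeneous_traces_mostly_accepted(self, analysis_products):
        fits = analysis_products["fits"]
        assert np.mean([f.accepted for f in fits]) >= 0.9

    def test_few_fits_pass_with_warning(self):
        fits = [tr.TraceFit(make_trace([1.0]), np.zeros(1, np.int8), np.eye(2),
                            float(r), 0.0) for r in (1, 2, 100)]
        with pytest.warns(UserWarning, match="fewer than 5"):
            fits = tr.filter_traces_by_rmsd(fits)
        assert all(f.accepted for f in fits)
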