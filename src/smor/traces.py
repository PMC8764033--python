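"""Per-peak intensity traces and two-state HMM idealization.

The intensity of each selected peak is followed over time (mean over the
3x3 footprint).  Intensities pooled over *all* selected traces of a movie
are fit with a two-component Gaussian mixture -- the "double Gaussian" --
whose components define the unbound and bound emission levels unique to
that movie.  Each trace is then idealized with a two-state hidden Markov
model with Gaussian emissions held fixed at those pooled values while the
transition matrix is estimated by EM; the Viterbi path gives the
bound/unbound trajectory.  Traces whose root-mean-square deviation from
the idealized two-level fit is more than two standard deviations above
the median RMSD of the population (e.g. because a neighboring binding
event bleeds into the footprint) are rejected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from hmmlearn.hmm import GaussianHMM
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit
from skimage.filters import threshold_otsu
from sklearn.mixture import GaussianMixture

from smor.peaks import Peak, REJECTED_RMSD, SELECTED
from smor.preprocess import MovieStack


class DegenerateFitError(RuntimeError):
    """Raised when the pooled intensity histogram has no two-state structure."""


@dataclass
class Trace:
    """Intensity time series of one peak (3x3 footprint mean per frame)."""

    peak: Peak
    intensities: np.ndarray
    frame_interval: float

    def __len__(self) -> int:
        return len(self.intensities)


@dataclass
class IntensityModel:
    """Pooled two-level Gaussian emission model of a movie."""

    mu_unbound: float
    sigma_unbound: float
    mu_bound: float
    sigma_bound: float
    weight_unbound: float

    def __post_init__(self) -> None:
        if self.mu_bound <= self.mu_unbound:
            raise ValueError("mu_bound must exceed mu_unbound")
        if self.sigma_unbound <= 0 or self.sigma_bound <= 0:
            raise ValueError("sigmas must be positive")
        if not 0.0 < self.weight_unbound < 1.0:
            raise ValueError("weight_unbound must be in (0, 1)")


@dataclass
class TraceFit:
    """Idealized two-state fit of a trace."""

    trace: Trace
    state_path: np.ndarray            # per frame: 0 = unbound, 1 = bound
    transition_matrix: np.ndarray     # 2x2 row-stochastic
    rmsd: float
    log_likelihood: float
    converged: bool = True
    accepted: bool = True
    ll_history: tuple = ()            # EM log-likelihood per iteration

    @property
    def peak(self) -> Peak:
        return self.trace.peak


def extract_trace(movie: MovieStack, peak: Peak) -> Trace:
    """Per-frame mean intensity over the peak's 3x3 footprint."""
    _, h, w = movie.shape
    if not (1 <= peak.x <= w - 2 and 1 <= peak.y <= h - 2):
        raise ValueError(f"peak footprint at ({peak.x}, {peak.y}) leaves the image")
    window = movie.frames[:, peak.y - 1 : peak.y + 2, peak.x - 1 : peak.x + 2]
    return Trace(peak, window.mean(axis=(1, 2)).astype(float), movie.frame_interval)


def pool_intensities(traces: list[Trace], max_values: int = 200_000) -> np.ndarray:
    """Pooled intensity sample over all traces (deterministic stride subsample)."""
    pooled = np.concatenate([t.intensities for t in traces])
    if len(pooled) > max_values:
        stride = int(np.ceil(len(pooled) / max_values))
        pooled = pooled[::stride]
    return pooled


def _double_gauss(x, a1, mu1, s1, a2, mu2, s2):
    return (a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2)
            + a2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2))


def fit_double_gaussian(traces: list[Trace] | np.ndarray,
                        tol: float = 1e-6, max_iter: int = 500,
                        n_bins: int = 256) -> IntensityModel:
    """Double-Gaussian fit of the pooled intensity histogram.

    The pooled per-frame intensities are histogrammed and a sum of two
    Gaussians is least-squares fitted to the counts.  Fitting the
    *histogram* rather than maximizing a two-component mixture likelihood
    matters: frames in which a molecule was bound for only part of the
    exposure form a smear between the two levels, and a mixture EM fit
    absorbs that smear into an inflated "bound" component, whereas the
    histogram fit locks onto the two modes -- the unbound baseline and the
    fully bound level.  The component with the lower mean is labeled
    unbound.  Raises :class:`DegenerateFitError` when no second mode
    exists or the fitted components collapse
    (``|mu_bound - mu_unbound| < max(sigma)``).

    Falls back to a two-component Gaussian-mixture EM fit (tolerance
    ``tol``, ``max_iter`` iterations) if the curve fit fails to converge.
    """
    anchor = None
    if isinstance(traces, list):
        values = pool_intensities(traces)
        # median of per-trace maxima: a robust estimate of the fully bound
        # level even when almost every bound frame is a partial exposure
        anchor = float(np.median([t.intensities.max() for t in traces]))
    else:
        values = np.asarray(traces, float)
    if len(values) < 100:
        raise ValueError("need at least 100 pooled intensity values")
    if np.ptp(values) == 0:
        raise DegenerateFitError("no two-state structure detected: constant intensities")

    counts, edges = np.histogram(values, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_width = edges[1] - edges[0]
    counts = uniform_filter1d(counts.astype(float), size=3)

    # initialization: split the sample at the Otsu threshold and take
    # robust location/width of each side
    thr = float(threshold_otsu(values))
    low, high = values[values <= thr], values[values > thr]
    if len(high) < 30 or len(low) < 30:
        raise DegenerateFitError("no two-state structure detected: single mode")

    def _loc_scale(v):
        med = float(np.median(v))
        mad = float(np.median(np.abs(v - med)))
        return med, max(1.4826 * mad, bin_width)

    mu1_init, s1_init = _loc_scale(low)
    mu2_init, s2_init = _loc_scale(high)

    def _amp(mu):
        return max(float(counts[np.argmin(np.abs(centers - mu))]), 1.0)

    def _fit(p0, lo_b, hi_b):
        p0 = np.clip(p0, lo_b + 1e-12,
                     np.where(np.isfinite(hi_b), hi_b - 1e-12, p0))
        popt, _ = curve_fit(_double_gauss, centers, counts, p0=p0,
                            bounds=(lo_b, hi_b), maxfev=10000)
        a1, mu1, s1, a2, mu2, s2 = (float(v) for v in popt)
        if mu1 > mu2:
            a1, mu1, s1, a2, mu2, s2 = a2, mu2, s2, a1, mu1, s1
        return a1, mu1, s1, a2, mu2, s2

    def _degenerate(f):
        # the unbound width is the per-frame noise scale: a genuine bound
        # level sits many noise widths above the baseline, whereas
        # components splitting a single mode (or one soaked into the
        # partial-exposure smear) stay within a width or two
        if f is None:
            return True
        _, mu1, s1, _, mu2, s2 = f
        return (mu2 - mu1) < max(6.0 * s1, 1.5 * s2)

    lo_b = np.array([0.0, centers[0], bin_width / 4, 0.0, thr, bin_width / 4])
    hi_b = np.array([np.inf, thr, np.ptp(centers), np.inf, centers[-1],
                     np.ptp(centers)])
    try:
        fitted = _fit([_amp(mu1_init), mu1_init, s1_init,
                       _amp(mu2_init), mu2_init, s2_init], lo_b, hi_b)
    except RuntimeError:
        fitted = None

    if _degenerate(fitted) and anchor is not None \
            and anchor > mu1_init + 6.0 * s1_init:
        # very short dwells leave mostly partial-exposure frames: the
        # histogram between the levels is a smear the free fit sinks into.
        # Re-fit with the bound component anchored near the per-trace
        # maxima and its width kept at a plausible noise scale.
        mu2_lo = mu1_init + 0.75 * (anchor - mu1_init)
        mu2_hi = max(min(float(centers[-1]), anchor + 5.0 * s1_init),
                     mu2_lo + bin_width)
        s2_hi = max(0.35 * (anchor - mu1_init), bin_width)
        lo_a = np.array([0.0, centers[0], bin_width / 4, 0.0, mu2_lo,
                         bin_width / 4])
        hi_a = np.array([np.inf, thr, np.ptp(centers), np.inf, mu2_hi, s2_hi])
        try:
            fitted = _fit([_amp(mu1_init), mu1_init, s1_init, _amp(anchor),
                           anchor, max(3.0 * s1_init, bin_width)], lo_a, hi_a)
        except RuntimeError:
            fitted = None

    if fitted is None:
        gmm = GaussianMixture(n_components=2, covariance_type="full", tol=tol,
                              max_iter=max_iter, n_init=1, random_state=0)
        gmm.fit(values.reshape(-1, 1))
        order = np.argsort(gmm.means_.ravel())
        mus = gmm.means_.ravel()[order]
        sig = np.sqrt(gmm.covariances_.ravel())[order]
        wts = gmm.weights_.ravel()[order]
        fitted = (wts[0] / sig[0], float(mus[0]), float(sig[0]),
                  wts[1] / sig[1], float(mus[1]), float(sig[1]))

    if _degenerate(fitted):
        raise DegenerateFitError(
            "no two-state structure detected: components overlap"
        )
    a1, mu1, s1, a2, mu2, s2 = fitted
    mass1, mass2 = a1 * s1, a2 * s2
    weight = float(np.clip(mass1 / (mass1 + mass2), 1e-6, 1.0 - 1e-6))
    return IntensityModel(
        mu_unbound=mu1, sigma_unbound=s1,
        mu_bound=mu2, sigma_bound=s2,
        weight_unbound=weight,
    )


def _build_hmm(model: IntensityModel, self_transition: float,
               params: str, n_iter: int, tol: float) -> GaussianHMM:
    h = GaussianHMM(n_components=2, covariance_type="diag", n_iter=n_iter,
                    tol=tol, params=params, init_params="")
    h.startprob_ = np.array([model.weight_unbound, 1.0 - model.weight_unbound])
    p = self_transition
    h.transmat_ = np.array([[p, 1.0 - p], [1.0 - p, p]])
    h.means_ = np.array([[model.mu_unbound], [model.mu_bound]])
    h.covars_ = np.array([[model.sigma_unbound**2], [model.sigma_bound**2]])
    return h


def fit_hmm(trace: Trace, model: IntensityModel,
            reestimate_emissions: bool = False, self_transition: float = 0.95,
            max_iter: int = 100, tol: float = 1e-6,
            shared_sigma: bool = True) -> TraceFit:
    """Idealize one trace with a two-state Gaussian-emission HMM.

    Emission parameters are held fixed at the pooled double-Gaussian
    values (state 0 = unbound, state 1 = bound) while the transition
    matrix is re-estimated by EM; set ``reestimate_emissions=True`` for
    full Baum-Welch.  The state path is the Viterbi (most probable) path;
    RMSD is computed against the state means along that path.

    With ``shared_sigma`` (the default) both emission widths are set to
    the unbound (measurement-noise) width, which places the state
    decision boundary at the midpoint of the two levels.  The fitted
    bound-state width in the pooled histogram reflects brightness
    heterogeneity across molecules and partial-exposure frames rather
    than per-frame noise; using it directly would drag the boundary far
    toward the baseline and count barely occupied frames as bound.
    """
    params = "stmc" if reestimate_emissions else "st"
    if shared_sigma and not reestimate_emissions:
        model = IntensityModel(model.mu_unbound, model.sigma_unbound,
                               model.mu_bound, model.sigma_unbound,
                               model.weight_unbound)
    h = _build_hmm(model, self_transition, params, max_iter, tol)
    x = np.asarray(trace.intensities, dtype=float).reshape(-1, 1)
    converged = True
    history: tuple = ()
    hmm_logger = logging.getLogger("hmmlearn")
    prev_level = hmm_logger.level
    hmm_logger.setLevel(logging.ERROR)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                if max_iter > 0:
                    h.fit(x)
                    converged = bool(h.monitor_.converged)
                    history = tuple(h.monitor_.history)
                    if not converged and len(history) >= 2:
                        # a sub-tolerance negative step is float noise,
                        # not an EM failure
                        converged = abs(history[-1] - history[-2]) <= tol
            except Exception:  # EM failure: keep the initialized model, flag it
                h = _build_hmm(model, self_transition, params, 0, tol)
                converged = False
    finally:
        hmm_logger.setLevel(prev_level)
    # a state never visited leaves its transition row empty after EM;
    # restore the prior row so scoring and Viterbi remain defined
    tm = np.asarray(h.transmat_, dtype=float)
    p = self_transition
    prior = np.array([[p, 1.0 - p], [1.0 - p, p]])
    row_sums = tm.sum(axis=1)
    bad = ~np.isfinite(row_sums) | (np.abs(row_sums - 1.0) > 1e-6)
    if bad.any():
        tm[bad] = prior[bad]
        h.transmat_ = tm
    sp = np.asarray(h.startprob_, dtype=float)
    if not np.isfinite(sp).all() or abs(sp.sum() - 1.0) > 1e-6:
        h.startprob_ = np.array([model.weight_unbound, 1.0 - model.weight_unbound])
    log_likelihood = float(h.score(x))
    path = h.predict(x).astype(np.int8)
    if reestimate_emissions and h.means_[0, 0] > h.means_[1, 0]:
        path = (1 - path).astype(np.int8)
        h.transmat_ = h.transmat_[::-1, ::-1].copy()
    means = (np.asarray(h.means_).ravel() if reestimate_emissions
             else np.array([model.mu_unbound, model.mu_bound]))
    if reestimate_emissions:
        means = np.sort(means)
    fitted = means[path]
    rmsd = float(np.sqrt(np.mean((trace.intensities - fitted) ** 2)))
    return TraceFit(trace, path, np.asarray(h.transmat_), rmsd,
                    log_likelihood, converged=converged, ll_history=history)


def filter_traces_by_rmsd(fits: list[TraceFit], n_sd: float = 2.0,
                          two_sided: bool = False) -> list[TraceFit]:
    """Reject traces whose RMSD is an outlier of the population.

    The default rule is one-sided high -- ``rmsd > median + n_sd * SD`` --
    since an unusually *good* two-level fit is not a defect; the
    ``two_sided`` flag also rejects below ``median - n_sd * SD``.  Rejected
    fits get ``accepted=False`` and their peak status becomes
    ``rejected_rmsd``.  Fewer than 5 fits pass unfiltered with a warning.
    The input list is updated in place and returned.
    """
    if len(fits) == 0:
        return fits
    rmsds = np.array([f.rmsd for f in fits])
    if len(fits) < 5:
        warnings.warn("fewer than 5 traces: RMSD statistics are unreliable, "
                      "all traces pass", stacklevel=2)
        return fits
    med = float(np.median(rmsds))
    sd = float(np.std(rmsds))
    hi = med + n_sd * sd
    lo = med - n_sd * sd
    for f in fits:
        bad = f.rmsd > hi or (two_sided and f.rmsd < lo)
        if bad:
            f.accepted = False
            if f.peak.status == SELECTED:
                f.peak.status = REJECTED_RMSD
    return fits
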