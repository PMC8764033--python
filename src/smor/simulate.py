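"""Synthetic TIRF movie generator with known two-state binding kinetics.

The simulator emulates the statistical structure the analysis pipeline has
to defeat: immobilized receptor sites whose ligand occupancy alternates
between bound and unbound states with exponentially distributed dwell
times, diffraction-limited Gaussian spots, a centered Gaussian excitation
gradient (the TIRF evanescent-wave profile), multimeric contaminants at
integer multiples of the monomer brightness, ligand stuck to the glass for
the whole movie, slow lateral drift, and shot + read noise on top of a
camera offset.

Occupancy is integrated *within* each exposure, not sampled at frame
boundaries, so a binding event shorter than a frame produces a genuinely
attenuated single-frame spot -- the "single-frame" events that the
dwell-time bookkeeping must count but exclude from the exponential fit.

Ground truth (site positions, continuous-time state trajectories, the
complete bound intervals, and the drift track) is returned alongside the
movie for parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import erf

from smor.preprocess import MovieStack

BOUND = "bound"
UNBOUND = "unbound"


@dataclass
class SimConfig:
    """Parameters of a simulated movie.

    Durations are seconds, positions and widths are pixels, intensities
    are camera counts (one photoelectron = one count).
    """

    image_size: int = 512
    n_frames: int = 2000
    frame_interval: float = 0.1
    n_sites: int = 150
    tau_bound: float = 0.4          # true mean bound dwell, 1/k_off
    tau_unbound: float = 10.0       # true mean unbound dwell, 1/(k_on*[L])
    psf_sigma: float = 1.0
    monomer_amplitude: float = 1500.0  # photons/frame at the field center
    illumination_sigma: float = 150.0  # Gaussian excitation width; inf = flat
    background_rate: float = 5.0       # photons/pixel/frame at the center
    multimer_fraction: float = 0.05
    multimer_amplitudes: tuple[int, ...] = (2, 3)
    stuck_fraction: float = 0.02
    min_separation: float = 5.0
    drift_velocity: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px/frame
    drift_jitter_sd: float = 0.0
    shot_noise: bool = True
    read_noise_sd: float = 1.5
    camera_offset: float = 100.0
    bleach_tau: float | None = None  # default: 100x the movie duration
    edge_margin: float = 6.0
    positions: np.ndarray | None = None  # explicit (n, 2) site (x, y); overrides
    seed: int = 0                        # n_sites / min_separation placement

    def __post_init__(self) -> None:
        if self.bleach_tau is None:
            self.bleach_tau = 100.0 * self.n_frames * self.frame_interval
        if self.positions is not None:
            self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
            self.n_sites = len(self.positions)
        self.validate()

    def validate(self) -> None:
        if self.image_size < 8 or self.n_frames < 1:
            raise ValueError("image_size and n_frames must be positive")
        for name in ("frame_interval", "tau_bound", "tau_unbound",
                     "monomer_amplitude", "bleach_tau"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("multimer_fraction", "stuck_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.psf_sigma < 0.5:
            raise ValueError("psf_sigma must be >= 0.5 px (diffraction limit)")
        if self.bleach_tau < 10.0 * self.tau_bound:
            raise ValueError(
                "bleach_tau must be >= 10*tau_bound: photobleaching must be "
                "slow compared with the dwell times being measured"
            )

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval

    def to_dict(self) -> dict:
        d = asdict(self)
        d["multimer_amplitudes"] = list(self.multimer_amplitudes)
        d["drift_velocity"] = list(self.drift_velocity)
        return d


@dataclass
class GroundTruth:
    """Per-site truth channel of a simulated movie."""

    positions: np.ndarray        # (n_sites, 2) subpixel (x, y)
    multipliers: np.ndarray      # (n_sites,) amplitude multiple (1 = monomer)
    is_stuck: np.ndarray         # (n_sites,) bool
    trajectories: list           # per site: list of (state, t_start, t_end)
    drift_track: np.ndarray      # (n_frames, 2) (dx, dy)

    def true_dwells(self, site: int | None = None) -> np.ndarray:
        """Complete (uncensored) bound intervals, in seconds.

        Intervals touching the start or end of the movie are excluded: only
        dwells whose full extent was observed count as truth for the
        exponential estimator.
        """
        sites = range(len(self.trajectories)) if site is None else [site]
        out = []
        for s in sites:
            traj = self.trajectories[s]
            if not traj:
                continue
            t_end = traj[-1][2]
            for state, a, b in traj:
                if state == BOUND and a > 0.0 and b < t_end:
                    out.append(b - a)
        return np.asarray(out)

    def bound_fraction(self) -> float:
        """Time-averaged fraction of (site, time) spent bound."""
        total = 0.0
        bound = 0.0
        for traj in self.trajectories:
            for state, a, b in traj:
                total += b - a
                if state == BOUND:
                    bound += b - a
        return bound / total if total > 0 else 0.0


def sample_state_trajectory(tau_bound: float, tau_unbound: float,
                            duration: float, rng: np.random.Generator,
                            initial_state: str | None = None) -> list:
    """Alternating bound/unbound renewal trajectory on ``[0, duration]``.

    Interval lengths are exponential with the corresponding mean; the
    initial state is drawn from the stationary distribution,
    ``p(bound) = tau_bound / (tau_bound + tau_unbound)``, unless given.
    Because the exponential is memoryless the first residual interval has
    the same distribution as a full one, so this sampling is stationary.
    """
    if tau_bound <= 0 or tau_unbound <= 0:
        raise ValueError("tau_bound and tau_unbound must be > 0")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if duration == 0:
        return []
    if initial_state is None:
        p_bound = tau_bound / (tau_bound + tau_unbound)
        state = BOUND if rng.random() < p_bound else UNBOUND
    else:
        state = initial_state
    traj = []
    t = 0.0
    while t < duration:
        mean = tau_bound if state == BOUND else tau_unbound
        length = rng.exponential(mean)
        end = min(t + length, duration)
        traj.append((state, t, end))
        t = end
        state = UNBOUND if state == BOUND else BOUND
    return traj


def occupancy_per_frame(trajectory: list, n_frames: int, frame_interval: float) -> np.ndarray:
    """Fraction of each frame's exposure spent in the bound state."""
    occ = np.zeros(n_frames)
    dt = frame_interval
    for state, a, b in trajectory:
        if state != BOUND:
            continue
        f0 = int(a / dt)
        f1 = min(int(math.ceil(b / dt)), n_frames)
        for f in range(f0, f1):
            lo = max(a, f * dt)
            hi = min(b, (f + 1) * dt)
            if hi > lo:
                occ[f] += (hi - lo) / dt
    return np.clip(occ, 0.0, 1.0)


def _psf_patch(x: float, y: float, sigma: float, radius: int,
               size: int) -> tuple[slice, slice, np.ndarray]:
    """Pixel-integrated Gaussian PSF of unit mass around ``(x, y)``.

    Each pixel receives the exact integral of the 2-D Gaussian over its
    area (difference of error functions), so the patch conserves photon
    mass to ~1e-9 for a radius of 6 sigma.
    """
    cx, cy = int(round(x)), int(round(y))
    x0, x1 = max(cx - radius, 0), min(cx + radius + 1, size)
    y0, y1 = max(cy - radius, 0), min(cy + radius + 1, size)
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    s = sigma * math.sqrt(2.0)
    fx = 0.5 * (erf((xs + 0.5 - x) / s) - erf((xs - 0.5 - x) / s))
    fy = 0.5 * (erf((ys + 0.5 - y) / s) - erf((ys - 0.5 - y) / s))
    return slice(y0, y1), slice(x0, x1), np.outer(fy, fx)


def _sample_positions(n: int, size: int, margin: float, min_sep: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Uniform positions with a minimum pairwise separation (dart throwing)."""
    lo, hi = margin, size - margin
    if hi <= lo:
        raise ValueError("image too small for the requested edge margin")
    positions: list[tuple[float, float]] = []
    attempts = 0
    max_attempts = max(10000, 200 * n)
    while len(positions) < n:
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {n} sites with min_separation={min_sep}; "
                "reduce the density or the separation"
            )
        attempts += 1
        p = rng.uniform(lo, hi, size=2)
        if min_sep > 0 and positions:
            arr = np.asarray(positions)
            if np.min(np.hypot(arr[:, 0] - p[0], arr[:, 1] - p[1])) < min_sep:
                continue
        positions.append((p[0], p[1]))
    return np.asarray(positions)


def illumination_profile(size: int, sigma: float) -> np.ndarray:
    """Centered 2-D Gaussian excitation profile with peak 1 (flat if inf)."""
    if not np.isfinite(sigma):
        return np.ones((size, size))
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = (xx - c) ** 2 + (yy - c) ** 2
    return np.exp(-r2 / (2.0 * sigma**2))


def render_movie(config: SimConfig) -> tuple[MovieStack, GroundTruth]:
    """Render a movie stack and its ground truth from a :class:`SimConfig`.

    Per frame, each site contributes
    ``amplitude * illumination(x, y) * occupancy * bleach(t)`` rendered as
    a pixel-integrated Gaussian PSF; the per-pixel expectation (plus a
    shot-noise background) is Poisson-sampled, then Gaussian read noise
    and the camera offset are added.  With all noise disabled the analog
    expectation image is returned unquantized so photon-conservation
    checks hold exactly.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    size, t_frames, dt = cfg.image_size, cfg.n_frames, cfg.frame_interval

    if cfg.positions is not None:
        positions = np.array(cfg.positions, dtype=float)
    else:
        positions = _sample_positions(cfg.n_sites, size, cfg.edge_margin,
                                      cfg.min_separation, rng)
    multipliers = np.ones(cfg.n_sites)
    n_multi = int(round(cfg.multimer_fraction * cfg.n_sites))
    n_stuck = int(round(cfg.stuck_fraction * cfg.n_sites))
    order = rng.permutation(cfg.n_sites)
    multi_idx = order[:n_multi]
    stuck_idx = order[n_multi : n_multi + n_stuck]
    if n_multi:
        multipliers[multi_idx] = rng.choice(cfg.multimer_amplitudes, size=n_multi)
    is_stuck = np.zeros(cfg.n_sites, dtype=bool)
    is_stuck[stuck_idx] = True

    duration = t_frames * dt
    trajectories = []
    for s in range(cfg.n_sites):
        if is_stuck[s]:
            trajectories.append([(BOUND, 0.0, duration)])
        else:
            trajectories.append(
                sample_state_trajectory(cfg.tau_bound, cfg.tau_unbound, duration, rng)
            )

    # drift: cumulative velocity plus optional per-frame jitter, zero at frame 0
    steps = np.tile(np.asarray(cfg.drift_velocity, dtype=float), (t_frames, 1))
    if cfg.drift_jitter_sd > 0:
        steps += rng.normal(0.0, cfg.drift_jitter_sd, size=(t_frames, 2))
    steps[0] = 0.0
    drift = np.cumsum(steps, axis=0)

    illum = illumination_profile(size, cfg.illumination_sigma)
    background = (cfg.background_rate * illum).astype(np.float32)

    # per-frame buckets of (site, occupancy) for frames where a site emits
    buckets: list[list[tuple[int, float]]] = [[] for _ in range(t_frames)]
    for s in range(cfg.n_sites):
        occ = occupancy_per_frame(trajectories[s], t_frames, dt)
        for f in np.nonzero(occ > 0)[0]:
            buckets[f].append((s, occ[f]))

    radius = max(3, int(math.ceil(6.0 * cfg.psf_sigma)))
    drifting = bool(np.any(np.abs(drift) > 1e-12))
    patches = {}
    if not drifting:
        for s in range(cfg.n_sites):
            x, y = positions[s]
            patches[s] = _psf_patch(x, y, cfg.psf_sigma, radius, size)

    def site_amplitude(s: int) -> float:
        x, y = positions[s]
        i = illum[min(int(round(y)), size - 1), min(int(round(x)), size - 1)]
        return cfg.monomer_amplitude * multipliers[s] * i

    amps = np.array([site_amplitude(s) for s in range(cfg.n_sites)])

    noisy = cfg.shot_noise or cfg.read_noise_sd > 0
    out = np.empty((t_frames, size, size), dtype=np.float32)
    overflow = 0
    bleach_mid = np.exp(-(np.arange(t_frames) + 0.5) * dt / cfg.bleach_tau)
    bg64 = background.astype(np.float64)
    chunk_len = max(1, min(t_frames, int(8e6 // (size * size))))
    # reused work buffers: the render loop churns through gigabytes per
    # movie and fresh allocations dominate the run time otherwise
    expect = np.empty((chunk_len, size, size), dtype=np.float64)
    noise_buf = np.empty((chunk_len, size, size), dtype=np.float32)
    for c0 in range(0, t_frames, chunk_len):
        c1 = min(c0 + chunk_len, t_frames)
        buf = expect[: c1 - c0]
        buf[:] = bg64
        for f in range(c0, c1):
            for s, occ in buckets[f]:
                if drifting:
                    x, y = positions[s] + drift[f]
                    ys, xs, patch = _psf_patch(x, y, cfg.psf_sigma, radius, size)
                else:
                    ys, xs, patch = patches[s]
                buf[f - c0, ys, xs] += (amps[s] * occ * bleach_mid[f]) * patch
        chunk = out[c0:c1]
        if cfg.shot_noise:
            np.copyto(chunk, rng.poisson(buf), casting="unsafe")
        else:
            np.copyto(chunk, buf, casting="unsafe")
        if cfg.read_noise_sd > 0:
            noise = noise_buf[: c1 - c0]
            rng.standard_normal(out=noise, dtype=np.float32)
            noise *= cfg.read_noise_sd
            chunk += noise
        chunk += np.float32(cfg.camera_offset)
        if noisy:
            np.rint(chunk, out=chunk)
        overflow += int(np.count_nonzero(chunk > 65535))
        np.clip(chunk, 0.0, 65535.0, out=chunk)
    if overflow:
        import warnings

        warnings.warn(f"{overflow} pixel values overflowed the 16-bit range and "
                      "were clipped", stacklevel=2)

    movie = MovieStack(out, dt, pixel_size=16.0)
    truth = GroundTruth(positions, multipliers, is_stuck, trajectories, drift)
    return movie, truth
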