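"""Candidate binding-site detection and intensity-based rejection.

Peaks are 3 x 3 pixel squares centered on local maxima of the corrected
maximum-intensity projection.  Two population rules then remove
contaminants: peaks brighter than median + 3 SD of the maximum-projection
intensities are multimers; peaks whose *minimum*-projection intensity
exceeds median + 3 SD sit on long-lived stuck ligand or elevated
background rather than on a transient binding site.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import peak_local_max

from smor.preprocess import Projection

SELECTED = "selected"
REJECTED_BRIGHT = "rejected_bright"
REJECTED_DIM_BACKGROUND = "rejected_dim_background"
REJECTED_RMSD = "rejected_rmsd"


@dataclass
class Peak:
    """A 3x3-pixel candidate binding site at integer center ``(x, y)``."""

    x: int
    y: int
    max_intensity: float
    min_intensity: float
    status: str = SELECTED

    @property
    def selected(self) -> bool:
        return self.status == SELECTED


@dataclass
class PeakPopulationStats:
    median_max: float
    sd_max: float
    median_min: float
    sd_min: float
    n_sd: float = 3.0

    @property
    def threshold_max(self) -> float:
        return self.median_max + self.n_sd * self.sd_max

    @property
    def threshold_min(self) -> float:
        return self.median_min + self.n_sd * self.sd_min


def footprint_mean(image: np.ndarray, x: int, y: int) -> float:
    """Mean intensity over the 3x3 footprint centered on ``(x, y)``."""
    return float(image[y - 1 : y + 2, x - 1 : x + 2].mean())


def default_detect_threshold(image: np.ndarray, n_sd: float = 5.0) -> float:
    """Robust background-based detection threshold: median + n_sd * MAD-SD."""
    med = float(np.median(image))
    mad_sd = 1.4826 * float(np.median(np.abs(image - med)))
    return med + n_sd * mad_sd


def detect_peaks(max_proj: Projection, min_proj: Projection,
                 min_separation: int = 3,
                 detect_threshold: float | None = None) -> list[Peak]:
    """Find local maxima of the corrected max projection as candidate peaks.

    Maxima are non-maximum-suppressed at ``min_separation`` pixels;
    footprints touching the image border are dropped.  Each peak records
    the mean over its 3x3 footprint in both projections.  If no threshold
    is given, a robust background estimate (median + 5 MAD-SD of the max
    projection) is used.
    """
    image = np.asarray(max_proj.image, dtype=float)
    if detect_threshold is None:
        detect_threshold = default_detect_threshold(image)
    coords = peak_local_max(image, min_distance=min_separation,
                            threshold_abs=detect_threshold, exclude_border=1)
    peaks = []
    for row, col in coords:
        peaks.append(Peak(
            x=int(col), y=int(row),
            max_intensity=footprint_mean(max_proj.image, int(col), int(row)),
            min_intensity=footprint_mean(min_proj.image, int(col), int(row)),
        ))
    return peaks


def _sd(values: np.ndarray, robust: bool) -> float:
    if robust:
        med = np.median(values)
        return 1.4826 * float(np.median(np.abs(values - med)))
    return float(np.std(values))


def filter_peaks(peaks: list[Peak], n_sd: float = 3.0,
                 robust: bool = False) -> tuple[list[Peak], PeakPopulationStats]:
    """Reject too-bright (multimer) and elevated-background peaks.

    Both tests are applied to every peak: ``max_intensity`` above
    median + ``n_sd``*SD of the population marks a multimer
    (``rejected_bright``); ``min_intensity`` above its own median +
    ``n_sd``*SD marks persistent background (``rejected_dim_background``).
    SD is the plain sample standard deviation by default; set
    ``robust=True`` for a MAD-based alternative.  Fewer than 5 peaks pass
    unfiltered with a warning.  Statuses are updated in place and the same
    list is returned with the population statistics.
    """
    if len(peaks) == 0:
        return peaks, PeakPopulationStats(np.nan, np.nan, np.nan, np.nan, n_sd)
    max_ints = np.array([p.max_intensity for p in peaks])
    min_ints = np.array([p.min_intensity for p in peaks])
    stats = PeakPopulationStats(
        float(np.median(max_ints)), _sd(max_ints, robust),
        float(np.median(min_ints)), _sd(min_ints, robust), n_sd,
    )
    if len(peaks) < 5:
        warnings.warn("fewer than 5 peaks: population statistics are unreliable, "
                      "all peaks pass", stacklevel=2)
        return peaks, stats
    for p in peaks:
        if p.status != SELECTED:
            continue
        if p.max_intensity > stats.threshold_max:
            p.status = REJECTED_BRIGHT
        elif p.min_intensity > stats.threshold_min:
            p.status = REJECTED_DIM_BACKGROUND
    return peaks, stats
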