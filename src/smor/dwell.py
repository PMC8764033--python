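"""Dwell-interval extraction and exponential maximum-likelihood inference.

A bound interval (dwell) is a maximal run of bound frames in an accepted
state path.  Runs touching the first or last frame are censored -- their
true length is only bounded below -- and runs of exactly one frame are
"single-frame" events: almost certainly real binding, but with a duration
that is unresolved below the frame interval, so they are counted and
reported but excluded from the exponential fit.

The mean dwell time tau is the exponential maximum-likelihood estimate.
For uncensored dwells that is the sample mean; because events shorter
than about a frame and a half are recorded as single-frame and excluded,
the observed multi-frame dwells are left-truncated, and by the
memorylessness of the exponential the truncation-corrected MLE is the
sample mean minus the truncation point (``min_dwell``).  The pipeline
applies this correction by default; calling :func:`mle_exponential`
directly without ``min_dwell`` gives the plain closed form.

``k_off = 1 / tau``; the standard error is ``tau / sqrt(n)``; an estimate
is flagged reliable only when ``tau >= 3 * frame_interval``, since dwell
times below about three frames cannot be measured dependably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MEASURED = "measured"
SINGLE_FRAME = "single_frame"
NO_BINDING = "no_binding"


@dataclass
class DwellSet:
    """Bound-interval durations pooled over the accepted traces of a movie."""

    durations: np.ndarray     # seconds; excludes uncensored single-frame runs
    censored: np.ndarray      # bool, same length: touches movie start/end
    single_frame_count: int
    frame_interval: float
    n_traces: int = 0

    def __post_init__(self) -> None:
        self.durations = np.asarray(self.durations, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.durations.shape != self.censored.shape:
            raise ValueError("durations and censored flags must align")

    @property
    def uncensored(self) -> np.ndarray:
        return self.durations[~self.censored]

    @property
    def n_events(self) -> int:
        """All bound events seen: dwells (censored or not) plus single-frame."""
        return len(self.durations) + self.single_frame_count


@dataclass
class DwellEstimate:
    """Exponential-MLE summary of a dwell-time measurement."""

    tau: float | None
    se: float | None
    n: int
    k_off: float | None
    reliable: bool
    classification: str
    single_frame_count: int = 0
    frame_interval: float = 0.0


def bound_runs(state_path: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of bound state as ``(start_frame, length, censored)``."""
    path = np.asarray(state_path).astype(bool)
    if path.size == 0:
        return []
    padded = np.concatenate([[False], path, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    runs = []
    for s, e in zip(starts, ends):
        censored = s == 0 or e == len(path)
        runs.append((int(s), int(e - s), censored))
    return runs


def extract_dwells(fits: list, frame_interval: float) -> DwellSet:
    """Pool bound intervals from the accepted trace fits of a movie.

    Uncensored one-frame runs are tallied as single-frame events and kept
    out of the duration list; censored runs of any length are kept with
    their censoring flag.
    """
    durations: list[float] = []
    censored: list[bool] = []
    single_frame = 0
    n_traces = 0
    for fit in fits:
        if not getattr(fit, "accepted", True):
            continue
        n_traces += 1
        path = fit.state_path if hasattr(fit, "state_path") else fit
        for _, length, cens in bound_runs(path):
            if length == 1 and not cens:
                single_frame += 1
            else:
                durations.append(length * frame_interval)
                censored.append(cens)
    return DwellSet(np.asarray(durations), np.asarray(censored, dtype=bool),
                    single_frame, frame_interval, n_traces)


def mle_exponential(dwells: DwellSet, include_censored: bool = False,
                    min_dwell: float | None = None,
                    min_events: int = 2) -> DwellEstimate:
    """Exponential maximum-likelihood estimate of the mean dwell time.

    Parameters
    ----------
    include_censored : bool
        If True, censored durations contribute their observed lengths to
        the likelihood: ``tau = sum(all durations) / n_uncensored``.  By
        default censored dwells are simply dropped and ``tau`` is the
        arithmetic mean of the uncensored durations (the closed-form MLE).
    min_dwell : float, optional
        Left-truncation point of the observed dwells.  When the shortest
        observable event is ``min_dwell`` seconds (single-frame exclusion
        makes this about 1.5 frame intervals), the truncated-exponential
        MLE subtracts it from the mean.
    min_events : int
        Below this many total bound events the movie is classified
        ``no_binding`` (or ``single_frame`` if only single-frame events
        were seen) and no ``tau`` is reported.
    """
    usable = dwells.uncensored
    n = len(usable)
    if n < 2 or dwells.n_events < min_events:
        cls = SINGLE_FRAME if dwells.single_frame_count > 0 else NO_BINDING
        if n == 0 and len(dwells.durations) == 0 and dwells.single_frame_count == 0:
            cls = NO_BINDING
        return DwellEstimate(None, None, n, None, False, cls,
                             dwells.single_frame_count, dwells.frame_interval)
    if include_censored:
        tau = float(dwells.durations.sum()) / n
    else:
        tau = float(usable.mean())
    if min_dwell:
        corrected = tau - min_dwell
        if corrected <= 0:
            # degenerate: all observed dwells at the truncation floor
            corrected = dwells.frame_interval / 2.0
        tau = corrected
    se = tau / np.sqrt(n)
    reliable = tau >= 3.0 * dwells.frame_interval
    return DwellEstimate(tau, float(se), n, 1.0 / tau, bool(reliable), MEASURED,
                         dwells.single_frame_count, dwells.frame_interval)


def survival_curve(dwells: DwellSet, estimate: DwellEstimate) -> pd.DataFrame:
    """Empirical and fitted survival of the uncensored dwell distribution.

    Returns a table with the survival fraction ``S(t) = P(dwell > t)``
    evaluated at 0 and at every observed dwell, together with the fitted
    exponential ``exp(-t / tau)`` on the same grid.
    """
    if estimate.classification != MEASURED:
        raise ValueError("survival curve requires a measured dwell estimate")
    ts = np.sort(dwells.uncensored)
    n = len(ts)
    grid = np.concatenate([[0.0], ts])
    s_emp = np.concatenate([[1.0], 1.0 - (np.arange(1, n + 1)) / n])
    s_fit = np.exp(-grid / estimate.tau)
    return pd.DataFrame({"t": grid, "s_empirical": s_emp, "s_fit": s_fit})
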