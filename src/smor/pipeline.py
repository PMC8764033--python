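"""End-to-end orchestration of the dwell-time analysis pipeline.

Stage order: crop -> max/min projections -> flat-field correction ->
(optional) drift correction -> peak detection -> intensity filtering ->
trace extraction -> pooled double-Gaussian -> per-trace HMM -> RMSD
filtering -> dwell extraction -> exponential MLE -> report.  "No binding"
and "no two-state structure" are reportable outcomes, not crashes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from smor import dwell as dwell_mod
from smor import peaks as peaks_mod
from smor import preprocess as pre
from smor import traces as traces_mod
from smor.dwell import DwellEstimate, DwellSet, NO_BINDING
from smor.io import read_movie
from smor.preprocess import FlatFieldError, MovieStack
from smor.traces import DegenerateFitError, IntensityModel


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run, with defaults.

    ``drift`` is ``"auto"`` (enabled when the acquisition interval exceeds
    1 s, where stage drift becomes comparable to a PSF over the movie),
    ``"on"`` or ``"off"``.  ``truncation_correction`` subtracts the
    1.5-frame detection floor from the mean dwell (see :mod:`smor.dwell`).
    """

    crop_size: int = 300
    bin_size: int = 20
    mask_quantile: float = 0.75
    smoothing_sigma: float | None = None
    flatfield_iterations: int = 3
    camera_offset: float = 100.0
    drift: str = "auto"
    drift_segment_len: int = 50
    min_separation: int = 3
    detect_threshold: float | None = None
    peak_n_sd: float = 3.0
    robust_stats: bool = False
    rmsd_n_sd: float = 2.0
    reestimate_emissions: bool = False
    hmm_shared_sigma: bool = True
    hmm_self_transition: float = 0.95
    hmm_max_iter: int = 100
    hmm_tol: float = 1e-6
    include_censored: bool = False
    truncation_correction: bool = True
    min_events: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.drift not in ("auto", "on", "off"):
            raise ValueError("drift must be 'auto', 'on' or 'off'")
        if self.crop_size < 8:
            raise ValueError("crop_size too small")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class RunReport:
    """Per-stage counts and the final dwell estimate of one movie."""

    outcome: str                       # "ok", "no_binding", "no_two_state_structure"
    estimate: DwellEstimate | None
    n_peaks_detected: int = 0
    n_peaks_selected: int = 0
    n_rejected_bright: int = 0
    n_rejected_dim_background: int = 0
    n_rejected_rmsd: int = 0
    n_traces_accepted: int = 0
    n_dwells: int = 0
    n_censored: int = 0
    single_frame_count: int = 0
    drift_corrected: bool = False
    intensity_model: IntensityModel | None = None
    config: RunConfig | None = None
    dwells: DwellSet | None = None
    version: str = ""

    def __post_init__(self) -> None:
        rejected = (self.n_rejected_bright + self.n_rejected_dim_background
                    + self.n_rejected_rmsd)
        if self.n_peaks_detected and self.n_peaks_selected + rejected != self.n_peaks_detected:
            raise ValueError("peak counts are inconsistent")

    def to_dict(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "dwells"}
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2, default=_jsonable)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def analyze_movie(movie: MovieStack | str | Path, config: RunConfig | None = None,
                  frame_interval: float | None = None) -> RunReport:
    """Run the full dwell-time analysis on one movie.

    ``movie`` may be a :class:`MovieStack` or a path to a TIFF (in which
    case ``frame_interval`` must be given).  Returns a :class:`RunReport`;
    movies with no detectable binding or no two-state intensity structure
    yield the corresponding outcome instead of raising.
    """
    if config is None:
        config = RunConfig()
    from smor import __version__

    if not isinstance(movie, MovieStack):
        movie = read_movie(movie, frame_interval=frame_interval)
    if movie.n_frames < 2:
        raise ValueError("need at least 2 frames to analyze binding kinetics")

    def empty_report(outcome: str, **counts) -> RunReport:
        est = DwellEstimate(None, None, 0, None, False, NO_BINDING, 0,
                            movie.frame_interval)
        return RunReport(outcome=outcome, estimate=est, config=config,
                         version=__version__, **counts)

    # --- stage 1: crop + projections -------------------------------------
    size = min(config.crop_size, movie.shape[1], movie.shape[2])
    cropped = pre.crop_center(movie, size)
    max_proj = pre.project(cropped, "max")

    # --- stage 2: flat-field correction ----------------------------------
    try:
        filt = pre.build_flatfield(
            max_proj, bin_size=config.bin_size,
            smoothing_sigma=config.smoothing_sigma,
            mask_quantile=config.mask_quantile,
            camera_offset=config.camera_offset,
            n_iter=config.flatfield_iterations,
        )
    except FlatFieldError:
        return empty_report("no_binding")
    corrected = pre.apply_flatfield(cropped, filt, config.camera_offset)

    # --- stage 3: drift correction (long acquisition intervals) ----------
    drift_on = config.drift == "on" or (
        config.drift == "auto" and movie.frame_interval > 1.0
    )
    drift_applied = False
    if drift_on and corrected.n_frames >= 2 * config.drift_segment_len:
        track = pre.estimate_drift(corrected, config.drift_segment_len)
        corrected = pre.apply_drift(corrected, track, config.camera_offset)
        drift_applied = True

    max_proj_c = pre.project(corrected, "max")
    min_proj_c = pre.project(corrected, "min")

    # --- stage 4: peak detection and intensity filtering ------------------
    peaks = peaks_mod.detect_peaks(max_proj_c, min_proj_c,
                                   min_separation=config.min_separation,
                                   detect_threshold=config.detect_threshold)
    n_detected = len(peaks)
    if n_detected == 0:
        return empty_report("no_binding", drift_corrected=drift_applied)
    peaks, _ = peaks_mod.filter_peaks(peaks, n_sd=config.peak_n_sd,
                                      robust=config.robust_stats)
    selected = [p for p in peaks if p.selected]
    if not selected:
        return empty_report(
            "no_binding", n_peaks_detected=n_detected,
            n_rejected_bright=sum(p.status == peaks_mod.REJECTED_BRIGHT for p in peaks),
            n_rejected_dim_background=sum(
                p.status == peaks_mod.REJECTED_DIM_BACKGROUND for p in peaks),
            drift_corrected=drift_applied,
        )

    # --- stage 5: traces, pooled double Gaussian, HMM, RMSD filter --------
    trace_list = [traces_mod.extract_trace(corrected, p) for p in selected]
    try:
        model = traces_mod.fit_double_gaussian(trace_list)
    except DegenerateFitError:
        return empty_report(
            "no_two_state_structure", n_peaks_detected=n_detected,
            n_peaks_selected=len(selected),
            n_rejected_bright=sum(p.status == peaks_mod.REJECTED_BRIGHT for p in peaks),
            n_rejected_dim_background=sum(
                p.status == peaks_mod.REJECTED_DIM_BACKGROUND for p in peaks),
            drift_corrected=drift_applied,
        )
    fits = [traces_mod.fit_hmm(t, model,
                               reestimate_emissions=config.reestimate_emissions,
                               self_transition=config.hmm_self_transition,
                               max_iter=config.hmm_max_iter, tol=config.hmm_tol,
                               shared_sigma=config.hmm_shared_sigma)
            for t in trace_list]
    fits = traces_mod.filter_traces_by_rmsd(fits, n_sd=config.rmsd_n_sd)
    accepted = [f for f in fits if f.accepted]

    # --- stage 6: dwell extraction and exponential MLE --------------------
    dwells = dwell_mod.extract_dwells(accepted, corrected.frame_interval)
    min_dwell = 1.5 * corrected.frame_interval if config.truncation_correction else None
    estimate = dwell_mod.mle_exponential(dwells,
                                         include_censored=config.include_censored,
                                         min_dwell=min_dwell,
                                         min_events=config.min_events)

    outcome = "ok" if estimate.classification == dwell_mod.MEASURED else estimate.classification
    return RunReport(
        outcome=outcome,
        estimate=estimate,
        n_peaks_detected=n_detected,
        n_peaks_selected=len(selected) - sum(not f.accepted for f in fits),
        n_rejected_bright=sum(p.status == peaks_mod.REJECTED_BRIGHT for p in peaks),
        n_rejected_dim_background=sum(
            p.status == peaks_mod.REJECTED_DIM_BACKGROUND for p in peaks),
        n_rejected_rmsd=sum(not f.accepted for f in fits),
        n_traces_accepted=len(accepted),
        n_dwells=len(dwells.durations),
        n_censored=int(dwells.censored.sum()),
        single_frame_count=dwells.single_frame_count,
        drift_corrected=drift_applied,
        intensity_model=model,
        config=config,
        dwells=dwells,
        version=__version__,
    )
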