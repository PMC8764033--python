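"""Shared fixtures: one moderately sized simulated movie and its analysis.

The movie is rendered once per session and reused read-only by the
detection, trace and pipeline tests; anything that mutates state builds
its own copy.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from smor import preprocess as pre
from smor import peaks as pk
from smor import traces as tr
from smor.simulate import SimConfig, render_movie

CAMERA_OFFSET = 100.0


@pytest.fixture(scope="session")
def analysis_sim():
    """A 200 px / 600 frame movie with 100 sites, multimers and stuck ligand."""
    cfg = SimConfig(
        image_size=200, n_frames=600, frame_interval=0.1, n_sites=100,
        tau_bound=0.5, tau_unbound=10.0, min_separation=7.0,
        multimer_fraction=0.05, stuck_fraction=0.03, seed=11,
    )
    movie, truth = render_movie(cfg)
    return cfg, movie, truth


@pytest.fixture(scope="session")
def analysis_products(analysis_sim):
    """Corrected projections, filtered peaks, pooled model and HMM fits."""
    cfg, movie, truth = analysis_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        max_proj = pre.project(movie, "max")
        filt = pre.build_flatfield(max_proj, camera_offset=CAMERA_OFFSET)
        corrected = pre.apply_flatfield(movie, filt, CAMERA_OFFSET)
        max_c = pre.project(corrected, "max")
        min_c = pre.project(corrected, "min")
        peaks = pk.detect_peaks(max_c, min_c)
        peaks, stats = pk.filter_peaks(peaks)
        selected = [p for p in peaks if p.selected]
        traces = [tr.extract_trace(corrected, p) for p in selected]
        model = tr.fit_double_gaussian(traces)
        fits = [tr.fit_hmm(t, model) for t in traces]
        fits = tr.filter_traces_by_rmsd(fits)
    return {
        "config": cfg,
        "truth": truth,
        "corrected": corrected,
        "max_proj": max_c,
        "min_proj": min_c,
        "peaks": peaks,
        "stats": stats,
        "traces": traces,
        "model": model,
        "fits": fits,
    }


def nearest_site(truth, x, y):
    """Index and distance of the ground-truth site closest to (x, y)."""
    d = np.hypot(truth.positions[:, 0] - x, truth.positions[:, 1] - y)
    i = int(np.argmin(d))
    return i, float(d[i])
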