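"""Diagnostic figures: peak overlays, idealized traces, dwell survival."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_peak_overlay(max_proj, peaks, ax=None):
    """Max projection with selected peaks in red, rejected in blue."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    img = max_proj.image
    ax.imshow(img, cmap="gray", vmax=np.quantile(img, 0.999))
    for p in peaks:
        color = "red" if p.selected else "blue"
        ax.add_patch(plt.Circle((p.x, p.y), 4, fill=False, color=color, lw=0.8))
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    return ax


def plot_trace(fit, model, ax=None):
    """Intensity trace with the idealized two-level HMM path overlaid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    t = np.arange(len(fit.trace.intensities)) * fit.trace.frame_interval
    means = np.array([model.mu_unbound, model.mu_bound])
    color = "red" if fit.accepted else "blue"
    ax.plot(t, fit.trace.intensities, color=color, lw=0.5)
    ax.plot(t, means[fit.state_path], color="black", lw=1.2)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("intensity (counts)")
    ax.set_title(f"peak ({fit.peak.x}, {fit.peak.y})  RMSD {fit.rmsd:.1f}"
                 + ("" if fit.accepted else "  [rejected]"))
    return ax


def plot_survival(curve, estimate, ax=None):
    """Empirical dwell survival with the fitted exponential overlay."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.step(curve["t"], curve["s_empirical"], where="post", label="data")
    ax.plot(curve["t"], curve["s_fit"], "r-",
            label=f"exp fit, tau = {estimate.tau:.3g} s")
    ax.set_xlabel("dwell time (s)")
    ax.set_ylabel("survival fraction")
    ax.legend()
    return ax
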