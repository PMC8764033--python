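"""Equilibrium binding analysis of fluorescence-anisotropy titrations.

A fixed, trace concentration of fluorescent peptide (typically 10 nM) is
titrated with increasing binding protein; the anisotropy ``r`` rises from
the free-probe value ``r_free`` toward the bound value ``r_bound`` as the
probe is complexed.  Because the probe is far below the K_D, free protein
is approximately total protein and the one-site binding isotherm is the
hyperbola

    r([P]) = r_free + (r_bound - r_free) * [P] / (K_D + [P]).

An exact quadratic ligand-depletion form is available for cases where the
probe concentration is not negligible.  Competition-format experiments
(an unlabeled second degron added at constant concentration) are compared
by the fold change of the apparent K_D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class Titration:
    """One anisotropy titration: protein concentrations vs anisotropy."""

    protein_concentrations: np.ndarray   # molar, strictly increasing
    anisotropy_values: np.ndarray
    se: np.ndarray | None = None         # per-point standard error
    probe_concentration: float = 10e-9   # molar
    competitor: tuple[str, float] | None = None  # (name, molar)

    def __post_init__(self) -> None:
        self.protein_concentrations = np.asarray(self.protein_concentrations, float)
        self.anisotropy_values = np.asarray(self.anisotropy_values, float)
        c = self.protein_concentrations
        if np.any(c < 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be >= 0 and strictly increasing")
        if not np.all(np.isfinite(self.anisotropy_values)):
            raise ValueError("anisotropy values must be finite")
        if len(c) != len(self.anisotropy_values):
            raise ValueError("concentrations and values must align")


@dataclass
class BindingFit:
    """One-site equilibrium binding fit of a titration."""

    k_d: float
    r_free: float
    r_bound: float
    k_d_se: float
    r_free_se: float
    r_bound_se: float
    saturation_reached: bool
    significant_binding: bool = True

    def __post_init__(self) -> None:
        if self.significant_binding and self.k_d <= 0:
            raise ValueError("K_D must be positive")


def one_site(p: np.ndarray, k_d: float, r_free: float, r_bound: float) -> np.ndarray:
    """Hyperbolic one-site isotherm (free protein ~ total protein)."""
    return r_free + (r_bound - r_free) * p / (k_d + p)


def one_site_depletion(p: np.ndarray, k_d: float, r_free: float,
                       r_bound: float, probe: float) -> np.ndarray:
    """Exact quadratic isotherm accounting for probe depletion."""
    s = p + probe + k_d
    frac = (s - np.sqrt(s**2 - 4.0 * p * probe)) / (2.0 * probe)
    return r_free + (r_bound - r_free) * frac


def fit_one_site(t: Titration, depletion: bool = False) -> BindingFit:
    """Least-squares one-site binding fit of a titration.

    Endpoints ``r_free`` and ``r_bound`` are fitted along with ``K_D``.
    ``saturation_reached`` is set when the top concentration is at least
    5x the fitted K_D; unsaturated fits are still returned but their K_D
    is only loosely constrained.  A flat titration (fitted amplitude
    indistinguishable from noise, or K_D far beyond the titrated range)
    is reported with ``significant_binding=False``.
    """
    p = t.protein_concentrations
    r = t.anisotropy_values
    if len(p) < 5:
        raise ValueError("need at least 5 titration points")
    span = float(r.max() - r.min())
    p0 = [max(np.median(p), 1e-12), float(r[0]), float(r[-1]) + 0.1 * span]
    if depletion:
        def f(pp, kd, rf, rb):
            return one_site_depletion(pp, kd, rf, rb, t.probe_concentration)
    else:
        f = one_site
    sigma = t.se if t.se is not None and np.all(np.asarray(t.se) > 0) else None
    bounds = ([1e-15, -np.inf, -np.inf], [np.inf, np.inf, np.inf])
    try:
        popt, pcov = curve_fit(f, p, r, p0=p0, sigma=sigma, bounds=bounds,
                               maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"one-site binding fit did not converge: {exc}") from exc
    kd, r_free, r_bound = (float(v) for v in popt)
    ses = np.sqrt(np.clip(np.diag(pcov), 0, None))
    noise = float(np.mean(t.se)) if t.se is not None else max(1e-12, 0.02 * span)
    amplitude = r_bound - r_free
    significant = amplitude > 3.0 * noise and kd < 100.0 * p.max()
    saturation = bool(p.max() >= 5.0 * kd)
    if not significant:
        warnings.warn("no significant binding detected in titration", stacklevel=2)
    return BindingFit(kd, r_free, r_bound, float(ses[0]), float(ses[1]),
                      float(ses[2]), saturation, significant)


def compare_competition(fit_alone: BindingFit, fit_with: BindingFit) -> float:
    """Fold change in apparent K_D caused by an unlabeled competitor.

    Returns ``K_D(alone) / K_D(with competitor)``; values above 1 mean the
    competitor *improves* apparent affinity (allosteric enhancement).
    """
    if not (fit_alone.significant_binding and fit_with.significant_binding):
        raise ValueError("both fits must show significant binding")
    return fit_alone.k_d / fit_with.k_d


def default_concentrations(top: float = 30.6e-6, n: int = 12) -> np.ndarray:
    """Two-fold dilution series from ``top`` downward (ascending order)."""
    return top / (2.0 ** np.arange(n))[::-1]


def simulate_titration(k_d: float, r_free: float = 0.06, r_bound: float = 0.20,
                       concentrations: np.ndarray | None = None,
                       noise_sd: float = 0.004, n_reads: int = 10,
                       seed: int = 0, probe_concentration: float = 10e-9,
                       depletion: bool = False) -> Titration:
    """Synthetic titration: one-site curve plus per-read Gaussian noise.

    Each reaction is read ``n_reads`` times with independent noise of SD
    ``noise_sd``; the recorded value is the mean of the reads and the
    per-point SE is ``noise_sd / sqrt(n_reads)``.
    """
    if k_d <= 0:
        raise ValueError("K_D must be positive")
    rng = np.random.default_rng(seed)
    p = default_concentrations() if concentrations is None else np.asarray(concentrations, float)
    if depletion:
        truth = one_site_depletion(p, k_d, r_free, r_bound, probe_concentration)
    else:
        truth = one_site(p, k_d, r_free, r_bound)
    if noise_sd > 0:
        reads = truth[:, None] + rng.normal(0.0, noise_sd, size=(len(p), n_reads))
        values = reads.mean(axis=1)
    else:
        values = truth.copy()
    se = np.full(len(p), noise_sd / np.sqrt(n_reads))
    return Titration(p, values, se, probe_concentration)
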