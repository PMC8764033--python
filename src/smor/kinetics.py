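"""Kinetic and equilibrium constants derived from dwell-time measurements.

The reciprocal of the mean dwell time is the dissociation rate constant,
``k_off = 1 / tau``.  Combining a single-molecule ``k_off`` with an
equilibrium ``K_D`` from an ensemble titration gives the association rate
``k_on = k_off / K_D``; conversely, when ``k_on`` can be assumed equal
between two receptor variants, an unmeasurably tight ``K_D`` can be
inferred from the measured off-rate as ``K_D = k_off / k_on``.  Fold
ratios of dwell times quantify activator specificity.

Reported values follow the usual conventions of the field: k_off to two
significant figures, inferred k_on and K_D to one; stored values keep
full precision and rounding is presentation-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor, log10

import pandas as pd

from smor.dwell import DwellEstimate, MEASURED, NO_BINDING, SINGLE_FRAME

MEASURED_SMOR = "measured_smor"
MEASURED_ANISOTROPY = "measured_anisotropy"
INFERRED = "inferred"


def round_sig(x: float, sig_figs: int) -> float:
    """Round to ``sig_figs`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, -int(floor(log10(abs(x)))) + (sig_figs - 1))


def infer_kon(k_off: float, k_d: float) -> float:
    """Association rate constant ``k_on = k_off / K_D`` (M^-1 s^-1)."""
    if k_off <= 0 or k_d <= 0:
        raise ValueError("k_off and K_D must be positive")
    return k_off / k_d


def infer_kd(k_off: float, k_on: float) -> float:
    """Equilibrium dissociation constant ``K_D = k_off / k_on`` (M)."""
    if k_off <= 0 or k_on <= 0:
        raise ValueError("k_off and k_on must be positive")
    return k_off / k_on


def fold_ratio(tau_a: float, tau_b: float, sig_figs: int | None = None) -> float:
    """Ratio ``tau_a / tau_b``, optionally rounded to significant figures."""
    if tau_a <= 0 or tau_b <= 0:
        raise ValueError("dwell times must be positive")
    r = tau_a / tau_b
    return round_sig(r, sig_figs) if sig_figs else r


@dataclass
class KineticsRecord:
    """One ligand-receptor entry of a kinetics summary table.

    ``kon_transferred`` marks records whose ``K_D`` (or ``k_on``) was
    inferred under the explicit assumption that the association rate is
    shared with another receptor variant -- never a silent default.
    """

    ligand: str
    receptor: str
    tau: float | None = None          # seconds
    se: float | None = None
    k_off: float | None = None        # s^-1
    k_on: float | None = None         # M^-1 s^-1
    k_d: float | None = None          # M
    provenance: str = MEASURED_SMOR
    classification: str = MEASURED
    kon_transferred: bool = False

    def __post_init__(self) -> None:
        if self.tau is not None and self.k_off is None:
            self.k_off = 1.0 / self.tau
        if None not in (self.k_off, self.k_on, self.k_d):
            if abs(self.k_d * self.k_on - self.k_off) / self.k_off > 1e-9:
                raise ValueError("inconsistent record: K_D * k_on != k_off")

    @classmethod
    def from_estimate(cls, ligand: str, receptor: str,
                      estimate: DwellEstimate) -> "KineticsRecord":
        return cls(ligand=ligand, receptor=receptor, tau=estimate.tau,
                   se=estimate.se, k_off=estimate.k_off,
                   classification=estimate.classification)

    def with_inferred_kd(self, k_on: float, transferred: bool = True) -> "KineticsRecord":
        """New record with ``K_D`` inferred from this record's off-rate."""
        if self.k_off is None:
            raise ValueError("cannot infer K_D without a measured k_off")
        return KineticsRecord(self.ligand, self.receptor, self.tau, self.se,
                              self.k_off, k_on, infer_kd(self.k_off, k_on),
                              provenance=INFERRED,
                              classification=self.classification,
                              kon_transferred=transferred)

    def format_cell(self, sig_figs: int = 3) -> str:
        if self.classification == SINGLE_FRAME:
            return "SF"
        if self.classification == NO_BINDING or self.tau is None:
            return "No binding"
        return f"{round_sig(self.tau, sig_figs):g} s"


def build_summary_table(records: list[KineticsRecord],
                        sig_figs: int = 3) -> pd.DataFrame:
    """Ligand x receptor matrix of dwell times in report format.

    Measured entries render as seconds; single-frame-only entries as
    ``SF``; undetectable ones as ``No binding``.  Duplicate
    (ligand, receptor) pairs are rejected.
    """
    if not records:
        return pd.DataFrame()
    seen = set()
    for r in records:
        key = (r.ligand, r.receptor)
        if key in seen:
            raise ValueError(f"duplicate entry for {key}")
        seen.add(key)
    ligands = list(dict.fromkeys(r.ligand for r in records))
    receptors = list(dict.fromkeys(r.receptor for r in records))
    table = pd.DataFrame(index=ligands, columns=receptors, dtype=object)
    for r in records:
        table.loc[r.ligand, r.receptor] = r.format_cell(sig_figs)
    table.index.name = "ligand"
    return table
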