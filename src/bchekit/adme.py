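"""Closed-form ADME and bioanalytical calculators.

Caco-2 apparent permeability with withdrawal/replacement mass-balance
correction, efflux ratio, brain-to-plasma partitioning, solubility unit
conversion, LC-MS/MS matrix-effect QC metrics, and the novel-object
discrimination index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError

__all__ = [
    "PermeabilityExperiment",
    "PappResult",
    "BioanalyticalQC",
    "apparent_permeability",
    "efflux_ratio",
    "brain_plasma_ratio",
    "aggregate_ratios",
    "solubility_to_millimolar",
    "matrix_effect_metrics",
    "discrimination_index",
]

# default Caco-2 geometry: Millicell insert, apical 400 uL / basolateral 800 uL
DEFAULT_AREA_CM2 = 0.7
DEFAULT_C0_UM = 100.0


@dataclass
class PermeabilityExperiment:
    """One directional Caco-2 transport run.

    ``sample_times`` in minutes; ``acceptor_concs`` the concentration (uM)
    measured in each withdrawn sample; when ``replacement`` is on, every
    withdrawal of ``withdrawal_volume`` uL is replaced by blank buffer, which
    dilutes the acceptor compartment and must be corrected for in the
    cumulative transported amount.
    """

    direction: str                      # "A->B" or "B->A"
    donor_conc_C0: float                # uM
    membrane_area: float                # cm^2
    acceptor_volume: float              # uL
    donor_volume: float                 # uL
    sample_times: np.ndarray            # min
    acceptor_concs: np.ndarray          # uM
    withdrawal_volume: float = 0.0      # uL
    replacement: bool = True
    sink_violation: bool = False

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        self.acceptor_concs = np.asarray(self.acceptor_concs, dtype=float)
        if self.direction not in ("A->B", "B->A"):
            raise InputError("direction must be 'A->B' or 'B->A'")
        if self.sample_times.shape != self.acceptor_concs.shape:
            raise InputError("sample_times and acceptor_concs must have equal length")
        if np.any(np.diff(self.sample_times) <= 0):
            raise InputError("sample_times must be strictly increasing")
        if np.any(self.acceptor_concs < 0):
            raise InputError("acceptor concentrations must be nonnegative")
        if self.withdrawal_volume >= self.acceptor_volume:
            raise InputError("withdrawal_volume must be smaller than acceptor_volume")
        for name in ("donor_conc_C0", "membrane_area", "acceptor_volume", "donor_volume"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")


@dataclass
class PappResult:
    """Apparent permeability coefficient and the quality of its flux regression."""

    papp: float          # nm/s
    direction: str
    r_squared: float
    sink_ok: bool = True


@dataclass(frozen=True)
class BioanalyticalQC:
    """Mean detector responses of the three spike sets used for assay validation.

    set A: analyte in pure reconstitution solvent; set B: blank matrix spiked
    after extraction; set C: blank matrix spiked before extraction.
    """

    set_A: float
    set_B: float
    set_C: float

    def __post_init__(self) -> None:
        if min(self.set_A, self.set_B, self.set_C) <= 0:
            raise InputError("all QC set means must be positive")


def cumulative_transported(exp: PermeabilityExperiment) -> np.ndarray:
    """Cumulative amount (pmol) in the acceptor at each sample time.

    Q_k = V * C_k + sum_{j<k} v_w * C_j : the amount currently in the
    compartment plus everything carried away by earlier withdrawals
    (replacement with blank assumed).  Without replacement the compartment
    volume itself shrinks after each withdrawal.
    """
    C = exp.acceptor_concs
    vw = exp.withdrawal_volume
    if exp.replacement or vw == 0:
        removed = np.concatenate([[0.0], np.cumsum(vw * C[:-1])])
        return exp.acceptor_volume * C + removed
    volumes = exp.acceptor_volume - vw * np.arange(C.size)
    if np.any(volumes <= 0):
        raise InputError("withdrawals exhaust the acceptor compartment")
    removed = np.concatenate([[0.0], np.cumsum(vw * C[:-1])])
    return volumes * C + removed


def apparent_permeability(
    exp: PermeabilityExperiment,
    correct_withdrawal: bool = True,
    sample_subset: slice | None = None,
    sink_threshold: float = 0.10,
) -> PappResult:
    """Papp = (dQ/dt) / (A * C0), reported in nm/s.

    dQ/dt is the least-squares slope of cumulative transported amount versus
    time over all samples (or a configured subset).  When
    ``correct_withdrawal`` is off the raw compartment amount ``V * C_k`` is
    regressed instead, underestimating the flux whenever samples were
    withdrawn.
    """
    if exp.sample_times.size < 3:
        raise InputError("need at least 3 samples for the flux regression")
    if np.max(exp.acceptor_concs) > sink_threshold * exp.donor_conc_C0:
        warnings.warn(
            "sink condition violated: acceptor concentration exceeds "
            f"{sink_threshold:.0%} of the donor concentration", stacklevel=2,
        )
        sink_ok = False
    else:
        sink_ok = True

    Q = cumulative_transported(exp) if correct_withdrawal else exp.acceptor_volume * exp.acceptor_concs
    t_s = exp.sample_times * 60.0
    if sample_subset is not None:
        Q, t_s = Q[sample_subset], t_s[sample_subset]
    A = np.vstack([t_s, np.ones(t_s.size)]).T
    coef, res, *_ = np.linalg.lstsq(A, Q, rcond=None)
    slope = float(coef[0])  # pmol/s
    if np.any(np.diff(Q) < -1e-9 * max(Q.max(), 1.0)):
        warnings.warn("cumulative transported amount is non-monotone", stacklevel=2)
    ss_tot = float(np.sum((Q - Q.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - (float(res[0]) if res.size else 0.0) / ss_tot
    # pmol/s / (cm^2 * pmol/uL) = uL/(s cm^2) = 1e-3 cm/s = 1e4 nm/s
    papp = max(slope, 0.0) / (exp.membrane_area * exp.donor_conc_C0) * 1e4
    return PappResult(papp=papp, direction=exp.direction, r_squared=r2, sink_ok=sink_ok)


def efflux_ratio(papp_BA: float, papp_AB: float) -> float:
    """ER = Papp(B->A) / Papp(A->B); ER >> 1 indicates active efflux."""
    if papp_AB <= 0 or papp_BA < 0:
        raise InputError("Papp(A->B) must be positive and Papp(B->A) nonnegative")
    return papp_BA / papp_AB


def brain_plasma_ratio(brain_conc: float, plasma_conc: float) -> float:
    """Brain (ng/g) over plasma (ng/mL) concentration, 1 g ~ 1 mL convention."""
    if plasma_conc <= 0:
        raise InputError("plasma concentration must be positive")
    if brain_conc < 0:
        raise InputError("brain concentration must be nonnegative")
    return brain_conc / plasma_conc


def aggregate_ratios(ratios) -> tuple[float, float]:
    """Mean and standard error of per-animal ratios."""
    r = np.asarray(ratios, dtype=float)
    if r.size < 2:
        raise InputError("need at least two animals to aggregate")
    return float(r.mean()), float(r.std(ddof=1) / math.sqrt(r.size))


def solubility_to_millimolar(solubility_mg_per_ml: float, molecular_weight: float) -> float:
    """Convert mg/mL to mM: mM = 1000 * (mg/mL) / MW(g/mol)."""
    if molecular_weight <= 0:
        raise InputError("molecular weight must be positive")
    if solubility_mg_per_ml < 0:
        raise InputError("solubility must be nonnegative")
    return 1000.0 * solubility_mg_per_ml / molecular_weight


def matrix_effect_metrics(qc: BioanalyticalQC) -> dict[str, float]:
    """Matrix effect ME = B/A - 1, recovery RE = C/B, process efficiency PE = C/A."""
    return {
        "ME": qc.set_B / qc.set_A - 1.0,
        "RE": qc.set_C / qc.set_B,
        "PE": qc.set_C / qc.set_A,
    }


def discrimination_index(explore_familiar_EA: float, explore_novel_EC: float) -> float:
    """DI = (EC - EA) / (EA + EC) x 100; zero means no novelty preference.

    Animals with total exploration under 5 s are excluded upstream of this
    calculation.
    """
    EA, EC = explore_familiar_EA, explore_novel_EC
    if EA < 0 or EC < 0:
        raise InputError("exploration times must be nonnegative")
    if EA + EC == 0:
        raise InputError("total exploration time must be positive")
    return (EC - EA) / (EA + EC) * 100.0
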