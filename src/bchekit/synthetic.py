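"""Synthetic-data generators: each one is the exact inverse partner of an
analyzer, so noiseless generate -> analyze round-trips are identities.

The kinetics generator reproduces the UV/vis progress-curve design used to
characterize the inhibitors: duplicate 10-min reads of 50 uM
butyrylthiocholine hydrolyzed by 0.5 nM hBChE at inhibitor concentrations
0/10/20/50/100/200 nM.  The dose-response generator emulates the triplicate
endpoint Ellman screen (500 uM substrate, 8-point half-log dilution) and the
Caco-2 generator the bidirectional transport protocol with seven 20-min
samples and withdrawal/replacement dilution.

Noise is additive Gaussian on the recorded signal; magnitudes default to
0.5% of the plateau signal for kinetics, 3 RA points for dose-response and
2% of the donor concentration for Caco-2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .adme import DEFAULT_AREA_CM2, DEFAULT_C0_UM, PermeabilityExperiment
from .dose_response import DoseResponseTable, four_pl
from .exceptions import InputError
from .kinetics import (
    MIXED_SCHEME,
    AssayConditions,
    KineticParams,
    ProgressCurve,
    ProgressCurveSet,
    SchemeSpec,
    product_to_absorbance,
    simulate_progress,
)

__all__ = [
    "NoiseSpec",
    "generate_progress_set",
    "generate_dose_response",
    "generate_caco2",
    "TRUTH_SETS",
    "FIG_DESIGN_INHIBITOR_NM",
    "half_log_dilution",
]

#: Inhibitor concentrations (nM) of the reference progress-curve design.
FIG_DESIGN_INHIBITOR_NM = (0.0, 10.0, 20.0, 50.0, 100.0, 200.0)

#: Reference ground-truth parameter sets for simulation studies.  Ki values
#: (nM) are those measured for the characterized BChE inhibitors on purified
#: recombinant and on full-plasma hBChE; Km, kcat, Kp and Kii are
#: representative of hBChE/butyrylthiocholine Ellman kinetics, chosen so the
#: uninhibited 50 uM curve plateaus within the 10-min read.  ``toy`` is a
#: round-number set for documentation and oracle tests.
TRUTH_SETS: dict[str, KineticParams] = {
    "compound-2-purified": KineticParams(Km=22.0, kcat=800.0, Kp=100.0, Ki=10.2, Kii=30.0),
    "s-plus-3-purified": KineticParams(Km=22.0, kcat=800.0, Kp=100.0, Ki=14.9, Kii=45.0),
    "r-minus-3-purified": KineticParams(Km=22.0, kcat=800.0, Kp=100.0, Ki=6.6, Kii=20.0),
    "compound-2-plasma": KineticParams(Km=22.0, kcat=800.0, Kp=100.0, Ki=22.7, Kii=70.0),
    "s-plus-3-plasma": KineticParams(Km=22.0, kcat=800.0, Kp=100.0, Ki=52.0, Kii=160.0),
    "r-minus-3-plasma": KineticParams(Km=22.0, kcat=800.0, Kp=100.0, Ki=12.1, Kii=40.0),
    "toy": KineticParams(Km=25.0, kcat=500.0, Kp=50.0, Ki=10.0, Kii=40.0),
}


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise on the recorded signal."""

    sigma: float = 0.0
    seed: int | None = None
    kind: str = "additive-Gaussian"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise InputError("sigma must be nonnegative")
        if self.kind != "additive-Gaussian":
            raise InputError("only additive-Gaussian noise is supported")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def default_kinetics_sigma(conditions: AssayConditions) -> float:
    """0.5% of the plateau product signal (uM)."""
    return 0.005 * conditions.S0


def generate_progress_set(
    params: KineticParams,
    scheme: SchemeSpec = MIXED_SCHEME,
    conditions: AssayConditions | None = None,
    inhibitor_concs=FIG_DESIGN_INHIBITOR_NM,
    replicates: int = 2,
    noise: NoiseSpec | None = None,
    dt: float = 2.0,
    with_absorbance: bool = False,
) -> ProgressCurveSet:
    """Simulate a family of (optionally noisy) duplicate progress curves.

    Returns a ProgressCurveSet whose metadata-free truth is *params*;
    identical seeds reproduce identical datasets bit-for-bit.
    """
    conditions = conditions or AssayConditions()
    if 0.0 not in [float(c) for c in inhibitor_concs]:
        raise InputError("inhibitor_concs must include the uninhibited control (0)")
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    noise = noise or NoiseSpec(sigma=0.0)
    rng = noise.rng()
    t = np.arange(0.0, conditions.duration + dt / 2, dt)
    curves = []
    for I in inhibitor_concs:
        clean = simulate_progress(params, scheme, conditions, float(I), t)
        for r in range(replicates):
            P = clean.product.copy()
            noisy = noise.sigma > 0
            if noisy:
                P = P + rng.normal(0.0, noise.sigma, size=P.size)
            curve = ProgressCurve(
                times=t, product=P, inhibitor_conc=float(I),
                replicate_id=f"r{r + 1}", is_noisy=noisy,
            )
            if with_absorbance:
                curve = product_to_absorbance(curve, conditions)
            curves.append(curve)
    return ProgressCurveSet(conditions=conditions, curves=curves)


def half_log_dilution(top_conc_M: float, n_points: int = 8) -> np.ndarray:
    """Descending half-log (sqrt(10)) serial dilution starting at *top_conc_M*."""
    if top_conc_M <= 0 or n_points < 2:
        raise InputError("need positive top concentration and >= 2 points")
    return top_conc_M * 10.0 ** (-0.5 * np.arange(n_points))


def generate_dose_response(
    ic50_M: float,
    conc_design_M=None,
    replicates: int = 3,
    noise: NoiseSpec | None = None,
    top: float = 100.0,
    bottom: float = 0.0,
    hill: float = 1.0,
) -> DoseResponseTable:
    """Simulate replicate residual activities from a generating 4PL.

    Default design: 8-point half-log dilution centered a decade above the
    IC50, in triplicate, with 3-RA-point Gaussian noise.
    """
    if conc_design_M is None:
        conc_design_M = half_log_dilution(ic50_M * 10 ** 1.75, 8)
    conc = np.asarray(conc_design_M, dtype=float)
    noise = noise or NoiseSpec(sigma=3.0)
    rng = noise.rng()
    cs, ras, reps = [], [], []
    for c in conc:
        truth = four_pl(c, top, bottom, hill, ic50_M)
        for r in range(replicates):
            val = truth + (rng.normal(0.0, noise.sigma) if noise.sigma > 0 else 0.0)
            cs.append(c)
            ras.append(float(val))
            reps.append(r + 1)
    return DoseResponseTable(
        concentrations=np.array(cs), ra_percent=np.array(ras),
        replicate=np.array(reps),
    )


def generate_caco2(
    true_papp_nm_s: float,
    direction: str = "A->B",
    membrane_area: float = DEFAULT_AREA_CM2,
    donor_conc_C0: float = DEFAULT_C0_UM,
    acceptor_volume: float = 800.0,
    donor_volume: float = 400.0,
    withdrawal_volume: float = 160.0,
    n_samples: int = 7,
    interval_min: float = 20.0,
    noise: NoiseSpec | None = None,
) -> PermeabilityExperiment:
    """Simulate a directional Caco-2 run with withdrawal/replacement dilution.

    A constant flux J = Papp * A * C0 feeds the acceptor compartment; at each
    sample time the measured concentration reflects all earlier withdrawals
    (replaced with blank buffer), so the series honors exact mass balance and
    the analyzer's corrected regression recovers ``true_papp_nm_s`` exactly
    in the noiseless case.
    """
    if true_papp_nm_s < 0:
        raise InputError("true_papp must be nonnegative")
    if withdrawal_volume >= acceptor_volume:
        raise InputError("withdrawal_volume must be smaller than acceptor_volume")
    noise = noise if noise is not None else NoiseSpec(sigma=0.0)
    rng = noise.rng()
    # nm/s -> uL/(s cm^2): papp * 1e-4 ; flux in pmol/s
    flux = true_papp_nm_s * 1e-4 * membrane_area * donor_conc_C0
    times = interval_min * np.arange(1, n_samples + 1)
    concs = np.empty(n_samples)
    amount = 0.0  # pmol currently in the acceptor
    for k in range(n_samples):
        amount += flux * interval_min * 60.0
        c_k = amount / acceptor_volume
        concs[k] = c_k
        amount -= withdrawal_volume * c_k  # withdrawn, replaced with blank
    if noise.sigma > 0:
        # sigma is the fractional noise on each acceptor sample (0.02 = 2%)
        concs = np.clip(
            concs + rng.normal(0.0, 1.0, size=n_samples) * noise.sigma * concs,
            0.0, None,
        )
    sink_violation = bool(np.max(concs, initial=0.0) > 0.10 * donor_conc_C0)
    return PermeabilityExperiment(
        direction=direction, donor_conc_C0=donor_conc_C0,
        membrane_area=membrane_area, acceptor_volume=acceptor_volume,
        donor_volume=donor_volume, sample_times=times, acceptor_concs=concs,
        withdrawal_volume=withdrawal_volume, replacement=True,
        sink_violation=sink_violation,
    )
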