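"""Reaction scheme, rate law and progress-curve simulation for cholinesterase inhibition.

The model is mixed (competitive + uncompetitive) inhibition of an enzyme
obeying Michaelis--Menten kinetics, with the reaction product itself acting
as a competitive inhibitor and with explicit substrate depletion.  Under the
rapid-equilibrium (fast-binding) assumption the instantaneous rate is

    v = kcat * E0 * S / [ Km * (1 + I/Ki + P/Kp) + S * (1 + I/Kii) ]

with S, P in uM, inhibitor I and the inhibition constants Ki, Kii in nM, and
total enzyme E0 in nM.  A branch that is switched off in the scheme simply
drops its term from the denominator.  An explicit mass-action formulation of
the same binding topology is provided for checking the fast-binding limit
and for constructing slow-binding controls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import ConfigurationError, InputError, NumericError

__all__ = [
    "SchemeSpec",
    "KineticParams",
    "AssayConditions",
    "ProgressCurve",
    "ProgressCurveSet",
    "instantaneous_rate",
    "simulate_progress",
    "simulate_mass_action",
    "product_to_absorbance",
    "linearity_diagnostic",
    "MIXED_SCHEME",
    "COMPETITIVE_SCHEME",
    "UNCOMPETITIVE_SCHEME",
]

#: Default molar absorptivity of the thiocholine--thionitrobenzoate chromophore
#: detected at 412 nm in the Ellman assay (M^-1 cm^-1).  A conventional value;
#: exposed as configuration and never fitted.
DEFAULT_EPSILON = 14150.0

NM_TO_UM = 1e-3

# Integration tolerances: plateau detection on full-depletion curves needs
# tight control of the late, nearly-flat phase.
_RTOL = 1e-8
_ATOL = 1e-10


@dataclass(frozen=True)
class SchemeSpec:
    """Topology of the inhibition scheme.

    Parameters
    ----------
    binds_free_enzyme
        Inhibitor binds free enzyme E (competitive branch, constant ``Ki``).
    binds_es_complex
        Inhibitor binds the ES complex (uncompetitive branch, constant ``Kii``).
    product_inhibition
        Product competes with substrate on free enzyme (constant ``Kp``).
    binding_mode
        ``"rapid-equilibrium"`` (default) or ``"explicit-association"``; the
        latter requires an association rate ``k_on`` in the parameter set.
    """

    binds_free_enzyme: bool = True
    binds_es_complex: bool = True
    product_inhibition: bool = True
    binding_mode: str = "rapid-equilibrium"

    def __post_init__(self) -> None:
        if self.binding_mode not in ("rapid-equilibrium", "explicit-association"):
            raise ConfigurationError(
                f"unknown binding_mode {self.binding_mode!r}"
            )

    @property
    def has_inhibitor_branch(self) -> bool:
        return self.binds_free_enzyme or self.binds_es_complex

    def free_parameter_names(self) -> list[str]:
        """Names of the kinetic constants this scheme actually uses."""
        names = ["Km", "kcat"]
        if self.product_inhibition:
            names.append("Kp")
        if self.binds_free_enzyme:
            names.append("Ki")
        if self.binds_es_complex:
            names.append("Kii")
        return names


MIXED_SCHEME = SchemeSpec(True, True, True)
COMPETITIVE_SCHEME = SchemeSpec(True, False, True)
UNCOMPETITIVE_SCHEME = SchemeSpec(False, True, True)


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants of the scheme.

    Units: ``Km``, ``Kp`` in uM; ``kcat`` in 1/s; ``Ki``, ``Kii`` in nM;
    ``k_on`` in 1/(nM s) (only used in explicit-association mode, with
    dissociation rate ``k_on * Ki`` resp. ``k_on * Kii``).  A constant whose
    branch is off in the scheme may be ``None`` (treated as infinite).
    """

    Km: float
    kcat: float
    Kp: float | None = None
    Ki: float | None = None
    Kii: float | None = None
    k_on: float | None = None

    def __post_init__(self) -> None:
        for name in ("Km", "kcat"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ConfigurationError(f"{name} must be strictly positive and finite, got {v}")
        for name in ("Kp", "Ki", "Kii", "k_on"):
            v = getattr(self, name)
            if v is not None and not (math.isfinite(v) and v > 0):
                raise ConfigurationError(f"{name} must be strictly positive and finite or None, got {v}")

    def validate_for(self, scheme: SchemeSpec, inhibitor_used: bool = True) -> None:
        """Check every branch enabled in *scheme* has its constant."""
        if scheme.product_inhibition and self.Kp is None:
            raise ConfigurationError("product_inhibition branch enabled but Kp is absent")
        if inhibitor_used:
            if not scheme.has_inhibitor_branch:
                raise ConfigurationError(
                    "inhibitor simulated/fitted but neither binds_free_enzyme nor binds_es_complex is enabled"
                )
            if scheme.binds_free_enzyme and self.Ki is None:
                raise ConfigurationError("binds_free_enzyme branch enabled but Ki is absent")
            if scheme.binds_es_complex and self.Kii is None:
                raise ConfigurationError("binds_es_complex branch enabled but Kii is absent")
        if scheme.binding_mode == "explicit-association" and self.k_on is None:
            raise ConfigurationError("explicit-association mode requires k_on")

    def replace(self, **kwargs) -> "KineticParams":
        return replace(self, **kwargs)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "Km": self.Km, "kcat": self.kcat, "Kp": self.Kp,
            "Ki": self.Ki, "Kii": self.Kii, "k_on": self.k_on,
        }


@dataclass(frozen=True)
class AssayConditions:
    """Geometry and composition of one progress-curve experiment.

    ``S0`` initial substrate (uM), ``E0`` total enzyme (nM), ``duration`` read
    time (s), ``path_length`` optical path (cm), ``epsilon`` chromophore molar
    absorptivity (1/(M cm)).
    """

    S0: float = 50.0
    E0: float = 0.5
    duration: float = 600.0
    path_length: float = 0.05
    wavelength: float = 412.0
    epsilon: float = DEFAULT_EPSILON
    temperature_label: str = "25 C"

    def __post_init__(self) -> None:
        for name in ("S0", "E0", "duration", "path_length", "epsilon"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ConfigurationError(f"{name} must be strictly positive, got {v}")
        # catalytic assumption: enzyme trace-level relative to substrate
        if self.E0 * NM_TO_UM >= 0.01 * self.S0:
            warnings.warn(
                "E0 is >= 1% of S0; the trace-enzyme approximation is questionable",
                stacklevel=2,
            )

    def as_dict(self) -> dict:
        return {
            "S0_uM": self.S0, "E0_nM": self.E0, "duration_s": self.duration,
            "path_length_cm": self.path_length, "wavelength_nm": self.wavelength,
            "epsilon_M_cm": self.epsilon, "temperature_label": self.temperature_label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssayConditions":
        return cls(
            S0=d["S0_uM"], E0=d["E0_nM"], duration=d["duration_s"],
            path_length=d["path_length_cm"], wavelength=d.get("wavelength_nm", 412.0),
            epsilon=d.get("epsilon_M_cm", DEFAULT_EPSILON),
            temperature_label=d.get("temperature_label", ""),
        )


@dataclass
class ProgressCurve:
    """One product-formation time course at a single inhibitor concentration."""

    times: np.ndarray              # s, strictly increasing, first >= 0
    product: np.ndarray            # uM
    inhibitor_conc: float = 0.0    # nM
    absorbance: np.ndarray | None = None  # AU
    replicate_id: str = "r1"
    is_noisy: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.product = np.asarray(self.product, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.product.shape:
            raise InputError("times and product must be 1-D arrays of equal length")
        if self.times.size and (self.times[0] < 0 or np.any(np.diff(self.times) <= 0)):
            raise InputError("times must be strictly increasing with first >= 0")
        if self.inhibitor_conc < 0:
            raise InputError("inhibitor_conc must be >= 0")
        if self.absorbance is not None:
            self.absorbance = np.asarray(self.absorbance, dtype=float)
            if self.absorbance.shape != self.times.shape:
                raise InputError("absorbance must match times in length")

    @property
    def signal(self) -> np.ndarray:
        """The recorded signal: absorbance if present, else product concentration."""
        return self.absorbance if self.absorbance is not None else self.product

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ProgressCurveSet:
    """A family of progress curves sharing assay conditions (one experiment)."""

    conditions: AssayConditions
    curves: list[ProgressCurve] = field(default_factory=list)

    def validate(self) -> None:
        if not any(c.inhibitor_conc == 0 for c in self.curves):
            raise InputError("a ProgressCurveSet must contain an uninhibited (I=0) control curve")
        S0 = self.conditions.S0
        for c in self.curves:
            tol = 0.0 if not c.is_noisy else 5 * max(1e-12, float(np.std(c.product[: max(3, len(c) // 10)])))
            if np.any(c.product < -tol - 1e-9) or np.any(c.product > S0 + tol + 1e-9):
                raise InputError(
                    f"curve {c.replicate_id} at I={c.inhibitor_conc} nM has product outside [0, S0]"
                )

    @property
    def inhibitor_concs(self) -> list[float]:
        return sorted({c.inhibitor_conc for c in self.curves})

    def __iter__(self):
        return iter(self.curves)

    def __len__(self) -> int:
        return len(self.curves)


# ---------------------------------------------------------------------------
# rate law and simulators
# ---------------------------------------------------------------------------

def _denominator(S, P, I, params: KineticParams, scheme: SchemeSpec):
    """Denominator of the rapid-equilibrium rate law; array-safe in S and P."""
    km_factor = 1.0
    if scheme.binds_free_enzyme and params.Ki is not None:
        km_factor = km_factor + I / params.Ki
    if scheme.product_inhibition and params.Kp is not None:
        km_factor = km_factor + P / params.Kp
    s_factor = 1.0
    if scheme.binds_es_complex and params.Kii is not None:
        s_factor = s_factor + I / params.Kii
    return params.Km * km_factor + S * s_factor


def instantaneous_rate(
    S: float,
    P: float,
    I: float,
    params: KineticParams,
    scheme: SchemeSpec,
    E0: float,
) -> float:
    """Rapid-equilibrium rate of product formation, in uM/s.

    ``S``, ``P`` in uM; ``I`` and ``E0`` in nM.
    """
    if S < 0 or P < 0 or I < 0:
        raise InputError("concentrations must be nonnegative")
    params.validate_for(scheme, inhibitor_used=I > 0)
    if E0 <= 0:
        raise InputError("E0 must be positive")
    if scheme.binds_free_enzyme and params.Ki is not None and E0 > params.Ki / 5:
        warnings.warn(
            "E0 > Ki/5: inhibitor depletion by enzyme binding is neglected but may matter",
            stacklevel=2,
        )
    if S == 0:
        return 0.0
    vmax = params.kcat * E0 * NM_TO_UM  # uM/s
    return vmax * S / _denominator(S, P, I, params, scheme)


def simulate_progress(
    params: KineticParams,
    scheme: SchemeSpec,
    conditions: AssayConditions,
    I: float,
    t_grid: Sequence[float],
    replicate_id: str = "r1",
) -> ProgressCurve:
    """Integrate dP/dt = v(S0 - P, P, I) over *t_grid* (single stiff ODE).

    Substrate is eliminated through conservation S(t) = S0 - P(t), so mass
    balance holds exactly by construction.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise InputError("t_grid must be strictly increasing and start at 0")
    if I < 0:
        raise InputError("inhibitor concentration must be >= 0")
    params.validate_for(scheme, inhibitor_used=I > 0)
    S0 = conditions.S0
    vmax = params.kcat * conditions.E0 * NM_TO_UM

    def rhs(_t, y):
        P = min(max(y[0], 0.0), S0)
        S = S0 - P
        return [vmax * S / _denominator(S, P, I, params, scheme)]

    sol = solve_ivp(
        rhs, (0.0, float(t[-1])), [0.0], t_eval=t, method="LSODA",
        rtol=_RTOL, atol=_ATOL,
    )
    if not sol.success:
        raise NumericError(f"progress-curve integration failed: {sol.message}")
    P = np.clip(sol.y[0], 0.0, S0)
    return ProgressCurve(times=t, product=P, inhibitor_conc=I, replicate_id=replicate_id)


def simulate_mass_action(
    params: KineticParams,
    scheme: SchemeSpec,
    conditions: AssayConditions,
    I: float,
    t_grid: Sequence[float],
    fast_rate: float = 100.0,
    replicate_id: str = "r1",
    return_species: bool = False,
):
    """Explicit mass-action simulation of the full species system.

    Species: E, ES, EI, ESI, EP (uM) plus S and P.  Inhibitor binding uses
    ``k_on`` (1/(nM s)) with dissociation ``k_on*Ki`` from E and ``k_on*Kii``
    from ES; ESI is formed through ES + I.  Substrate and product binding are
    given fast rates (``fast_rate`` in 1/(uM s)) with dissociation
    ``fast_rate*Km`` resp. ``fast_rate*Kp``, so their equilibration is much
    faster than turnover and the rapid-equilibrium law is the k_on -> inf
    limit.  Free inhibitor is held constant (enzyme is trace-level).
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise InputError("t_grid must be strictly increasing and start at 0")
    if scheme.binding_mode != "explicit-association":
        raise ConfigurationError("simulate_mass_action requires binding_mode='explicit-association'")
    params.validate_for(scheme, inhibitor_used=I > 0)

    S0 = conditions.S0
    E0_uM = conditions.E0 * NM_TO_UM
    I_nM = float(I)
    kon = params.k_on * 1e3 if params.k_on is not None else 0.0  # 1/(uM s)
    I_uM = I_nM * NM_TO_UM
    koff_E = (params.k_on * params.Ki) if (scheme.binds_free_enzyme and params.k_on and params.Ki) else 0.0
    koff_ES = (params.k_on * params.Kii) if (scheme.binds_es_complex and params.k_on and params.Kii) else 0.0
    ks_on = fast_rate
    ks_off = fast_rate * params.Km
    if ks_off < 100 * params.kcat:
        # keep substrate binding quasi-equilibrated relative to turnover
        ks_on = 100 * params.kcat / params.Km
        ks_off = 100 * params.kcat
    kp_on = fast_rate if scheme.product_inhibition else 0.0
    kp_off = fast_rate * params.Kp if (scheme.product_inhibition and params.Kp) else 0.0

    bind_E = scheme.binds_free_enzyme
    bind_ES = scheme.binds_es_complex

    def rhs(_t, y):
        E, ES, EI, ESI, EP, S, P = y
        v_sb = ks_on * E * S - ks_off * ES
        v_cat = params.kcat * ES
        v_ei = (kon * E * I_uM - koff_E * EI) if bind_E else 0.0
        v_esi = (kon * ES * I_uM - koff_ES * ESI) if bind_ES else 0.0
        v_ep = kp_on * E * P - kp_off * EP
        return [
            -v_sb + v_cat - v_ei - v_ep,   # E
            v_sb - v_cat - v_esi,          # ES
            v_ei,                          # EI
            v_esi,                         # ESI
            v_ep,                          # EP
            -v_sb,                         # S
            v_cat - v_ep,                  # P
        ]

    y0 = [E0_uM, 0.0, 0.0, 0.0, 0.0, S0, 0.0]
    sol = solve_ivp(rhs, (0.0, float(t[-1])), y0, t_eval=t, method="LSODA",
                    rtol=_RTOL, atol=_ATOL)
    if not sol.success:
        raise NumericError(f"mass-action integration failed: {sol.message}")
    enzyme_total = sol.y[0] + sol.y[1] + sol.y[2] + sol.y[3] + sol.y[4]
    if np.max(np.abs(enzyme_total - E0_uM)) > 1e-6 * E0_uM + 10 * _ATOL:
        raise NumericError("enzyme conservation violated beyond tolerance")
    P = np.clip(sol.y[6], 0.0, S0)
    curve = ProgressCurve(times=t, product=P, inhibitor_conc=I_nM, replicate_id=replicate_id)
    if return_species:
        return curve, {n: sol.y[i] for i, n in enumerate(["E", "ES", "EI", "ESI", "EP", "S", "P"])}
    return curve


def product_to_absorbance(curve: ProgressCurve, conditions: AssayConditions) -> ProgressCurve:
    """Attach a Beer--Lambert absorbance trace: A = epsilon * l * P(M)."""
    if conditions.epsilon is None or conditions.epsilon <= 0:
        raise ConfigurationError("epsilon must be set and positive")
    A = conditions.epsilon * conditions.path_length * curve.product * 1e-6
    return ProgressCurve(
        times=curve.times, product=curve.product, inhibitor_conc=curve.inhibitor_conc,
        absorbance=A, replicate_id=curve.replicate_id, is_noisy=curve.is_noisy,
    )


def linearity_diagnostic(
    curve: ProgressCurve,
    early_fraction: float = 0.05,
    threshold: float = 0.02,
    S0: float | None = None,
) -> dict:
    """Quadratic-vs-linear comparison on the early reaction phase.

    Fits P = c0 + c1*t + c2*t^2 over the window where the signal change is
    below ``early_fraction`` of the total change (and below 10% substrate
    depletion when ``S0`` is known).  The statistic is the signed ratio of the
    quadratic to the linear contribution at the end of the window,
    ``c2*T^2 / (c1*T)``; fast-binding inhibitors show none
    (|statistic| < ``threshold``), a slow-binding lag shows up as a marked
    early-phase curvature.
    """
    if not 0 < early_fraction <= 1:
        raise InputError("early_fraction must be in (0, 1]")
    sig = curve.signal
    # contiguous prefix below the substrate-depletion cap
    allowed = np.ones(sig.size, bool)
    if S0 is not None:
        allowed = curve.product <= 0.10 * S0
        bad = np.flatnonzero(~allowed)
        if bad.size:
            allowed[bad[0]:] = False
    if allowed.sum() < 8:
        raise InputError(f"need >= 8 early points, got {int(allowed.sum())}")
    total = sig[-1] - sig[0]
    limit = sig[0] + early_fraction * total if total > 0 else sig[-1]
    mask = (sig <= limit) & allowed if total > 0 else allowed.copy()
    idx = np.flatnonzero(~mask)
    if idx.size:  # keep the window contiguous from t=0
        mask[idx[0]:] = False
    if mask.sum() < 8:  # widen sparse windows to the minimum point count
        mask[:] = False
        mask[np.flatnonzero(allowed)[:8]] = True
    t, y = curve.times[mask], sig[mask]
    T = t[-1] - t[0]
    coef = np.polynomial.polynomial.polyfit(t - t[0], y, 2)
    lin = coef[1] * T
    quad = coef[2] * T * T
    stat = quad / lin if lin != 0 else (0.0 if quad == 0 else np.inf)
    return {
        "statistic": float(stat),
        "label": "fast-binding" if abs(stat) < threshold else "slow-binding-suspect",
        "n_points": int(mask.sum()),
    }
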