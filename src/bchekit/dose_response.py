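"""Endpoint Ellman-assay analysis: initial velocities, residual activity,
four-parameter-logistic IC50, selectivity ratios, and mechanistic IC50
prediction from the progress-curve constants.

The endpoint screen runs at high substrate (500 uM default) with short
(2 min) reads; inhibitory potency is expressed as residual activity
RA = vi/v0 x 100% and summarized by the IC50 of a fitted 4PL,
RA(c) = bottom + (top - bottom) / (1 + (c/ic50)^hill).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ConfigurationError, InputError, NumericError
from .kinetics import (
    AssayConditions,
    KineticParams,
    ProgressCurve,
    SchemeSpec,
    simulate_progress,
)

__all__ = [
    "VelocityPair",
    "DoseResponseTable",
    "FourPLFit",
    "FourPLRegressor",
    "CensoredValue",
    "initial_velocity",
    "residual_activity",
    "fit_four_pl",
    "selectivity_ratio",
    "ic50_from_mechanism",
    "racemate_ic50",
    "four_pl",
]

#: Default endpoint-screen substrate concentration (uM) and read length (s).
ENDPOINT_S0 = 500.0
ENDPOINT_READ_S = 120.0


@dataclass(frozen=True)
class VelocityPair:
    """Matched uninhibited/inhibited initial velocities (signal per second)."""

    v0: float
    vi: float
    compound_conc: float = 0.0  # M

    def __post_init__(self) -> None:
        if self.v0 <= 0:
            raise InputError("v0 must be positive")
        if self.vi < 0:
            raise InputError("vi must be nonnegative")


@dataclass
class DoseResponseTable:
    """Replicate residual activities (%) over a serial dilution (M)."""

    concentrations: np.ndarray       # M, one entry per measurement
    ra_percent: np.ndarray           # %, same length
    replicate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.ra_percent = np.asarray(self.ra_percent, dtype=float)
        if self.concentrations.shape != self.ra_percent.shape:
            raise InputError("concentrations and ra_percent must have equal length")
        if np.any(self.concentrations <= 0):
            raise InputError("concentrations must be strictly positive")
        if not np.all(np.isfinite(self.ra_percent)):
            raise InputError("RA values must be finite")
        if np.unique(self.concentrations).size < 4:
            raise InputError("need at least 4 distinct concentrations")


@dataclass
class FourPLFit:
    """Fitted four-parameter logistic."""

    top: float
    bottom: float
    hill: float
    ic50: float                      # M
    standard_errors: dict[str, float]
    rss: float

    def __post_init__(self) -> None:
        if self.ic50 <= 0 or self.top <= self.bottom or self.hill <= 0:
            raise NumericError(
                f"invalid 4PL fit: top={self.top}, bottom={self.bottom}, "
                f"hill={self.hill}, ic50={self.ic50}"
            )

    def predict(self, conc) -> np.ndarray:
        return four_pl(conc, self.top, self.bottom, self.hill, self.ic50)

    def as_dict(self) -> dict:
        return {
            "top_percent": self.top, "bottom_percent": self.bottom,
            "hill": self.hill, "ic50_M": self.ic50,
            "standard_errors": self.standard_errors, "rss": self.rss,
        }


@dataclass(frozen=True)
class CensoredValue:
    """A bound-censored measurement, e.g. an IC50 reported as '> 100 uM'."""

    value: float
    censor: str = ">"  # ">" lower bound, "<" upper bound

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise InputError("censored value must be positive")
        if self.censor not in (">", "<"):
            raise InputError("censor must be '>' or '<'")

    def __str__(self) -> str:
        return f"{self.censor} {self.value:g}"


def four_pl(conc, top: float, bottom: float, hill: float, ic50: float):
    """Four-parameter logistic, decreasing in concentration for hill > 0."""
    c = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def initial_velocity(
    curve: ProgressCurve,
    window_s: float = ENDPOINT_READ_S,
    max_depletion: float = 0.10,
    S0: float | None = None,
) -> float:
    """Ordinary-least-squares slope of the early linear phase (signal / s).

    The window is the first ``window_s`` seconds, truncated to keep substrate
    depletion below ``max_depletion`` when ``S0`` is known; at least 5 samples
    are required.
    """
    sig = curve.signal
    mask = curve.times <= curve.times[0] + window_s
    if S0 is not None:
        depl = curve.product <= max_depletion * S0
        idx = np.flatnonzero(~depl)
        if idx.size:
            depl[idx[0]:] = False
        mask &= depl
    if mask.sum() < 5:
        raise InputError(f"initial-velocity window has {int(mask.sum())} points; need >= 5")
    t, y = curve.times[mask], sig[mask]
    A = np.vstack([t, np.ones(t.size)]).T
    slope = float(np.linalg.lstsq(A, y, rcond=None)[0][0])
    return slope


def residual_activity(pair: VelocityPair) -> float:
    """RA = vi/v0 x 100 (percent)."""
    return 100.0 * pair.vi / pair.v0


class FourPLRegressor(BaseEstimator, RegressorMixin):
    """Least-squares four-parameter logistic fit of RA(%) vs concentration.

    ``X`` is the concentration (M), shape ``(n,)`` or ``(n, 1)``; ``y`` the
    residual activity in percent.  IC50 is optimized in log space; top and
    bottom are bounded ([80, 120] and [-10, 20] by default) to stabilize
    sparse designs.

    Attributes
    ----------
    top_, bottom_, hill_, ic50_ : float
        Fitted parameters (ic50_ in M).
    fit_ : FourPLFit
        Full record with standard errors and RSS.
    """

    def __init__(
        self,
        top_bounds: tuple[float, float] = (80.0, 120.0),
        bottom_bounds: tuple[float, float] = (-10.0, 20.0),
        hill_bounds: tuple[float, float] = (0.1, 10.0),
    ):
        self.top_bounds = top_bounds
        self.bottom_bounds = bottom_bounds
        self.hill_bounds = hill_bounds

    def fit(self, X, y):
        c = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if c.size != y.size:
            raise InputError("X and y must have equal length")
        if np.any(c <= 0):
            raise InputError("concentrations must be positive")
        span = np.log10(c.max() / c.min())
        if span < 1.0:
            warnings.warn("concentration design spans less than one decade", stacklevel=2)
        if np.ptp(y) < 1e-9:
            raise NumericError("all-flat response: IC50 unidentifiable")

        # start at the concentration whose mean response is nearest midway
        uc = np.unique(c)
        means = np.array([y[c == v].mean() for v in uc])
        mid = (means.max() + means.min()) / 2
        ic50_0 = uc[np.argmin(np.abs(means - mid))]
        x0 = np.array([
            np.clip(means.max(), *self.top_bounds),
            np.clip(means.min(), *self.bottom_bounds),
            1.0,
            math.log(ic50_0),
        ])
        lb = [self.top_bounds[0], self.bottom_bounds[0], self.hill_bounds[0],
              math.log(c.min()) - math.log(1e4)]
        ub = [self.top_bounds[1], self.bottom_bounds[1], self.hill_bounds[1],
              math.log(c.max()) + math.log(1e4)]

        def resid(p):
            top, bottom, hill, logic50 = p
            return four_pl(c, top, bottom, hill, math.exp(logic50)) - y

        sol = least_squares(resid, x0, bounds=(lb, ub), method="trf",
                            x_scale="jac", ftol=1e-12, xtol=1e-12, gtol=1e-12)
        if not sol.success:
            raise NumericError(f"4PL fit failed: {sol.message}")
        top, bottom, hill, logic50 = sol.x
        rss = float(2 * sol.cost)
        n, k = y.size, 4
        stderr = {name: float("nan") for name in ("top", "bottom", "hill", "ic50")}
        if n > k:
            try:
                cov = rss / (n - k) * np.linalg.inv(sol.jac.T @ sol.jac)
                d = np.sqrt(np.clip(np.diag(cov), 0, None))
                stderr = {
                    "top": float(d[0]), "bottom": float(d[1]), "hill": float(d[2]),
                    "ic50": float(math.exp(logic50) * d[3]),
                }
            except np.linalg.LinAlgError:
                pass
        self.top_, self.bottom_ = float(top), float(bottom)
        self.hill_, self.ic50_ = float(hill), float(math.exp(logic50))
        self.fit_ = FourPLFit(self.top_, self.bottom_, self.hill_, self.ic50_, stderr, rss)
        return self

    def predict(self, X):
        check_is_fitted(self, "ic50_")
        return four_pl(np.asarray(X, dtype=float).reshape(-1),
                       self.top_, self.bottom_, self.hill_, self.ic50_)


def fit_four_pl(table: DoseResponseTable, seed: int | None = None) -> FourPLFit:
    """Fit the 4PL to a dose-response table and return the fitted record."""
    est = FourPLRegressor()
    est.fit(table.concentrations, table.ra_percent)
    return est.fit_


def selectivity_ratio(ic50_hAChE, ic50_hBChE):
    """SR = IC50(hAChE) / IC50(hBChE); censored inputs propagate as bounds."""
    if isinstance(ic50_hBChE, CensoredValue):
        raise InputError("a censored hBChE IC50 cannot yield a selectivity ratio")
    if ic50_hBChE <= 0:
        raise InputError("IC50 values must be positive")
    if isinstance(ic50_hAChE, CensoredValue):
        return CensoredValue(ic50_hAChE.value / ic50_hBChE, ic50_hAChE.censor)
    if ic50_hAChE <= 0:
        raise InputError("IC50 values must be positive")
    return ic50_hAChE / ic50_hBChE


def ic50_from_mechanism(params: KineticParams, scheme: SchemeSpec, S: float) -> float:
    """Closed-form IC50 (nM) implied by the rapid-equilibrium rate law at t=0.

    With no product present, vi/v0 = 1/2 at
    IC50 = (Km + S) / (Km/Ki + S/Kii), absent branches contributing 0.
    """
    if S <= 0:
        raise InputError("S must be positive")
    if not scheme.has_inhibitor_branch:
        raise ConfigurationError("at least one inhibitor branch must be enabled")
    params.validate_for(scheme)
    denom = 0.0
    if scheme.binds_free_enzyme:
        denom += params.Km / params.Ki
    if scheme.binds_es_complex:
        denom += S / params.Kii
    return (params.Km + S) / denom


def _mixture_velocity_ratio(c_total: float, params_R: KineticParams,
                            params_S: KineticParams, scheme: SchemeSpec, S: float) -> float:
    """v(mixture at total conc c)/v0 at t=0, each enantiomer at c/2 (nM)."""
    km_factor, s_factor = 1.0, 1.0
    for p in (params_R, params_S):
        if scheme.binds_free_enzyme:
            km_factor += (c_total / 2) / p.Ki
        if scheme.binds_es_complex:
            s_factor += (c_total / 2) / p.Kii
    v0 = S / (params_R.Km + S)
    v = S / (params_R.Km * km_factor + S * s_factor)
    return v / v0


def racemate_ic50(params_R: KineticParams, params_S: KineticParams,
                  scheme: SchemeSpec, S: float) -> float:
    """IC50 (nM, total concentration) of a 1:1 enantiomer mixture.

    The rate-law denominator extends additively with each enantiomer present
    at half the total concentration; the total concentration halving the
    uninhibited velocity is found numerically.  Requires both parameter sets
    to share Km (same enzyme and substrate).
    """
    if not scheme.has_inhibitor_branch:
        raise ConfigurationError("at least one inhibitor branch must be enabled")
    params_R.validate_for(scheme)
    params_S.validate_for(scheme)
    if not math.isclose(params_R.Km, params_S.Km, rel_tol=1e-9):
        raise ConfigurationError("enantiomer parameter sets must share Km")

    def f(c):
        return _mixture_velocity_ratio(c, params_R, params_S, scheme, S) - 0.5

    lo, hi = 1e-6, 1.0
    while f(hi) > 0:
        hi *= 10
        if hi > 1e12:
            raise NumericError("racemate IC50 bracket not found")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def simulated_ic50(
    params: KineticParams,
    scheme: SchemeSpec,
    S: float = ENDPOINT_S0,
    E0: float = 0.5,
    read_s: float = ENDPOINT_READ_S,
    tol_sf: float = 1e-4,
) -> float:
    """IC50 (nM) located by bisection on simulated early-phase velocity ratios.

    Independent of the closed form: simulates short progress curves and finds
    the inhibitor concentration where the fitted initial-velocity ratio is 0.5.
    """
    conditions = AssayConditions(S0=S, E0=E0, duration=read_s)
    t = np.linspace(0.0, read_s, 25)

    def vel(I: float) -> float:
        curve = simulate_progress(params, scheme, conditions, I, t)
        return initial_velocity(curve, window_s=read_s, S0=S)

    v0 = vel(0.0)

    def f(I):
        return vel(I) / v0 - 0.5

    lo, hi = 1e-6, 1.0
    while f(hi) > 0:
        hi *= 10
        if hi > 1e12:
            raise NumericError("simulated IC50 bracket not found")
    return float(brentq(f, lo, hi, rtol=tol_sf))
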