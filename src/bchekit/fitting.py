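"""Global nonlinear fitting of the inhibition scheme to progress-curve families.

All curves of an experiment (every inhibitor concentration, every replicate)
are fitted simultaneously by least squares on the recorded signal, with the
kinetic constants shared across curves.  Optimization runs in log-parameter
space with multistart; candidate scheme topologies are compared by AICc.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ConfigurationError, InputError, NumericError
from .kinetics import (
    AssayConditions,
    KineticParams,
    ProgressCurve,
    ProgressCurveSet,
    SchemeSpec,
    simulate_progress,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "GlobalKineticsRegressor",
    "fit_progress_set",
    "compare_schemes",
    "confidence_intervals",
    "aicc",
]

_ALL_PARAMS = ("Km", "kcat", "Kp", "Ki", "Kii")


def aicc(rss: float, n: int, k: int) -> float:
    """Corrected Akaike information criterion for a least-squares fit.

    AICc = n ln(rss/n) + 2k + 2k(k+1)/(n-k-1).
    """
    if n <= k + 1:
        raise InputError(f"AICc undefined for n={n}, k={k}")
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class FitConfig:
    """Options controlling the global fit."""

    free_parameters: tuple[str, ...] | None = None  # default: all scheme-relevant
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    log_scale: bool = True
    multistart: int = 5
    seed: int | None = None
    weighting: str = "uniform"  # uniform | per-curve

    def __post_init__(self) -> None:
        if self.multistart < 1:
            raise ConfigurationError("multistart must be >= 1")
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo < hi):
                raise ConfigurationError(f"bounds for {name} must satisfy 0 < lo < hi")
        if self.weighting not in ("uniform", "per-curve"):
            raise ConfigurationError("weighting must be 'uniform' or 'per-curve'")


@dataclass
class FitResult:
    """Outcome of a global progress-curve fit."""

    estimates: KineticParams
    standard_errors: dict[str, float]
    rss: float
    n_points: int
    n_params: int
    aicc: float
    converged: bool
    per_curve_residuals: dict[str, float]
    free_parameters: tuple[str, ...]
    warnings: list[str] = field(default_factory=list)
    scheme: SchemeSpec | None = None

    def as_dict(self) -> dict:
        return {
            "estimates": self.estimates.as_dict(),
            "standard_errors": self.standard_errors,
            "rss": self.rss,
            "n_points": self.n_points,
            "n_params": self.n_params,
            "aicc": self.aicc,
            "converged": self.converged,
            "per_curve_residuals": self.per_curve_residuals,
            "free_parameters": list(self.free_parameters),
            "warnings": self.warnings,
        }


class GlobalKineticsRegressor(BaseEstimator, RegressorMixin):
    """Shared-parameter fit of the inhibition scheme across progress curves.

    Follows the scikit-learn estimator protocol.  ``X`` is an ``(n, 2)``
    array with columns ``[time_s, inhibitor_nM]`` and ``y`` the measured
    signal (product concentration in uM, or absorbance if ``signal_scale``
    maps product to signal units); rows belonging to the same inhibitor
    concentration form one model curve, replicates are simply repeated rows.

    Parameters
    ----------
    scheme : SchemeSpec
        Binding topology to fit.
    conditions : AssayConditions
        Fixed assay geometry (S0, E0, read length).
    free_parameters : tuple of str, optional
        Subset of ``("Km", "kcat", "Kp", "Ki", "Kii")`` to optimize; default
        all constants the scheme uses.
    fixed_params : KineticParams, optional
        Values for constants held fixed (and initial fallbacks).
    signal_scale : float
        Multiplier mapping product concentration (uM) to the measured signal;
        1.0 when fitting product directly, ``epsilon * l * 1e-6`` when fitting
        absorbance.
    multistart : int
        Number of optimizer starts; the first uses heuristic initials, the
        rest log-space jitters (factor up to x/÷3).
    seed : int or None
        Seed for the jitter RNG.

    Attributes
    ----------
    params_ : KineticParams
        Fitted constants.
    result_ : FitResult
        Full fit record (uncertainties, RSS, AICc, convergence flag).
    """

    def __init__(
        self,
        scheme: SchemeSpec | None = None,
        conditions: AssayConditions | None = None,
        free_parameters: tuple[str, ...] | None = None,
        fixed_params: KineticParams | dict | None = None,
        bounds: dict | None = None,
        signal_scale: float = 1.0,
        multistart: int = 5,
        seed: int | None = None,
    ):
        self.scheme = scheme
        self.conditions = conditions
        self.free_parameters = free_parameters
        self.fixed_params = fixed_params
        self.bounds = bounds
        self.signal_scale = signal_scale
        self.multistart = multistart
        self.seed = seed

    # -- internals ---------------------------------------------------------

    def _base_dict(self) -> dict:
        """Fixed constants (and initial-value overrides) as a plain dict."""
        if self.fixed_params is None:
            return {}
        if isinstance(self.fixed_params, KineticParams):
            return self.fixed_params.as_dict()
        return dict(self.fixed_params)

    def _resolve_free(self, scheme: SchemeSpec) -> tuple[str, ...]:
        if self.free_parameters is not None:
            free = tuple(self.free_parameters)
            unknown = set(free) - set(_ALL_PARAMS)
            if unknown:
                raise ConfigurationError(f"unknown free parameters: {sorted(unknown)}")
            return free
        return tuple(scheme.free_parameter_names())

    def _default_bounds(self, name: str, initial: float) -> tuple[float, float]:
        if self.bounds and name in self.bounds:
            return self.bounds[name]
        return (initial / 1e3, initial * 1e3)

    def _heuristic_initials(self, X, y, scheme: SchemeSpec) -> dict[str, float]:
        """Rough initial constants from the uninhibited curve and early rates."""
        cond = self.conditions
        t, I = X[:, 0], X[:, 1]
        initials: dict[str, float] = {}
        base = self._base_dict()

        def early_rate(mask) -> float:
            tt, yy = t[mask], y[mask]
            order = np.argsort(tt)
            tt, yy = tt[order], yy[order]
            # average duplicate time points, use first ~10% of the read
            cut = tt <= tt[0] + 0.1 * (tt[-1] - tt[0]) + 1e-12
            if cut.sum() < 3:
                cut = np.zeros_like(tt, bool)
                cut[: max(3, tt.size // 10)] = True
            A = np.vstack([tt[cut], np.ones(cut.sum())]).T
            slope = np.linalg.lstsq(A, yy[cut], rcond=None)[0][0]
            return max(slope, 1e-12)

        m0 = I == 0
        if not m0.any():
            raise InputError("global fit requires an uninhibited (I=0) control curve")
        v0 = early_rate(m0) / self.signal_scale  # uM/s
        Km0 = base.get("Km") or cond.S0 / 2
        kcat0 = base.get("kcat") or v0 * (Km0 + cond.S0) / (cond.S0 * cond.E0 * 1e-3)
        initials["Km"] = Km0
        initials["kcat"] = max(kcat0, 1e-6)
        if scheme.product_inhibition:
            initials["Kp"] = base.get("Kp") or cond.S0
        # inhibitor concentration halving the early rate
        if scheme.has_inhibitor_branch:
            concs = sorted(set(I[I > 0]))
            ki_guess = base.get("Ki") or base.get("Kii")
            if ki_guess is None and concs:
                ratios = np.array([early_rate(I == c) for c in concs]) / (v0 * self.signal_scale)
                below = np.flatnonzero(ratios <= 0.5)
                if below.size:
                    ki_guess = concs[below[0]] / (1 + cond.S0 / Km0)
                else:
                    ki_guess = concs[-1]
                ki_guess = max(ki_guess, 1e-3)
            ki_guess = ki_guess or 10.0
            if scheme.binds_free_enzyme:
                initials["Ki"] = base.get("Ki") or ki_guess
            if scheme.binds_es_complex:
                initials["Kii"] = base.get("Kii") or 3 * ki_guess
        return initials

    def _params_from_vector(self, theta, free, fixed_dict) -> KineticParams:
        d = dict(fixed_dict)
        for name, v in zip(free, theta):
            d[name] = float(np.exp(v))
        return KineticParams(
            Km=d.get("Km"), kcat=d.get("kcat"), Kp=d.get("Kp"),
            Ki=d.get("Ki"), Kii=d.get("Kii"), k_on=d.get("k_on"),
        )

    def _predict_curves(self, params: KineticParams, grids) -> dict:
        out = {}
        for I, t in grids.items():
            curve = simulate_progress(params, self.scheme, self.conditions, I, t)
            out[I] = curve.product * self.signal_scale
        return out

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2 or X.shape[0] != y.shape[0]:
            raise InputError("X must be (n, 2) [time_s, inhibitor_nM] matching y")
        if self.scheme is None or self.conditions is None:
            raise ConfigurationError("scheme and conditions must be set before fitting")
        scheme = self.scheme
        free = self._resolve_free(scheme)
        needed = set(scheme.free_parameter_names())
        missing = needed - set(free) - {
            n for n in _ALL_PARAMS if self._base_dict().get(n) is not None
        }
        if missing:
            raise ConfigurationError(
                f"constants {sorted(missing)} are required by the scheme but neither free nor fixed"
            )

        initials = self._heuristic_initials(X, y, scheme)
        fixed_dict = {}
        base = self._base_dict()
        for name in _ALL_PARAMS:
            if name not in free:
                val = base.get(name) or initials.get(name)
                if val is not None:
                    fixed_dict[name] = val
        if base.get("k_on") is not None:
            fixed_dict["k_on"] = base["k_on"]

        # unique integration grid per inhibitor concentration
        t, I = X[:, 0], X[:, 1]
        grids: dict[float, np.ndarray] = {}
        index: dict[float, np.ndarray] = {}
        for c in np.unique(I):
            mask = I == c
            tt = np.unique(t[mask])
            if tt[0] != 0:
                tt = np.concatenate([[0.0], tt])
            grids[float(c)] = tt
            # map each row to its position in the curve grid
            index[float(c)] = np.searchsorted(tt, t[mask])

        row_order = {float(c): np.flatnonzero(I == c) for c in np.unique(I)}
        theta0 = np.log([initials[n] for n in free])
        lb = np.log([self._default_bounds(n, initials[n])[0] for n in free])
        ub = np.log([self._default_bounds(n, initials[n])[1] for n in free])
        theta0 = np.clip(theta0, lb, ub)

        def residuals(theta):
            try:
                p = self._params_from_vector(theta, free, fixed_dict)
                preds = self._predict_curves(p, grids)
            except (NumericError, ConfigurationError):
                return np.full(y.size, 1e6)
            r = np.empty(y.size)
            for c, rows in row_order.items():
                r[rows] = y[rows] - preds[c][index[c]]
            return r

        rng = np.random.default_rng(self.seed)
        best = None
        n_fail = 0
        for start in range(int(self.multistart)):
            th = theta0 if start == 0 else np.clip(
                theta0 + rng.uniform(-np.log(3), np.log(3), size=theta0.size), lb, ub
            )
            try:
                # diff_step large enough that finite differences of the ODE
                # solution are not dominated by integrator noise
                sol = least_squares(residuals, th, bounds=(lb, ub), method="trf",
                                    x_scale="jac", diff_step=1e-4,
                                    ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=2000)
            except Exception:
                n_fail += 1
                continue
            if not sol.success:
                n_fail += 1
                continue
            if best is None or sol.cost < best.cost:
                best = sol

        warns: list[str] = []
        converged = best is not None
        if best is None:
            # keep the initial point as a flagged, non-converged result
            theta_hat = theta0
            res = residuals(theta_hat)
            rss = float(res @ res)
            jac = None
            warns.append("optimizer failed to converge from all starts")
        else:
            theta_hat = best.x
            rss = float(2 * best.cost)
            res = best.fun
            jac = best.jac
            if n_fail:
                warns.append(f"{n_fail} of {self.multistart} starts failed")

        n, k = y.size, len(free)
        params_hat = self._params_from_vector(theta_hat, free, fixed_dict)

        # asymptotic standard errors via the log-space Jacobian (delta method)
        stderr = {name: float("nan") for name in free}
        if jac is not None and n > k:
            s2 = rss / (n - k)
            JTJ = jac.T @ jac
            try:
                cov_log = s2 * np.linalg.inv(JTJ)
                diag = np.clip(np.diag(cov_log), 0, None)
                for i, name in enumerate(free):
                    stderr[name] = float(np.exp(theta_hat[i]) * math.sqrt(diag[i]))
                # unidentifiability: near-singular curvature in some direction
                eigs = np.linalg.eigvalsh(JTJ)
                if eigs[0] < 1e-10 * max(eigs[-1], 1e-300):
                    warns.append("parameter combination nearly unidentifiable (flat objective direction)")
            except np.linalg.LinAlgError:
                warns.append("singular Jacobian: parameters unidentifiable from these data")

        per_curve = {}
        for c, rows in row_order.items():
            per_curve[f"I={c:g}nM"] = float(np.sum(res[rows] ** 2))

        self.params_ = params_hat
        self.rss_ = rss
        self.n_points_ = n
        self.result_ = FitResult(
            estimates=params_hat,
            standard_errors=stderr,
            rss=rss,
            n_points=n,
            n_params=k,
            aicc=aicc(max(rss, 1e-300), n, k),
            converged=converged,
            per_curve_residuals=per_curve,
            free_parameters=free,
            warnings=warns,
            scheme=scheme,
        )
        for w in warns:
            warnings.warn(w, stacklevel=2)
        return self

    def predict(self, X):
        check_is_fitted(self, "params_")
        X = np.asarray(X, dtype=float)
        t, I = X[:, 0], X[:, 1]
        out = np.empty(t.size)
        for c in np.unique(I):
            mask = I == c
            tt = np.unique(t[mask])
            grid = tt if tt[0] == 0 else np.concatenate([[0.0], tt])
            curve = simulate_progress(self.params_, self.scheme, self.conditions, float(c), grid)
            out[mask] = np.interp(t[mask], grid, curve.product * self.signal_scale)
        return out


# ---------------------------------------------------------------------------
# module-level operations on ProgressCurveSet
# ---------------------------------------------------------------------------

def set_to_xy(curve_set: ProgressCurveSet, use_absorbance: bool | None = None):
    """Stack a curve family into the ``(X, y)`` design used by the estimator."""
    if use_absorbance is None:
        use_absorbance = all(c.absorbance is not None for c in curve_set)
    rows, ys = [], []
    for c in curve_set:
        sig = c.absorbance if use_absorbance else c.product
        if sig is None:
            raise InputError(f"curve {c.replicate_id} lacks the requested signal")
        rows.append(np.column_stack([c.times, np.full(len(c), c.inhibitor_conc)]))
        ys.append(sig)
    scale = (
        curve_set.conditions.epsilon * curve_set.conditions.path_length * 1e-6
        if use_absorbance else 1.0
    )
    return np.vstack(rows), np.concatenate(ys), scale


def fit_progress_set(
    curve_set: ProgressCurveSet,
    scheme: SchemeSpec,
    config: FitConfig | None = None,
    fixed_params: KineticParams | dict | None = None,
) -> FitResult:
    """Globally fit *scheme* to every curve of *curve_set* simultaneously."""
    config = config or FitConfig()
    curve_set.validate()
    X, y, scale = set_to_xy(curve_set)
    est = GlobalKineticsRegressor(
        scheme=scheme,
        conditions=curve_set.conditions,
        free_parameters=config.free_parameters,
        fixed_params=fixed_params,
        bounds=config.bounds or None,
        signal_scale=scale,
        multistart=config.multistart,
        seed=config.seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return est.result_


def compare_schemes(
    curve_set: ProgressCurveSet,
    candidates: list[SchemeSpec],
    config: FitConfig | None = None,
    fixed_params: KineticParams | dict | None = None,
) -> tuple[list[dict], SchemeSpec]:
    """Fit each candidate topology to the same data and rank by AICc.

    Returns the ranking table (ascending AICc) and the selected scheme:
    lowest AICc, with ties (delta AICc < 2) broken toward fewer parameters.
    """
    if len(candidates) < 1:
        raise InputError("need at least one candidate scheme")
    rows = []
    for scheme in candidates:
        fit = fit_progress_set(curve_set, scheme, config, fixed_params)
        if not fit.converged:
            warnings.warn(
                f"candidate {scheme} excluded from ranking: fit did not converge",
                stacklevel=2,
            )
            continue
        rows.append({"scheme": scheme, "aicc": fit.aicc, "n_params": fit.n_params, "fit": fit})
    if not rows:
        raise NumericError("no candidate scheme converged")
    rows.sort(key=lambda r: r["aicc"])
    best_aicc = rows[0]["aicc"]
    for r in rows:
        r["delta_aicc"] = r["aicc"] - best_aicc
    # parsimony tie-break within delta AICc < 2
    contenders = [r for r in rows if r["delta_aicc"] < 2.0]
    selected = min(contenders, key=lambda r: (r["n_params"], r["delta_aicc"]))["scheme"]
    return rows, selected


def confidence_intervals(
    curve_set: ProgressCurveSet,
    scheme: SchemeSpec,
    fit: FitResult,
    B: int = 200,
    seed: int | None = None,
    level: float = 0.95,
    config: FitConfig | None = None,
) -> dict[str, tuple[float, float]]:
    """Residual-bootstrap percentile confidence intervals for the fitted constants.

    Residuals of the original fit are resampled with replacement, added to
    the fitted curves, and the model refitted (single start at the point
    estimate).  Requires a converged fit and ``B >= 100``.
    """
    if not fit.converged:
        raise InputError("confidence intervals require a converged fit")
    if B < 100:
        raise InputError("B must be >= 100")
    X, y, scale = set_to_xy(curve_set)
    base_est = GlobalKineticsRegressor(
        scheme=scheme, conditions=curve_set.conditions,
        free_parameters=fit.free_parameters, fixed_params=fit.estimates,
        signal_scale=scale, multistart=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base_est.fit(X, y)
    yhat = base_est.predict(X)
    resid = y - yhat

    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {n: [] for n in fit.free_parameters}
    n_fail = 0
    for _ in range(B):
        yb = yhat + rng.choice(resid, size=resid.size, replace=True)
        est = GlobalKineticsRegressor(
            scheme=scheme, conditions=curve_set.conditions,
            free_parameters=fit.free_parameters, fixed_params=fit.estimates,
            signal_scale=scale, multistart=1,
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(X, yb)
            if not est.result_.converged:
                n_fail += 1
                continue
        except Exception:
            n_fail += 1
            continue
        for name in fit.free_parameters:
            draws[name].append(est.params_.as_dict()[name])
    if n_fail > 0.2 * B:
        raise NumericError(f"bootstrap refit failures exceeded 20% ({n_fail}/{B})")
    alpha = (1 - level) / 2
    out = {}
    for name, vals in draws.items():
        lo, hi = np.quantile(vals, [alpha, 1 - alpha])
        point = fit.estimates.as_dict()[name]
        out[name] = (float(min(lo, point)), float(max(hi, point)))
    return out
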