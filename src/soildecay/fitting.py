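"""Nonlinear least-squares estimation of the two decay models.

Per condition, both models are fitted by bounded trust-region least
squares with a data-driven initial guess and deterministic jittered
restarts on non-convergence.  Goodness of fit is the conventional
``R^2 = 1 - SS_res / SS_tot`` (total sum of squares about the observed
mean) and the regression F-test p-value

    F = (SS_reg / (n_params - 1)) / (SS_res / (n_obs - n_params)).

Because the plateau model nests the first-order model (``y0 = 0``), a
converged plateau fit can never have a larger residual sum of squares
than the first-order fit on the same data, up to optimizer tolerance.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .models import (
    LN2,
    FirstOrderParams,
    PlateauParams,
    dt50_first_order,
    half_life_degradable_fraction,
)

__all__ = [
    "FIRST_ORDER",
    "PLATEAU",
    "FitOptions",
    "InitialGuess",
    "FitResult",
    "ModelComparison",
    "InsufficientDataError",
    "UndefinedStatisticError",
    "FitComparisonError",
    "initial_guess",
    "fit_model",
    "r_squared",
    "regression_p_value",
    "compare_models",
    "data_fingerprint",
]

FIRST_ORDER = "first_order"
PLATEAU = "plateau"
MODEL_KINDS = (FIRST_ORDER, PLATEAU)

_EPS_CONC = 1e-6  # concentration epsilon used by the initial guess
_B_MIN, _B_MAX = 1e-6, 20.0
_Y0_ZERO_TOL = 1e-6  # plateau estimates below this report y0 = 0
_TIE_TOL = 1e-12  # parsimony tie-break on delta R^2


class InsufficientDataError(ValueError):
    """Too few distinct time points for the requested model."""


class UndefinedStatisticError(ValueError):
    """A statistic (R^2, p) is undefined for degenerate data."""


class FitComparisonError(ValueError):
    """compare_models called on fits of different data or failed fits."""


@dataclass
class FitOptions:
    """Options controlling one model fit."""

    use_means: bool = False  # fit per-time-point means instead of replicates
    seed: int = 0  # drives the deterministic restart jitter
    n_restarts: int = 5
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12


@dataclass
class InitialGuess:
    y0: float
    a: float
    b: float
    degenerate: bool = False  # flat data: amplitude pinned at epsilon


@dataclass
class FitResult:
    """One fitted model on one condition's data."""

    model_kind: str
    params: FirstOrderParams | PlateauParams | None
    r_squared: float
    p_value: float
    dt50_days: float
    n_obs: int
    ss_res: float
    ss_tot: float
    converged: bool
    n_params: int
    condition_id: str = ""
    data_fingerprint: str = ""
    note: str = ""


@dataclass
class ModelComparison:
    condition_id: str
    r2_first_order: float
    r2_plateau: float
    delta_r2: float
    preferred: str


def _as_xy(times, concentrations):
    t = np.asarray(times, dtype=float).ravel()
    y = np.asarray(concentrations, dtype=float).ravel()
    if t.size != y.size:
        raise ValueError("times and concentrations must have equal length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("times and concentrations must be finite")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    order = np.lexsort((y, t))  # fit invariant to input row order
    return t[order], y[order]


def data_fingerprint(times, concentrations) -> str:
    """Order-independent hash of a (time, concentration) data set."""
    t, y = _as_xy(times, concentrations)
    buf = np.ascontiguousarray(np.round(np.column_stack([t, y]), 9))
    return hashlib.sha1(buf.tobytes()).hexdigest()


def _n_params(model_kind: str) -> int:
    if model_kind == FIRST_ORDER:
        return 2
    if model_kind == PLATEAU:
        return 3
    raise ValueError(f"unknown model kind {model_kind!r}")


def initial_guess(times, concentrations, model_kind: str) -> InitialGuess:
    """Data-driven starting values for the nonlinear fit.

    Plateau: ``y0`` from the mean of the last two sampling times, ``a``
    from the earliest-time mean above the plateau, ``b`` from the slope of
    an ordinary least-squares line of ``log(y - y0 + eps)`` against time
    over the points above the plateau (fallback ``ln2 / (t_max / 10)``).
    First-order is the same with ``y0`` forced to zero.
    """
    n_params = _n_params(model_kind)
    t, y = _as_xy(times, concentrations)
    unique_t = np.unique(t)
    if unique_t.size < n_params + 1:
        raise InsufficientDataError(
            f"{model_kind} fit needs at least {n_params + 1} distinct time "
            f"points, got {unique_t.size}"
        )

    def time_mean(tv: float) -> float:
        return float(y[t == tv].mean())

    if model_kind == PLATEAU:
        y0_init = max(0.0, float(np.mean([time_mean(v) for v in unique_t[-2:]])))
    else:
        y0_init = 0.0
    a_init = max(_EPS_CONC, time_mean(unique_t[0]) - y0_init)
    degenerate = a_init == _EPS_CONC

    t_max = unique_t[-1]
    b_init = LN2 / (t_max / 10.0) if t_max > 0 else 1.0
    mask = y > y0_init
    if np.unique(t[mask]).size >= 2:
        slope = np.polyfit(t[mask], np.log(y[mask] - y0_init + _EPS_CONC), 1)[0]
        if slope < 0:
            b_init = -slope
    b_init = float(np.clip(b_init, _B_MIN, _B_MAX))
    return InitialGuess(y0=y0_init, a=a_init, b=b_init, degenerate=degenerate)


def r_squared(observed, predicted) -> float:
    """``1 - SS_res / SS_tot`` with SS_tot about the observed mean."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size != pred.size:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise UndefinedStatisticError("zero total sum of squares: R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def _f_test_p(ss_res: float, ss_tot: float, n_obs: int, n_params: int) -> float:
    df1 = n_params - 1
    df2 = n_obs - n_params
    if df1 < 1 or df2 < 1:
        raise UndefinedStatisticError("not enough observations for the F test")
    if ss_tot <= 0:
        raise UndefinedStatisticError("zero total sum of squares: F undefined")
    if ss_res <= 0:
        return 0.0  # perfect fit; p underflows below 1e-16
    ss_reg = max(0.0, ss_tot - ss_res)
    f_stat = (ss_reg / df1) / (ss_res / df2)
    return float(stats.f.sf(f_stat, df1, df2))


def regression_p_value(fit: FitResult) -> float:
    """Upper-tail regression-F probability of a converged fit."""
    if not fit.converged:
        raise UndefinedStatisticError("fit did not converge; p-value withheld")
    return _f_test_p(fit.ss_res, fit.ss_tot, fit.n_obs, fit.n_params)


def _model_fun(model_kind: str):
    if model_kind == FIRST_ORDER:
        return lambda x, t: x[0] * np.exp(-x[1] * t)
    return lambda x, t: x[0] + x[1] * np.exp(-x[2] * t)


def fit_model(
    times,
    concentrations,
    model_kind: str,
    options: FitOptions | None = None,
    condition_id: str = "",
) -> FitResult:
    """Fit one model to one condition's data by bounded least squares.

    Bounds keep the parameters physical: ``y0 in [0, max(y)]``,
    ``a in (0, 2 max(y)]``, ``b in [1e-6, 20]`` per day.  On
    non-convergence, up to ``options.n_restarts`` deterministically
    jittered restarts are attempted; if all fail the result is flagged
    ``converged=False`` with the statistics withheld (NaN).
    """
    options = options or FitOptions()
    n_params = _n_params(model_kind)
    t_raw, y_raw = _as_xy(times, concentrations)
    fingerprint = data_fingerprint(t_raw, y_raw)
    if options.use_means:
        t = np.unique(t_raw)
        y = np.array([y_raw[t_raw == tv].mean() for tv in t])
    else:
        t, y = t_raw, y_raw

    guess = initial_guess(t, y, model_kind)
    y_max = float(y.max())
    if y_max <= 0:
        raise UndefinedStatisticError("all concentrations are zero")
    a_lo = 1e-9
    if model_kind == FIRST_ORDER:
        lb = np.array([a_lo, _B_MIN])
        ub = np.array([2.0 * y_max, _B_MAX])
        x0 = np.array([guess.a, guess.b])
    else:
        lb = np.array([0.0, a_lo, _B_MIN])
        ub = np.array([y_max, 2.0 * y_max, _B_MAX])
        x0 = np.array([guess.y0, guess.a, guess.b])
    x0 = np.clip(x0, lb, ub)

    fun = _model_fun(model_kind)

    def residuals(x):
        return fun(x, t) - y

    def solve(x_start):
        return optimize.least_squares(
            residuals,
            x_start,
            bounds=(lb, ub),
            method="trf",
            ftol=options.ftol,
            xtol=options.xtol,
            gtol=options.gtol,
            max_nfev=2000,
        )

    result = solve(x0)
    if not result.success:
        rng = np.random.default_rng(options.seed)
        best = result if np.isfinite(result.cost) else None
        for _ in range(options.n_restarts):
            jitter = np.exp(rng.normal(0.0, 0.5, size=x0.size))
            trial = solve(np.clip(x0 * jitter, lb, ub))
            if best is None or trial.cost < best.cost:
                best = trial
            if trial.success:
                break
        result = best if best is not None else result

    x = np.asarray(result.x, dtype=float)
    note = ""
    if guess.degenerate:
        note = "degenerate: no decay signal in data"
    if model_kind == PLATEAU and 0.0 < x[0] < _Y0_ZERO_TOL:
        x[0] = 0.0
        note = (note + "; " if note else "") + (
            "y0 at lower bound: plateau model coincides with first-order"
        )

    pred = fun(x, t)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    n_obs = int(y.size)
    converged = bool(result.success)

    if model_kind == FIRST_ORDER:
        params: FirstOrderParams | PlateauParams = FirstOrderParams(
            a=max(x[0], a_lo), b=max(x[1], _B_MIN)
        )
        dt50 = dt50_first_order(params.b)
    else:
        params = PlateauParams(
            y0=max(x[0], 0.0), a=max(x[1], a_lo), b=max(x[2], _B_MIN)
        )
        dt50 = half_life_degradable_fraction(params)

    if not converged:
        note = (note + "; " if note else "") + "optimizer did not converge"
        r2 = p_val = float("nan")
    elif ss_tot == 0.0:
        note = (note + "; " if note else "") + "zero variance: R^2/p undefined"
        r2 = p_val = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
        if r2 < 0.0:
            # constant curves are in the model closure, so a converged fit
            # can only fall below 0 by optimizer tolerance
            r2 = 0.0
        p_val = _f_test_p(ss_res, ss_tot, n_obs, n_params)

    return FitResult(
        model_kind=model_kind,
        params=params,
        r_squared=r2,
        p_value=p_val,
        dt50_days=dt50,
        n_obs=n_obs,
        ss_res=ss_res,
        ss_tot=ss_tot,
        converged=converged,
        n_params=n_params,
        condition_id=condition_id,
        data_fingerprint=fingerprint,
        note=note,
    )


def compare_models(
    fit_fo: FitResult, fit_pl: FitResult, threshold: float = 0.0
) -> ModelComparison:
    """Compare a first-order and a plateau fit of the same data.

    The plateau model is preferred only when its R^2 advantage exceeds
    ``threshold`` (plus a 1e-12 parsimony tie-break, since the models are
    nested and coincide at ``y0 = 0``).
    """
    if fit_fo.model_kind != FIRST_ORDER or fit_pl.model_kind != PLATEAU:
        raise FitComparisonError(
            "expected (first_order, plateau) fits, got "
            f"({fit_fo.model_kind}, {fit_pl.model_kind})"
        )
    if fit_fo.data_fingerprint != fit_pl.data_fingerprint:
        raise FitComparisonError("fits are not based on the same data")
    if not (fit_fo.converged and fit_pl.converged):
        raise FitComparisonError("both fits must have converged")
    delta = fit_pl.r_squared - fit_fo.r_squared
    preferred = PLATEAU if delta > threshold + _TIE_TOL else FIRST_ORDER
    return ModelComparison(
        condition_id=fit_fo.condition_id,
        r2_first_order=fit_fo.r_squared,
        r2_plateau=fit_pl.r_squared,
        delta_r2=delta,
        preferred=preferred,
    )
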