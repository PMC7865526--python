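"""Dissolution-profile models and per-vessel curve fitting.

The first stage of the in vitro-in vivo simulation workflow describes each
vessel's dissolution profile (percent of dose dissolved versus time, at pH
1.2, 4.5 and 6.8) with a small empirical release model.  Candidate models are
fitted by ordinary least squares on the percent scale and ranked by AIC; the
simplest adequate model is kept, and its parameters are averaged across
vessels to give one (m0, Kd)-type parameter set per product and pH.

Model equations (t in minutes, y in percent of dose):

========== ====================================== =================
model_id   y(t)                                   parameters
========== ====================================== =================
first_order 100*m0*(1 - exp(-kd*t))               m0, kd
zero_order  k0*t                                  k0
weibull     100*m0*(1 - exp(-(t/td)**b))          m0, td, b
logistic    100*m0 / (1 + exp(-k*(t - t50)))      m0, k, t50
higuchi     kh*sqrt(t)                            kh
peppas      kp*t**n                               kp, n
========== ====================================== =================

``m0`` is the maximum dissolvable fraction of the dose (dimensionless), and
``kd`` the first-order dissolution rate constant in 1/min.  AIC and BIC use
the Gaussian least-squares form ``n*ln(SSR/n) + {2, ln(n)}*p``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DissolutionCurve",
    "FirstOrderParams",
    "ModelFit",
    "DissolutionSummary",
    "FitError",
    "MODELS",
    "predict_dissolution",
    "fit_curve",
    "compare_models",
    "summarize_fits",
]

VALID_PH = (1.2, 4.5, 6.8)


class FitError(RuntimeError):
    """Raised when a dissolution model cannot be fitted to a curve."""


@dataclass(frozen=True)
class FirstOrderParams:
    """First-order release parameters: plateau fraction ``m0`` and rate ``kd``.

    ``m0`` is the maximum fraction of the dose that dissolves (values slightly
    above 1 can arise from assay noise; values above 1.2 are rejected and
    values above 1.05 are flagged), ``kd`` is in 1/min.
    """

    m0: float
    kd: float

    def __post_init__(self) -> None:
        if not 0.0 < self.m0 <= 1.2:
            raise ValueError(f"m0 must be in (0, 1.2], got {self.m0}")
        if self.kd <= 0.0:
            raise ValueError(f"kd must be positive, got {self.kd}")

    @property
    def flagged_supersaturated(self) -> bool:
        return self.m0 > 1.05


@dataclass(frozen=True)
class DissolutionCurve:
    """One vessel's (time, % dissolved) series at one buffer pH."""

    vessel_id: str
    ph_condition: float
    times: np.ndarray
    percent_dissolved: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.percent_dissolved, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "percent_dissolved", y)
        if self.ph_condition not in VALID_PH:
            raise ValueError(f"ph_condition must be one of {VALID_PH}")
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise ValueError("times and percent_dissolved must be 1-D of equal length")
        if t.size < 3:
            raise ValueError("need at least 3 points")
        if t[0] < 0:
            raise ValueError("first time must be >= 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"times must be strictly increasing (vessel {self.vessel_id})")
        if np.any(y < 0):
            raise ValueError("percent_dissolved must be non-negative")


@dataclass(frozen=True)
class ModelFit:
    """Result of fitting one release model to one vessel's curve."""

    model_id: str
    params: dict[str, float]
    param_se: dict[str, float]
    ssr: float
    n_obs: int
    aic: float
    bic: float
    vessel_id: str = ""


@dataclass(frozen=True)
class DissolutionSummary:
    """Across-vessel mean parameters and their relative standard errors (%)."""

    ph_condition: float
    model_id: str
    mean_params: dict[str, float]
    rse_percent: dict[str, float]
    n_vessels: int = 0


# --- model definitions -------------------------------------------------------


def _first_order(t, m0, kd):
    return 100.0 * m0 * (1.0 - np.exp(-kd * t))


def _zero_order(t, k0):
    return k0 * t


def _weibull(t, m0, td, b):
    return 100.0 * m0 * (1.0 - np.exp(-((t / td) ** b)))


def _logistic(t, m0, k, t50):
    return 100.0 * m0 / (1.0 + np.exp(-k * (t - t50)))


def _higuchi(t, kh):
    return kh * np.sqrt(t)


def _peppas(t, kp, n):
    return kp * t**n


@dataclass(frozen=True)
class _ModelDef:
    func: Callable
    param_names: tuple[str, ...]
    guess: Callable[[np.ndarray, np.ndarray], tuple[float, ...]]
    bounds: tuple[Sequence[float], Sequence[float]]
    # weibull/peppas powers are undefined at t = 0; those models drop it
    drop_t0: bool = False


def _half_rise_time(t: np.ndarray, y: np.ndarray) -> float:
    """First time at which y exceeds half its plateau; robust default 1."""
    plateau = float(np.max(y))
    if plateau <= 0:
        return 1.0
    above = t[y >= 0.5 * plateau]
    thalf = float(above[0]) if above.size else float(t[-1])
    return max(thalf, 1e-6)


def _guess_first_order(t, y):
    m0 = min(max(np.max(y) / 100.0, 1e-3), 1.2)
    kd = math.log(2.0) / _half_rise_time(t, y)
    return (m0, kd)


def _guess_weibull(t, y):
    m0 = min(max(np.max(y) / 100.0, 1e-3), 1.2)
    return (m0, _half_rise_time(t, y) / math.log(2.0) ** 1.0, 1.0)


def _guess_logistic(t, y):
    m0 = min(max(np.max(y) / 100.0, 1e-3), 1.2)
    t50 = _half_rise_time(t, y)
    return (m0, 2.0 / max(t50, 1e-6), t50)


def _guess_peppas(t, y):
    tp, yp = t[t > 0], y[t > 0]
    pos = yp > 0
    if pos.sum() >= 2:
        n, logk = np.polyfit(np.log(tp[pos]), np.log(yp[pos]), 1)
        return (float(np.exp(logk)), float(np.clip(n, 0.05, 3.0)))
    return (1.0, 0.5)


MODELS: dict[str, _ModelDef] = {
    "first_order": _ModelDef(
        _first_order, ("m0", "kd"), _guess_first_order, ([1e-6, 1e-8], [1.2, 10.0])
    ),
    "zero_order": _ModelDef(
        _zero_order,
        ("k0",),
        lambda t, y: (max(float(np.max(y) / max(t[-1], 1e-9)), 1e-9),),
        ([1e-9], [np.inf]),
    ),
    "weibull": _ModelDef(
        _weibull, ("m0", "td", "b"), _guess_weibull, ([1e-6, 1e-6, 0.05], [1.2, 1e5, 10.0]),
        drop_t0=True,
    ),
    "logistic": _ModelDef(
        _logistic, ("m0", "k", "t50"), _guess_logistic,
        ([1e-6, 1e-8, -1e4], [1.2, 10.0, 1e5]),
    ),
    "higuchi": _ModelDef(
        _higuchi,
        ("kh",),
        lambda t, y: (max(float(np.max(y) / max(math.sqrt(t[-1]), 1e-9)), 1e-9),),
        ([1e-9], [np.inf]),
    ),
    "peppas": _ModelDef(
        _peppas, ("kp", "n"), _guess_peppas, ([1e-9, 0.01], [np.inf, 5.0]), drop_t0=True
    ),
}


# --- operations --------------------------------------------------------------


def predict_dissolution(
    t: float | np.ndarray, params: FirstOrderParams, dose: float = 1.0
) -> np.ndarray | float:
    """Amount dissolved at time ``t`` under first-order release.

    Returns ``m0 * dose * (1 - exp(-kd * t))``; with ``dose=100`` this is the
    percent-of-dose form.  Monotone non-decreasing in ``t`` with asymptote
    ``m0 * dose``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    if dose < 0:
        raise ValueError("dose must be non-negative")
    out = params.m0 * dose * (1.0 - np.exp(-params.kd * t_arr))
    return out if t_arr.shape else float(out)


def fit_curve(
    curve: DissolutionCurve,
    model_id: str = "first_order",
    initial_guess: Sequence[float] | None = None,
) -> ModelFit:
    """Least-squares fit of one release model to one vessel's curve.

    Raises :class:`FitError` on non-convergence or degenerate (all-zero)
    response.  AIC/BIC use the Gaussian least-squares form; standard errors
    come from the Jacobian-based asymptotic covariance.
    """
    if model_id not in MODELS:
        raise ValueError(f"unknown model_id {model_id!r}; choose from {sorted(MODELS)}")
    mdef = MODELS[model_id]
    t = curve.times
    y = curve.percent_dissolved
    if mdef.drop_t0:
        keep = t > 0
        t, y = t[keep], y[keep]
    p = len(mdef.param_names)
    if t.size < p + 1:
        raise FitError(
            f"{model_id}: {t.size} usable points < {p + 1} required "
            f"(vessel {curve.vessel_id})"
        )
    if np.all(y == 0):
        raise FitError(f"all-zero response: rate unidentifiable (vessel {curve.vessel_id})")

    p0 = tuple(initial_guess) if initial_guess is not None else mdef.guess(t, y)
    p0 = tuple(np.clip(p0, mdef.bounds[0], mdef.bounds[1]))
    try:
        popt, pcov = curve_fit(
            mdef.func, t, y, p0=p0, bounds=mdef.bounds, maxfev=20000,
            xtol=1e-14, ftol=1e-14, gtol=1e-14, method="trf",
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"{model_id} fit failed on vessel {curve.vessel_id}: {exc}") from exc

    resid = y - mdef.func(t, *popt)
    ssr = float(resid @ resid)
    n = int(t.size)
    if ssr > 0:
        aic = n * math.log(ssr / n) + 2 * p
        bic = n * math.log(ssr / n) + p * math.log(n)
    else:  # perfect fit: criteria diverge to -inf; keep ordering meaningful
        aic = bic = -math.inf
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return ModelFit(
        model_id=model_id,
        params=dict(zip(mdef.param_names, map(float, popt))),
        param_se=dict(zip(mdef.param_names, map(float, se))),
        ssr=ssr,
        n_obs=n,
        aic=aic,
        bic=bic,
        vessel_id=curve.vessel_id,
    )


def compare_models(
    curve: DissolutionCurve, model_ids: Iterable[str] | None = None
) -> list[ModelFit]:
    """Fit several candidate models and rank them by AIC (ascending).

    Ties break toward fewer parameters, then lower BIC.  Models that fail to
    converge are dropped; if none converges a :class:`FitError` is raised.
    """
    ids = list(model_ids) if model_ids is not None else list(MODELS)
    fits: list[ModelFit] = []
    failures: dict[str, str] = {}
    for mid in ids:
        try:
            fits.append(fit_curve(curve, mid))
        except FitError as exc:
            failures[mid] = str(exc)
    if not fits:
        raise FitError(f"no candidate model converged: {failures}")
    fits.sort(key=lambda f: (f.aic, len(f.params), f.bic))
    return fits


def summarize_fits(fits: Sequence[ModelFit], ph_condition: float) -> DissolutionSummary:
    """Across-vessel mean parameters with RSE% of the mean.

    ``rse_percent = 100 * (SD / sqrt(n)) / mean`` per parameter, using the
    sample standard deviation (ddof=1) over vessels.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 vessel fits to summarize")
    model_ids = {f.model_id for f in fits}
    if len(model_ids) != 1:
        raise ValueError(f"mixed model_ids in summary: {sorted(model_ids)}")
    (model_id,) = model_ids
    names = list(fits[0].params)
    mat = np.array([[f.params[k] for k in names] for f in fits], dtype=float)
    mean = mat.mean(axis=0)
    sem = mat.std(axis=0, ddof=1) / math.sqrt(mat.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        rse = np.where(mean != 0, 100.0 * sem / np.abs(mean), np.inf)
    return DissolutionSummary(
        ph_condition=ph_condition,
        model_id=model_id,
        mean_params=dict(zip(names, map(float, mean))),
        rse_percent=dict(zip(names, map(float, rse))),
        n_vessels=len(fits),
    )
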