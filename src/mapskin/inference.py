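"""Local sensitivity analysis and Levenberg-Marquardt parameter estimation.

Sensitivity coefficients are normalised local elasticities

    S(p, Y) = (dY / Y) / (dp / p)

evaluated by central finite difference at the nominal point: a coefficient
of +2 means a 1 % parameter increase raises the output by about 2 %.
Fitting minimises the weighted sum of squared residuals between model
predictions and observations with the Levenberg-Marquardt algorithm (via
lmfit), within box bounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import lmfit

__all__ = ["SensitivityResult", "FitResult", "sensitivity_matrix", "fit_parameters"]


@dataclass(frozen=True)
class SensitivityResult:
    """Normalised sensitivity coefficients, parameters x output metrics."""

    coefficients: pd.DataFrame
    rel_step: float

    def most_influential(self, metric: str, n: int = 5) -> pd.Series:
        """Parameters ranked by |coefficient| for one output metric."""
        col = self.coefficients[metric]
        return col.reindex(col.abs().sort_values(ascending=False).index).head(n)


@dataclass
class FitResult:
    """Levenberg-Marquardt fit outcome."""

    estimates: dict
    rss: float
    converged: bool
    n_iter: int
    message: str
    at_bounds: dict = field(default_factory=dict)
    lmfit_result: object | None = None

    def report(self) -> dict:
        return {
            "estimates": self.estimates,
            "rss": self.rss,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "message": self.message,
            "at_bounds": self.at_bounds,
        }


def sensitivity_matrix(
    model: Callable[[Mapping[str, float]], object],
    params: Mapping[str, float],
    param_subset: Sequence[str],
    output_metrics: Mapping[str, Callable[[object], float]],
    rel_step: float = 0.1,
) -> SensitivityResult:
    """Central-difference normalised sensitivities of scalar output metrics.

    ``model`` maps a full parameter dictionary to an output object (e.g. a
    trajectory); each entry of ``output_metrics`` reduces that object to a
    scalar (layer amount at a time, C_max, AUC, ...).  Positive coefficients
    mean the output increases with the parameter.  Metrics evaluating to 0
    at the nominal point have no defined relative sensitivity and are
    reported as NaN.
    """
    if not 0 < rel_step <= 0.5:
        raise ValueError("rel_step must be in (0, 0.5]")
    missing = [p for p in param_subset if p not in params]
    if missing:
        raise KeyError(f"unknown parameters {missing}")
    y0_obj = model(dict(params))
    y0 = {m: float(f(y0_obj)) for m, f in output_metrics.items()}

    rows = {}
    for p in param_subset:
        if params[p] == 0:
            raise ValueError(f"cannot take a relative step on {p!r} = 0")
        hi = dict(params)
        lo = dict(params)
        hi[p] = params[p] * (1 + rel_step)
        lo[p] = params[p] * (1 - rel_step)
        out_hi = model(hi)
        out_lo = model(lo)
        row = {}
        for m, f in output_metrics.items():
            if y0[m] == 0:
                row[m] = np.nan
                continue
            row[m] = (float(f(out_hi)) - float(f(out_lo))) / (2 * rel_step * y0[m])
        rows[p] = row
    df = pd.DataFrame.from_dict(rows, orient="index")[list(output_metrics)]
    return SensitivityResult(coefficients=df, rel_step=rel_step)


def fit_parameters(
    predict: Callable[[Mapping[str, float]], np.ndarray],
    observed: np.ndarray,
    free_params: Mapping[str, tuple],
    weights: np.ndarray | None = None,
    log_residuals: bool = False,
    max_nfev: int | None = None,
) -> FitResult:
    """Levenberg-Marquardt least-squares fit within box bounds.

    ``free_params`` maps parameter name to ``(start, lower, upper)``.
    Residuals are ``w * (pred - obs)`` or, with ``log_residuals``,
    ``w * (log10 pred - log10 obs)`` — useful when the observations span
    decades.  Deterministic for identical inputs; on non-convergence the
    best iterate is returned with ``converged=False``.  If the optimiser
    somehow ends worse than it started, the starting point is returned.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    if obs.size == 0:
        raise ValueError("observed series is empty")
    if len(free_params) < 1:
        raise ValueError("need at least one free parameter")
    w = np.ones_like(obs) if weights is None else np.asarray(weights, float).ravel()
    if w.size != obs.size:
        raise ValueError("weights must match observations")

    floor = 1e-300
    obs_t = np.log10(np.maximum(obs, floor)) if log_residuals else obs

    lp = lmfit.Parameters()
    for name, (start, lo, hi) in free_params.items():
        if not lo <= start <= hi:
            raise ValueError(f"start for {name!r} outside its bounds")
        lp.add(name, value=start, min=lo, max=hi)

    def residual(pars):
        vals = {name: pars[name].value for name in free_params}
        pred = np.asarray(predict(vals), dtype=float).ravel()
        pred_t = np.log10(np.maximum(pred, floor)) if log_residuals else pred
        return w * (pred_t - obs_t)

    r0 = residual(lp)
    rss0 = float(r0 @ r0)
    out = lmfit.minimize(residual, lp, method="leastsq", max_nfev=max_nfev)
    estimates = {name: float(out.params[name].value) for name in free_params}
    rss = float(np.sum(np.asarray(out.residual) ** 2))
    if rss > rss0:
        estimates = {name: float(start) for name, (start, _, _) in free_params.items()}
        rss = rss0
    span = {name: hi - lo for name, (_, lo, hi) in free_params.items()}
    at_bounds = {
        name: bool(min(estimates[name] - lo, hi - estimates[name]) <= 1e-8 * span[name])
        for name, (_, lo, hi) in free_params.items()
    }
    return FitResult(
        estimates=estimates,
        rss=rss,
        converged=bool(out.success),
        n_iter=int(out.nfev),
        message=str(out.message),
        at_bounds=at_bounds,
        lmfit_result=out,
    )
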