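"""Four-parameter logistic (4PL) dose-response fitting.

The model is the GraphPad "log(agonist) vs. response — variable slope"
family::

    response = bottom + (top - bottom) / (1 + 10**((log_ic50 - log10(dose)) * hill))

fitted by bounded nonlinear least squares with multi-start initialization
over a grid of log-IC50 and both Hill-slope signs.  Responses are fold
changes versus DMSO, so the default bounds keep ``top`` in [0.5, 1.5] and
``bottom`` >= 0 (both overridable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import NoDoseDependenceError


def four_param_logistic(log_dose: np.ndarray, top: float, bottom: float,
                        log_ic50: float, hill_slope: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - log_dose)
                                                     * hill_slope))


@dataclass
class DoseResponseFit:
    """Results of a 4PL fit; ``ic50 = 10**log_ic50`` by construction."""

    top: float
    bottom: float
    log_ic50: float
    hill_slope: float
    ic50: float
    residual_sse: float
    converged: bool
    n_points: int
    bound_active: bool = False
    message: str = ""

    def predict(self, doses) -> np.ndarray:
        return four_param_logistic(np.log10(np.asarray(doses, float)),
                                   self.top, self.bottom,
                                   self.log_ic50, self.hill_slope)

    def summary(self) -> str:
        lines = [
            "4PL dose-response fit",
            "---------------------",
            f"n points      {self.n_points}",
            f"top           {self.top:.6g}",
            f"bottom        {self.bottom:.6g}",
            f"log IC50      {self.log_ic50:.6g}",
            f"IC50          {self.ic50:.6g}",
            f"Hill slope    {self.hill_slope:.6g}",
            f"residual SSE  {self.residual_sse:.6g}",
            f"converged     {self.converged}",
        ]
        if self.bound_active:
            lines.append("note: a parameter sits on its bound")
        return "\n".join(lines)


DEFAULT_BOUNDS = {
    "top": (0.5, 1.5),
    "bottom": (0.0, math.inf),
    "hill_slope": (-10.0, 10.0),
}


class DoseResponseModel:
    """4PL model bound to one compound's (dose, response) data.

    Parameters
    ----------
    doses : array-like
        Concentrations, all > 0 (any consistent unit; IC50 inherits it).
    responses : array-like
        Fold-change responses at those doses.
    bounds : dict, optional
        Overrides for the default parameter bounds; keys among
        ``top, bottom, log_ic50, hill_slope``, values (lo, hi).
    """

    def __init__(self, doses, responses, bounds: dict | None = None):
        self.doses = np.asarray(doses, float)
        self.responses = np.asarray(responses, float)
        if self.doses.shape != self.responses.shape:
            raise ValueError("doses and responses must have equal length")
        if (self.doses <= 0).any():
            raise ValueError("doses must be strictly positive")
        if np.unique(self.doses).size < 4:
            raise ValueError("need >= 4 distinct doses for a 4PL fit")
        self.log_doses = np.log10(self.doses)
        b = dict(DEFAULT_BOUNDS)
        b.setdefault("log_ic50",
                     (self.log_doses.min() - 3.0, self.log_doses.max() + 3.0))
        if bounds:
            b.update(bounds)
        self.bounds = b

    def fit(self, n_starts: int = 5) -> DoseResponseFit:
        """Bounded least squares from a multi-start grid; best SSE wins."""
        y = self.responses
        span = float(y.max() - y.min())
        scale = max(abs(float(y.mean())), 1.0)
        if span < 1e-9 * scale:
            raise NoDoseDependenceError("no dose dependence: responses are flat")

        names = ("top", "bottom", "log_ic50", "hill_slope")
        lo = np.array([self.bounds[n][0] for n in names])
        hi = np.array([self.bounds[n][1] for n in names])

        def clip(v, i):
            return float(np.clip(v, lo[i] + 1e-12 if np.isfinite(lo[i]) else v,
                                 hi[i] - 1e-12 if np.isfinite(hi[i]) else v))

        def resid(p):
            return four_param_logistic(self.log_doses, *p) - y

        top0 = clip(float(y.max()), 0)
        bot0 = clip(float(y.min()), 1)
        grid = np.linspace(self.log_doses.min(), self.log_doses.max(),
                           max(n_starts, 2))
        best = None
        for lg in grid:
            for h in (1.0, -1.0, 2.0, -2.0):
                p0 = np.clip([top0, bot0, lg, h], lo, hi)
                try:
                    sol = least_squares(resid, p0, bounds=(lo, hi),
                                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
                except ValueError:
                    continue
                sse = float(np.sum(sol.fun ** 2))
                if best is None or sse < best[0]:
                    best = (sse, sol)
        sse, sol = best
        top, bottom, log_ic50, hill = (float(v) for v in sol.x)
        on_bound = bool(np.any(np.isclose(sol.x, lo, atol=1e-9)
                               | np.isclose(sol.x, hi, atol=1e-9)))
        return DoseResponseFit(
            top=top, bottom=bottom, log_ic50=log_ic50, hill_slope=hill,
            ic50=10.0 ** log_ic50, residual_sse=sse,
            converged=bool(sol.success), n_points=int(y.size),
            bound_active=on_bound, message=str(sol.message),
        )


def fit_dose_response(doses, responses, bounds: dict | None = None
                      ) -> DoseResponseFit:
    """Functional wrapper over :class:`DoseResponseModel`."""
    return DoseResponseModel(doses, responses, bounds=bounds).fit()
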