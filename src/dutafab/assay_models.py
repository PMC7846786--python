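"""Quantitative assay models: 4-parameter logistic dose-response fits and
DLS-bead viscosity conversion.

The 4PL model is y = bottom + (top − bottom) / (1 + (x/IC50)^n_H); IC50 is
the dose of half-maximal effect and n_H the Hill coefficient.  Fitting is
performed in log-dose space for conditioning, with a deterministic
initialisation (top/bottom from the signal extrema, IC50 from the dose
bracketing the half-maximal signal, n_H = 1).

The viscosity model converts the apparent hydrodynamic radius of tracer
beads measured by dynamic light scattering into solution viscosity via
η = η₀ · (r_h / r_h,0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import DutafabError


@dataclass(frozen=True)
class DoseResponseFit:
    top: float
    bottom: float
    ic50: float
    hill: float
    rss: float
    converged: bool

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.bottom + (self.top - self.bottom) / (
            1.0 + np.power(x / self.ic50, self.hill)
        )


def _4pl(x, top, bottom, log_ic50, hill):
    return bottom + (top - bottom) / (1.0 + np.exp(hill * (np.log(x) - log_ic50)))


def fit_4pl(x, y, init: dict | None = None) -> DoseResponseFit:
    """Least-squares 4PL fit of signal y against dose x (> 0).

    Requires at least 5 dose points.  Non-convergence is flagged on the
    result (with a warning) rather than raised, so partial estimates remain
    inspectable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DutafabError("x and y must be 1-D arrays of equal length")
    if len(x) < 5:
        raise DutafabError("need at least 5 dose points")
    if np.any(x <= 0):
        raise DutafabError("doses must be positive")

    init = init or {}
    top0 = float(init.get("top", y.max()))
    bottom0 = float(init.get("bottom", y.min()))
    if "ic50" in init:
        log_ic50_0 = float(np.log(init["ic50"]))
    else:
        # dose whose signal is closest to half-maximal
        half = 0.5 * (top0 + bottom0)
        log_ic50_0 = float(np.log(x[np.argmin(np.abs(y - half))]))
    hill0 = float(init.get("hill", 1.0))
    # sign of the trend decides the sign of the initial Hill coefficient
    if np.corrcoef(np.log(x), y)[0, 1] > 0:
        hill0 = -abs(hill0)

    def resid(p):
        return _4pl(x, *p) - y

    sol = least_squares(resid, [top0, bottom0, log_ic50_0, hill0],
                        method="lm", max_nfev=20000)
    top, bottom, log_ic50, hill = sol.x
    converged = bool(sol.success)
    if not converged:
        warnings.warn("4PL fit did not converge; returning partial estimates")
    if hill < 0:  # canonical form: positive n_H with top at low dose
        hill = -hill
        top, bottom = bottom, top
    return DoseResponseFit(
        top=float(top), bottom=float(bottom), ic50=float(np.exp(log_ic50)),
        hill=float(hill), rss=float(2.0 * sol.cost), converged=converged,
    )


@dataclass(frozen=True)
class ViscosityEstimate:
    eta0: float  # solvent viscosity, cP
    rh: float    # apparent bead hydrodynamic radius, nm
    rh0: float   # bead radius in water, nm
    eta: float   # solution viscosity, cP


def viscosity_from_dls(eta0: float, rh: float, rh0: float) -> ViscosityEstimate:
    """Solution viscosity from the DLS bead-tracer method: η = η₀·(r_h/r_h,0)."""
    if min(eta0, rh, rh0) <= 0:
        raise DutafabError("eta0, rh and rh0 must all be positive")
    return ViscosityEstimate(eta0, rh, rh0, eta0 * rh / rh0)
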