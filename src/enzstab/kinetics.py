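"""Michaelis–Menten parameter estimation.

V₀ = V_max·[S]/(K_M + [S]).  Parameters are first estimated by the
Hanes–Woolf linearisation,

    [S]/V₀ = [S]/V_max + K_M/V_max,

i.e. an ordinary regression of S/V₀ on S giving V_max = 1/slope and
K_M = intercept/slope, and then refined by unweighted nonlinear least
squares started from the Hanes–Woolf values.  Parameter standard
deviations come from the curvature (Jacobian) at the optimum; for the
linearised fit they are propagated from the regression coefficient
covariance by the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = ["MMDataset", "MMFit", "michaelis_menten", "hanes_woolf_fit", "mm_nls_fit"]


def michaelis_menten(S, vmax: float, km: float):
    """Initial velocity V₀ at substrate concentration S."""
    S = np.asarray(S, dtype=float)
    return vmax * S / (km + S)


@dataclass(frozen=True)
class MMDataset:
    """Paired substrate concentrations (mM) and initial velocities (mM min⁻¹)."""

    substrate: tuple[float, ...]
    velocity: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.substrate) != len(self.velocity):
            raise ValueError("substrate and velocity must have equal length")

    @classmethod
    def from_arrays(cls, S: Sequence[float], V0: Sequence[float]) -> "MMDataset":
        return cls(tuple(float(s) for s in S), tuple(float(v) for v in V0))


@dataclass(frozen=True)
class MMFit:
    """Fitted Michaelis–Menten parameters with uncertainties."""

    vmax: float
    km: float
    vmax_sd: float
    km_sd: float
    method: str                     # "hanes-woolf" | "nls"
    rss: float
    converged: bool = True
    n_iterations: int | None = None


def hanes_woolf_fit(data: MMDataset) -> MMFit:
    """Hanes–Woolf linear regression estimate of (V_max, K_M).

    Requires at least three distinct positive substrate concentrations and
    strictly positive velocities.  Non-saturating data (slope ≤ 0) raise a
    fit-failure error.
    """
    S = np.asarray(data.substrate, dtype=float)
    V = np.asarray(data.velocity, dtype=float)
    if (S <= 0).any():
        raise ValueError("Hanes-Woolf requires strictly positive substrate")
    if (V <= 0).any():
        raise ValueError("Hanes-Woolf requires strictly positive velocities")
    if np.unique(S).size < 3:
        raise ValueError("need >= 3 distinct substrate concentrations")

    y = S / V
    X = np.column_stack([S, np.ones_like(S)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    if slope <= 0:
        raise ValueError("non-saturating data: Hanes-Woolf slope <= 0")

    vmax = 1.0 / slope
    km = intercept / slope

    # delta-method SDs from the coefficient covariance
    resid = y - X @ coef
    dof = max(S.size - 2, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    # vmax = 1/b0 ; km = b1/b0
    g_vmax = np.array([-1.0 / slope**2, 0.0])
    g_km = np.array([-intercept / slope**2, 1.0 / slope])
    vmax_sd = math.sqrt(float(g_vmax @ cov @ g_vmax))
    km_sd = math.sqrt(float(g_km @ cov @ g_km))

    rss = float(np.sum((V - michaelis_menten(S, vmax, km)) ** 2))
    return MMFit(vmax=vmax, km=km, vmax_sd=vmax_sd, km_sd=km_sd,
                 method="hanes-woolf", rss=rss)


def mm_nls_fit(
    data: MMDataset,
    init: MMFit | tuple[float, float] | None = None,
    max_iterations: int = 2000,
    tolerance: float = 1e-12,
) -> MMFit:
    """Unweighted nonlinear least-squares Michaelis–Menten fit.

    ``init`` supplies starting values (an :class:`MMFit`, usually from
    :func:`hanes_woolf_fit`, or a bare (vmax, km) pair); when omitted the
    Hanes–Woolf estimate is computed internally.  On non-convergence the
    initial values are echoed back with ``converged=False``.
    """
    S = np.asarray(data.substrate, dtype=float)
    V = np.asarray(data.velocity, dtype=float)
    if init is None:
        init = hanes_woolf_fit(data)
    p0 = (init.vmax, init.km) if isinstance(init, MMFit) else (float(init[0]), float(init[1]))
    if p0[0] <= 0 or p0[1] <= 0:
        raise ValueError("initial (vmax, km) must be positive")

    try:
        popt, pcov, infodict, _, ier = optimize.curve_fit(
            michaelis_menten, S, V, p0=p0, maxfev=max_iterations,
            ftol=tolerance, xtol=tolerance, full_output=True,
        )
        converged = ier in (1, 2, 3, 4)
    except RuntimeError:
        popt, pcov, infodict, converged = np.array(p0), None, {"nfev": max_iterations}, False

    if not converged:
        return MMFit(vmax=p0[0], km=p0[1], vmax_sd=math.nan, km_sd=math.nan,
                     method="nls", rss=float(np.sum((V - michaelis_menten(S, *p0)) ** 2)),
                     converged=False, n_iterations=int(infodict.get("nfev", 0)))

    sds = np.sqrt(np.diag(pcov)) if pcov is not None and np.isfinite(pcov).all() else [math.nan] * 2
    rss = float(np.sum((V - michaelis_menten(S, *popt)) ** 2))
    return MMFit(vmax=float(popt[0]), km=float(popt[1]),
                 vmax_sd=float(sds[0]), km_sd=float(sds[1]),
                 method="nls", rss=rss, converged=True,
                 n_iterations=int(infodict.get("nfev", 0)))
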