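"""First-order deactivation kinetics, Arrhenius analysis and thermodynamics.

Storage at a fixed temperature is modelled as irreversible first-order
loss of activity, E(t) = E₀·exp(−k_d·t), so ln(E/E₀) is linear in time and
the deactivation constant k_d (month⁻¹) is minus the slope.  Across
temperatures k_d follows the Arrhenius law

    ln k_d = ln A − E_d / (R·T)

from which the deactivation energy E_d and frequency factor A are obtained
by regressing ln k_d on 1/T.  Per temperature the derived quantities are

    t½ = ln 2 / k_d                      (shelf-life, months)
    ΔH‡ = E_d − R·T                      (activation enthalpy)
    ΔG‡ = −R·T · ln( k_d·h / (k_B·T) )   (activation free energy)
    ΔS‡ = (ΔH‡ − ΔG‡) / T                (activation entropy)

ΔG‡ from the Eyring expression is only defined once a unit for k_d is
fixed.  The default mode ``paper-months`` feeds k_d in month⁻¹ straight
into the expression — the convention used in the enzyme-storage stability
literature whose tables this module reproduces.  Mode ``si-seconds``
converts k_d to s⁻¹ (30-day months) first; it yields the physically
conventional Eyring ΔG‡ and is provided because the choice matters
scientifically (the two differ by R·T·ln(seconds per month) ≈ 36 kJ mol⁻¹
at room temperature).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .constants import SECONDS_PER_MONTH, LITERATURE, PhysicalConstants

__all__ = [
    "IsothermFit",
    "ArrheniusFit",
    "ThermoRecord",
    "fit_kd",
    "half_life",
    "arrhenius_fit",
    "enthalpy",
    "gibbs",
    "entropy",
    "thermo_table",
    "predict_half_life",
]

log = logging.getLogger(__name__)

KdUnitMode = Literal["paper-months", "si-seconds"]


@dataclass(frozen=True)
class IsothermFit:
    """Per-temperature first-order decay fit of ln(E/E₀) on time."""

    temperature: float        # K
    k_d: float                # month-1 (negative => activity increased)
    intercept: float
    r_squared: float
    n_points: int

    @property
    def deactivation_observed(self) -> bool:
        return self.k_d > 0.0


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius regression of ln k_d on 1/T."""

    E_d: float                # J mol-1
    ln_A: float               # ln(month-1)
    r_squared: float
    temperatures: tuple[float, ...]

    def k_d(self, temperature: float, constants: PhysicalConstants = LITERATURE) -> float:
        """Predicted deactivation constant (month⁻¹) at a temperature."""
        return math.exp(self.ln_A - self.E_d / (constants.R * temperature))


@dataclass(frozen=True)
class ThermoRecord:
    """One row of the thermodynamic summary table."""

    temperature: float              # K
    k_d: float                      # month-1
    t_half: float                   # months
    dH: float | None                # kJ mol-1 (None without an Arrhenius fit)
    dG: float                       # kJ mol-1
    dS: float | None                # J mol-1 K-1
    kd_unit_mode: KdUnitMode = "paper-months"


def fit_kd(
    times: Sequence[float],
    activities: Sequence[float],
    initial_activity: float,
    through_origin: bool = False,
    temperature: float = math.nan,
) -> IsothermFit:
    """Fit ln(E/E₀) vs time (months) by ordinary least squares; k_d = −slope.

    The regression keeps a free intercept by default: E₀ is itself a noisy
    measurement, so forcing the line through ln(1) = 0 would propagate its
    error into the slope.  ``through_origin=True`` forces the intercept to
    zero for sensitivity checks.

    A non-positive slope magnitude (k_d ≤ 0, activity constant or rising)
    is returned as-is and flagged via ``deactivation_observed``; it is not
    an error.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(activities, dtype=float)
    if t.size != a.size or t.size < 2:
        raise ValueError("need at least two paired (time, activity) points")
    if (a <= 0).any():
        raise ValueError("activities must be strictly positive to take logs")
    if initial_activity <= 0:
        raise ValueError("initial activity must be positive")
    if np.ptp(t) == 0:
        raise ValueError("all times identical: slope undefined")

    y = np.log(a / initial_activity)
    if through_origin:
        slope = float(np.dot(t, y) / np.dot(t, t))
        intercept = 0.0
        resid = y - slope * t
    else:
        res = stats.linregress(t, y)
        slope, intercept = float(res.slope), float(res.intercept)
        resid = y - (slope * t + intercept)

    sst = float(((y - y.mean()) ** 2).sum())
    ssr = float((resid**2).sum())
    if sst == 0.0:
        r2 = 1.0 if ssr == 0.0 else 0.0  # constant trace: perfect constant fit
    else:
        r2 = max(0.0, 1.0 - ssr / sst)
    return IsothermFit(
        temperature=temperature,
        k_d=-slope,
        intercept=intercept,
        r_squared=r2,
        n_points=int(t.size),
    )


def half_life(k_d: float) -> float:
    """Half-life t½ = ln2/k_d (months).  Undefined for k_d ≤ 0."""
    if k_d <= 0:
        raise ValueError("half-life undefined for non-positive k_d (no deactivation)")
    return math.log(2.0) / k_d


def arrhenius_fit(
    isotherms: Iterable[IsothermFit | tuple[float, float]],
    constants: PhysicalConstants = LITERATURE,
) -> ArrheniusFit:
    """Regress ln k_d on 1/T; E_d = −slope·R, ln A = intercept.

    Accepts ``IsothermFit`` objects or bare (temperature, k_d) pairs.
    Isotherms with k_d ≤ 0 (no deactivation observed, e.g. activity gain
    under refrigeration) cannot enter the log regression; they are dropped
    with a warning.  At least three positive-k_d isotherms at distinct
    temperatures are required for a reportable E_d.
    """
    pairs: list[tuple[float, float]] = []
    for iso in isotherms:
        T, kd = (iso.temperature, iso.k_d) if isinstance(iso, IsothermFit) else iso
        if kd <= 0:
            log.warning("dropping isotherm at %.2f K: k_d=%.3g <= 0", T, kd)
            continue
        pairs.append((float(T), float(kd)))
    if len(pairs) < 3:
        raise ValueError("Arrhenius fit needs >= 3 isotherms with k_d > 0")
    T = np.array([p[0] for p in pairs])
    kd = np.array([p[1] for p in pairs])
    if np.unique(T).size < 2:
        raise ValueError("Arrhenius fit needs distinct temperatures")
    res = stats.linregress(1.0 / T, np.log(kd))
    r2 = float(res.rvalue**2)
    return ArrheniusFit(
        E_d=-float(res.slope) * constants.R,
        ln_A=float(res.intercept),
        r_squared=r2,
        temperatures=tuple(T.tolist()),
    )


def enthalpy(E_d: float, temperature: float, constants: PhysicalConstants = LITERATURE) -> float:
    """Activation enthalpy ΔH‡ = E_d − R·T, in kJ mol⁻¹ (E_d in J mol⁻¹)."""
    return (E_d - constants.R * temperature) / 1000.0


def gibbs(
    k_d: float,
    temperature: float,
    constants: PhysicalConstants = LITERATURE,
    kd_unit_mode: KdUnitMode = "paper-months",
) -> float:
    """Activation free energy ΔG‡ = −R·T·ln(k_d·h/(k_B·T)), in kJ mol⁻¹.

    See the module docstring for the k_d unit convention behind
    ``kd_unit_mode``.
    """
    if k_d <= 0:
        raise ValueError("Gibbs energy undefined for non-positive k_d")
    if kd_unit_mode == "si-seconds":
        k_d = k_d / SECONDS_PER_MONTH
    elif kd_unit_mode != "paper-months":
        raise ValueError(f"unknown kd_unit_mode {kd_unit_mode!r}")
    R, h, kb = constants.R, constants.h, constants.k_b
    return -R * temperature * math.log(k_d * h / (kb * temperature)) / 1000.0


def entropy(dH: float, dG: float, temperature: float) -> float:
    """Activation entropy ΔS‡ = (ΔH‡ − ΔG‡)/T in J mol⁻¹ K⁻¹ (inputs kJ mol⁻¹)."""
    return (dH - dG) * 1000.0 / temperature


def thermo_table(
    isotherms: Iterable[IsothermFit | tuple[float, float]],
    arrhenius: ArrheniusFit | float | None = None,
    constants: PhysicalConstants = LITERATURE,
    kd_unit_mode: KdUnitMode = "paper-months",
) -> list[ThermoRecord]:
    """Thermodynamic summary, one record per temperature.

    ``arrhenius`` may be an :class:`ArrheniusFit`, a bare E_d in J mol⁻¹,
    or None — in which case the E_d-dependent fields (ΔH‡, hence ΔS‡) are
    left ``None`` and flagged by their absence.
    """
    if isinstance(arrhenius, ArrheniusFit):
        E_d: float | None = arrhenius.E_d
    else:
        E_d = arrhenius
    records = []
    for iso in isotherms:
        T, kd = (iso.temperature, iso.k_d) if isinstance(iso, IsothermFit) else iso
        if kd <= 0:
            log.warning("skipping thermo record at %.2f K: k_d <= 0", T)
            continue
        dG = gibbs(kd, T, constants, kd_unit_mode)
        if E_d is None:
            dH = dS = None
        else:
            dH = enthalpy(E_d, T, constants)
            dS = entropy(dH, dG, T)
        records.append(
            ThermoRecord(
                temperature=T,
                k_d=kd,
                t_half=half_life(kd),
                dH=dH,
                dG=dG,
                dS=dS,
                kd_unit_mode=kd_unit_mode,
            )
        )
    return records


def predict_half_life(
    temperature: float,
    arrhenius: ArrheniusFit,
    constants: PhysicalConstants = LITERATURE,
) -> float:
    """Predicted shelf-life t½ (months) at any temperature from the
    Arrhenius fit; strictly decreasing in T when E_d > 0."""
    return half_life(arrhenius.k_d(temperature, constants))
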