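"""Volumetric, relative and specific laccase activity.

Activity is assayed spectrophotometrically by following ABTS oxidation at
420 nm.  One unit (U) oxidises 1 μmol of ABTS per minute; volumetric
activity is expressed per litre of sample (U L⁻¹):

    U L⁻¹ = (ΔE · V_t · 1e6) / (ε · d · V_s)

with ΔE the absorbance change per minute (AU min⁻¹), V_t the total reaction
volume (mL), ε the molar extinction coefficient of oxidised ABTS
(M⁻¹ cm⁻¹), d the optical path (cm) and V_s the sample volume (mL).  The
1e6 factor converts the molar rate to μmol; without it the quotient is a
molar concentration rate, not U L⁻¹.  The convention is recorded in output
metadata wherever activities are written.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ABTS_EXTINCTION_420NM",
    "AssayReading",
    "ActivityRecord",
    "volumetric_activity",
    "relative_activity",
    "specific_activity",
]

#: Molar extinction coefficient of the ABTS radical cation at 420 nm
#: (M⁻¹ cm⁻¹).  External constant from the assay literature; override per
#: instrument/protocol if a different calibration is in use.
ABTS_EXTINCTION_420NM: float = 36_000.0

_MICROMOL_PER_MOL = 1e6


@dataclass(frozen=True)
class AssayReading:
    """One spectrophotometric reading.

    delta_absorbance : AU min⁻¹ change over the 1-minute reaction
    total_volume_ml  : total reaction volume V_t (mL)
    extinction       : ε (M⁻¹ cm⁻¹)
    path_cm          : cuvette path length d (cm)
    sample_volume_ml : sample volume V_s (mL)
    """

    delta_absorbance: float
    total_volume_ml: float
    extinction: float = ABTS_EXTINCTION_420NM
    path_cm: float = 1.0
    sample_volume_ml: float = 0.02

    def __post_init__(self) -> None:
        if self.total_volume_ml <= 0 or self.sample_volume_ml <= 0:
            raise ValueError("assay volumes must be positive")
        if self.extinction <= 0:
            raise ValueError("extinction coefficient must be positive")
        if self.path_cm <= 0:
            raise ValueError("optical path must be positive")
        if self.delta_absorbance < 0:
            raise ValueError("negative absorbance change: not a valid oxidation run")


@dataclass(frozen=True)
class ActivityRecord:
    """Derived activity quantities for one sample."""

    activity: float                  # U L-1
    relative: float | None = None    # % of initial
    specific: float | None = None    # U mg-1
    protein: float | None = None     # mg L-1


def volumetric_activity(reading: AssayReading) -> float:
    """Volumetric activity (U L⁻¹) from a single assay reading."""
    return (
        reading.delta_absorbance * reading.total_volume_ml * _MICROMOL_PER_MOL
    ) / (reading.extinction * reading.path_cm * reading.sample_volume_ml)


def relative_activity(activity: float, initial_activity: float) -> float:
    """Activity as a percentage of the initial activity.

    Values above 100% are legitimate (storage can transiently activate an
    enzyme preparation) and are not clamped.
    """
    if initial_activity <= 0:
        raise ValueError("initial activity must be positive")
    return 100.0 * activity / initial_activity


def specific_activity(activity: float, protein: float) -> float:
    """Specific activity (U mg⁻¹) from volumetric activity and protein
    concentration (mg L⁻¹)."""
    if protein <= 0:
        raise ValueError("protein concentration must be positive")
    return activity / protein
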