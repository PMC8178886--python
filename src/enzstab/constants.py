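"""Physical constants used by the thermodynamic calculations.

Two precision modes are provided.  The default pins each constant to the
precision customarily quoted in the accelerated-stability literature
(R = 8.314 J mol⁻¹ K⁻¹, h = 6.626e-34 J s, k_B = 1.38e-23 J K⁻¹) so that
published thermodynamic tables can be reproduced digit-for-digit.  The
``codata`` mode switches to full-precision CODATA-2018 values for work where
reproduction of rounded literature tables is not the goal.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PhysicalConstants", "LITERATURE", "CODATA", "SECONDS_PER_MONTH"]

#: Months are calendar-stabilised to 30 days for any month↔second conversion.
SECONDS_PER_MONTH: float = 30.0 * 24.0 * 3600.0


@dataclass(frozen=True)
class PhysicalConstants:
    """Gas constant R, Planck constant h and Boltzmann constant k_B."""

    R: float = 8.314          # J mol-1 K-1
    h: float = 6.626e-34      # J s
    k_b: float = 1.38e-23     # J K-1

    @classmethod
    def literature(cls) -> "PhysicalConstants":
        """Constants at the precision quoted in stability-study reports."""
        return cls()

    @classmethod
    def codata(cls) -> "PhysicalConstants":
        """Full-precision (exact, SI-2019) values."""
        return cls(R=8.31446261815324, h=6.62607015e-34, k_b=1.380649e-23)


LITERATURE = PhysicalConstants.literature()
CODATA = PhysicalConstants.codata()
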