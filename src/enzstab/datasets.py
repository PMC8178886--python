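"""Packaged reference inputs.

The JSON fixture bundles the published summary values of the laccase
storage-stability study this package models — per-temperature deactivation
constants, the fitted deactivation energy, the pilot variability estimate,
the design targets, and the per-temperature Michaelis–Menten parameters.
These are *inputs* (generator ground truth and worked-example parameters),
not expected outputs.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any

__all__ = ["load_published_inputs"]


def load_published_inputs() -> dict[str, Any]:
    """The published study inputs as a plain dictionary."""
    ref = resources.files("enzstab").joinpath("data/published_study.json")
    with ref.open() as fh:
        return json.load(fh)
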