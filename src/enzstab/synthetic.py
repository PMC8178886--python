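"""Synthetic data with known ground truth for every pipeline input.

The generators emulate the study conditions of a year-long storage
stability trial of a recombinant laccase concentrate:

* three production batches (strata) of vials diluted to a common initial
  activity of 16,575.50 U L⁻¹, stored at five temperatures whose
  first-order deactivation constants come from the published
  accelerated-stability table (k_d from 0.003 to 0.400 month⁻¹);
* additive Gaussian measurement noise with SD 96.6 U L⁻¹, the pooled
  pilot-study estimate, truncated at zero with a logged count;
* Michaelis–Menten velocity tables over the assay's 0.1–3 mM ABTS range;
* trajectories built as a reference structure plus independent isotropic
  Gaussian displacements with a per-residue amplitude profile (optionally
  wrapped in global rigid-body motion to exercise superposition).

Everything is deterministic under a fixed seed, and each writer leaves a
JSON sidecar recording the ground truth it was generated from.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import DEFAULT_SCHEDULE
from .kinetics import michaelis_menten
from .trajectory import Trajectory

__all__ = [
    "StudySpec",
    "TrajectorySpec",
    "generate_study",
    "generate_mm_dataset",
    "generate_trajectory",
    "write_study_csv",
]

log = logging.getLogger(__name__)

#: Published per-temperature deactivation constants (month⁻¹) used as the
#: default ground truth (study-mean storage temperatures in K).
TABLE_KD: dict[float, float] = {
    240.98: 3e-3,
    277.40: 0.015,
    297.53: 0.055,
    303.27: 0.135,
    309.58: 0.400,
}

#: Initial activity of the diluted concentrate batches (U L⁻¹).
INITIAL_ACTIVITY = 16_575.50
#: Between-batch SD of the initial activity (U L⁻¹).
INITIAL_ACTIVITY_SD = 268.92
#: Pooled pilot-study measurement SD (U L⁻¹).
PILOT_NOISE_SD = 96.6
#: Specific activity of the concentrate (U mg⁻¹), used to attach a protein
#: concentration column.
SPECIFIC_ACTIVITY = 758.71


@dataclass(frozen=True)
class StudySpec:
    """Conditions of a synthetic stability study."""

    n_batches: int = 3
    vials_per_batch: int = 400
    initial_activity_mean: float = INITIAL_ACTIVITY
    initial_activity_sd: float = INITIAL_ACTIVITY_SD
    temperatures: tuple[float, ...] = tuple(TABLE_KD)
    true_kd: Mapping[float, float] = field(default_factory=lambda: dict(TABLE_KD))
    noise_sd: float = PILOT_NOISE_SD
    schedule_months: tuple[float, ...] = DEFAULT_SCHEDULE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_batches <= 0 or self.vials_per_batch <= 0:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0 or self.initial_activity_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        missing = [T for T in self.temperatures if T not in self.true_kd]
        if missing:
            raise ValueError(f"temperatures missing from true_kd: {missing}")
        if any(k < 0 for k in self.true_kd.values()):
            raise ValueError("deactivation constants must be non-negative")
        if list(self.schedule_months) != sorted(set(self.schedule_months)):
            raise ValueError("schedule must be strictly increasing")


@dataclass(frozen=True)
class TrajectorySpec:
    """Conditions of a synthetic Gaussian-fluctuation trajectory."""

    n_residues: int = 50
    atoms_per_residue: int = 3          # backbone N, CA, C
    n_frames: int = 1000
    amplitude_profile: tuple[float, ...] | None = None   # per-residue SD, Å
    reference_coordinates: np.ndarray | None = None      # (n_atoms, 3) Å
    rigid_body_motion: bool = False
    temperature: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues <= 0 or self.atoms_per_residue <= 0:
            raise ValueError("counts must be positive")
        if self.n_frames < 2:
            raise ValueError("a trajectory needs at least 2 frames")
        if self.amplitude_profile is not None:
            if len(self.amplitude_profile) != self.n_residues:
                raise ValueError("amplitude profile must have one entry per residue")
            if any(a < 0 for a in self.amplitude_profile):
                raise ValueError("amplitudes must be non-negative")


def generate_study(spec: StudySpec) -> pd.DataFrame:
    """Simulate the full vial population of a stability study.

    One record per (batch, temperature, vial, month):
    activity = E₀(batch) · exp(−k_d(T)·t) + N(0, noise_sd), truncated at 0.
    Batch initial activities scatter about the nominal mean with the
    between-batch SD (each batch is diluted to target, imperfectly).
    Vials are partitioned into strata (batches) of equal size.

    Columns: batch, temperature_K, vial_id, month, activity_UL,
    protein_mg_per_L.
    """
    rng = np.random.default_rng(spec.seed)
    batches = [f"L{i + 1}" for i in range(spec.n_batches)]
    batch_e0 = spec.initial_activity_mean + rng.normal(
        0.0, spec.initial_activity_sd, size=spec.n_batches
    )
    protein = batch_e0 / SPECIFIC_ACTIVITY  # mg L-1, constant per batch

    records = []
    n_truncated = 0
    months = np.asarray(spec.schedule_months, dtype=float)
    for T in spec.temperatures:
        kd = spec.true_kd[T]
        for b, (batch, e0, prot) in enumerate(zip(batches, batch_e0, protein)):
            decay = e0 * np.exp(-kd * months)            # (n_months,)
            noise = rng.normal(0.0, spec.noise_sd,
                               size=(spec.vials_per_batch, months.size))
            act = decay[None, :] + noise
            n_truncated += int((act < 0).sum())
            act = np.clip(act, 0.0, None)
            for v in range(spec.vials_per_batch):
                vial_id = b * spec.vials_per_batch + v
                for m, a in zip(months, act[v]):
                    records.append((batch, T, vial_id, m, a, prot))
    if n_truncated:
        log.info("truncated %d negative activity draws to 0", n_truncated)
    df = pd.DataFrame.from_records(
        records,
        columns=["batch", "temperature_K", "vial_id", "month",
                 "activity_UL", "protein_mg_per_L"],
    )
    df.attrs["ground_truth"] = {
        "true_kd": dict(spec.true_kd),
        "batch_E0": {b: float(e) for b, e in zip(batches, batch_e0)},
        "noise_sd": spec.noise_sd,
        "seed": spec.seed,
        "n_truncated": n_truncated,
    }
    return df


def generate_mm_dataset(
    vmax: float,
    km: float,
    s_grid: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    replicates: int = 3,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Michaelis–Menten velocity table: V₀ = vmax·S/(km+S) + N(0, noise_sd).

    The default substrate grid is 8 log-spaced points over the assay's
    0.1–3 mM range, each measured in triplicate.  Columns: S_mM, V0_mM_min.
    """
    if vmax <= 0 or km <= 0:
        raise ValueError("vmax and km must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if s_grid is None:
        s_grid = np.geomspace(0.1, 3.0, 8)
    S = np.repeat(np.asarray(s_grid, dtype=float), replicates)
    V = michaelis_menten(S, vmax, km) + rng.normal(0.0, noise_sd, S.size)
    df = pd.DataFrame({"S_mM": S, "V0_mM_min": V})
    df.attrs["ground_truth"] = {"vmax": vmax, "km": km, "noise_sd": noise_sd}
    return df


def _default_reference(n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """A smooth helical backbone so the reference is non-degenerate."""
    t = np.arange(n_atoms) * 0.6
    return np.column_stack([4.0 * np.cos(t), 4.0 * np.sin(t), 1.5 * t])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q


def generate_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Gaussian-fluctuation trajectory about a reference structure.

    Each frame is the reference plus independent isotropic Gaussian
    displacements: every coordinate of every atom of residue r gets
    N(0, amplitude_profile[r]) noise, so the expected per-atom RMSF is
    amplitude·√3.  With ``rigid_body_motion`` a random rotation and
    translation is applied per frame; all fluctuation measures must be
    invariant to it after superposition.
    """
    rng = np.random.default_rng(spec.seed)
    n_atoms = spec.n_residues * spec.atoms_per_residue
    ref = (np.asarray(spec.reference_coordinates, dtype=float)
           if spec.reference_coordinates is not None
           else _default_reference(n_atoms, rng))
    if ref.shape != (n_atoms, 3):
        raise ValueError("reference coordinates must have shape (n_atoms, 3)")
    amp = (np.asarray(spec.amplitude_profile, dtype=float)
           if spec.amplitude_profile is not None
           else np.full(spec.n_residues, 0.5))
    atom_amp = np.repeat(amp, spec.atoms_per_residue)

    coords = ref[None, :, :] + rng.normal(
        0.0, 1.0, size=(spec.n_frames, n_atoms, 3)
    ) * atom_amp[None, :, None]
    if spec.rigid_body_motion:
        for i in range(spec.n_frames):
            R = _random_rotation(rng)
            t = rng.normal(0.0, 10.0, size=3)
            coords[i] = coords[i] @ R.T + t

    backbone = ["N", "CA", "C"]
    names = [backbone[a % 3] if spec.atoms_per_residue == 3 else f"X{a}"
             for a in range(spec.atoms_per_residue)]
    atom_names = np.array(names * spec.n_residues, dtype=object)
    residue_ids = np.repeat(np.arange(1, spec.n_residues + 1), spec.atoms_per_residue)
    return Trajectory(coords=coords, atom_names=atom_names,
                      residue_ids=residue_ids, temperature=spec.temperature)


def write_study_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table plus its ground-truth JSON sidecar."""
    path = Path(path)
    df.to_csv(path, index=False)
    truth = df.attrs.get("ground_truth", {})
    with open(path.with_suffix(".truth.json"), "w") as fh:
        json.dump(truth, fh, indent=2)
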