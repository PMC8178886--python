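"""Trajectory fluctuation analysis: RMSD, per-residue RMSF, ΔRMSF and
Cα-covariance PCA.

This module post-processes molecular-dynamics trajectories (it never runs
them).  All operators work on a plain :class:`Trajectory` container —
frames × atoms × 3 coordinates in Å with an atom→residue map — so the same
code handles multi-model PDB files, whitespace XYZ files with a residue
sidecar, or synthetic coordinate arrays.

Rigid-body motion is removed by least-squares (Kabsch) superposition with
a proper rotation enforced.  Per-residue RMSF averages the per-atom
fluctuations of the backbone skeleton (C, CA, N) about the time-average
structure after one iterative fit pass (fit to the first frame, recompute
the mean, refit to the mean).  ΔRMSF profiles are differences against a
base temperature (the lowest, by the study's convention); residues whose
ΔRMSF spread across temperatures exceeds a 0.5 Å standard-deviation cutoff
are flagged and merged into fluctuating regions.  PCA diagonalises the
3N×3N covariance of the superposed Cα coordinates; per-residue
contributions are the squared norms of each residue's three eigenvector
components, normalised to sum to one per component.

Hydrogens are excluded everywhere by an atom-name filter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "FluctuationProfile",
    "PCAResult",
    "superpose",
    "superpose_trajectory",
    "rmsd_series",
    "rmsf_per_residue",
    "delta_rmsf",
    "flag_fluctuating",
    "find_regions",
    "pca_ca",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_xyz",
    "write_xyz",
]

BACKBONE_ATOMS = ("N", "CA", "C")


def _is_hydrogen(name: str) -> bool:
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() == "H"


@dataclass
class Trajectory:
    """Coordinates (n_frames, n_atoms, 3) in Å with atom metadata."""

    coords: np.ndarray
    atom_names: np.ndarray          # str per atom
    residue_ids: np.ndarray         # int per atom
    temperature: float | None = None  # K label

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.atom_names.size or self.coords.shape[1] != self.residue_ids.size:
            raise ValueError("atom metadata must match the atom count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    @property
    def residues(self) -> np.ndarray:
        """Unique residue ids in file order."""
        _, idx = np.unique(self.residue_ids, return_index=True)
        return self.residue_ids[np.sort(idx)]

    def selection(self, atom_names: Sequence[str] | None = None,
                  include_hydrogens: bool = False) -> np.ndarray:
        """Boolean atom mask by atom name, hydrogens dropped by default."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if atom_names is not None:
            wanted = {n.strip().upper() for n in atom_names}
            mask &= np.array([str(n).strip().upper() in wanted for n in self.atom_names])
        if not include_hydrogens:
            mask &= ~np.array([_is_hydrogen(str(n)) for n in self.atom_names])
        return mask


@dataclass
class FluctuationProfile:
    """Per-residue fluctuation summary at one temperature."""

    residue_ids: np.ndarray
    rmsf: np.ndarray                          # Å
    temperature: float | None = None
    delta_rmsf: np.ndarray | None = None      # vs base, Å
    flagged: np.ndarray | None = None         # residue ids
    regions: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class PCAResult:
    """Eigenstructure of the Cα positional covariance."""

    eigenvalues: np.ndarray                   # Å², descending, top-k
    variance_proportions: np.ndarray          # λ_i / Σλ over the full spectrum
    eigenvectors: np.ndarray                  # (3N, k), columns
    residue_ids: np.ndarray
    residue_contributions: np.ndarray         # (n_residues, k), each column sums to 1
    mean_structure: np.ndarray                # (N, 3)


# ---------------------------------------------------------------------------
# superposition

def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference`` (Kabsch).

    Returns ``(rotation, translation, rmsd)`` where the fitted coordinates
    are ``mobile @ rotation.T + translation`` and the RMSD is evaluated over
    the selection used for fitting.  A proper rotation (det = +1) is
    enforced.  Degenerate selections — fewer than three atoms, or atoms
    that are coincident/collinear — are rejected.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have matching shapes")
    sel = np.ones(mobile.shape[0], bool) if selection is None else np.asarray(selection, bool)
    m, r = mobile[sel], reference[sel]
    if m.shape[0] < 3:
        raise ValueError("superposition needs at least 3 selected atoms")

    mc, rc = m.mean(axis=0), r.mean(axis=0)
    P, Q = m - mc, r - rc
    # rank < 2 => coincident or collinear points: rotation underdetermined
    if np.linalg.matrix_rank(P, tol=1e-10) < 2:
        raise ValueError("degenerate selection: coincident or collinear atoms")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    fitted = m @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - r) ** 2, axis=1))))
    return R, t, rmsd


def superpose_trajectory(traj: Trajectory, reference: np.ndarray,
                         selection: np.ndarray | None = None) -> np.ndarray:
    """All frames rigidly fitted to ``reference``; returns fitted coords."""
    out = np.empty_like(traj.coords)
    for i, frame in enumerate(traj.coords):
        R, t, _ = superpose(frame, reference, selection)
        out[i] = frame @ R.T + t
    return out


def rmsd_series(
    traj: Trajectory,
    reference: np.ndarray | None = None,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (Å) after superposing each frame onto the reference
    (default: the first frame) over the selection (default: heavy atoms)."""
    if reference is None:
        reference = traj.coords[0]
    if selection is None:
        selection = traj.selection()
    return np.array([
        superpose(frame, reference, selection)[2] for frame in traj.coords
    ])


def _mean_fitted(traj: Trajectory, selection: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One iterative fit pass: fit to frame 0, average, refit to the average."""
    fitted = superpose_trajectory(traj, traj.coords[0], selection)
    mean = fitted.mean(axis=0)
    refitted = superpose_trajectory(
        Trajectory(fitted, traj.atom_names, traj.residue_ids), mean, selection
    )
    return refitted, refitted.mean(axis=0)


def rmsf_per_residue(
    traj: Trajectory,
    atom_names: Sequence[str] = BACKBONE_ATOMS,
) -> FluctuationProfile:
    """Backbone RMSF (Å) averaged per residue.

    Frames are superposed on the time-average structure; per-atom RMSF is
    the root-mean-square deviation from the time-average position, and the
    residue value averages its selected backbone atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = traj.selection(atom_names)
    if not sel.any():
        raise ValueError("selection matches no atoms")
    fitted, mean = _mean_fitted(traj, sel)
    dev2 = np.sum((fitted - mean) ** 2, axis=2)        # (frames, atoms)
    atom_rmsf = np.sqrt(dev2.mean(axis=0))             # (atoms,)

    residues = traj.residues
    values = np.array([
        atom_rmsf[sel & (traj.residue_ids == rid)].mean() for rid in residues
    ])
    return FluctuationProfile(residue_ids=residues, rmsf=values,
                              temperature=traj.temperature)


def delta_rmsf(profile: FluctuationProfile, base: FluctuationProfile) -> FluctuationProfile:
    """ΔRMSF = RMSF(T) − RMSF(base), per residue.  Positive values mean the
    residue fluctuates more than at the base temperature."""
    if not np.array_equal(profile.residue_ids, base.residue_ids):
        raise ValueError("profiles cover different residue sets")
    return FluctuationProfile(
        residue_ids=profile.residue_ids,
        rmsf=profile.rmsf,
        temperature=profile.temperature,
        delta_rmsf=profile.rmsf - base.rmsf,
    )


def flag_fluctuating(
    delta_profiles: Sequence[FluctuationProfile],
    cutoff: float = 0.5,
) -> np.ndarray:
    """Residues whose ΔRMSF spread exceeds the cutoff (Å).

    The standard deviation (ddof=1) is taken per residue across the set of
    ΔRMSF profiles (one per non-base temperature); residues with SD
    strictly greater than ``cutoff`` are flagged.
    """
    if not delta_profiles:
        raise ValueError("need at least one delta profile")
    ids = delta_profiles[0].residue_ids
    deltas = []
    for p in delta_profiles:
        if p.delta_rmsf is None:
            raise ValueError("profile lacks delta_rmsf; call delta_rmsf() first")
        if not np.array_equal(p.residue_ids, ids):
            raise ValueError("profiles cover different residue sets")
        deltas.append(p.delta_rmsf)
    spread = np.vstack(deltas).std(axis=0, ddof=1 if len(deltas) > 1 else 0)
    return ids[spread > cutoff]


def find_regions(
    flagged: Sequence[int],
    gap_tolerance: int = 2,
    min_size: int = 2,
) -> list[tuple[int, int]]:
    """Merge flagged residues into maximal intervals.

    Residues whose indices differ by at most ``gap_tolerance + 1`` join the
    same interval; intervals spanning fewer than ``min_size`` residues are
    dropped (isolated fluctuating residues are reported separately by the
    caller, not as regions).
    """
    ids = sorted(set(int(r) for r in flagged))
    if not ids:
        return []
    regions: list[tuple[int, int]] = []
    start = prev = ids[0]
    for r in ids[1:]:
        if r - prev <= gap_tolerance + 1:
            prev = r
        else:
            regions.append((start, prev))
            start = prev = r
    regions.append((start, prev))
    return [(a, b) for a, b in regions if b - a + 1 >= min_size]


# ---------------------------------------------------------------------------
# PCA

def pca_ca(traj: Trajectory, k: int = 5) -> PCAResult:
    """PCA of the Cα positional covariance.

    The covariance matrix (3N × 3N) of the RMS-fitted Cα coordinates is
    diagonalised; the top-``k`` eigenpairs are reported with variance
    proportions λᵢ/Σλ over the full spectrum.  Per-residue contribution to
    a component is the squared norm of that residue's three eigenvector
    entries (they sum to one per component since eigenvectors are unit).
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    sel = traj.selection(["CA"])
    if not sel.any():
        raise ValueError("no CA atoms in trajectory")
    sub = Trajectory(traj.coords[:, sel, :], traj.atom_names[sel],
                     traj.residue_ids[sel], traj.temperature)
    fitted, mean = _mean_fitted(sub, np.ones(sub.n_atoms, bool))

    X = fitted.reshape(sub.n_frames, -1) - mean.reshape(-1)
    n3 = X.shape[1]
    rank = min(sub.n_frames - 1, n3)
    if k > rank:
        raise ValueError(f"k={k} exceeds covariance rank {rank}")
    cov = X.T @ X / (sub.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)

    total = evals.sum()
    proportions = evals[:k] / total if total > 0 else np.zeros(k)
    vecs = evecs[:, :k]
    per_res = (vecs.reshape(-1, 3, k) ** 2).sum(axis=1)   # (N, k)
    per_res = per_res / per_res.sum(axis=0, keepdims=True)
    return PCAResult(
        eigenvalues=evals[:k],
        variance_proportions=proportions,
        eigenvectors=vecs,
        residue_ids=sub.residue_ids,
        residue_contributions=per_res,
        mean_structure=mean,
    )


# ---------------------------------------------------------------------------
# I/O

def read_multimodel_pdb(path: str | Path, temperature: float | None = None) -> Trajectory:
    """Read a multi-model PDB (MODEL/ENDMDL records) into a Trajectory."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()           # AtomArrayStack
    coords = np.asarray(stack.coord, dtype=float)
    if coords.ndim == 2:                  # single model
        coords = coords[None, ...]
    return Trajectory(
        coords=coords,
        atom_names=np.asarray(stack.atom_name, dtype=object),
        residue_ids=np.asarray(stack.res_id, dtype=int),
        temperature=temperature,
    )


def write_multimodel_pdb(traj: Trajectory, path: str | Path,
                         res_names: Sequence[str] | None = None) -> None:
    """Write a Trajectory as a multi-model PDB via biotite."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    n = traj.n_atoms
    atoms = struc.AtomArrayStack(traj.n_frames, n)
    atoms.coord = np.asarray(traj.coords, dtype=np.float32)
    atoms.atom_name = np.asarray([str(a) for a in traj.atom_names])
    atoms.res_id = np.asarray(traj.residue_ids, dtype=int)
    atoms.res_name = np.asarray(res_names if res_names is not None else ["ALA"] * n)
    atoms.chain_id = np.asarray(["A"] * n)
    atoms.element = np.asarray([str(a).strip()[:1] for a in traj.atom_names])
    atoms.hetero = np.zeros(n, dtype=bool)
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def read_xyz(path: str | Path, residue_map: str | Path) -> Trajectory:
    """Read a whitespace XYZ trajectory plus a JSON residue-map sidecar.

    The XYZ format repeats, per frame: an atom-count line, a comment line,
    then ``name x y z`` lines.  The sidecar maps atom order to residues:
    ``{"residue_ids": [...], "atom_names": [...], "temperature": ...}``
    (atom_names optional; XYZ element symbols are used when absent).
    """
    with open(residue_map) as fh:
        side = json.load(fh)
    lines = Path(path).read_text().split("\n")
    frames, names = [], None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].split()[0])
        block = lines[i + 2: i + 2 + n]
        frame_names, xyz = [], []
        for row in block:
            parts = row.split()
            frame_names.append(parts[0])
            xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(xyz)
        names = frame_names
        i += 2 + n
    coords = np.asarray(frames, dtype=float)
    atom_names = np.asarray(side.get("atom_names", names), dtype=object)
    return Trajectory(
        coords=coords,
        atom_names=atom_names,
        residue_ids=np.asarray(side["residue_ids"], dtype=int),
        temperature=side.get("temperature"),
    )


def write_xyz(traj: Trajectory, path: str | Path, residue_map: str | Path) -> None:
    """Write a whitespace XYZ trajectory with its JSON residue-map sidecar."""
    with open(path, "w") as fh:
        for f, frame in enumerate(traj.coords):
            fh.write(f"{traj.n_atoms}\nframe {f}\n")
            for name, (x, y, z) in zip(traj.atom_names, frame):
                fh.write(f"{name} {x:.6f} {y:.6f} {z:.6f}\n")
    side = {
        "residue_ids": [int(r) for r in traj.residue_ids],
        "atom_names": [str(a) for a in traj.atom_names],
        "temperature": traj.temperature,
    }
    with open(residue_map, "w") as fh:
        json.dump(side, fh)
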