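"""Structural metrics: Kabsch superposition, RMSD series, per-residue RMSF.

RMSD measures the whole-selection displacement of a frame from a
reference after optimal rigid-body superposition; RMSF measures the
per-atom fluctuation about the time-average structure (frames are
superposed to the reference first, so drift is not conflated with
fluctuation), averaged within each residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .model_io import Frame, MolecularSystem, Trajectory

__all__ = [
    "BACKBONE_NAMES",
    "Superposition",
    "kabsch_superpose",
    "select_atoms",
    "rmsd_series",
    "rmsf_per_residue",
]

#: Protein backbone atom names used for "backbone" selections.
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O"})


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid superposition y -> R y + t minimizing RMSD to x."""

    rotation: np.ndarray     # (3, 3), proper orthonormal
    translation: np.ndarray  # (3,), angstrom
    rmsd: float              # angstrom

    def apply(self, y: np.ndarray) -> np.ndarray:
        return y @ self.rotation.T + self.translation


def kabsch_superpose(
    x: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None
) -> Superposition:
    """Weighted least-squares rigid superposition of y onto x (Kabsch).

    Returns the proper rotation R and translation t minimizing
    sum_i w_i |x_i - (R y_i + t)|^2, and the weighted RMSD of the
    superposed pair. Requires >= 3 non-collinear points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("x and y must be matching (n, 3) arrays")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for a superposition")
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    wsum = weights.sum()
    xc = x - np.average(x, axis=0, weights=weights)
    yc = y - np.average(y, axis=0, weights=weights)
    for label, arr in (("x", xc), ("y", yc)):
        s = np.linalg.svd(arr * np.sqrt(weights)[:, None], compute_uv=False)
        if s[1] <= 1e-10 * max(s[0], 1.0):
            raise ValueError(f"{label} coordinates are collinear or "
                             "degenerate; superposition is ill-defined")
    rot, _ = Rotation.align_vectors(xc, yc, weights=weights)
    r_mat = rot.as_matrix()
    resid = xc - yc @ r_mat.T
    rmsd = float(np.sqrt(np.sum(weights * np.sum(resid**2, axis=1)) / wsum))
    t = np.average(x, axis=0, weights=weights) - r_mat @ np.average(
        y, axis=0, weights=weights
    )
    return Superposition(rotation=r_mat, translation=t, rmsd=rmsd)


def select_atoms(
    system: MolecularSystem,
    names: Sequence[str] | str | None = None,
    groups: Sequence[str] | None = None,
    indices: np.ndarray | None = None,
) -> np.ndarray:
    """Resolve an atom selection to an index array.

    ``names`` may be the string ``"backbone"`` (N, CA, C, O of protein
    residues) or a list of atom names; ``groups`` a list of group labels;
    ``indices`` an explicit array. Criteria combine with AND.
    """
    mask = np.ones(system.n_atoms, dtype=bool)
    if names is not None:
        if isinstance(names, str):
            if names != "backbone":
                raise ValueError("string selection must be 'backbone'")
            mask &= np.isin(system.names, sorted(BACKBONE_NAMES))
            mask &= system.group_mask("protein")
        else:
            mask &= np.isin(system.names, list(names))
    if groups is not None:
        mask &= system.group_mask(*groups)
    if indices is not None:
        explicit = np.zeros(system.n_atoms, dtype=bool)
        explicit[np.asarray(indices, dtype=int)] = True
        mask &= explicit
    sel = np.flatnonzero(mask)
    if sel.size == 0:
        raise ValueError("empty atom selection")
    return sel


def rmsd_series(
    trajectory: Trajectory,
    reference: Frame | None = None,
    selection: np.ndarray | None = None,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (angstrom) of a selection against a reference frame.

    The reference defaults to the first frame. With ``superpose`` each
    frame is optimally superposed on the selection before measuring;
    without it, raw displacement is reported.
    """
    reference = reference or trajectory.frames[0]
    if selection is None:
        selection = np.arange(trajectory.system.n_atoms)
    if selection.size == 0:
        raise ValueError("empty atom selection")
    ref = reference.coordinates[selection]
    out = np.empty(trajectory.n_frames)
    for j, f in enumerate(trajectory.frames):
        mob = f.coordinates[selection]
        if superpose:
            out[j] = kabsch_superpose(ref, mob).rmsd
        else:
            out[j] = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
    return out


def rmsf_per_residue(
    trajectory: Trajectory,
    selection: np.ndarray | None = None,
    superpose: bool = True,
    reference_index: int = 0,
) -> pd.Series:
    """Per-residue RMSF (angstrom): per-atom sqrt(<|r_i(t) - <r_i>|^2>)
    after superposing every frame to the reference frame, averaged within
    each residue.

    Returns a Series indexed by (chain, residue_index, residue_name).
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    system = trajectory.system
    if selection is None:
        selection = np.arange(system.n_atoms)
    ref = trajectory.frames[reference_index].coordinates[selection]
    stacked = np.empty((trajectory.n_frames, selection.size, 3))
    for j, f in enumerate(trajectory.frames):
        mob = f.coordinates[selection]
        stacked[j] = kabsch_superpose(ref, mob).apply(mob) if superpose else mob
    mean_pos = stacked.mean(axis=0)
    per_atom = np.sqrt(
        np.mean(np.sum((stacked - mean_pos) ** 2, axis=2), axis=0)
    )
    key = pd.MultiIndex.from_arrays(
        [
            system.chains[selection],
            system.residue_indices[selection],
            system.residue_names[selection],
        ],
        names=["chain", "residue_index", "residue_name"],
    )
    return (
        pd.Series(per_atom, index=key, name="rmsf")
        .groupby(level=[0, 1, 2], sort=False)
        .mean()
    )
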