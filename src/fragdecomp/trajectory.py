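"""Rigid-body superposition and trajectory descriptors: RMSD, ΔRMSD, RMSF.

All quantities are in Å and ns.  Superposition uses the Kabsch algorithm
(least-squares optimal proper rotation); RMSD is reported over a selection
("heavy_atoms" by default, matching the all-heavy-atom convention of MD
stability plots), ΔRMSD is the max−min spread of the RMSD series within a
time window, and RMSF is the per-residue root-mean-square fluctuation of
atoms about their time-averaged positions after per-frame fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .mol_io import Structure, Trajectory

__all__ = [
    "RmsdSeries",
    "RmsfProfile",
    "kabsch_superpose",
    "rmsd",
    "rmsd_series",
    "delta_rmsd",
    "rmsf",
    "selection_indices",
]

Selection = Literal["heavy_atoms", "all"] | Sequence[int]


@dataclass(eq=False)
class RmsdSeries:
    times: np.ndarray
    values: np.ndarray
    selection_label: str = "heavy_atoms"
    reference_label: str = "first_frame"


@dataclass(eq=False)
class RmsfProfile:
    residue_ids: list[tuple]
    rmsf_values: np.ndarray


def selection_indices(structure: Structure, selection: Selection) -> np.ndarray:
    """Atom indices (in structure order) for a named or explicit selection."""
    if isinstance(selection, str):
        if selection == "all":
            return np.arange(structure.n_atoms)
        if selection == "heavy_atoms":
            return np.array([i for i, a in enumerate(structure.atoms)
                             if not a.is_hydrogen], dtype=int)
        raise ValueError(f"unknown selection {selection!r}")
    return np.asarray(selection, dtype=int)


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     fit_selection: Sequence[int] | None = None,
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, transformed)`` such that
    ``transformed = mobile @ rotation.T + translation``; the rotation is
    proper (determinant +1).  The fit is computed over ``fit_selection``
    (all atoms when None) and applied to every atom.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = (np.arange(len(mobile)) if fit_selection is None
           else np.asarray(fit_selection, dtype=int))
    if len(sel) < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    m = mobile[sel]
    r = reference[sel]
    cm, cr = m.mean(axis=0), r.mean(axis=0)
    h = (m - cm).T @ (r - cr)
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) fit selection")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rotation = vt.T @ diag @ u.T
    translation = cr - rotation @ cm
    transformed = mobile @ rotation.T + translation
    return rotation, translation, transformed


def rmsd(frame: Structure, reference: Structure,
         selection: Selection = "heavy_atoms", fit: bool = True) -> float:
    """Root-mean-square deviation (Å) between corresponding atoms."""
    if frame.n_atoms != reference.n_atoms:
        raise ValueError(
            f"atom-count mismatch: {frame.n_atoms} vs {reference.n_atoms}")
    idx = selection_indices(frame, selection)
    x = frame.coords()
    y = reference.coords()
    if fit:
        _, _, x = kabsch_superpose(x, y, idx)
    diff = x[idx] - y[idx]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def rmsd_series(trajectory: Trajectory,
                reference: Literal["first_frame"] | Structure = "first_frame",
                selection: Selection = "heavy_atoms",
                fit: bool = True) -> RmsdSeries:
    """Per-frame RMSD against a fixed reference structure."""
    ref = trajectory.frames[0] if reference == "first_frame" else reference
    values = np.array([rmsd(f, ref, selection, fit) for f in trajectory])
    label = selection if isinstance(selection, str) else "custom"
    ref_label = "first_frame" if reference == "first_frame" else "supplied"
    return RmsdSeries(times=np.asarray(trajectory.times, dtype=float),
                      values=values, selection_label=label,
                      reference_label=ref_label)


def delta_rmsd(series: RmsdSeries, window: tuple[float, float]) -> float:
    """Spread (max − min, Å) of the RMSD values inside a time window."""
    t0, t1 = window
    mask = (series.times >= t0) & (series.times <= t1)
    if not np.any(mask):
        raise ValueError(f"window {window} contains no samples")
    vals = series.values[mask]
    return float(vals.max() - vals.min())


def rmsf(trajectory: Trajectory, selection: Selection = "heavy_atoms",
         fit_reference: Literal["mean_structure", "first_frame"] = "mean_structure",
         fit: bool = True) -> RmsfProfile:
    """Per-residue RMSF (Å) about time-mean positions after superposition.

    Each frame is fitted (over the selection) to the reference — the first
    frame, or the iterated mean structure — then for every selected atom the
    mean squared displacement about its time-mean position is computed and
    averaged over the residue's selected atoms before taking the root.
    """
    first = trajectory.frames[0]
    idx = selection_indices(first, selection)
    coords = trajectory.coords()
    if len(trajectory) == 1:
        warnings.warn("single-frame trajectory: RMSF is identically zero",
                      stacklevel=2)

    def fit_all(ref: np.ndarray) -> np.ndarray:
        out = np.empty_like(coords)
        for i, x in enumerate(coords):
            _, _, out[i] = kabsch_superpose(x, ref, idx)
        return out

    if fit and len(trajectory) > 1:
        fitted = fit_all(coords[0])
        if fit_reference == "mean_structure":
            fitted = fit_all(fitted.mean(axis=0))
    else:
        fitted = coords

    mean_pos = fitted.mean(axis=0)
    msf_per_atom = np.mean(np.sum((fitted - mean_pos) ** 2, axis=2), axis=0)

    residue_ids: list[tuple] = []
    values = []
    sel_set = set(idx.tolist())
    pos = 0
    for res in first.residues:
        atom_idx = [pos + k for k in range(len(res.atoms))]
        pos += len(res.atoms)
        chosen = [i for i in atom_idx if i in sel_set]
        if not chosen:
            continue
        residue_ids.append(res.residue_id)
        values.append(float(np.sqrt(np.mean(msf_per_atom[chosen]))))
    return RmsfProfile(residue_ids=residue_ids,
                       rmsf_values=np.array(values))
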