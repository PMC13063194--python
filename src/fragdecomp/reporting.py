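"""Ensemble statistics, BIRD panels, pose classification and export.

``ensemble_stats`` summarises per-conformation interaction energies with
the mean, both standard-deviation conventions (population, n denominator;
sample, n−1) and the coefficient of variation C_V = 100·σ/|mean|; published
tables of this kind mix the two conventions, so both are always stored and
the one used for display is explicit.

A BIRD panel (Binding site, Interaction energy, Residue Domain) lists each
binding-site residue's interaction energy tagged with the ligand region it
chiefly engages and the contact types it makes; pose classification assigns
docked poses to named binding sites by proximity and surfaces per-site
frequencies and best scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .mfcc import ResidueEnergy
from .mol_io import Atom, Residue, Structure, min_atom_distance

__all__ = [
    "StatsRow",
    "PoseRecord",
    "BirdPanel",
    "PoseClassification",
    "ensemble_stats",
    "bird_panel",
    "classify_poses",
    "combined_site_mean",
]


@dataclass
class StatsRow:
    """Summary statistics of one set of per-conformation energies (kcal/mol)."""

    label: str
    values: list[float]
    mean: float
    sigma_population: float
    sigma_sample: float
    cv_percent: float
    sigma_convention_used: Literal["population", "sample"]

    def presentation(self, from_rounded: bool = False) -> dict[str, float]:
        """Rounded display values: mean 1 d.p., σ 2 d.p., C_V 1 d.p.

        With ``from_rounded`` the C_V is recomputed from the already rounded
        mean and σ, mirroring tables typeset that way.
        """
        sigma = (self.sigma_population
                 if self.sigma_convention_used == "population"
                 else self.sigma_sample)
        if from_rounded:
            cv = 100.0 * round(sigma, 2) / abs(round(self.mean, 1))
        else:
            cv = self.cv_percent
        return {"mean": round(self.mean, 1), "sigma": round(sigma, 2),
                "cv_percent": round(cv, 1)}


@dataclass(eq=False)
class PoseRecord:
    """One docked pose: identifier, docking score and ligand coordinates."""

    pose_id: str
    score: float
    coordinates: list[Atom]
    assigned_site: str = "unassigned"

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"pose {self.pose_id}: non-finite score")


@dataclass(eq=False)
class BirdPanel:
    rows: list[dict]
    total: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


@dataclass(eq=False)
class PoseClassification:
    frequencies: dict[str, int]
    best_pose: dict[str, PoseRecord]
    headline: list[tuple[str, PoseRecord]]


def ensemble_stats(values: Sequence[float], label: str = "",
                   sigma_convention: Literal["population", "sample"] = "sample",
                   ) -> StatsRow:
    """Mean, both σ conventions and C_V of per-conformation energies.

    Rounding happens only at presentation; the stored statistics are exact.
    """
    values = [float(v) for v in values]
    if len(values) < 2:
        raise ValueError("need at least 2 values for dispersion statistics")
    arr = np.asarray(values)
    mean = float(arr.mean())
    sigma_pop = float(arr.std(ddof=0))
    sigma_samp = float(arr.std(ddof=1))
    sigma = sigma_pop if sigma_convention == "population" else sigma_samp
    if mean == 0:
        raise ValueError("C_V undefined for zero mean")
    return StatsRow(label=label, values=values, mean=mean,
                    sigma_population=sigma_pop, sigma_sample=sigma_samp,
                    cv_percent=100.0 * sigma / abs(mean),
                    sigma_convention_used=sigma_convention)


def bird_panel(energies: Sequence[ResidueEnergy],
               contacts: Sequence[tuple[tuple, str, float]] = (),
               sort: Literal["by_energy", "by_sequence"] = "by_energy",
               ) -> BirdPanel:
    """Assemble the per-residue energy panel with region tags and contact types."""
    contact_types: dict[tuple, list[str]] = {}
    for rid, ctype, _dist in contacts:
        contact_types.setdefault(rid, []).append(ctype)
    rows = []
    for e in energies:
        rows.append({
            "residue": e.label,
            "residue_id": e.residue_id,
            "energy_kcal_mol": e.energy,
            "region_tag": e.region_tag,
            "contact_types": sorted(set(contact_types.get(e.residue_id, []))),
        })
    if sort == "by_energy":
        rows.sort(key=lambda r: r["energy_kcal_mol"])
    elif sort == "by_sequence":
        rows.sort(key=lambda r: (r["residue_id"][0], r["residue_id"][1]))
    else:
        raise ValueError(f"unknown sort {sort!r}")
    return BirdPanel(rows=rows, total=float(sum(e.energy for e in energies)))


def classify_poses(poses: Sequence[PoseRecord],
                   sites: dict[str, set[tuple]],
                   structure: Structure,
                   assign_cutoff: float = 5.0) -> PoseClassification:
    """Assign poses to binding sites by proximity; tabulate frequency and best score.

    A pose goes to the site whose defining residues lie closest to it
    (minimum inter-atomic distance), provided that distance is within
    ``assign_cutoff``; otherwise it is unassigned.  The headline surfaces
    the lowest-score pose in each of the two most frequently hit sites.
    """
    if not poses:
        raise ValueError("no poses to classify")
    site_atoms: dict[str, list[Atom]] = {}
    for site, residue_ids in sites.items():
        atoms: list[Atom] = []
        for rid in residue_ids:
            atoms.extend(structure.find_residue(rid).atoms)
        if not atoms:
            raise ValueError(f"site {site} references no atoms")
        site_atoms[site] = atoms

    frequencies = {site: 0 for site in sites}
    frequencies["unassigned"] = 0
    best: dict[str, PoseRecord] = {}
    for pose in poses:
        dists = {site: min_atom_distance(pose.coordinates, atoms)
                 for site, atoms in site_atoms.items()}
        site = min(dists, key=dists.get)
        if dists[site] > assign_cutoff:
            site = "unassigned"
        pose.assigned_site = site
        frequencies[site] += 1
        if site != "unassigned":
            cur = best.get(site)
            if (cur is None or pose.score < cur.score
                    or (pose.score == cur.score and pose.pose_id < cur.pose_id)):
                best[site] = pose

    top_sites = sorted((s for s in sites if frequencies[s] > 0),
                       key=lambda s: (-frequencies[s], s))[:2]
    headline = [(s, best[s]) for s in top_sites if s in best]
    return PoseClassification(frequencies=frequencies, best_pose=best,
                              headline=headline)


def combined_site_mean(mean_a: float, mean_b: float) -> float:
    """Arithmetic mean of the magnitudes of two per-site mean energies.

    Used to compare ligands by their overall affinity across two binding
    sites; the result is a positive magnitude in kcal/mol.
    """
    return (abs(mean_a) + abs(mean_b)) / 2.0
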