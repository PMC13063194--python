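"""Conjugate-cap fragmentation and per-residue interaction-energy decomposition.

For a residue of interest R_i in a protein chain, the decomposition builds
four auxiliary systems from R_i, its sequence neighbours acting as
*conjugate caps*, and the ligand L:

    S1 = caps + R_i + L        S2 = caps + R_i
    S3 = caps + L              S4 = caps

and evaluates the interaction energy as

    E(L - R_i) = E_S1 - E_S2 - E_S3 + E_S4

with a pluggable :class:`~fragdecomp.energy.EnergyBackend`.  The caps are
the full adjacent residues, severed at their distal backbone bonds, with
every dangling bond passivated by a hydrogen placed on the severed-bond
axis (1.09 Å from carbon, 1.01 Å from nitrogen).  Cap atoms are the *same
objects* in all four systems, so for any pairwise-additive backend every
cap-involving term cancels algebraically and the combination equals the
exact R_i–L cross interaction; for a quantum-chemical backend the caps
approximate the electronic environment of the peptide bond.

Bridging waters, when included, are placed identically in all four systems,
so they too cancel for pairwise backends while letting a quantum backend
see the bridging environment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .energy import EnergyBackend
from .mol_io import (Atom, LigandRegionMap, Residue, Structure,
                     min_atom_distance, write_pdb)

__all__ = [
    "SelectionCriteria",
    "SelectedResidue",
    "CappedFragment",
    "MFCCSystems",
    "ResidueEnergy",
    "DecompositionProfile",
    "select_binding_residues",
    "select_bridging_waters",
    "build_capped_fragment",
    "assemble_systems",
    "mfcc_interaction_energy",
    "decompose_site",
    "radius_profile",
    "export_systems",
    "energies_to_frame",
]

#: Passivating hydrogen bond lengths (Å) by the heavy atom left dangling.
PASSIVATION_BOND_LENGTH = {"C": 1.09, "N": 1.01}


@dataclass
class SelectionCriteria:
    """Geometric cutoffs of the binding-site selection.

    ``residue_cutoff`` (default 10 Å) selects the amino-acid residues whose
    closest atom lies within that distance of the ligand; ``water_cutoff``
    (default 2.5 Å) selects waters adjacent to a selected residue or to the
    ligand.  The metric is the minimum inter-atomic distance and both
    cutoffs are inclusive.
    """

    residue_cutoff: float = 10.0
    water_cutoff: float = 2.5

    def __post_init__(self) -> None:
        if self.residue_cutoff <= 0 or self.water_cutoff <= 0:
            raise ValueError("selection cutoffs must be positive")


@dataclass(eq=False)
class SelectedResidue:
    """A binding-site residue annotated with its closest-atom distance to the ligand."""

    residue: Residue
    min_distance: float


@dataclass(eq=False)
class CappedFragment:
    """R_i with its conjugate caps and the passivating hydrogens."""

    core: Residue
    cap_prev: list[Atom]
    cap_next: list[Atom]
    passivating_hydrogens: list[Atom]

    @property
    def cap_atoms(self) -> list[Atom]:
        return self.cap_prev + self.cap_next

    @property
    def all_atoms(self) -> list[Atom]:
        return self.cap_prev + list(self.core.atoms) + self.cap_next


@dataclass(eq=False)
class MFCCSystems:
    """The four auxiliary atom collections; cap atoms shared across all four."""

    S1: list[Atom]
    S2: list[Atom]
    S3: list[Atom]
    S4: list[Atom]
    included_waters: list[Residue] = field(default_factory=list)


@dataclass(eq=False)
class ResidueEnergy:
    """Per-residue ligand interaction energy (kcal/mol) with region attribution."""

    residue_id: tuple[str, int, str, str]
    energy: float
    min_distance: float
    region_breakdown: dict[str, float] | None = None
    region_tag: str | None = None

    @property
    def label(self) -> str:
        chain, seq, icode, name = self.residue_id
        return f"{name}{seq}{icode}".strip()


@dataclass(eq=False)
class DecompositionProfile:
    """Cumulative interaction energy as a function of the selection radius."""

    radii: np.ndarray
    cumulative_energy: np.ndarray


def select_binding_residues(structure: Structure, ligand: Residue,
                            criteria: SelectionCriteria | None = None,
                            ) -> list[SelectedResidue]:
    """Amino-acid residues whose closest atom is within the residue cutoff.

    Returned in chain order, each annotated with its minimum inter-atomic
    distance to the ligand; the cutoff is inclusive.
    """
    criteria = criteria or SelectionCriteria()
    if ligand not in structure.residues:
        raise KeyError(f"ligand {ligand.label} is not a residue of the structure")
    out = []
    for res in structure.residues:
        if res.kind != "amino_acid":
            continue
        d = min_atom_distance(res.atoms, ligand.atoms)
        if d <= criteria.residue_cutoff:
            out.append(SelectedResidue(res, d))
    return out


def select_bridging_waters(structure: Structure,
                           residues: Sequence[Residue | SelectedResidue],
                           ligand: Residue,
                           criteria: SelectionCriteria | None = None,
                           ) -> list[Residue]:
    """Waters within the water cutoff of any selected residue or the ligand."""
    criteria = criteria or SelectionCriteria()
    groups = [r.residue if isinstance(r, SelectedResidue) else r for r in residues]
    out = []
    for res in structure.residues:
        if res.kind != "water":
            continue
        near = min_atom_distance(res.atoms, ligand.atoms) <= criteria.water_cutoff
        if not near:
            near = any(min_atom_distance(res.atoms, g.atoms) <= criteria.water_cutoff
                       for g in groups)
        if near:
            out.append(res)
    out.sort(key=lambda r: r.seq_number)
    return out


def _chain_neighbor(structure: Structure, residue: Residue,
                    offset: int) -> Residue | None:
    """Sequence-adjacent amino acid in the same chain, or None at a terminus."""
    target = residue.seq_number + offset
    for r in structure.residues:
        if (r.chain_id == residue.chain_id and r.seq_number == target
                and r.kind == "amino_acid"):
            return r
    return None


def _passivating_hydrogen(heavy: Atom, toward: Atom, serial: int) -> Atom:
    length = PASSIVATION_BOND_LENGTH.get(heavy.element.upper())
    if length is None:
        raise ValueError(
            f"no passivation bond length for element {heavy.element!r}")
    vec = toward.coords - heavy.coords
    norm = np.linalg.norm(vec)
    if norm == 0:
        raise ValueError("severed-bond vector has zero length")
    return Atom(serial=serial, name=f"H{heavy.name}", element="H",
                coords=heavy.coords + vec / norm * length, charge=0.0)


def build_capped_fragment(structure: Structure, residue_id: tuple,
                          ) -> CappedFragment:
    """Build R_i plus conjugate caps from the chain-adjacent residues.

    Each cap is the *entire* adjacent residue; the bond that connected it to
    the next residue out (C of R_{i+1} to N of R_{i+2}, or N of R_{i-1} to C
    of R_{i-2}) is severed and passivated with a hydrogen on the original
    bond axis.  Chain termini simply lack the corresponding cap or
    passivation.  Geometry is deterministic: identical inputs give
    bit-identical fragments.
    """
    residue = structure.find_residue(residue_id)
    if residue.kind != "amino_acid":
        raise ValueError(f"unsupported residue for fragmentation: {residue.res_name}")
    for needed in ("N", "CA", "C"):
        try:
            residue.get_atom(needed)
        except KeyError:
            raise ValueError(
                f"residue {residue.label} is missing backbone atom {needed}"
            ) from None

    # passivation serials live far above the structure's own range so they
    # cannot collide with atoms added to the structure later (e.g. waters)
    next_serial = max(a.serial for a in structure.atoms) + 1_000_000
    hydrogens: list[Atom] = []

    def cap_from(neighbor: Residue | None, distal: Residue | None,
                 sever_atom: str, toward_atom: str) -> list[Atom]:
        nonlocal next_serial
        if neighbor is None:
            return []
        atoms = [a.copy() for a in neighbor.atoms]
        if distal is not None:
            heavy = next(a for a in atoms if a.name == sever_atom)
            h = _passivating_hydrogen(heavy, distal.get_atom(toward_atom),
                                      next_serial)
            next_serial += 1
            hydrogens.append(h)
            atoms.append(h)
        return atoms

    prev_res = _chain_neighbor(structure, residue, -1)
    next_res = _chain_neighbor(structure, residue, +1)
    prev2 = _chain_neighbor(structure, prev_res, -1) if prev_res else None
    next2 = _chain_neighbor(structure, next_res, +1) if next_res else None

    cap_prev = cap_from(prev_res, prev2, sever_atom="N", toward_atom="C")
    cap_next = cap_from(next_res, next2, sever_atom="C", toward_atom="N")
    return CappedFragment(core=residue, cap_prev=cap_prev, cap_next=cap_next,
                          passivating_hydrogens=hydrogens)


def assemble_systems(fragment: CappedFragment, ligand: Residue,
                     waters: Sequence[Residue] = (),
                     water_policy: Literal["all_systems", "none"] = "all_systems",
                     ) -> MFCCSystems:
    """Assemble S1–S4 from a capped fragment, the ligand and optional waters.

    Waters under ``all_systems`` enter every system as the *same* atom
    objects, preserving the algebraic cancellation for pairwise backends.
    """
    core = list(fragment.core.atoms)
    caps = fragment.cap_atoms
    lig = list(ligand.atoms)
    water_atoms: list[Atom] = []
    included: list[Residue] = []
    if water_policy == "all_systems":
        included = list(waters)
        water_atoms = [a for w in included for a in w.atoms]

    serials = [a.serial for a in caps + core + lig + water_atoms]
    if len(serials) != len(set(serials)):
        raise ValueError("atom collision: duplicate serials across systems")

    return MFCCSystems(
        S1=caps + core + lig + water_atoms,
        S2=caps + core + water_atoms,
        S3=caps + lig + water_atoms,
        S4=caps + water_atoms,
        included_waters=included,
    )


def mfcc_interaction_energy(systems: MFCCSystems,
                            backend: EnergyBackend) -> float:
    """E_S1 − E_S2 − E_S3 + E_S4 under the given backend (kcal/mol)."""
    energies = {}
    for label in ("S1", "S2", "S3", "S4"):
        try:
            energies[label] = backend.evaluate(getattr(systems, label))
        except Exception as exc:
            raise RuntimeError(f"backend failed on system {label}: {exc}") from exc
    return energies["S1"] - energies["S2"] - energies["S3"] + energies["S4"]


def _partition_ligand_by_region(ligand: Residue, region_map: LigandRegionMap,
                                ) -> dict[str, list[Atom]]:
    """Assign every ligand atom to a region.

    Atoms named in the map go to their region; unmapped atoms (typically
    hydrogens) are attributed to the region of the nearest mapped atom, so
    that the per-region energies always sum to the total.
    """
    mapped = [a for a in ligand.atoms if region_map.region_of(a.name) is not None]
    if not mapped:
        raise ValueError("region map covers no atom of the ligand")
    parts: dict[str, list[Atom]] = {label: [] for label in region_map.labels}
    for atom in ligand.atoms:
        label = region_map.region_of(atom.name)
        if label is None:
            nearest = min(mapped,
                          key=lambda m: float(np.linalg.norm(m.coords - atom.coords)))
            label = region_map.region_of(nearest.name)
        parts[label].append(atom)
    return parts


def decompose_site(structure: Structure, ligand: Residue,
                   backend: EnergyBackend,
                   criteria: SelectionCriteria | None = None,
                   region_map: LigandRegionMap | None = None,
                   water_policy: Literal["all_systems", "none"] = "none",
                   ) -> list[ResidueEnergy]:
    """Per-residue ligand interaction energies over the selected binding site.

    For each residue within the selection cutoff, builds the capped fragment,
    assembles S1–S4 (with bridging waters under ``water_policy="all_systems"``)
    and applies the four-system combination.  With a pairwise-additive
    backend and a region map, the per-region breakdown is the exact
    cross-interaction restricted to each region's ligand atoms; for other
    backends each residue only receives the tag of the region closest to it.
    """
    criteria = criteria or SelectionCriteria()
    selected = select_binding_residues(structure, ligand, criteria)
    if region_map is not None:
        region_map.validate_against(ligand)
        parts = _partition_ligand_by_region(ligand, region_map)
    out: list[ResidueEnergy] = []
    for sel in selected:
        fragment = build_capped_fragment(
            structure, sel.residue.residue_id[:3])
        waters: list[Residue] = []
        if water_policy == "all_systems":
            waters = select_bridging_waters(structure, [sel.residue], ligand,
                                            criteria)
        systems = assemble_systems(fragment, ligand, waters, water_policy
                                   if water_policy == "all_systems" else "none")
        energy = mfcc_interaction_energy(systems, backend)
        breakdown = None
        tag = None
        if region_map is not None:
            if backend.is_pairwise_additive:
                breakdown = {}
                for label, atoms in parts.items():
                    if not atoms:
                        breakdown[label] = 0.0
                        continue
                    # interaction of R_i with this region's ligand atoms,
                    # via the backend contract only (exact for additive backends)
                    core = list(sel.residue.atoms)
                    breakdown[label] = (backend.evaluate(core + atoms)
                                        - backend.evaluate(core)
                                        - backend.evaluate(atoms))
                tag = max(breakdown, key=lambda k: abs(breakdown[k]))
            else:
                nearest = min(
                    (a for a in ligand.atoms
                     if region_map.region_of(a.name) is not None),
                    key=lambda a: min_atom_distance(sel.residue.atoms, [a]))
                tag = region_map.region_of(nearest.name)
        out.append(ResidueEnergy(residue_id=sel.residue.residue_id,
                                 energy=energy, min_distance=sel.min_distance,
                                 region_breakdown=breakdown, region_tag=tag))
    return out


def radius_profile(energies: Sequence[ResidueEnergy],
                   radii: Sequence[float]) -> DecompositionProfile:
    """Cumulative interaction energy at each selection radius.

    The value at radius r sums the energies of all residues whose closest
    atom lies within r (inclusive); the profile at the final radius equals
    the total over all residues it covers.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or len(radii) == 0 or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be a strictly increasing 1-D sequence")
    dists = np.array([e.min_distance for e in energies])
    vals = np.array([e.energy for e in energies])
    cumulative = np.array([vals[dists <= r].sum() for r in radii])
    return DecompositionProfile(radii=radii, cumulative_energy=cumulative)


def export_systems(systems: MFCCSystems, outdir: str | Path,
                   tag: str = "fragment") -> Path:
    """Write one PDB and one XYZ per auxiliary system plus a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    for label in ("S1", "S2", "S3", "S4"):
        atoms: list[Atom] = getattr(systems, label)
        copies = [a.copy() for a in atoms]
        for i, a in enumerate(copies, start=1):
            a.serial = i  # exchange files use compact local numbering
        res = Residue(chain_id="A", seq_number=1, insertion_code="",
                      res_name="FRG", atoms=copies, kind="other")
        pdb_path = outdir / f"{tag}_{label}.pdb"
        pdb_path.write_text(write_pdb(Structure([res])))
        xyz_path = outdir / f"{tag}_{label}.xyz"
        lines = [str(len(atoms)), f"{tag} {label}"]
        for a in atoms:
            x, y, z = a.coords
            lines.append(f"{a.element:<2s} {x:14.8f} {y:14.8f} {z:14.8f}")
        xyz_path.write_text("\n".join(lines) + "\n")
        manifest[label] = {"pdb": pdb_path.name, "xyz": xyz_path.name,
                           "n_atoms": len(atoms)}
    manifest_path = outdir / f"{tag}_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def energies_to_frame(energies: Sequence[ResidueEnergy],
                      region_labels: Sequence[str] = ("i", "ii", "iii"),
                      ) -> pd.DataFrame:
    """Tabulate a decomposition as a DataFrame (CSV-ready)."""
    rows = []
    for e in energies:
        chain, seq, icode, name = e.residue_id
        row = {"chain": chain, "seq_number": seq, "insertion_code": icode,
               "res_name": name, "min_distance_A": e.min_distance,
               "energy_kcal_mol": e.energy}
        for label in region_labels:
            row[f"region_{label}"] = (e.region_breakdown or {}).get(label, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)
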