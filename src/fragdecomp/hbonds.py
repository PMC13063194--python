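"""Geometric hydrogen-bond detection, water bridges, occupancy and contacts.

A hydrogen bond is accepted when the donor–acceptor distance does not
exceed ``max_da_distance`` (default 3.4 Å) and, whenever a hydrogen bonded
to the donor is present, the D–H···A angle lies in
``[angle_min, angle_max]`` (default 90–180°).  Both boundaries are
inclusive.  Donors are N/O atoms carrying at least one covalently bonded
hydrogen; acceptors are N and O (S optionally).  When the structure has no
hydrogens, detection degrades to the distance criterion alone and the
record is flagged by ``dha_angle is None``.

Occupancy over a trajectory is the percentage of frames in which a given
donor–acceptor pair satisfies the criteria.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .mol_io import Atom, Residue, Structure, Trajectory

__all__ = [
    "HBondCriteria",
    "HBond",
    "OccupancyRecord",
    "ContactRule",
    "DEFAULT_CONTACT_RULES",
    "detect_hbonds",
    "detect_water_bridges",
    "hbond_occupancy",
    "classify_contacts",
]

#: Numerical guard for boundary comparisons (well below any physical tolerance).
_EPS = 1e-9

#: Maximum covalent X–H bond length used to associate hydrogens with donors.
_COVALENT_XH = 1.25


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond criteria; both boundaries inclusive."""

    max_da_distance: float = 3.4
    angle_min: float = 90.0
    angle_max: float = 180.0
    shell: float = 4.0
    acceptor_elements: frozenset[str] = frozenset({"N", "O"})

    def __post_init__(self) -> None:
        if not (0 < self.angle_min <= self.angle_max <= 180):
            raise ValueError("need 0 < angle_min <= angle_max <= 180")
        if self.max_da_distance <= 0 or self.shell <= 0:
            raise ValueError("distances must be positive")


@dataclass(eq=False)
class HBond:
    donor: Atom
    hydrogen: Atom | None
    acceptor: Atom
    da_distance: float
    dha_angle: float | None
    bridging_water: Residue | None = None


@dataclass
class OccupancyRecord:
    """Fraction of frames in which one donor–acceptor bond is present."""

    bond_key: tuple[int, int]
    frames_present: int
    frames_total: int

    @property
    def occupancy_percent(self) -> float:
        return 100.0 * self.frames_present / self.frames_total


def _residue_of(structure: Structure) -> dict[int, Residue]:
    return {a.serial: r for r in structure.residues for a in r.atoms}


def _bonded_hydrogens(donor: Atom, residue: Residue) -> list[Atom]:
    out = []
    for a in residue.atoms:
        if a.is_hydrogen and a.serial != donor.serial:
            if np.linalg.norm(a.coords - donor.coords) <= _COVALENT_XH:
                out.append(a)
    return out


def dha_angle(donor: Atom, hydrogen: Atom, acceptor: Atom) -> float:
    """The D–H···A angle at the hydrogen, in degrees."""
    v1 = donor.coords - hydrogen.coords
    v2 = acceptor.coords - hydrogen.coords
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def _detect_directed(donors_side: Sequence[Atom], acceptors_side: Sequence[Atom],
                     res_of: dict[int, Residue], criteria: HBondCriteria,
                     ) -> tuple[list[HBond], set[frozenset[int]]]:
    """One direction of the scan.

    Returns the accepted bonds plus the set of pairs whose donor carried an
    explicit hydrogen (whether accepted or angle-rejected), so that the
    distance-only fallback cannot resurrect an angle-rejected pair from the
    hydrogen-less direction.
    """
    bonds: list[HBond] = []
    h_evaluated: set[frozenset[int]] = set()
    for d in donors_side:
        if d.element.upper() not in ("N", "O"):
            continue
        hydrogens = _bonded_hydrogens(d, res_of[d.serial])
        for a in acceptors_side:
            if a.element.upper() not in criteria.acceptor_elements:
                continue
            if a.serial == d.serial:
                continue
            dist = float(np.linalg.norm(d.coords - a.coords))
            if dist > criteria.max_da_distance + _EPS:
                continue
            if hydrogens:
                h_evaluated.add(frozenset((d.serial, a.serial)))
                best = None
                for h in hydrogens:
                    ang = dha_angle(d, h, a)
                    if (criteria.angle_min - _EPS <= ang
                            <= criteria.angle_max + _EPS):
                        if best is None or ang > best[1]:
                            best = (h, ang)
                if best is None:
                    continue
                bonds.append(HBond(d, best[0], a, dist, best[1]))
            else:
                # no hydrogen on the donor: distance-only detection, flagged
                bonds.append(HBond(d, None, a, dist, None))
    return bonds, h_evaluated


def detect_hbonds(structure: Structure, group_a: Sequence[Atom],
                  group_b: Sequence[Atom],
                  criteria: HBondCriteria | None = None) -> list[HBond]:
    """Hydrogen bonds across two disjoint atom groups.

    Donor/acceptor roles are resolved by chemistry, not argument order:
    both directions are scanned and the result is symmetric under swapping
    the groups.  Output is ordered by (donor serial, acceptor serial).
    """
    criteria = criteria or HBondCriteria()
    if {a.serial for a in group_a} & {b.serial for b in group_b}:
        raise ValueError("atom groups must be disjoint")
    res_of = _residue_of(structure)
    fwd, h_fwd = _detect_directed(group_a, group_b, res_of, criteria)
    rev, h_rev = _detect_directed(group_b, group_a, res_of, criteria)
    h_evaluated = h_fwd | h_rev
    # a hydrogen-resolved evaluation supersedes the distance-only fallback
    # for the same atom pair; pairs with no hydrogen anywhere keep one
    # record, with the lower-serial atom in the donor slot
    by_pair: dict[frozenset[int], list[HBond]] = {}
    for b in fwd + rev:
        pair = frozenset((b.donor.serial, b.acceptor.serial))
        if b.hydrogen is None and pair in h_evaluated:
            continue
        by_pair.setdefault(pair, []).append(b)
    unique: list[HBond] = []
    for recs in by_pair.values():
        angled = [b for b in recs if b.hydrogen is not None]
        if angled:
            seen: set[tuple[int, int]] = set()
            for b in angled:
                key = (b.donor.serial, b.acceptor.serial)
                if key not in seen:
                    seen.add(key)
                    unique.append(b)
        else:
            unique.append(min(recs, key=lambda b: b.donor.serial))
    unique.sort(key=lambda b: (b.donor.serial, b.acceptor.serial))
    return unique


def detect_water_bridges(structure: Structure, group_a: Sequence[Atom],
                         group_b: Sequence[Atom], waters: Sequence[Residue],
                         criteria: HBondCriteria | None = None) -> list[HBond]:
    """Water-mediated bridges: one water hydrogen-bonded to both groups.

    Each returned record pairs the group-a partner (donor slot) with the
    group-b partner (acceptor slot); ``da_distance`` is their direct
    separation, ``bridging_water`` identifies the mediating water and
    ``dha_angle`` is None because the geometry involves two bonds.
    """
    criteria = criteria or HBondCriteria()
    out: list[HBond] = []
    for water in waters:
        to_a = detect_hbonds(structure, water.atoms, list(group_a), criteria)
        if not to_a:
            continue
        to_b = detect_hbonds(structure, water.atoms, list(group_b), criteria)
        for ba in to_a:
            partner_a = ba.acceptor if ba.donor in water.atoms else ba.donor
            for bb in to_b:
                partner_b = bb.acceptor if bb.donor in water.atoms else bb.donor
                out.append(HBond(
                    donor=partner_a, hydrogen=None, acceptor=partner_b,
                    da_distance=float(np.linalg.norm(
                        partner_a.coords - partner_b.coords)),
                    dha_angle=None, bridging_water=water))
    out.sort(key=lambda b: (b.donor.serial, b.acceptor.serial))
    return out


def hbond_occupancy(trajectory: Trajectory, group_a: Sequence[int | Atom],
                    group_b: Sequence[int | Atom],
                    criteria: HBondCriteria | None = None,
                    ) -> list[OccupancyRecord]:
    """Per-bond occupancy over a trajectory.

    Groups are given as atom serials (or atoms, from any frame); for every
    donor–acceptor pair observed in at least one frame, the record counts
    the frames in which :func:`detect_hbonds` reports it.
    """
    criteria = criteria or HBondCriteria()
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    serials_a = {a.serial if isinstance(a, Atom) else int(a) for a in group_a}
    serials_b = {b.serial if isinstance(b, Atom) else int(b) for b in group_b}
    counts: dict[tuple[int, int], int] = {}
    for frame in trajectory:
        atom_by_serial = {a.serial: a for a in frame.atoms}
        ga = [atom_by_serial[s] for s in sorted(serials_a)]
        gb = [atom_by_serial[s] for s in sorted(serials_b)]
        for bond in detect_hbonds(frame, ga, gb, criteria):
            key = (bond.donor.serial, bond.acceptor.serial)
            counts[key] = counts.get(key, 0) + 1
    n = len(trajectory)
    return [OccupancyRecord(bond_key=k, frames_present=v, frames_total=n)
            for k, v in sorted(counts.items())]


# ---------------------------------------------------------------------------
# Contact typology
# ---------------------------------------------------------------------------

@dataclass
class ContactRule:
    """A named contact rule: matches an atom pair within ``max_distance``."""

    name: str
    max_distance: float
    predicate: Callable[[Atom, Atom], bool]


def _is_aliphatic_carbon(atom: Atom) -> bool:
    return atom.element.upper() == "C"


def _is_cation(atom: Atom) -> bool:
    return atom.charge is not None and atom.charge >= 0.5


def pi_cation_rule(ring_atom_names: set[str], max_distance: float = 4.0,
                   ) -> ContactRule:
    """A π–cation rule keyed on the ligand's aromatic ring atom names."""
    def pred(protein_atom: Atom, ligand_atom: Atom) -> bool:
        return _is_cation(protein_atom) and ligand_atom.name in ring_atom_names
    return ContactRule("pi-cation", max_distance, pred)


DEFAULT_CONTACT_RULES: list[ContactRule] = [
    ContactRule("hydrophobic (alkyl)", 4.0,
                lambda p, l: _is_aliphatic_carbon(p) and _is_aliphatic_carbon(l)),
]


def classify_contacts(structure: Structure, ligand: Residue,
                      criteria: HBondCriteria | None = None,
                      rules: Sequence[ContactRule] | None = None,
                      ) -> list[tuple[tuple, str, float]]:
    """Label protein–ligand contacts within the interaction shell.

    Hydrogen bonds are delegated to :func:`detect_hbonds`; remaining atom
    pairs inside the shell (default 4 Å) are labelled by the first matching
    rule and fall back to "van der Waals".  Returns one
    ``(residue_id, contact_type, min_distance)`` row per residue and type.
    """
    criteria = criteria or HBondCriteria()
    rules = DEFAULT_CONTACT_RULES if rules is None else list(rules)
    out: dict[tuple[tuple, str], float] = {}

    for res in structure.residues:
        if res.kind != "amino_acid":
            continue
        hbonded_pairs: set[tuple[int, int]] = set()
        for bond in detect_hbonds(structure, res.atoms, ligand.atoms, criteria):
            key = (res.residue_id, "hydrogen bond")
            out[key] = min(out.get(key, np.inf), bond.da_distance)
            hbonded_pairs.add((bond.donor.serial, bond.acceptor.serial))
        for pa in res.atoms:
            for la in ligand.atoms:
                dist = float(np.linalg.norm(pa.coords - la.coords))
                if dist > criteria.shell + _EPS:
                    continue
                if ((pa.serial, la.serial) in hbonded_pairs
                        or (la.serial, pa.serial) in hbonded_pairs):
                    continue
                label = "van der Waals"
                for rule in rules:
                    if dist <= rule.max_distance + _EPS and rule.predicate(pa, la):
                        label = rule.name
                        break
                key = (res.residue_id, label)
                out[key] = min(out.get(key, np.inf), dist)

    return [(rid, label, d) for (rid, label), d in sorted(
        out.items(), key=lambda kv: (kv[0][0][1], kv[0][1]))]
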