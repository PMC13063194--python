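"""Synthetic fixtures: idealized peptides, a steroid-like ligand, complexes,
clustered trajectories and planted hydrogen-bond geometries.

Everything here is generated from seeds — no structure downloads — and is
deliberately idealized: peptides are poly-alanine backbones built from
standard bond lengths and angles (chemically plausible, not
energy-minimized), the ligand is a rigid planar fused-ring mimic of a
steroid scaffold with hydroxyl-like oxygens at either end, and charges are
drawn per residue with zero net sum so classical Coulomb energies stay
bounded.  Each generator is deterministic for a fixed seed and emits the
planted quantities (labels, geometries, charges) needed as oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .energy import BackendParams
from .mol_io import (Atom, LigandRegionMap, Residue, Structure, Trajectory,
                     min_atom_distance)

__all__ = [
    "GeneratorSpec",
    "make_peptide",
    "make_steroid_like_ligand",
    "make_complex",
    "make_clustered_trajectory",
    "make_hbond_trajectory",
    "plant_hbond",
    "add_water",
]

# Idealized backbone geometry (Å / degrees).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.530
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 117.2
ANGLE_C_N_CA = 121.7

_TORSIONS = {"extended": (-139.0, 135.0), "helix": (-57.0, -47.0)}


@dataclass
class GeneratorSpec:
    """Parameters of the synthetic study system.

    Defaults describe the reference conditions exercised throughout the
    test battery: an 8-residue extended chain, a steroid-like ligand in
    contact at 3.5 Å, and 300-frame trajectories drawn from 3 cluster
    centres separated by 8× the per-atom noise σ of 0.3 Å.
    """

    n_residues: int = 8
    chain_geometry: Literal["extended", "helix"] = "extended"
    ligand_template: str = "steroid_like"
    site_residue: int = 4
    contact_distance: float = 3.5
    n_frames: int = 300
    n_clusters: int = 3
    cluster_separation: float = 8.0
    noise_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_residues, self.n_frames, self.n_clusters) < 1:
            raise ValueError("counts must be >= 1")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if self.cluster_separation <= 0:
            raise ValueError("cluster_separation must be positive")


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d bonded to c with given internal coordinates (NeRF)."""
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.sin(ang) * math.cos(dih),
                        bond * math.sin(ang) * math.sin(dih)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def make_peptide(n_residues: int = 8,
                 chain_geometry: Literal["extended", "helix"] = "extended",
                 chain_id: str = "A", seed: int = 0) -> Structure:
    """Idealized poly-alanine chain (heavy atoms N, CA, C, O, CB per residue).

    Bond lengths and angles are fixed at standard values; the backbone
    torsions are those of the requested secondary structure.  Fully
    deterministic; the seed is accepted for interface uniformity.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    phi, psi = _TORSIONS[chain_geometry]
    omega = 180.0

    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([BOND_N_CA, 0.0, 0.0])
    ang = math.radians(ANGLE_N_CA_C)
    c = ca + BOND_CA_C * np.array([-math.cos(ang), math.sin(ang), 0.0])

    residues: list[Residue] = []
    serial = 1
    for i in range(1, n_residues + 1):
        atoms = {}
        for name, element, coords in (("N", "N", n), ("CA", "C", ca),
                                      ("C", "C", c)):
            atoms[name] = Atom(serial=serial, name=name, element=element,
                               coords=coords.copy())
            serial += 1
        o = _place(n, ca, c, BOND_C_O, 120.8, psi + 180.0)
        atoms["O"] = Atom(serial=serial, name="O", element="O", coords=o)
        serial += 1
        cb = _place(c, n, ca, BOND_CA_CB, 110.4, 122.0)
        atoms["CB"] = Atom(serial=serial, name="CB", element="C", coords=cb)
        serial += 1
        residues.append(Residue(chain_id=chain_id, seq_number=i,
                                insertion_code="", res_name="ALA",
                                atoms=[atoms[k] for k in
                                       ("N", "CA", "C", "O", "CB")],
                                kind="amino_acid"))
        if i < n_residues:
            n_next = _place(n, ca, c, BOND_C_N, ANGLE_CA_C_N, psi)
            ca_next = _place(ca, c, n_next, BOND_N_CA, ANGLE_C_N_CA, omega)
            c_next = _place(c, n_next, ca_next, BOND_CA_C, ANGLE_N_CA_C, phi)
            n, ca, c = n_next, ca_next, c_next
    return Structure(residues)


def make_steroid_like_ligand(template: str = "steroid_like",
                             res_name: str = "LIG",
                             first_serial: int = 1000,
                             ) -> tuple[Residue, LigandRegionMap]:
    """Rigid planar fused-ring mimic (18 C + 2 O) with regions i/ii/iii.

    An acene-like strip of fused six-membered carbon rings carries a
    hydroxyl-like oxygen at each end: O3 on the region-i terminus and O17
    on the region-iii terminus (the conventional steroid carbonyl/hydroxyl
    positions).  The region map partitions all 20 heavy atoms.
    """
    if template != "steroid_like":
        raise ValueError(f"unknown ligand template {template!r}")
    b = 1.40  # aromatic C-C
    dx, dy = b * math.sin(math.pi / 3), b * 0.5
    atoms: list[Atom] = []
    serial = first_serial
    names_bottom, names_top = [], []
    for k in range(9):  # bottom zig-zag chain C1..C9
        name = f"C{k + 1}"
        names_bottom.append(name)
        atoms.append(Atom(serial=serial, name=name, element="C",
                          coords=np.array([k * dx, dy * (k % 2), 0.0])))
        serial += 1
    for k in range(9):  # top zig-zag chain C10..C18
        name = f"C{k + 10}"
        names_top.append(name)
        atoms.append(Atom(serial=serial, name=name, element="C",
                          coords=np.array([k * dx, 2 * b - dy * (k % 2) + dy,
                                           0.0])))
        serial += 1
    o3 = Atom(serial=serial, name="O3", element="O",
              coords=atoms[0].coords + np.array([-1.02, -1.02, 0.0]))
    serial += 1
    o17 = Atom(serial=serial, name="O17", element="O",
               coords=atoms[17].coords + np.array([1.02, 1.02, 0.0]))
    atoms += [o3, o17]
    ligand = Residue(chain_id="L", seq_number=1, insertion_code="",
                     res_name=res_name, atoms=atoms, kind="ligand")
    region_map = LigandRegionMap({
        "i": frozenset({"C1", "C2", "C3", "C10", "C11", "C12", "O3"}),
        "ii": frozenset({"C4", "C5", "C6", "C13", "C14", "C15"}),
        "iii": frozenset({"C7", "C8", "C9", "C16", "C17", "C18", "O17"}),
    })
    return ligand, region_map


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _assign_zero_sum_charges(atoms: Sequence[Atom], rng: np.random.Generator,
                             scale: float = 0.15) -> None:
    q = rng.normal(scale=scale, size=len(atoms))
    q -= q.mean()
    for atom, charge in zip(atoms, q):
        atom.charge = float(charge)


def make_complex(peptide: Structure | None = None,
                 ligand: Residue | None = None,
                 site_residue: int = 4,
                 contact_distance: float = 3.5,
                 charges_rule: Literal["neutral", "none"] = "neutral",
                 seed: int = 0,
                 ) -> tuple[Structure, BackendParams, LigandRegionMap]:
    """Protein–ligand complex with the ligand placed at an exact contact distance.

    The ligand (randomly oriented per seed) is translated along the axis
    from the chosen residue so that the minimum inter-atomic distance to
    that residue equals ``contact_distance`` to within 1e-6 Å.  Charges are
    drawn per residue with zero net sum under the ``neutral`` rule, making
    the structure immediately usable with the pairwise backend.
    """
    rng = np.random.default_rng(seed)
    if peptide is None:
        peptide = make_peptide(seed=seed)
    peptide = Structure([r.copy() for r in peptide.residues])
    if ligand is None:
        ligand, _rm = make_steroid_like_ligand()
    _, region_map = make_steroid_like_ligand(res_name=ligand.res_name)
    ligand = ligand.copy()

    max_serial = max(a.serial for a in peptide.atoms)
    for i, a in enumerate(ligand.atoms):
        a.serial = max_serial + 1 + i

    target = peptide.find_residue(("A", site_residue, ""))
    base_coords = np.array([a.coords for a in ligand.atoms])
    base_coords -= base_coords.mean(axis=0)

    # approach perpendicular to the chain axis so a long ligand clears
    # the sequence neighbours of the contact residue
    cas = np.array([r.get_atom("CA").coords for r in peptide.residues
                    if r.kind == "amino_acid"])
    chain_axis = cas[-1] - cas[0]
    chain_axis /= max(np.linalg.norm(chain_axis), 1e-9)
    res_centroid = np.mean([a.coords for a in target.atoms], axis=0)
    v = res_centroid - peptide.coords().mean(axis=0)
    direction = v - np.dot(v, chain_axis) * chain_axis
    if np.linalg.norm(direction) < 1e-6:
        direction = np.cross(chain_axis, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(direction) < 1e-6:
            direction = np.cross(chain_axis, np.array([0.0, 1.0, 0.0]))
    direction /= np.linalg.norm(direction)

    placed = False
    pep_atoms = [a for r in peptide.residues for a in r.atoms]
    for _attempt in range(50):
        lig_coords = base_coords @ _rotation_matrix(rng).T
        lig_coords += res_centroid + direction * 12.0
        for a, xyz in zip(ligand.atoms, lig_coords):
            a.coords = xyz.copy()
        for _ in range(100):
            d = min_atom_distance(target.atoms, ligand.atoms)
            if abs(d - contact_distance) < 1e-9:
                break
            ta = min(target.atoms, key=lambda x: min(
                np.linalg.norm(x.coords - la.coords) for la in ligand.atoms))
            la = min(ligand.atoms,
                     key=lambda x: np.linalg.norm(x.coords - ta.coords))
            axis = la.coords - ta.coords
            axis /= np.linalg.norm(axis)
            shift = (contact_distance - d) * axis
            for a in ligand.atoms:
                a.coords = a.coords + shift
        converged = abs(min_atom_distance(target.atoms, ligand.atoms)
                        - contact_distance) < 1e-6
        clash = min_atom_distance(pep_atoms, ligand.atoms) < 0.8
        if converged and not clash:
            placed = True
            break
    if not placed:
        raise ValueError("steric overlap in generated complex")

    complex_structure = Structure(peptide.residues + [ligand])
    complex_structure.validate()

    if charges_rule == "neutral":
        for res in complex_structure.residues:
            _assign_zero_sum_charges(res.atoms, rng)
    return complex_structure, BackendParams(), region_map


def add_water(structure: Structure, position: np.ndarray,
              seq_number: int | None = None) -> Residue:
    """Append a 3-atom water (O, H1, H2) centred at ``position``."""
    max_serial = max(a.serial for a in structure.atoms)
    if seq_number is None:
        seq_number = max(r.seq_number for r in structure.residues
                         if r.chain_id == "W") + 1 if any(
            r.chain_id == "W" for r in structure.residues) else 1
    position = np.asarray(position, dtype=float)
    o = Atom(serial=max_serial + 1, name="O", element="O",
             coords=position, charge=-0.834)
    h1 = Atom(serial=max_serial + 2, name="H1", element="H",
              coords=position + np.array([0.7572, 0.5865, 0.0]), charge=0.417)
    h2 = Atom(serial=max_serial + 3, name="H2", element="H",
              coords=position + np.array([-0.7572, 0.5865, 0.0]), charge=0.417)
    water = Residue(chain_id="W", seq_number=seq_number, insertion_code="",
                    res_name="HOH", atoms=[o, h1, h2], kind="water")
    structure.residues.append(water)
    return water


def make_clustered_trajectory(complex_structure: Structure,
                              spec: GeneratorSpec | None = None,
                              ) -> tuple[Trajectory, np.ndarray, dict]:
    """Trajectory drawn from k Gaussian-perturbed cluster centres.

    Cluster centres differ by rigid ligand displacements of magnitude
    ``cluster_separation × noise_sigma`` along distinct axes (an internal
    motion that frame superposition cannot remove); every frame adds
    isotropic Gaussian noise of ``noise_sigma`` to all atoms.  Frames are
    evenly assigned to clusters and shuffled deterministically per seed.
    Returns the trajectory, the planted per-frame labels, and a manifest.
    """
    spec = spec or GeneratorSpec()
    rng = np.random.default_rng(spec.seed)
    base = complex_structure.coords()
    n_atoms = len(base)
    ligand_idx = np.array([
        i for i, (res, a) in enumerate(
            (r, a) for r in complex_structure.residues for a in r.atoms)
        if res.kind == "ligand"])
    if len(ligand_idx) == 0:
        raise ValueError("complex has no ligand residue")

    sep = spec.cluster_separation * spec.noise_sigma
    axes = np.eye(3)
    offsets = np.array([(c // 3 + 1) * sep * axes[c % 3]
                        for c in range(spec.n_clusters)])

    labels = np.repeat(np.arange(spec.n_clusters),
                       -(-spec.n_frames // spec.n_clusters))[:spec.n_frames]
    labels = labels[rng.permutation(spec.n_frames)]

    frames = []
    for i, lab in enumerate(labels):
        coords = base.copy()
        coords[ligand_idx] += offsets[lab]
        coords += rng.normal(scale=spec.noise_sigma, size=(n_atoms, 3))
        frames.append(complex_structure.with_coords(
            coords, frame_index=i, time_ns=0.1 * i))
    trajectory = Trajectory(frames, times=0.1 * np.arange(spec.n_frames))
    manifest = {"seed": spec.seed, "n_clusters": spec.n_clusters,
                "noise_sigma": spec.noise_sigma,
                "cluster_separation": spec.cluster_separation,
                "offsets": offsets.tolist(),
                "labels": labels.tolist()}
    return trajectory, labels, manifest


def _acceptor_position(donor: np.ndarray, hydrogen: np.ndarray,
                       distance: float, angle_deg: float) -> np.ndarray:
    """Acceptor position giving exact D–A distance and D–H···A angle."""
    theta = math.radians(angle_deg)
    u = donor - hydrogen
    r = np.linalg.norm(u)
    u = u / r
    disc = distance ** 2 - (r * math.sin(theta)) ** 2
    if disc < 0:
        raise ValueError(
            f"infeasible geometry: D-A {distance} Å with D-H {r:.2f} Å "
            f"and angle {angle_deg} deg")
    ha = r * math.cos(theta) + math.sqrt(disc)
    if ha <= 0:
        raise ValueError("infeasible geometry: acceptor would sit on hydrogen")
    # any perpendicular completes the plane; fixed deterministic choice
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, u)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    return hydrogen + ha * (math.cos(theta) * u + math.sin(theta) * v)


def plant_hbond(structure: Structure, donor_serial: int, acceptor_serial: int,
                distance: float = 2.9, angle: float = 165.0) -> Structure:
    """Copy of the structure with an exact planted hydrogen-bond geometry.

    The acceptor atom is moved so the donor–acceptor distance and the
    D–H···A angle equal the requested values to within 1e-6.  If the donor
    carries no hydrogen, one is added at 1.01 Å pointing away from the
    donor's residue centroid.
    """
    new = Structure([r.copy() for r in structure.residues],
                    frame_index=structure.frame_index,
                    time_ns=structure.time_ns)
    atom_of = {a.serial: a for a in new.atoms}
    donor = atom_of[donor_serial]
    acceptor = atom_of[acceptor_serial]
    donor_res = next(r for r in new.residues if donor in r.atoms)

    hydrogen = None
    for a in donor_res.atoms:
        if a.is_hydrogen and np.linalg.norm(a.coords - donor.coords) <= 1.25:
            hydrogen = a
            break
    if hydrogen is None:
        centroid = np.mean([a.coords for a in donor_res.atoms], axis=0)
        away = donor.coords - centroid
        nrm = np.linalg.norm(away)
        away = away / nrm if nrm > 1e-9 else np.array([0.0, 0.0, 1.0])
        hydrogen = Atom(serial=max(a.serial for a in new.atoms) + 1,
                        name=f"H{donor.name}", element="H",
                        coords=donor.coords + 1.01 * away, charge=0.0)
        donor_res.atoms.append(hydrogen)

    acceptor.coords = _acceptor_position(donor.coords, hydrogen.coords,
                                         distance, angle)
    return new


def make_hbond_trajectory(structure: Structure, donor_serial: int,
                          acceptor_serial: int, n_frames: int,
                          present_frames: int, distance: float = 2.9,
                          angle: float = 165.0, broken_distance: float = 6.0,
                          seed: int = 0) -> tuple[Trajectory, np.ndarray]:
    """Trajectory in which the planted bond exists in exactly k of N frames.

    Present frames carry the exact planted geometry; absent frames move the
    acceptor to ``broken_distance`` (beyond any acceptance cutoff) at the
    same angle.  Which frames are "present" is a seeded permutation.
    Returns the trajectory and the boolean presence mask.
    """
    if not 0 <= present_frames <= n_frames:
        raise ValueError("present_frames must be within [0, n_frames]")
    rng = np.random.default_rng(seed)
    mask = np.zeros(n_frames, dtype=bool)
    mask[rng.permutation(n_frames)[:present_frames]] = True
    bonded = plant_hbond(structure, donor_serial, acceptor_serial,
                         distance, angle)
    broken = plant_hbond(structure, donor_serial, acceptor_serial,
                         broken_distance, angle)
    frames = []
    for i, present in enumerate(mask):
        src = bonded if present else broken
        frames.append(src.with_coords(src.coords(), frame_index=i,
                                      time_ns=0.1 * i))
    return Trajectory(frames, times=0.1 * np.arange(n_frames)), mask
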