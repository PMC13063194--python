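"""Structures, trajectories and ligand-region maps.

The in-memory model is deliberately small: an :class:`Atom` carries
coordinates plus the optional per-atom parameters (partial charge) that the
classical energy backend needs, a :class:`Residue` groups atoms under the
PDB identifier triple ``(chain, seq_number, insertion_code)``, and a
:class:`Structure` is an ordered list of residues.  A :class:`Trajectory`
is a list of topologically identical structures with nondecreasing times.

PDB reading and writing are delegated to :mod:`biotite`; the functions here
only translate between biotite's atom arrays and these containers, so
round-tripping preserves atom names, residue identifiers and coordinates to
the 3-decimal precision of the PDB coordinate field.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import yaml

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "Trajectory",
    "LigandRegionMap",
    "ParseError",
    "TopologyError",
    "read_pdb",
    "write_pdb",
    "min_atom_distance",
    "load_region_map",
    "DEFAULT_WATER_NAMES",
    "AMINO_ACID_NAMES",
]

#: Residue names recognised as water (TIP3P and crystallographic conventions).
DEFAULT_WATER_NAMES = frozenset({"HOH", "WAT", "TIP3", "SOL"})

#: Standard amino-acid residue names, including common His protonation variants.
AMINO_ACID_NAMES = frozenset({
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "HSD", "HSE", "HSP", "CYX",
})

ResidueKind = Literal["amino_acid", "water", "ligand", "other"]


class ParseError(ValueError):
    """Raised when PDB text cannot be interpreted."""


class TopologyError(ValueError):
    """Raised when frames of a multi-model file disagree in topology."""


@dataclass(eq=False)
class Atom:
    """A point atom: identity, element, Cartesian coordinates in Å."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    charge: float | None = None
    occupancy_flag: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"atom {self.name!r} has an empty element symbol")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


@dataclass(eq=False)
class Residue:
    """A residue: chain, PDB sequence number, insertion code, name, atoms."""

    chain_id: str
    seq_number: int
    insertion_code: str
    res_name: str
    atoms: list[Atom]
    kind: ResidueKind = "other"

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"residue {self.res_name} {self.seq_number} has no atoms")

    @property
    def residue_id(self) -> tuple[str, int, str, str]:
        return (self.chain_id, self.seq_number, self.insertion_code, self.res_name)

    @property
    def label(self) -> str:
        return f"{self.res_name}{self.seq_number}{self.insertion_code}".strip()

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def get_atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"atom {name!r} not in residue {self.label}")

    def copy(self) -> "Residue":
        return replace(self, atoms=[a.copy() for a in self.atoms])


@dataclass(eq=False)
class Structure:
    """An ordered collection of residues, optionally one frame of a trajectory."""

    residues: list[Residue]
    frame_index: int | None = None
    time_ns: float | None = None

    def __iter__(self):
        return iter(self.residues)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, *, frame_index: int | None = None,
                    time_ns: float | None = None) -> "Structure":
        """A topologically identical copy with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected {(self.n_atoms, 3)} coords, got {coords.shape}")
        new = Structure([r.copy() for r in self.residues],
                        frame_index=frame_index, time_ns=time_ns)
        for atom, xyz in zip(new.atoms, coords):
            atom.coords = np.array(xyz, dtype=float)
        return new

    def find_residue(self, residue_id: tuple) -> Residue:
        chain, seq, icode = residue_id[:3]
        for r in self.residues:
            if (r.chain_id, r.seq_number, r.insertion_code) == (chain, seq, icode):
                return r
        raise KeyError(f"residue {residue_id} not found")

    def validate(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(serials) != len(set(serials)):
            raise ValueError("atom serials are not globally unique")
        ids = [(r.chain_id, r.seq_number, r.insertion_code) for r in self.residues]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate residue identifier in structure")


@dataclass(eq=False)
class Trajectory:
    """Ordered frames of identical topology with nondecreasing times (ns)."""

    frames: list[Structure]
    times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory has no frames")
        if self.times is None:
            self.times = np.array(
                [f.time_ns if f.time_ns is not None else float(i)
                 for i, f in enumerate(self.frames)])
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.frames):
            raise ValueError("times and frames differ in length")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be nondecreasing")
        ref = self._topology_key(self.frames[0])
        for i, f in enumerate(self.frames[1:], start=1):
            if self._topology_key(f) != ref:
                raise TopologyError(f"frame {i} topology differs from frame 0")

    @staticmethod
    def _topology_key(s: Structure):
        return [(r.chain_id, r.seq_number, r.insertion_code, r.res_name,
                 tuple(a.name for a in r.atoms)) for r in s.residues]

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate array."""
        return np.stack([f.coords() for f in self.frames])


@dataclass
class LigandRegionMap:
    """Partition of ligand atom names into the labelled regions i / ii / iii."""

    regions: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for label, names in self.regions.items():
            names = frozenset(names)
            overlap = seen & names
            if overlap:
                raise ValueError(
                    f"atom(s) {sorted(overlap)} assigned to more than one region")
            seen |= names
            self.regions[label] = names

    @property
    def labels(self) -> list[str]:
        return list(self.regions)

    @property
    def all_atoms(self) -> frozenset[str]:
        return frozenset().union(*self.regions.values())

    def region_of(self, atom_name: str) -> str | None:
        for label, names in self.regions.items():
            if atom_name in names:
                return label
        return None

    def validate_against(self, ligand: Residue) -> list[str]:
        """Heavy ligand atoms missing from the map; warns if any."""
        missing = [a.name for a in ligand.heavy_atoms() if a.name not in self.all_atoms]
        if missing:
            warnings.warn(
                f"region map does not cover ligand heavy atoms: {missing}",
                stacklevel=2)
        return missing


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _classify(res_name: str, hetero: bool,
              water_names: frozenset[str]) -> ResidueKind:
    if res_name in water_names:
        return "water"
    if res_name in AMINO_ACID_NAMES:
        return "amino_acid"
    if hetero:
        return "ligand"
    return "other"


def _array_to_structure(arr, water_names: frozenset[str],
                        frame_index: int | None = None) -> Structure:
    serials = (arr.atom_id if "atom_id" in arr.get_annotation_categories()
               else np.arange(1, arr.array_length() + 1))
    residues: list[Residue] = []
    current_key = None
    current_atoms: list[Atom] = []

    def flush(key):
        chain, seq, icode, name, hetero = key
        residues.append(Residue(
            chain_id=str(chain), seq_number=int(seq), insertion_code=str(icode),
            res_name=str(name), atoms=current_atoms.copy(),
            kind=_classify(str(name), bool(hetero), water_names)))

    for i in range(arr.array_length()):
        key = (arr.chain_id[i], arr.res_id[i], arr.ins_code[i],
               arr.res_name[i], arr.hetero[i])
        if key != current_key:
            if current_key is not None:
                flush(current_key)
            current_key = key
            current_atoms = []
        element = str(arr.element[i])
        if not element:
            element = "".join(c for c in str(arr.atom_name[i]) if c.isalpha())[:1] or "X"
        current_atoms.append(Atom(
            serial=int(serials[i]), name=str(arr.atom_name[i]),
            element=element, coords=np.array(arr.coord[i], dtype=float)))
    if current_key is not None:
        flush(current_key)
    return Structure(residues, frame_index=frame_index)


def _structure_to_array(structure: Structure):
    import biotite.structure as struc

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    arr.add_annotation("atom_id", int)
    i = 0
    for res in structure.residues:
        hetero = res.kind in ("water", "ligand")
        for atom in res.atoms:
            if np.any(np.abs(atom.coords) >= 1e4):
                raise ValueError(
                    f"coordinate overflow for atom {atom.name}: not representable "
                    "in the fixed 8.3 PDB field")
            arr.chain_id[i] = res.chain_id or "A"
            arr.res_id[i] = res.seq_number
            arr.ins_code[i] = res.insertion_code
            arr.res_name[i] = res.res_name
            arr.hetero[i] = hetero
            arr.atom_name[i] = atom.name
            arr.element[i] = atom.element
            arr.atom_id[i] = atom.serial
            arr.coord[i] = atom.coords
            i += 1
    return arr


def read_pdb(source: str | Path, model_policy: Literal["first", "all"] = "first",
             water_names: Iterable[str] = DEFAULT_WATER_NAMES,
             ) -> Structure | Trajectory:
    """Read PDB text (or a path to it) into a Structure or Trajectory.

    With ``model_policy="all"`` every MODEL becomes one frame of a
    :class:`Trajectory`; with ``"first"`` only the first model is returned.
    Missing element fields are inferred from the atom name.
    """
    import biotite.structure.io.pdb as pdb_io

    water_names = frozenset(water_names)
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\n" not in source and Path(source).exists()):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        pdb_file = pdb_io.PDBFile.read(io.StringIO(text))
        n_models = pdb_file.get_model_count()
    except Exception as exc:  # pragma: no cover - biotite's message is wrapped
        raise ParseError(f"cannot parse PDB text: {exc}") from exc

    def get_model(m: int):
        try:
            return pdb_file.get_structure(model=m, extra_fields=["atom_id"],
                                          altloc="first")
        except Exception as exc:
            for ln, line in enumerate(text.splitlines(), start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    except ValueError:
                        raise ParseError(
                            f"malformed coordinate fields on line {ln}: {line!r}"
                        ) from exc
            raise ParseError(str(exc)) from exc

    if model_policy == "first":
        return _array_to_structure(get_model(1), water_names)
    frames = []
    for m in range(1, n_models + 1):
        frames.append(_array_to_structure(get_model(m), water_names,
                                          frame_index=m - 1))
    try:
        return Trajectory(frames)
    except TopologyError:
        raise
    except ValueError as exc:
        raise TopologyError(str(exc)) from exc


def write_pdb(structure: Structure | Trajectory) -> str:
    """Serialise a Structure (or a Trajectory, as a multi-model file) to PDB text."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb_io

    pdb_file = pdb_io.PDBFile()
    if isinstance(structure, Trajectory):
        arrays = [_structure_to_array(f) for f in structure.frames]
        stack = struc.stack(arrays)
        stack.set_annotation("atom_id", arrays[0].atom_id)
        pdb_file.set_structure(stack)
    else:
        pdb_file.set_structure(_structure_to_array(structure))
    out = io.StringIO()
    pdb_file.write(out)
    return out.getvalue()


def min_atom_distance(group_a: Sequence[Atom], group_b: Sequence[Atom]) -> float:
    """Minimum Euclidean distance (Å) over all cross pairs of two atom groups."""
    if not group_a or not group_b:
        raise ValueError("min_atom_distance requires two non-empty atom groups")
    xa = np.array([a.coords for a in group_a])
    xb = np.array([b.coords for b in group_b])
    d2 = np.sum((xa[:, None, :] - xb[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.min()))


def load_region_map(config: str | Path | dict) -> LigandRegionMap:
    """Load a ligand-region map from YAML/JSON text, a path, or a mapping.

    The config declares region labels (conventionally ``i``, ``ii``, ``iii``)
    each with a list of ligand atom names; names must not repeat across
    regions.
    """
    if isinstance(config, dict):
        data = config
    else:
        if isinstance(config, Path) or (isinstance(config, str)
                                        and "\n" not in config
                                        and Path(config).exists()):
            text = Path(config).read_text()
        else:
            text = str(config)
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError:
            data = json.loads(text)
    if not isinstance(data, dict) or not data:
        raise ValueError("region map config must be a non-empty mapping")
    regions = {str(k): frozenset(map(str, v)) for k, v in data.items()}
    return LigandRegionMap(regions)
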