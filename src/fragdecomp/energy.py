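"""Energy-evaluation backends for the fragment decomposition.

The decomposition core only requires an object satisfying the
:class:`EnergyBackend` contract: a deterministic ``evaluate(atoms)``
returning a total energy in kcal/mol, plus an ``is_pairwise_additive`` flag.
Quantum-chemical engines plug in through this contract (see
:class:`FileExchangeBackend`); the built-in :class:`PairwiseBackend`
implements a screened Coulomb + Lennard-Jones potential whose pairwise
additivity makes the conjugate-cap cancellation of the decomposition exact,
so it serves as the reference instrument for correctness testing.

Energies: kcal/mol.  Distances: Å.  Charges: elementary charge units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import yaml

from .mol_io import Atom

__all__ = [
    "COULOMB_CONSTANT",
    "HARTREE_TO_KCAL_MOL",
    "BackendParams",
    "EnergyBackend",
    "PairwiseBackend",
    "FileExchangeBackend",
    "pairwise_energy",
    "interaction_energy_direct",
]

#: Coulomb constant in kcal·Å·mol⁻¹·e⁻².
COULOMB_CONSTANT = 332.0637

#: Conversion factor from Hartree to kcal/mol.
HARTREE_TO_KCAL_MOL = 627.509474

#: Default per-element Lennard-Jones parameters (epsilon kcal/mol, sigma Å).
#: A deliberately small table — the classical backend is a verification
#: instrument, not a force field; override freely via BackendParams.
DEFAULT_LJ_PARAMS: dict[str, tuple[float, float]] = {
    "H": (0.0157, 1.069),
    "C": (0.0860, 3.400),
    "N": (0.1700, 3.250),
    "O": (0.2100, 2.960),
    "S": (0.2500, 3.564),
}


@dataclass
class BackendParams:
    """Parameters of the built-in screened Coulomb + LJ pair potential.

    ``relative_dielectric`` defaults to 40, echoing the implicit-solvation
    screening used in the quantum-chemical reference treatment; the Coulomb
    term is ``k·qi·qj/(eps_r·r)`` with no cutoff.  LJ mixing follows
    Lorentz–Berthelot (arithmetic sigma, geometric epsilon).
    """

    coulomb_constant: float = COULOMB_CONSTANT
    relative_dielectric: float = 40.0
    lj_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LJ_PARAMS))
    lj_enabled: bool = True
    coulomb_enabled: bool = True

    def __post_init__(self) -> None:
        if self.relative_dielectric <= 0:
            raise ValueError("relative_dielectric must be > 0")
        for el, (eps, sigma) in self.lj_params.items():
            if eps < 0 or sigma <= 0:
                raise ValueError(f"invalid LJ parameters for {el}: {(eps, sigma)}")

    @classmethod
    def from_yaml(cls, source: str | Path) -> "BackendParams":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        data = yaml.safe_load(text) or {}
        if "lj_params" in data:
            data["lj_params"] = {k: tuple(v) for k, v in data["lj_params"].items()}
        return cls(**data)

    def to_yaml(self) -> str:
        return yaml.safe_dump({
            "coulomb_constant": self.coulomb_constant,
            "relative_dielectric": self.relative_dielectric,
            "lj_params": {k: list(v) for k, v in self.lj_params.items()},
            "lj_enabled": self.lj_enabled,
            "coulomb_enabled": self.coulomb_enabled,
        })


@runtime_checkable
class EnergyBackend(Protocol):
    """Contract consumed by the decomposition core."""

    is_pairwise_additive: bool

    def evaluate(self, atoms: Sequence[Atom]) -> float:
        """Total energy of an atom collection in kcal/mol."""
        ...


def _gather(atoms: Sequence[Atom], params: BackendParams):
    coords = np.array([a.coords for a in atoms], dtype=float)
    charges = None
    eps = sig = None
    if params.coulomb_enabled:
        missing = [a.name for a in atoms if a.charge is None]
        if missing:
            raise ValueError(f"atoms without charges: {missing}")
        charges = np.array([a.charge for a in atoms], dtype=float)
    if params.lj_enabled:
        missing = [a.element for a in atoms if a.element not in params.lj_params]
        if missing:
            raise ValueError(f"elements without LJ parameters: {sorted(set(missing))}")
        eps = np.array([params.lj_params[a.element][0] for a in atoms])
        sig = np.array([params.lj_params[a.element][1] for a in atoms])
    return coords, charges, eps, sig


def _pair_energy_matrix(coords_a, coords_b, qa, qb, eps_a, eps_b, sig_a, sig_b,
                        params: BackendParams,
                        same_collection: bool = False) -> np.ndarray:
    """Energy of every (a, b) cross pair; no pair excluded, no cutoff."""
    diff = coords_a[:, None, :] - coords_b[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=-1))
    if same_collection:
        np.fill_diagonal(r, np.inf)
    if np.any(r == 0.0):
        raise ZeroDivisionError("coincident atoms: pair distance is zero")
    e = np.zeros_like(r)
    if params.coulomb_enabled:
        e += params.coulomb_constant * np.outer(qa, qb) / (
            params.relative_dielectric * r)
    if params.lj_enabled:
        sigma_ij = 0.5 * (sig_a[:, None] + sig_b[None, :])
        eps_ij = np.sqrt(np.outer(eps_a, eps_b))
        sr6 = (sigma_ij / r) ** 6
        e += 4.0 * eps_ij * (sr6 * sr6 - sr6)
    return e


def pairwise_energy(atoms: Sequence[Atom], params: BackendParams) -> float:
    """Total screened-Coulomb + LJ energy of an atom collection (kcal/mol).

    Sums over unordered atom pairs; empty and single-atom collections have
    zero energy by definition.
    """
    atoms = list(atoms)
    if len(atoms) < 2:
        return 0.0
    coords, q, eps, sig = _gather(atoms, params)
    e = _pair_energy_matrix(coords, coords, q, q, eps, eps, sig, sig, params,
                            same_collection=True)
    iu = np.triu_indices(len(atoms), k=1)
    return float(e[iu].sum())


def interaction_energy_direct(group_a: Sequence[Atom], group_b: Sequence[Atom],
                              params: BackendParams) -> float:
    """Cross-pair interaction energy between two disjoint atom groups.

    This is the brute-force oracle for the fragment decomposition: by
    pairwise additivity it equals ``E(a ∪ b) − E(a) − E(b)`` exactly.
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        return 0.0
    serials_a = {a.serial for a in group_a}
    if serials_a & {b.serial for b in group_b}:
        raise ValueError("groups share atoms (overlapping serials)")
    ca, qa, ea, sa = _gather(group_a, params)
    cb, qb, eb, sb = _gather(group_b, params)
    e = _pair_energy_matrix(ca, cb, qa, qb, ea, eb, sa, sb, params)
    return float(e.sum())


class PairwiseBackend:
    """The built-in classical backend: exact, deterministic, pairwise additive."""

    is_pairwise_additive = True

    def __init__(self, params: BackendParams | None = None) -> None:
        self.params = params or BackendParams()

    def evaluate(self, atoms: Sequence[Atom]) -> float:
        return pairwise_energy(atoms, self.params)


class FileExchangeBackend:
    """Adapter for an external quantum-chemistry engine via file exchange.

    For every evaluation the fragment is written as XYZ to
    ``workdir/<tag>.xyz``, ``runner(xyz_path)`` is invoked and must return
    the path of a one-line text file containing the total energy in Hartree,
    which is converted at :data:`HARTREE_TO_KCAL_MOL`.  External engines are
    generally not pairwise additive, so region attribution falls back to
    nearest-region tagging in the decomposition.
    """

    is_pairwise_additive = False

    def __init__(self, runner, workdir: str | Path = ".") -> None:
        self.runner = runner
        self.workdir = Path(workdir)
        self._counter = 0

    def evaluate(self, atoms: Sequence[Atom]) -> float:
        atoms = list(atoms)
        if not atoms:
            return 0.0
        self._counter += 1
        xyz = self.workdir / f"fragment_{self._counter:05d}.xyz"
        lines = [str(len(atoms)), "fragdecomp fragment"]
        for a in atoms:
            x, y, z = a.coords
            lines.append(f"{a.element:<2s} {x:14.8f} {y:14.8f} {z:14.8f}")
        xyz.write_text("\n".join(lines) + "\n")
        energy_file = Path(self.runner(xyz))
        hartree = float(energy_file.read_text().split()[0])
        return hartree * HARTREE_TO_KCAL_MOL
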