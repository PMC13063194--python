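import numpy as np
import pytest

from fragdecomp.energy import BackendParams, PairwiseBackend, \
    interaction_energy_direct
from fragdecomp.mfcc import (SelectionCriteria, assemble_systems,
                             build_capped_fragment, decompose_site,
                             mfcc_interaction_energy, radius_profile,
                             select_binding_residues, select_bridging_waters)
from fragdecomp.mol_io import Atom, Residue, Structure, min_atom_distance
from fragdecomp.synthetic import add_water, make_complex, make_peptide


def single_atom_residue(seq, x, kind="amino_acid", chain="A", name="CA",
                        res_name="GLY", serial=None):
    return Residue(chain, seq, "", res_name,
                   [Atom(serial or seq, name, "C", [x, 0.0, 0.0], charge=0.0)],
                   kind=kind)


class TestSelection:
    def test_far_ligand_selects_nothing(self):
        residues = [single_atom_residue(i, float(i)) for i in range(1, 4)]
        ligand = Residue("L", 1, "", "LIG",
                         [Atom(99, "C1", "C", [0.0, 50.0, 0.0])], kind="ligand")
        s = Structure(residues + [ligand])
        assert select_binding_residues(s, ligand) == []

    def test_constructed_geometry_matches_brute_force(self):
        # residues at x = 1..8; ligand at x = 0: those within 10 Å only
        residues = [single_atom_residue(i, 2.0 * i) for i in range(1, 9)]
        ligand = Residue("L", 1, "", "LIG",
                         [Atom(99, "C1", "C", [0.0, 0.0, 0.0])], kind="ligand")
        s = Structure(residues + [ligand])
        sel = select_binding_residues(s, ligand)
        expected = [r for r in residues
                    if min_atom_distance(r.atoms, ligand.atoms) <= 10.0]
        assert [x.residue.seq_number for x in sel] == \
            [r.seq_number for r in expected]
        assert [x.residue.seq_number for x in sel] == [1, 2, 3, 4, 5]
        for x in sel:
            assert x.min_distance == pytest.approx(2.0 * x.residue.seq_number)

    def test_cutoff_boundary_inclusive(self):
        residues = [single_atom_residue(1, 10.0)]
        ligand = Residue("L", 1, "", "LIG",
                         [Atom(99, "C1", "C", [0.0, 0.0, 0.0])], kind="ligand")
        s = Structure(residues + [ligand])
        sel = select_binding_residues(s, ligand)
        assert len(sel) == 1 and sel[0].min_distance == pytest.approx(10.0)

    def test_unknown_ligand_rejected(self):
        s = Structure([single_atom_residue(1, 0.0)])
        stray = Residue("L", 9, "", "LIG",
                        [Atom(99, "C1", "C", [0, 0, 0])], kind="ligand")
        with pytest.raises(KeyError):
            select_binding_residues(s, stray)


class TestWaterSelection:
    def _toy(self, water_x):
        res = single_atom_residue(1, 0.0)
        ligand = Residue("L", 1, "", "LIG",
                         [Atom(99, "C1", "C", [20.0, 0.0, 0.0])], kind="ligand")
        water = Residue("W", 1, "", "HOH",
                        [Atom(50, "O", "O", [water_x, 0.0, 0.0])], kind="water")
        return Structure([res, ligand, water]), res, ligand

    def test_no_waters_empty(self):
        res = single_atom_residue(1, 0.0)
        ligand = Residue("L", 1, "", "LIG",
                         [Atom(99, "C1", "C", [3.0, 0, 0])], kind="ligand")
        s = Structure([res, ligand])
        assert select_bridging_waters(s, [res], ligand) == []

    def test_water_near_ligand_included(self):
        s, res, ligand = self._toy(water_x=22.4)  # 2.4 Å from ligand, far from res
        waters = select_bridging_waters(s, [res], ligand)
        assert [w.res_name for w in waters] == ["HOH"]

    def test_water_beyond_cutoff_excluded(self):
        s, res, ligand = self._toy(water_x=10.0)  # 2.6+ Å from everything
        assert select_bridging_waters(s, [res], ligand) == []


class TestCappedFragment:
    def test_middle_residue_of_triple_has_no_passivation(self):
        pep = make_peptide(3)
        frag = build_capped_fragment(pep, ("A", 2, ""))
        # caps are the whole terminal residues; termini are free, no H needed
        assert len(frag.passivating_hydrogens) == 0
        assert len(frag.cap_prev) == 5 and len(frag.cap_next) == 5
        assert len(frag.all_atoms) == 15

    def test_interior_residue_of_pentapeptide_has_two_passivations(self):
        pep = make_peptide(5)
        frag = build_capped_fragment(pep, ("A", 3, ""))
        assert len(frag.passivating_hydrogens) == 2
        assert len(frag.cap_prev) == 6 and len(frag.cap_next) == 6

    def test_n_terminal_residue_has_empty_cap_prev(self):
        pep = make_peptide(3)
        frag = build_capped_fragment(pep, ("A", 1, ""))
        assert frag.cap_prev == []
        assert len(frag.cap_next) > 0

    def test_passivating_hydrogen_bond_lengths(self):
        pep = make_peptide(5)
        frag = build_capped_fragment(pep, ("A", 3, ""))
        # cap_prev severs at N (1.01 Å), cap_next severs at C (1.09 Å)
        h_prev = frag.passivating_hydrogens[0]
        n_atom = next(a for a in frag.cap_prev if a.name == "N")
        assert np.linalg.norm(h_prev.coords - n_atom.coords) == \
            pytest.approx(1.01, abs=1e-6)
        h_next = frag.passivating_hydrogens[1]
        c_atom = next(a for a in frag.cap_next if a.name == "C")
        assert np.linalg.norm(h_next.coords - c_atom.coords) == \
            pytest.approx(1.09, abs=1e-6)

    def test_missing_backbone_rejected(self):
        bad = Structure([single_atom_residue(1, 0.0)])
        with pytest.raises(ValueError, match="backbone"):
            build_capped_fragment(bad, ("A", 1, ""))

    def test_nonstandard_residue_rejected(self):
        lig = Residue("A", 1, "", "LIG",
                      [Atom(1, "C1", "C", [0, 0, 0])], kind="ligand")
        with pytest.raises(ValueError, match="LIG"):
            build_capped_fragment(Structure([lig]), ("A", 1, ""))

    def test_deterministic_geometry(self):
        pep = make_peptide(5)
        f1 = build_capped_fragment(pep, ("A", 3, ""))
        f2 = build_capped_fragment(pep, ("A", 3, ""))
        c1 = np.array([a.coords for a in f1.all_atoms])
        c2 = np.array([a.coords for a in f2.all_atoms])
        assert np.array_equal(c1, c2)


class TestAssembleSystems:
    def test_count_identities(self, complex_setup):
        cx, lig = complex_setup["structure"], complex_setup["ligand"]
        frag = build_capped_fragment(cx, ("A", 3, ""))
        systems = assemble_systems(frag, lig, water_policy="none")
        assert len(systems.S1) == len(systems.S2) + len(lig.atoms)
        assert len(systems.S3) == len(systems.S4) + len(lig.atoms)

    def test_waters_enter_all_systems_identically(self):
        cx, params, _ = make_complex(seed=7)
        lig = next(r for r in cx.residues if r.kind == "ligand")
        w1 = add_water(cx, lig.atoms[0].coords + np.array([0.0, 0.0, 2.2]))
        w2 = add_water(cx, lig.atoms[5].coords + np.array([0.0, 0.0, -2.2]))
        frag = build_capped_fragment(cx, ("A", 4, ""))
        systems = assemble_systems(frag, lig, [w1, w2],
                                   water_policy="all_systems")
        n_water_atoms = len(w1.atoms) + len(w2.atoms)
        for label in ("S1", "S2", "S3", "S4"):
            atoms = getattr(systems, label)
            water_members = [a for a in atoms
                             if a in w1.atoms or a in w2.atoms]
            assert len(water_members) == n_water_atoms

    def test_cap_atoms_shared_across_systems(self, complex_setup):
        cx, lig = complex_setup["structure"], complex_setup["ligand"]
        frag = build_capped_fragment(cx, ("A", 3, ""))
        systems = assemble_systems(frag, lig)
        for cap_atom in frag.cap_atoms:
            for label in ("S1", "S2", "S3", "S4"):
                assert cap_atom in getattr(systems, label)


class _ConstantBackend:
    is_pairwise_additive = False

    def __init__(self, c):
        self.c = c

    def evaluate(self, atoms):
        return self.c


class TestMfccEnergy:
    def test_matches_direct_oracle_on_seeded_complexes(self):
        # conjugate-cap cancellation is algebraically exact for a
        # pairwise-additive backend, whatever the geometry
        for seed in range(10):
            cx, params, _ = make_complex(seed=seed)
            backend = PairwiseBackend(params)
            lig = next(r for r in cx.residues if r.kind == "ligand")
            target = cx.find_residue(("A", 4, ""))
            frag = build_capped_fragment(cx, ("A", 4, ""))
            systems = assemble_systems(frag, lig, water_policy="none")
            e = mfcc_interaction_energy(systems, backend)
            ref = interaction_energy_direct(target.atoms, lig.atoms, params)
            assert abs(e - ref) <= 1e-8

    def test_far_ligand_gives_negligible_energy(self, complex_setup):
        cx = complex_setup["structure"]
        lig = complex_setup["ligand"]
        far = lig.copy()
        for a in far.atoms:
            a.coords = a.coords + np.array([1e6, 0.0, 0.0])
        frag = build_capped_fragment(cx, ("A", 3, ""))
        systems = assemble_systems(frag, far)
        e = mfcc_interaction_energy(systems, complex_setup["backend"])
        assert abs(e) < 1e-6

    def test_constant_backend_cancels_to_zero(self, complex_setup):
        cx, lig = complex_setup["structure"], complex_setup["ligand"]
        frag = build_capped_fragment(cx, ("A", 3, ""))
        systems = assemble_systems(frag, lig)
        assert mfcc_interaction_energy(systems, _ConstantBackend(42.0)) == 0.0

    def test_water_inclusion_leaves_energy_unchanged(self):
        cx, params, _ = make_complex(seed=11)
        backend = PairwiseBackend(params)
        lig = next(r for r in cx.residues if r.kind == "ligand")
        target = cx.find_residue(("A", 4, ""))
        frag = build_capped_fragment(cx, ("A", 4, ""))
        ref = interaction_energy_direct(target.atoms, lig.atoms, params)
        waters = []
        for k in range(3):
            waters.append(add_water(
                cx, lig.atoms[2 * k].coords + np.array([0.0, 0.0, 2.2])))
            systems = assemble_systems(frag, lig, waters,
                                       water_policy="all_systems")
            e = mfcc_interaction_energy(systems, backend)
            assert abs(e - ref) <= 1e-8


class TestDecomposeSite:
    def test_region_breakdown_sums_to_energy(self, complex_setup):
        energies = decompose_site(
            complex_setup["structure"], complex_setup["ligand"],
            complex_setup["backend"], region_map=complex_setup["region_map"])
        assert energies
        for e in energies:
            assert sum(e.region_breakdown.values()) == \
                pytest.approx(e.energy, abs=1e-9)
            assert e.region_tag in ("i", "ii", "iii")

    def test_total_matches_direct_interaction(self, complex_setup):
        cx, lig = complex_setup["structure"], complex_setup["ligand"]
        params = complex_setup["params"]
        energies = decompose_site(cx, lig, complex_setup["backend"])
        selected_atoms = []
        selected = {e.residue_id for e in energies}
        for r in cx.residues:
            if r.residue_id in selected:
                selected_atoms.extend(r.atoms)
        total = interaction_energy_direct(selected_atoms, lig.atoms, params)
        assert sum(e.energy for e in energies) == pytest.approx(total,
                                                                abs=1e-8)

    def test_empty_selection_gives_empty_list(self, complex_setup):
        cx, lig = complex_setup["structure"], complex_setup["ligand"]
        energies = decompose_site(cx, lig, complex_setup["backend"],
                                  SelectionCriteria(residue_cutoff=0.5))
        assert energies == []


class TestRadiusProfile:
    def _energy(self, dist, e):
        from fragdecomp.mfcc import ResidueEnergy
        return ResidueEnergy(("A", 1, "", "ALA"), e, dist)

    def test_single_residue_step(self):
        prof = radius_profile([self._energy(4.2, -5.0)], [3.0, 4.2, 5.0])
        assert prof.cumulative_energy.tolist() == [0.0, -5.0, -5.0]

    def test_final_value_conserves_total(self, complex_setup):
        energies = decompose_site(
            complex_setup["structure"], complex_setup["ligand"],
            complex_setup["backend"])
        prof = radius_profile(energies, [2.0, 5.0, 10.0])
        assert prof.cumulative_energy[-1] == \
            pytest.approx(sum(e.energy for e in energies), abs=1e-12)

    def test_matches_refiltering_oracle(self, complex_setup):
        energies = decompose_site(
            complex_setup["structure"], complex_setup["ligand"],
            complex_setup["backend"])
        radii = [1.0, 2.5, 4.0, 6.0, 8.0, 10.0]
        prof = radius_profile(energies, radii)
        for r, value in zip(radii, prof.cumulative_energy):
            oracle = sum(e.energy for e in energies if e.min_distance <= r)
            assert value == pytest.approx(oracle, abs=1e-12)

    def test_unsorted_radii_rejected(self):
        with pytest.raises(ValueError):
            radius_profile([self._energy(1.0, -1.0)], [5.0, 3.0])
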