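"""Per-residue interaction-energy decomposition of a synthetic complex.

Builds a small peptide-steroid complex, decomposes the ligand interaction
over the binding-site residues with the conjugate-cap scheme and the
built-in pairwise backend, and prints the per-residue energies with their
ligand-region breakdown plus the cumulative energy as a function of the
selection radius.
"""

from fragdecomp import (PairwiseBackend, decompose_site, energies_to_frame,
                        interaction_energy_direct, make_complex,
                        radius_profile)

structure, params, region_map = make_complex(site_residue=4,
                                             contact_distance=3.5, seed=1)
ligand = next(r for r in structure.residues if r.kind == "ligand")
backend = PairwiseBackend(params)

energies = decompose_site(structure, ligand, backend, region_map=region_map)
print(energies_to_frame(energies).round(4).to_string(index=False))

total = sum(e.energy for e in energies)
selected_atoms = [a for r in structure.residues
                  if r.residue_id in {e.residue_id for e in energies}
                  for a in r.atoms]
oracle = interaction_energy_direct(selected_atoms, ligand.atoms, params)
print(f"\nsum of residue energies : {total:+.6f} kcal/mol")
print(f"direct cross interaction: {oracle:+.6f} kcal/mol")
print(f"difference              : {abs(total - oracle):.2e} kcal/mol")

profile = radius_profile(energies, [2.0, 4.0, 6.0, 8.0, 10.0])
print("\nradius (A)  cumulative energy (kcal/mol)")
for r, e in zip(profile.radii, profile.cumulative_energy):
    print(f"   {r:5.1f}     {e:+.4f}")

# The per-residue energies sum exactly to the direct protein-ligand cross
# interaction (conjugate-cap cancellation is algebraic for a pairwise
# backend), and the cumulative profile converges to that total as the
# selection radius grows.
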