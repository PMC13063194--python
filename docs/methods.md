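# Methods

## Fragment decomposition model

The quantity of interest is the interaction energy between a ligand L and
each amino-acid residue R_i of a binding site. Because R_i is covalently
bonded into the chain, it cannot simply be excised; instead *conjugate
caps* — here the full adjacent residues R_{i−1} and R_{i+1}, including
side chains — stand in for the chain on either side. The caps' distal
backbone bonds (the N of R_{i−1} toward the C of R_{i−2}, the C of R_{i+1}
toward the N of R_{i+2}) are severed and passivated with a hydrogen placed
on the original bond axis at 1.09 Å from carbon or 1.01 Å from nitrogen,
standard C–H/N–H bond lengths. Chain termini simply lack the corresponding
cap or passivation. Four systems are evaluated — caps+R_i+L, caps+R_i,
caps+L, caps — and combined as E_S1 − E_S2 − E_S3 + E_S4.

Assumptions and consequences:

- **Cap extent.** Full adjacent residues are used as caps rather than
  backbone-only moieties. This is the most conservative reading of
  "caps formed from the immediately adjacent residues": it maximises the
  environment a quantum backend sees and makes the cancellation test
  strict (more atoms must cancel).
- **Byte-identical caps.** Cap atoms are the *same objects* in all four
  systems. For any pairwise-additive backend this makes the combination
  algebraically equal to the R_i–L cross-pair sum — the package's central
  invariant, verified to 1e-8 kcal/mol on 50 seeded complexes. The caps'
  bonds toward R_i are deliberately left unpassivated in S3/S4; adding
  hydrogens there would break byte-identity and with it the cancellation.
- **Waters.** Bridging waters (within 2.5 Å of a selected residue or the
  ligand) can be included; they enter all four systems identically, so
  they cancel exactly for additive backends while letting a quantum
  backend see the bridging environment. Where waters should sit in the
  four systems is not uniquely prescribed by the fragmentation scheme
  itself; identical placement is the only choice that preserves the
  additive-backend invariant, which is why it is the default.
- **Selection.** Binding-site residues are those whose minimum
  inter-atomic distance (any atom, hydrogens included when present) to the
  ligand is ≤ 10 Å, inclusive at the boundary. The cumulative
  radius-profile over these residues converges well before 10 Å in the
  synthetic systems, mirroring the behaviour expected of screened
  interactions.

## Energy backends

The built-in `PairwiseBackend` evaluates
k·q_i·q_j/(ε_r·r) + 4ε[(σ/r)¹² − (σ/r)⁶] over unordered pairs with
Lorentz–Berthelot mixing, k = 332.0637 kcal·Å·mol⁻¹·e⁻², no cutoff and no
periodic images (a cutoff would break the cancellation identity). The
relative dielectric defaults to 40, a screening value appropriate to a
partially buried protein–ligand interface (bulk water would be ~78); it is
a scalar divisor, deliberately the simplest screening model, because the
backend's role is verification, not force-field fidelity. The LJ table
covers H/C/N/O/S with generic values and is fully overridable. Charges are
in elementary units; energies in kcal/mol.

`FileExchangeBackend` adapts an external quantum-chemistry engine through
file exchange (write XYZ, read one energy in Hartree, convert at
627.509474 kcal/mol per Hartree). External engines are not pairwise
additive: per-region energy breakdowns are then unavailable and region
attribution falls back to tagging each residue with the region of the
nearest ligand atom.

## Region attribution

The ligand is partitioned into labelled regions (i/ii/iii) by atom name.
For additive backends the per-region energy of a residue is the exact
cross-interaction with that region's atoms, computed through the backend
contract as E(R_i ∪ region) − E(R_i) − E(region); ligand atoms missing
from the map (typically hydrogens) are attributed to the region of the
nearest mapped atom so the breakdown always sums to the total. A residue's
single region tag is the breakdown entry of largest magnitude.

## Hydrogen bonds

Donors are N/O atoms carrying a covalently bonded hydrogen (X–H ≤ 1.25 Å,
same residue); acceptors are N/O (S configurable). A bond requires
donor–acceptor distance ≤ 3.4 Å and, when a hydrogen is present, a
D–H···A angle in [90°, 180°]; both boundaries are inclusive, with a 1e-9
floating-point guard so exact boundary geometries are accepted while
violations at the 1e-6 level are rejected. Structures without hydrogens
degrade to distance-only detection, flagged by a null angle; a pair
already evaluated with an explicit hydrogen is never resurrected by the
distance-only fallback from the hydrogen-less direction. Water bridges
are waters satisfying the criteria simultaneously with an atom of each
group. Occupancy is the exact fraction of trajectory frames in which a
donor–acceptor pair passes detection. Contact typology beyond hydrogen
bonds (4 Å shell) uses an ordered rule table — alkyl C–C pairs as
hydrophobic, an optional π–cation rule, a van der Waals residual — and is
an approximate, documented substitute for proprietary interaction
taxonomies.

## Trajectory metrics

Superposition is the Kabsch least-squares proper rotation (SVD with
determinant correction; collinear selections are rejected). RMSD defaults
to heavy atoms against the first frame — the common convention for
stability plots; the reference is configurable since published curves do
not always state theirs. ΔRMSD is the max−min of the series inside a time
window. RMSF fits each frame to the reference (first frame, or the
once-iterated mean structure by default), computes each atom's mean
squared displacement about its time-mean position, averages within a
residue and takes the root. Mass weighting is off by default.

## Ensemble pipeline

Frames are flattened to coordinate features after superposition to the
first frame (alignment on, fitting heavy atoms, by default — otherwise
rigid drift masquerades as conformational variance). Dimensionality
reduction is pluggable: a deterministic PCA projection
(`linear_projection`, the default for exactly reproducible runs) or UMAP
(`neighbor_graph_nonlinear`, seed-pinned) — the clustering, not the
particular embedding, is the scientific claim. Clustering is a Gaussian
mixture; with `k="auto"` the component count minimises BIC over k ∈ [1, 8]
and the trace is stored. Representative conformations are raw coordinate
means over member frames after superposition — no geometry
re-idealisation — with one numerical refinement: a coordinate constant
across all member frames is reproduced bit-exactly rather than through
floating-point summation, so a cluster of identical frames returns that
frame exactly.

## Reporting

`ensemble_stats` stores the exact mean and *both* standard-deviation
conventions (population n, sample n−1), because published tables of this
kind demonstrably mix them row by row; the display convention is explicit
(sample by default) and rounding happens only at presentation (mean 1
d.p., σ 2 d.p., C_V 1 d.p.). C_V uses unrounded values by default, with a
presentation mode recomputing from rounded ones. The two-site combined
mean is the arithmetic mean of the two site means' magnitudes, applied to
the means as presented. Pose classification substitutes a reproducible
geometric rule for visual assignment: a pose joins the site whose defining
residues are nearest (minimum inter-atomic distance ≤ the 5 Å assignment
cutoff), per-site frequency and lowest-score pose are tabulated, and the
two most frequent sites' best poses are surfaced as the headline pair.

## Synthetic data: what it emulates and what it does not

The generator produces the statistical structure the analyses assume, not
realistic biomolecules: poly-alanine backbones at ideal bond geometry
(N–CA 1.458, CA–C 1.525, C–N 1.329, C=O 1.231, CA–CB 1.530 Å; extended or
helical torsions), a rigid planar acene-like fused-ring ligand (18 C) with
hydroxyl-like O3/O17 termini anchoring regions i and iii, per-residue
zero-sum Gaussian charges (scale 0.15 e) so Coulomb sums stay bounded, and
ligand placement at an exact requested contact distance (3.5 Å default,
solved to 1e-6 by translation along the closest-pair axis, orientation
re-drawn per seed until clash-free). Trajectories draw frames from k
cluster centres that differ by rigid *ligand* displacements — an internal
motion that protein superposition cannot remove — of magnitude
separation × noise σ (defaults 8 × 0.3 Å) along distinct axes, add
isotropic per-atom Gaussian noise, and shuffle deterministically; planted
labels, offsets and geometries are returned for oracle tests. Hydrogen
bonds are planted by moving the acceptor to the exact requested
distance/angle (adding a donor hydrogen if the heavy-atom-only peptide
lacks one).

Passing tests therefore demonstrate the *algorithms* — cancellation,
boundary handling, recovery, conservation — under controlled conditions;
they do not demonstrate force-field accuracy, real conformational
sampling, or the behaviour of quantum-chemical energies on real binding
sites.

## Problem sizes and numerical choices

Default test-battery conditions: 8-residue peptides (~60-atom complexes),
300-frame trajectories, 3 clusters, 50 seeded complexes for the exactness
experiment and 20 seeds for cluster recovery. Tolerances follow the source
of error: algebraic identities at 1e-8 to 1e-12 (floating-point
accumulation only), planted geometries at 1e-6, statistical recovery as
thresholds (ARI ≥ 0.95 in ≥ 18/20 runs; noise-σ re-estimate within 15%).
Ties in conformer ranking break lexicographically by label; GMM fits use 3
initialisations with a fixed seed for platform-stable labels.

## Known limitations

- Quantum-chemical energies are adapted, never computed: no DFT, no
  geometry optimisation, no implicit-solvation model beyond the scalar
  dielectric of the classical backend.
- The PDB surface targets coordinate files of the common ATOM/HETATM
  dialect; mmCIF, binary MD formats and protonation assignment are out of
  scope (convert externally).
- Contact typology is heuristic and not a reimplementation of any
  commercial interaction classifier.
- Nucleic acids and non-peptide polymers are not fragmentable; nonstandard
  residues are rejected by name rather than silently capped.
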