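"""Conformational-ensemble clustering and representative conformations.

Draws a 300-frame trajectory from three planted cluster centres, embeds
the frames, clusters them with a Gaussian mixture (component count chosen
by BIC), extracts the per-cluster average structures, scores each with the
fragment decomposition and ranks them by total interaction energy.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from fragdecomp import (GeneratorSpec, PairwiseBackend, decompose_site,
                        featurize, fit_gmm, make_clustered_trajectory,
                        make_complex, rank_conformers, reduce_dimensionality,
                        representative_conformations)

structure, params, region_map = make_complex(seed=3)
spec = GeneratorSpec(n_frames=300, n_clusters=3, cluster_separation=8.0,
                     noise_sigma=0.3, seed=3)
trajectory, planted_labels, _ = make_clustered_trajectory(structure, spec)

X = featurize(trajectory, align=True)
embedding = reduce_dimensionality(X, "linear_projection", n_dims=2, seed=3)
model = fit_gmm(embedding, k="auto", seed=3)
ari = adjusted_rand_score(planted_labels, model.labels)
print(f"chosen k = {model.n_clusters}, "
      f"agreement with planted labels (ARI) = {ari:.3f}")

backend = PairwiseBackend(params)
energies = {}
for rep in representative_conformations(trajectory, model):
    lig = next(r for r in rep.structure.residues if r.kind == "ligand")
    total = sum(e.energy for e in decompose_site(rep.structure, lig, backend))
    energies[f"cluster conf. {rep.cluster_index}"] = total
    print(f"cluster {rep.cluster_index}: {len(rep.member_frames)} frames, "
          f"total interaction energy {total:+.3f} kcal/mol")

ranking = rank_conformers(energies)
print(f"\nstrongest binder: {ranking.min_label} ({ranking.min_energy:+.3f})")
print(f"weakest binder:   {ranking.max_label} ({ranking.max_energy:+.3f})")

# With centres separated by 8x the frame noise the mixture model recovers
# the planted partition essentially perfectly, and the ranked per-cluster
# energies identify the strongest- and weakest-binding conformations.
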