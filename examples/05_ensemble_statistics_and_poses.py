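"""Ensemble statistics tables and docking-pose classification.

Summarises a set of per-conformation interaction energies the way a
results table would (mean, both standard-deviation conventions, C_V),
then classifies 20 synthetic docked poses into two binding sites by
proximity and reports per-site frequencies and best scores.
"""

import numpy as np

from fragdecomp import (PoseRecord, classify_poses, combined_site_mean,
                        ensemble_stats, make_complex)
from fragdecomp.mol_io import Atom

site1 = [-50.6, -51.6, -52.2, -54.8, -57.9]      # narrow ensemble
site2 = [-41.4, -61.1, -61.9, -67.0, -68.1, -69.7]  # wide ensemble
for label, values in [("site 1", site1), ("site 2", site2)]:
    row = ensemble_stats(values, label)
    p = row.presentation()
    print(f"{label}: mean {p['mean']:+.1f}  sigma(sample) {p['sigma']:.2f}  "
          f"C_V {p['cv_percent']:.1f}%  (n={len(values)})")
combined = combined_site_mean(ensemble_stats(site1).presentation()["mean"],
                              ensemble_stats(site2).presentation()["mean"])
print(f"combined two-site mean magnitude: {combined:.2f} kcal/mol\n")

structure, _, _ = make_complex(seed=17)
sites = {"site_a": {("A", 2, "", "ALA"), ("A", 3, "", "ALA")},
         "site_b": {("A", 6, "", "ALA"), ("A", 7, "", "ALA")}}

def pose_near(seq, pose_id, score):
    anchor = structure.find_residue(("A", seq, "")).get_atom("CB").coords
    return PoseRecord(pose_id, score, [
        Atom(6000 + abs(hash(pose_id)) % 1000, "C1", "C",
             anchor + np.array([0.0, 0.0, 2.0]))])

poses = [pose_near(2, f"a{i:02d}", -7.0 - 0.1 * i) for i in range(11)]
poses.append(pose_near(3, "a_best", -9.2))
poses += [pose_near(6, f"b{i:02d}", -7.5 - 0.1 * i) for i in range(7)]
poses.append(pose_near(7, "b_best", -8.7))

result = classify_poses(poses, sites, structure, assign_cutoff=5.0)
print("site frequencies:", result.frequencies)
for site, pose in result.headline:
    print(f"best pose in {site}: {pose.pose_id} (score {pose.score})")

# The wide ensemble's large sigma / C_V flags a heterogeneous set of
# binding conformations; pose classification reproduces the planted 12/8
# split and surfaces the lowest-score pose per site.
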