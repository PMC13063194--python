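"""Conformational-ensemble pipeline: featurize → reduce → cluster → represent.

Frames of a trajectory are flattened into coordinate feature vectors
(optionally after rigid superposition to the first frame), embedded in a
low-dimensional space, and clustered with a Gaussian mixture model.  Each
cluster is summarised by a *representative conformation*: the arithmetic
mean of its member frames' atomic coordinates (after superposition), kept
as raw averaged geometry.  Conformer ranking orders representatives by
their total interaction energy.

The nonlinear embedding (UMAP) is pluggable; a deterministic linear
principal-component projection is provided for dependency-light, exactly
reproducible pipelines, since the clustering — not the particular
embedding — is the quantity of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .mol_io import Structure, Trajectory
from .trajectory import Selection, kabsch_superpose, selection_indices

__all__ = [
    "EnsembleModel",
    "RepresentativeConformation",
    "ConformerRanking",
    "featurize",
    "filter_frames",
    "reduce_dimensionality",
    "fit_gmm",
    "representative_conformations",
    "rank_conformers",
]


@dataclass(eq=False)
class EnsembleModel:
    """Cluster assignment of trajectory frames in an embedding space."""

    labels: np.ndarray
    n_clusters: int
    embedding: np.ndarray
    seed: int
    responsibilities: np.ndarray | None = None
    selection_criterion_trace: dict[int, float] | None = None


@dataclass(eq=False)
class RepresentativeConformation:
    """Per-cluster structure with coordinates averaged over member frames."""

    cluster_index: int
    structure: Structure
    member_frames: list[int]


@dataclass(eq=False)
class ConformerRanking:
    """Conformers in ascending energy order, extrema flagged."""

    ordered: list[tuple[str, float]]
    min_label: str
    min_energy: float
    max_label: str
    max_energy: float


def featurize(trajectory: Trajectory, selection: Selection = "heavy_atoms",
              align: bool = True) -> np.ndarray:
    """Flatten selected per-frame coordinates into an (n_frames, 3m) matrix.

    With ``align`` every frame is rigidly superposed (over the selection)
    to the first frame, so the features capture internal motion only.
    """
    first = trajectory.frames[0]
    idx = selection_indices(first, selection)
    if len(idx) == 0:
        raise ValueError("empty atom selection")
    coords = trajectory.coords()
    if align:
        ref = coords[0]
        for i in range(len(coords)):
            _, _, coords[i] = kabsch_superpose(coords[i], ref, idx)
    return coords[:, idx, :].reshape(len(coords), -1)


def filter_frames(frames: Trajectory | Sequence[Structure],
                  ) -> tuple[Trajectory, dict[int, str]]:
    """Drop invalid frames (non-finite coordinates, topology mismatches).

    Returns the cleaned trajectory and a report mapping each dropped frame
    index to the reason.  Raises if nothing survives.
    """
    frame_list = list(frames.frames) if isinstance(frames, Trajectory) else list(frames)
    dropped: dict[int, str] = {}
    kept: list[Structure] = []
    ref_key = None
    for i, f in enumerate(frame_list):
        if not np.all(np.isfinite(f.coords())):
            dropped[i] = "non-finite coordinates"
            continue
        key = Trajectory._topology_key(f)
        if ref_key is None:
            ref_key = key
        elif key != ref_key:
            dropped[i] = "topology mismatch"
            continue
        kept.append(f)
    if not kept:
        raise ValueError("all frames were dropped")
    times = None
    if isinstance(frames, Trajectory):
        times = np.asarray(frames.times)[
            [i for i in range(len(frame_list)) if i not in dropped]]
    return Trajectory(kept, times=times), dropped


def reduce_dimensionality(matrix: np.ndarray,
                          method: Literal["neighbor_graph_nonlinear",
                                          "linear_projection"] = "linear_projection",
                          n_dims: int = 2, seed: int = 0) -> np.ndarray:
    """Embed frame features into ``n_dims`` dimensions, deterministically per seed.

    ``linear_projection`` is a principal-component projection;
    ``neighbor_graph_nonlinear`` uses UMAP, which preserves neighbourhood
    structure of the conformational ensemble at the cost of a stochastic,
    seed-pinned layout.
    """
    matrix = np.asarray(matrix, dtype=float)
    n_frames, n_features = matrix.shape
    if not (1 <= n_dims < n_features):
        raise ValueError(f"n_dims must be in [1, {n_features})")
    if n_frames < n_dims + 1:
        raise ValueError("need more frames than embedding dimensions")
    if method == "linear_projection":
        return PCA(n_components=n_dims, random_state=seed,
                   svd_solver="full").fit_transform(matrix)
    if method == "neighbor_graph_nonlinear":
        import umap

        reducer = umap.UMAP(n_components=n_dims, random_state=seed,
                            n_neighbors=min(15, n_frames - 1))
        return np.asarray(reducer.fit_transform(matrix), dtype=float)
    raise ValueError(f"unknown method {method!r}")


def fit_gmm(embedding: np.ndarray, k: int | Literal["auto"] = "auto",
            seed: int = 0, k_range: Sequence[int] = range(1, 9),
            ) -> EnsembleModel:
    """Fit a Gaussian mixture to the embedding; labels by maximum responsibility.

    With ``k="auto"`` the component count is chosen by the Bayesian
    information criterion over ``k_range`` (clipped to the frame count) and
    the per-k BIC trace is recorded on the model.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = len(embedding)
    trace = None
    if k == "auto":
        trace = {}
        for kk in k_range:
            if kk > n:
                break
            gm = GaussianMixture(n_components=kk, random_state=seed,
                                 n_init=3).fit(embedding)
            trace[kk] = float(gm.bic(embedding))
        k = min(trace, key=trace.get)
    elif k > n:
        raise ValueError(f"k={k} exceeds the number of frames ({n})")
    gm = GaussianMixture(n_components=int(k), random_state=seed,
                         n_init=3).fit(embedding)
    resp = gm.predict_proba(embedding)
    return EnsembleModel(labels=np.argmax(resp, axis=1), n_clusters=int(k),
                         embedding=embedding, seed=seed,
                         responsibilities=resp,
                         selection_criterion_trace=trace)


def representative_conformations(trajectory: Trajectory, model: EnsembleModel,
                                 align: bool = True,
                                 fit_selection: Selection = "heavy_atoms",
                                 ) -> list[RepresentativeConformation]:
    """Average member-frame coordinates per cluster into one structure each.

    Frames are superposed to the first frame before averaging when
    ``align``; empty clusters are skipped with a warning.  The averaged
    coordinates are raw means — no geometry re-idealisation.
    """
    first = trajectory.frames[0]
    coords = trajectory.coords()
    if align:
        idx = selection_indices(first, fit_selection)
        for i in range(len(coords)):
            _, _, coords[i] = kabsch_superpose(coords[i], coords[0], idx)
    out = []
    for c in range(model.n_clusters):
        members = np.flatnonzero(model.labels == c)
        if len(members) == 0:
            warnings.warn(f"cluster {c} has no member frames; skipped",
                          stacklevel=2)
            continue
        member_coords = coords[members]
        mean_coords = member_coords.mean(axis=0)
        # the mean of a constant column is that constant, bit-exactly
        constant = np.ptp(member_coords, axis=0) == 0
        mean_coords[constant] = member_coords[0][constant]
        out.append(RepresentativeConformation(
            cluster_index=c,
            structure=first.with_coords(mean_coords),
            member_frames=members.tolist()))
    return out


def rank_conformers(energies: dict[str, float]) -> ConformerRanking:
    """Order conformers by total interaction energy (ascending; ties by label).

    The first entry (most negative energy) is the strongest-binding
    conformation, the last the weakest; both are surfaced explicitly.
    """
    if not energies:
        raise ValueError("no conformer energies given")
    ordered = sorted(energies.items(), key=lambda kv: (kv[1], kv[0]))
    return ConformerRanking(
        ordered=ordered,
        min_label=ordered[0][0], min_energy=ordered[0][1],
        max_label=ordered[-1][0], max_energy=ordered[-1][1])
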