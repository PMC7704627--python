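"""k-means clustering of species on binary site features, with PCA.

Species are described by 0/1 presence indicators for a selected set of
matrices plus one telomerase-state indicator, then clustered with Lloyd's
algorithm under many random restarts.  Because k-means labels are
arbitrary, each result is reduced to a canonical form (clusters renamed
by first occurrence along the species order) so that distinct clusterings
can be deduplicated and ranked by their within-cluster sum of squares.
Selection among distinct clusterings — e.g. the one that best matches an
external grouping — is left to the caller; a label-homogeneity score is
provided to support it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .io import ACTIVE, StudyError
from .stats import SiteCountTable


@dataclass
class FeatureMatrix:
    """Species x feature 0/1 matrix with recorded column provenance."""

    data: pd.DataFrame

    def __post_init__(self):
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise StudyError("feature matrix entries must be 0/1")

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


STATE_COLUMN = "telomerase_active"


def build_features(table: SiteCountTable, selected_matrices: list[str],
                   *, use_counts: bool = False,
                   include_state: bool = True) -> FeatureMatrix:
    """Presence indicators for selected matrices (+ state indicator).

    Column order follows ``selected_matrices``; the telomerase indicator
    (active = 1) is appended last.  ``use_counts`` keeps raw counts
    instead of binarising (counts are then not constrained to 0/1).
    """
    missing = [m for m in selected_matrices if m not in table.counts.columns]
    if missing:
        raise StudyError(f"unknown matrix ids: {', '.join(missing)}")
    cols = table.counts[list(selected_matrices)]
    data = cols.copy() if use_counts else (cols >= 1).astype(int)
    if include_state:
        data[STATE_COLUMN] = (table.states == ACTIVE).astype(int)
    if use_counts:
        fm = FeatureMatrix.__new__(FeatureMatrix)  # counts may exceed 1
        fm.data = data
        return fm
    return FeatureMatrix(data=data)


@dataclass
class ClusteringResult:
    """One distinct k-means solution in canonical label form.

    ``assignments`` maps the species order of the feature matrix to
    cluster ids 0..k-1 renamed by first occurrence, so two label
    permutations of the same partition compare equal.
    """

    assignments: np.ndarray
    k: int
    wcss: float
    restart: int

    @property
    def canonical_form(self) -> tuple[int, ...]:
        return tuple(int(c) for c in self.assignments)

    def n_clusters_used(self) -> int:
        return len(set(self.canonical_form))


def canonicalise(labels: np.ndarray) -> np.ndarray:
    """Rename cluster labels by order of first occurrence."""
    mapping: dict[int, int] = {}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def kmeans_multi(features: FeatureMatrix, k: int, restarts: int = 100,
                 seed: int | None = None, *,
                 standardise: bool = False) -> list[ClusteringResult]:
    """Distinct k-means clusterings over random restarts, best first.

    Each restart runs Lloyd's algorithm from random initial centers;
    results are deduplicated by canonical form and sorted by
    within-cluster sum of squares ascending (ties by first restart).
    Deterministic given ``seed``.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible clustering")
    X = features.values
    n = X.shape[0]
    if k < 1 or k > n:
        raise StudyError(f"k must be in 1..{n}, got {k}")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if standardise:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    states = np.random.SeedSequence(seed).generate_state(restarts) % (2**31)
    found: dict[tuple[int, ...], ClusteringResult] = {}
    for r in range(restarts):
        km = KMeans(n_clusters=k, init="random", n_init=1,
                    random_state=int(states[r]))
        labels = canonicalise(km.fit_predict(X))
        key = tuple(int(c) for c in labels)
        if key not in found:
            found[key] = ClusteringResult(
                assignments=labels, k=k, wcss=float(km.inertia_), restart=r)
    return sorted(found.values(), key=lambda c: (c.wcss, c.restart))


def homogeneity(result: ClusteringResult, labels) -> float:
    """Mean within-cluster purity of an external label (1 = homogeneous).

    For each cluster, the fraction of members sharing the cluster's
    majority label, averaged over clusters.
    """
    labels = np.asarray([str(x) for x in labels])
    purities = []
    for c in set(result.canonical_form):
        members = labels[result.assignments == c]
        _, counts = np.unique(members, return_counts=True)
        purities.append(counts.max() / members.size)
    return float(np.mean(purities))


def pca_project(features: FeatureMatrix, dims: int = 2) -> pd.DataFrame:
    """Project species onto the top principal components.

    Columns are centered (not scaled) and the data projected onto the
    leading ``dims`` right singular directions.  Sign convention: each
    component's largest-magnitude loading is positive, so output is
    deterministic.  Identical rows project to the origin.
    """
    if dims < 1:
        raise ValueError(f"dims must be >= 1, got {dims}")
    X = features.values
    if dims > X.shape[1]:
        raise ValueError(f"dims {dims} exceeds number of features {X.shape[1]}")
    centered = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    comps = vt[:dims]
    for j in range(comps.shape[0]):
        lead = np.argmax(np.abs(comps[j]))
        if comps[j, lead] < 0:
            comps[j] = -comps[j]
    coords = centered @ comps.T
    return pd.DataFrame(
        coords, index=pd.Index(features.species_ids, name="species_id"),
        columns=[f"PC{i + 1}" for i in range(dims)],
    )


def write_clusterings(results: list[ClusteringResult],
                      species_ids: list[str], seed: int) -> str:
    """Distinct clusterings as TSV (species_id, cluster, rank, restart)."""
    lines = ["species_id\tcluster\trank\trestart\twcss\tseed"]
    for rank, res in enumerate(results):
        for sid, c in zip(species_ids, res.assignments):
            lines.append(f"{sid}\t{c}\t{rank}\t{res.restart}\t{res.wcss:.6g}\t{seed}")
    return "\n".join(lines) + "\n"


def plot_pca(coords: pd.DataFrame, assignments, path: str) -> None:
    """Scatter of the first two PCs coloured by cluster id."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    assignments = np.asarray(assignments)
    for c in sorted(set(int(a) for a in assignments)):
        sel = assignments == c
        ax.scatter(coords.iloc[sel, 0], coords.iloc[sel, 1], label=f"cluster {c}")
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
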