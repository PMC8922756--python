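"""Robinson-Foulds tree space: PCoA embedding, gene-tree clusters, the
gene-discordance (GD) metric and cluster-property comparisons.

The landscape of per-gene trees is summarized by their pairwise RF
distances; classical principal coordinates analysis embeds the matrix
(RF spaces are generally non-Euclidean, so negative-eigenvalue axes are
dropped and their magnitude reported); Ward agglomerative clustering
with silhouette-selected k identifies regions of tree space; GD is the
Euclidean distance of each gene tree to a designated species tree on the
first two principal coordinates.  Species trees can sit in the embedding
as points while staying out of the clustering.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_samples, silhouette_score

from .alignment import GeneAlignment
from .genetrees import DistanceMatrix, distance_matrix, nj_tree, rf_distance
from .molevol import significance_stars, welch_t

__all__ = [
    "TreeSpaceEmbedding",
    "ClusterAssignment",
    "tree_distance_matrix",
    "pcoa",
    "find_clusters",
    "gene_discordance",
    "cluster_property_report",
    "cluster_concatenate_and_retree",
]


@dataclass
class TreeSpaceEmbedding:
    labels: list[str]
    coordinates: np.ndarray  # n x k, axes ordered by decreasing eigenvalue
    eigenvalues: np.ndarray  # retained (positive), descending
    proportion: np.ndarray  # variance proportion per retained axis
    negative_magnitude: float  # total |negative eigenvalues| (distortion)

    def coords_of(self, label: str, n_axes: int = 2) -> np.ndarray:
        i = self.labels.index(label)
        k = min(n_axes, self.coordinates.shape[1])
        return self.coordinates[i, :k]


@dataclass
class ClusterAssignment:
    assignment: dict[str, int]  # label -> cluster id (1..k)
    k: int
    method: str
    silhouette: dict[str, float] = field(default_factory=dict)
    k_diagnostics: dict[int, float] = field(default_factory=dict)


def tree_distance_matrix(
    trees: list[dendropy.Tree], labels: list[str] | None = None
) -> DistanceMatrix:
    """Pairwise RF distances between trees sharing one tip set."""
    if labels is None:
        labels = [getattr(t, "gene_name", None) or f"tree{i + 1}" for i, t in enumerate(trees)]
    n = len(trees)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = rf_distance(trees[i], trees[j])
    return DistanceMatrix(list(labels), mat)


def pcoa(dm: DistanceMatrix, correction: str = "drop-negative") -> TreeSpaceEmbedding:
    """Classical metric scaling: double-center -1/2 J D^2 J and
    eigendecompose; coordinates are eigenvectors scaled by sqrt(lambda).

    Negative-eigenvalue axes (imaginary coordinates) cannot be retained;
    their total magnitude is reported so the embedding distortion can be
    judged.  For a Euclidean-embeddable input the retained coordinates
    reproduce the distances exactly.
    """
    if correction not in {"none", "drop-negative"}:
        raise ValueError(f"unknown correction {correction!r}")
    d = np.asarray(dm.matrix, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix not symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals).max(), 1.0) * 1e-10
    pos = evals > tol
    neg_mag = float(-evals[evals < -tol].sum())
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    total = evals[pos].sum() + neg_mag
    prop = evals[pos] / total if total > 0 else evals[pos] * 0.0
    return TreeSpaceEmbedding(list(dm.labels), coords, evals[pos], prop, neg_mag)


def find_clusters(
    dm: DistanceMatrix,
    k_range: range = range(2, 9),
    exclude_labels: list[str] | None = None,
) -> ClusterAssignment:
    """Ward agglomerative clustering on the tree distance matrix with k
    chosen by maximum mean silhouette over ``k_range``.

    ``exclude_labels`` (e.g. species-tree points) are left out of the
    clustering and of the silhouette statistics.  All-zero distances
    yield a single cluster with a warning.
    """
    exclude = set(exclude_labels or ())
    keep = [i for i, l in enumerate(dm.labels) if l not in exclude]
    labels = [dm.labels[i] for i in keep]
    mat = dm.matrix[np.ix_(keep, keep)]
    if len(labels) <= max(k_range):
        raise ValueError("need more items than the largest k considered")
    if np.allclose(mat, 0):
        warnings.warn("all tree distances are zero; single cluster, no k selection")
        return ClusterAssignment({l: 1 for l in labels}, 1, "ward+silhouette")
    z = linkage(squareform(mat, checks=False), method="ward")
    diagnostics: dict[int, float] = {}
    best_k, best_labels, best_score = None, None, -np.inf
    for k in k_range:
        lab = fcluster(z, k, criterion="maxclust")
        if len(set(lab)) < 2:
            continue
        score = silhouette_score(mat, lab, metric="precomputed")
        diagnostics[k] = float(score)
        if score > best_score:
            best_k, best_labels, best_score = k, lab, score
    if best_k is None:
        warnings.warn("no k in range produced >1 cluster; single cluster")
        return ClusterAssignment({l: 1 for l in labels}, 1, "ward+silhouette")
    # renumber clusters 1..k in order of first appearance for determinism
    remap: dict[int, int] = {}
    assignment = {}
    for l, c in zip(labels, best_labels):
        if c not in remap:
            remap[c] = len(remap) + 1
        assignment[l] = remap[c]
    sils = silhouette_samples(mat, best_labels, metric="precomputed")
    return ClusterAssignment(
        assignment,
        len(remap),
        "ward+silhouette",
        {l: float(s) for l, s in zip(labels, sils)},
        diagnostics,
    )


def gene_discordance(
    embedding: TreeSpaceEmbedding, reference_label: str
) -> dict[str, float]:
    """GD per tree: Euclidean distance to the reference (species-tree)
    point on the first two principal coordinates only."""
    if reference_label not in embedding.labels:
        raise ValueError(f"reference {reference_label!r} not in embedding")
    n_axes = min(2, embedding.coordinates.shape[1])
    if n_axes < 2:
        warnings.warn(f"only {n_axes} positive axes retained; GD uses those")
    ref = embedding.coords_of(reference_label, n_axes)
    return {
        l: float(np.linalg.norm(embedding.coords_of(l, n_axes) - ref))
        for l in embedding.labels
        if l != reference_label
    }


_PROPERTIES = ("gc", "aligned_length", "pv", "omega")


def cluster_property_report(
    table: pd.DataFrame, properties: tuple[str, ...] = _PROPERTIES
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster medians/quartiles and pairwise Welch t-tests per
    property.  ``table`` needs a ``cluster`` column plus the property
    columns; singleton clusters are excluded from testing with a warning.
    """
    if "cluster" not in table.columns:
        raise ValueError("table must carry a 'cluster' column")
    sizes = table.groupby("cluster").size()
    singletons = sizes[sizes < 2].index.tolist()
    if singletons:
        warnings.warn(f"singleton clusters excluded from tests: {singletons}")
    usable = [c for c in sizes.index if c not in singletons]
    rows = []
    for c, sub in table.groupby("cluster"):
        for prop in properties:
            v = sub[prop].dropna()
            rows.append(
                {
                    "cluster": c,
                    "property": prop,
                    "n": len(v),
                    "median": v.median(),
                    "q1": v.quantile(0.25),
                    "q3": v.quantile(0.75),
                }
            )
    summary = pd.DataFrame(rows)
    tests = []
    for c1, c2 in itertools.combinations(usable, 2):
        for prop in properties:
            x = table.loc[table["cluster"] == c1, prop].dropna()
            y = table.loc[table["cluster"] == c2, prop].dropna()
            if len(x) < 2 or len(y) < 2:
                continue
            t, p = welch_t(x, y)
            tests.append(
                {
                    "cluster1": c1,
                    "cluster2": c2,
                    "property": prop,
                    "t": t,
                    "p": p,
                    "stars": significance_stars(p),
                }
            )
    return summary, pd.DataFrame(tests)


def cluster_concatenate_and_retree(
    gene_alignments: dict[str, GeneAlignment],
    assignment: ClusterAssignment,
    reference_trees: dict[str, dendropy.Tree] | None = None,
    model: str = "JC69",
) -> dict[int, dict]:
    """Per cluster: concatenate its genes (fixed sorted order), infer one
    tree, and report RF distances to each reference tree."""
    out: dict[int, dict] = {}
    for c in sorted(set(assignment.assignment.values())):
        genes = sorted(g for g, cc in assignment.assignment.items() if cc == c)
        missing = [g for g in genes if g not in gene_alignments]
        if missing:
            raise ValueError(f"cluster {c}: no alignment for genes {missing}")
        concat = GeneAlignment.concatenate(
            [gene_alignments[g] for g in genes], name=f"cluster{c}"
        )
        tree = nj_tree(distance_matrix(concat, model))
        rfs = {
            name: rf_distance(tree, ref) for name, ref in (reference_trees or {}).items()
        }
        out[c] = {"genes": genes, "tree": tree, "rf_to_reference": rfs}
    return out
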