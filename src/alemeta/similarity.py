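"""Representational similarity between task networks.

Each network's (unthresholded) ALE map is flattened over the shared
mask into a vector; pairwise Pearson correlation r gives the distance
matrix D = 1 - r.  On D we provide:

* spectral (Fiedler-vector) reordering that groups similar networks
  contiguously along the diagonal;
* Ward agglomerative clustering (minimum-variance merges) and its
  dendrogram / flat cuts;
* classical (Torgerson) multidimensional scaling via double-centering,
  with a normalized stress measure;
* a similarity profile ranking every network against one reference
  (e.g. the pain network), with shares expressed as percentages.

Ward here operates on the 1 - r dissimilarities directly (Ward.D
convention); pass ``squared=True`` for the squared-dissimilarity
variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .corpus_io import VolumeMap

__all__ = [
    "DistanceMatrix",
    "Embedding",
    "vectorize_maps",
    "devectorize",
    "distance_matrix",
    "reorder_matrix",
    "ward_dendrogram",
    "cut_dendrogram",
    "mds_embed",
    "centrality_profile",
]


@dataclass
class DistanceMatrix:
    """Symmetric network x network dissimilarity (1 - r) with labels."""

    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("D shape does not match labels")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("D must be symmetric")
        if not np.allclose(np.diag(self.D), 0, atol=1e-10):
            raise ValueError("D must have zero diagonal")
        if np.any(self.D < -1e-10) or np.any(self.D > 2 + 1e-10):
            raise ValueError("1 - r entries must lie in [0, 2]")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)

    def permuted(self, order) -> "DistanceMatrix":
        order = list(order)
        return DistanceMatrix(
            labels=[self.labels[i] for i in order], D=self.D[np.ix_(order, order)]
        )


@dataclass
class Embedding:
    """Low-dimensional coordinates per network plus the residual stress."""

    labels: list[str]
    coords: np.ndarray  # (n, d)
    stress: float

    def pairwise_distances(self) -> np.ndarray:
        diff = self.coords[:, None, :] - self.coords[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))


def vectorize_maps(maps: list[VolumeMap], names: list[str] | None = None) -> np.ndarray:
    """Stack each map's in-mask values into a (network x voxel) matrix.

    Row order follows the input; column order is the C-order scan of the
    shared mask (the fixed voxel order every caller sees).  Maps that
    are constant over the mask are rejected: their correlation with
    anything is undefined.
    """
    if not maps:
        raise ValueError("no maps given")
    ref = maps[0]
    for m in maps[1:]:
        if not ref.same_grid(m):
            raise ValueError("maps are not on a common grid/mask")
    if names is None:
        names = [f"map{i}" for i in range(len(maps))]
    rows = []
    for name, m in zip(names, maps):
        v = m.values[m.mask]
        if np.ptp(v) == 0:
            raise ValueError(f"map {name!r} is constant over the mask; correlation undefined")
        rows.append(v)
    return np.stack(rows)


def devectorize(vector: np.ndarray, grid: VolumeMap) -> VolumeMap:
    """Inverse of one row of :func:`vectorize_maps`: paint the in-mask
    scan-order values back onto the grid (0 outside the mask)."""
    vector = np.asarray(vector, dtype=float)
    if vector.size != int(grid.mask.sum()):
        raise ValueError("vector length does not match the mask")
    values = np.zeros(grid.shape)
    values[grid.mask] = vector
    return grid.like(values)


def distance_matrix(vectors: np.ndarray, labels: list[str] | None = None) -> DistanceMatrix:
    """D_ij = 1 - Pearson r between rows i and j; zero diagonal."""
    vectors = np.asarray(vectors, dtype=float)
    if labels is None:
        labels = [f"net{i}" for i in range(vectors.shape[0])]
    sd = vectors.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"zero-variance vector for network {labels[int(flat[0])]!r}")
    r = np.corrcoef(vectors)
    D = 1.0 - r
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, 2.0)
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(labels=list(labels), D=D)


def reorder_matrix(dm: DistanceMatrix) -> list[int]:
    """Spectral reordering permutation.

    Builds the graph Laplacian of the similarity matrix S = 1 - D
    (negative similarities clipped to 0 so edge weights stay valid) and
    sorts networks by the Fiedler vector — the eigenvector of the
    second-smallest eigenvalue.  The eigenvector's global sign is fixed
    by making its first nonzero entry positive, so the permutation is
    deterministic.
    """
    S = np.clip(1.0 - dm.D, 0.0, None)
    np.fill_diagonal(S, 0.0)
    L = np.diag(S.sum(axis=1)) - S
    eigvals, eigvecs = np.linalg.eigh(L)
    fiedler = eigvecs[:, 1]
    nz = np.flatnonzero(np.abs(fiedler) > 1e-12)
    if nz.size and fiedler[nz[0]] < 0:
        fiedler = -fiedler
    return list(np.argsort(fiedler, kind="stable"))


def ward_dendrogram(dm: DistanceMatrix, squared: bool = False) -> np.ndarray:
    """Ward minimum-variance linkage on the 1 - r distances.

    Returns the standard (n-1, 4) linkage matrix (merge tree with
    heights).  Merge heights are non-decreasing.
    """
    d = squareform(dm.D, checks=False)
    if squared:
        d = d**2
    return linkage(d, method="ward")


def cut_dendrogram(Z: np.ndarray, dm: DistanceMatrix, n_clusters: int = 2) -> dict[str, int]:
    """Flat partition from the merge tree: label -> cluster id (1-based)."""
    assignments = fcluster(Z, t=n_clusters, criterion="maxclust")
    return dict(zip(dm.labels, (int(a) for a in assignments)))


def linkage_to_tree(Z: np.ndarray, labels: list[str]) -> dict:
    """Nested-dict rendering of a linkage matrix (for JSON export)."""
    n = len(labels)
    nodes: dict[int, dict] = {i: {"name": labels[i], "height": 0.0} for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        nodes[n + k] = {"height": float(h), "children": [nodes[int(a)], nodes[int(b)]]}
    return nodes[n + len(Z) - 1]


def mds_embed(dm: DistanceMatrix, d: int = 2) -> Embedding:
    """Classical (Torgerson) MDS.

    Double-centers the squared dissimilarities, B = -1/2 J D^2 J, and
    embeds on the top-d eigenvectors scaled by sqrt of their (positive)
    eigenvalues.  Stress is the normalized residual
    sqrt(sum (d_emb - D)^2 / sum D^2); it is 0 when D is exactly
    Euclidean and d is large enough, and decreases monotonically in d.
    """
    if not 1 <= d <= dm.n - 1:
        raise ValueError("embedding dimension must be in [1, n-1]")
    D2 = dm.D**2
    n = dm.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:d]
    lam = np.clip(eigvals[order], 0.0, None)
    coords = eigvecs[:, order] * np.sqrt(lam)
    emb = Embedding(labels=list(dm.labels), coords=coords, stress=0.0)
    diff = emb.pairwise_distances() - dm.D
    denom = (dm.D**2).sum()
    emb.stress = float(np.sqrt((diff**2).sum() / denom)) if denom > 0 else 0.0
    return emb


def centrality_profile(dm: DistanceMatrix, reference: str) -> pd.DataFrame:
    """Similarity of every other network to one reference network.

    Rows are sorted by decreasing similarity 1 - D[ref, i]; the
    ``percent`` column normalizes the similarity shares to sum to 100
    over the non-reference networks.  (Shares can exceed the [0, 100]
    range when anticorrelated networks give negative similarities;
    on meta-analytic maps similarities are typically non-negative.)
    """
    if reference not in dm.labels:
        raise KeyError(f"reference {reference!r} not among labels")
    ref = dm.labels.index(reference)
    rows = []
    for i, lab in enumerate(dm.labels):
        if i == ref:
            continue
        rows.append({"network": lab, "similarity": 1.0 - dm.D[ref, i]})
    df = pd.DataFrame(rows).sort_values("similarity", ascending=False, kind="stable")
    total = df["similarity"].sum()
    df["percent"] = 100.0 * df["similarity"] / total if total != 0 else 0.0
    return df.reset_index(drop=True)


def mean_distances(dm: DistanceMatrix) -> pd.Series:
    """Mean 1 - r distance of each network to all others (centrality:
    the hub-like network of a two-group design minimizes this)."""
    sums = dm.D.sum(axis=1) / (dm.n - 1)
    return pd.Series(sums, index=dm.labels, name="mean_distance")
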