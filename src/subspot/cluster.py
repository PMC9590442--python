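"""Two-track clustering.

The reference track (coarse simple-grid bins, enough UMIs per bin for stable
expression profiles) learns everything: log-normalization statistics, highly
variable genes (HVGs), per-gene scaling, PCA loadings and graph-community
labels.  The fine track (overlapping sliding-window bins) is then *projected*
into the learned PCA space with the reference's own statistics and receives a
label from its nearest reference bins — so cluster identities come from the
statistically solid coarse track while label geometry is resolved at the fine
track's denser bin lattice.

Conventions follow the common single-cell stack: log1p counts-per-10,000
normalization, per-gene z-scoring clipped at +/-10, centered PCA, a shared
nearest-neighbor (SNN) graph with Jaccard edge weights, and modularity-style
community detection (Leiden) at a fixed resolution and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import igraph
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .binning import BinnedMatrix

__all__ = [
    "ClusterModel",
    "ZeroTotalError",
    "normalize",
    "select_hvg",
    "fit_reference",
    "project",
    "transfer_labels",
]

#: SNN edges with Jaccard weight below this are pruned (ecosystem convention)
SNN_PRUNE = 1.0 / 15.0


class ZeroTotalError(ValueError):
    """A bin with zero total counts cannot be normalized."""


@dataclass
class ClusterModel:
    """Everything learned on the reference track, sufficient for out-of-sample
    projection and label transfer."""

    hvg: np.ndarray  # ordered gene ids
    gene_means: np.ndarray
    gene_sds: np.ndarray  # all > 0
    loadings: np.ndarray  # n_hvg x n_pcs, orthonormal columns
    reference_embedding: np.ndarray  # n_ref_bins x n_pcs
    reference_labels: np.ndarray  # int cluster ids per reference bin
    reference_bin_ids: np.ndarray
    normalization_scale: float = 1e4
    clip: float = 10.0

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.reference_labels))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "hvg": self.hvg.tolist(),
            "gene_means": self.gene_means.tolist(),
            "gene_sds": self.gene_sds.tolist(),
            "loadings": self.loadings.tolist(),
            "reference_embedding": self.reference_embedding.tolist(),
            "reference_labels": self.reference_labels.tolist(),
            "reference_bin_ids": self.reference_bin_ids.tolist(),
            "normalization_scale": self.normalization_scale,
            "clip": self.clip,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        d = json.loads(Path(path).read_text())
        return cls(
            hvg=np.array(d["hvg"], dtype=object),
            gene_means=np.array(d["gene_means"], dtype=float),
            gene_sds=np.array(d["gene_sds"], dtype=float),
            loadings=np.array(d["loadings"], dtype=float),
            reference_embedding=np.array(d["reference_embedding"], dtype=float),
            reference_labels=np.array(d["reference_labels"], dtype=int),
            reference_bin_ids=np.array(d["reference_bin_ids"], dtype=object),
            normalization_scale=float(d["normalization_scale"]),
            clip=float(d["clip"]),
        )


def normalize(binned: BinnedMatrix, scale: float = 1e4) -> sp.csr_matrix:
    """Log-normalize bin counts: ``ln(1 + scale * count / bin_total)``.

    Proportions within a bin are preserved (doubling every count of a bin
    leaves the result unchanged) and zeros map to zero.  Bins with zero total
    counts are rejected.
    """
    totals = np.asarray(binned.counts.sum(axis=1)).ravel()
    if (totals == 0).any():
        bad = binned.bin_ids[np.argmax(totals == 0)]
        raise ZeroTotalError(f"bin {bad!r} has zero total counts and cannot be normalized")
    out = binned.counts.astype(float).tocsr(copy=True)
    row_scale = scale / totals
    out.data = np.log1p(out.data * np.repeat(row_scale, np.diff(out.indptr)))
    return out


def select_hvg(normalized: sp.spmatrix, n_hvg: int) -> np.ndarray:
    """Indices of the ``n_hvg`` genes with highest variance of normalized
    values, ties broken by gene order (stable sort)."""
    n_genes = normalized.shape[1]
    if n_hvg <= 0:
        raise ValueError("n_hvg must be positive")
    if n_hvg > n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds gene count {n_genes}")
    X = sp.csr_matrix(normalized)
    mean = np.asarray(X.mean(axis=0)).ravel()
    mean_sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = np.maximum(mean_sq - mean**2, 0.0)
    order = np.argsort(-var, kind="stable")
    return order[:n_hvg]


def _scale_features(dense: np.ndarray, means: np.ndarray, sds: np.ndarray, clip: float) -> np.ndarray:
    return np.clip((dense - means) / sds, -clip, clip)


def _snn_graph(embedding: np.ndarray, k: int) -> sp.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard weights, pruned below
    :data:`SNN_PRUNE`.  ``k`` counts the point itself (as in the common
    single-cell convention)."""
    n = len(embedding)
    nn = NearestNeighbors(n_neighbors=k).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    A = sp.csr_matrix(
        (np.ones(n * k), (np.repeat(np.arange(n), k), idx.ravel())), shape=(n, n)
    )
    shared = (A @ A.T).toarray()
    with np.errstate(divide="ignore", invalid="ignore"):
        jaccard = shared / (2 * k - shared)
    jaccard[jaccard < SNN_PRUNE] = 0.0
    np.fill_diagonal(jaccard, 0.0)
    return sp.csr_matrix(jaccard)


def _leiden(graph: sp.csr_matrix, resolution: float, seed: int) -> np.ndarray:
    coo = sp.triu(graph, k=1).tocoo()
    g = igraph.Graph(
        n=graph.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.array(part.membership, dtype=int)


def fit_reference(
    binned_grid: BinnedMatrix,
    n_hvg: int = 2000,
    n_pcs: int = 20,
    k_neighbors: int = 20,
    resolution: float = 0.5,
    seed: int = 0,
    scale: float = 1e4,
    clip: float = 10.0,
) -> ClusterModel:
    """Learn the reference clustering on simple-grid bins.

    Pipeline: log-normalize -> HVG selection -> per-gene z-score with clip ->
    centered PCA -> SNN graph (``k_neighbors``) -> Leiden communities at
    ``resolution`` with a fixed ``seed``.  All statistics needed to project
    other bin tracks out-of-sample are stored on the returned model.
    ``n_hvg`` is capped at the gene count; zero-variance genes are excluded
    from the HVG set so every stored gene SD is positive.
    """
    n_bins = binned_grid.n_bins
    if n_bins < n_pcs:
        raise ValueError(
            f"only {n_bins} bins for n_pcs={n_pcs}; use a smaller n_pcs or larger bins"
        )
    if n_bins < k_neighbors + 1:
        raise ValueError(f"need at least k_neighbors+1={k_neighbors + 1} bins, have {n_bins}")

    norm = normalize(binned_grid, scale)
    hvg_idx = select_hvg(norm, min(n_hvg, norm.shape[1]))
    dense = np.asarray(norm[:, hvg_idx].todense())
    sds = dense.std(axis=0)
    variable = sds > 0
    if not variable.any():
        raise ValueError("no gene has positive variance across reference bins")
    hvg_idx = hvg_idx[variable]
    dense = dense[:, variable]
    means, sds = dense.mean(axis=0), sds[variable]

    Z = _scale_features(dense, means, sds, clip)
    pca = PCA(n_components=min(n_pcs, *Z.shape), svd_solver="full").fit(Z)
    loadings = pca.components_.T  # orthonormal columns
    embedding = Z @ loadings  # NB: no mean shift, so projection is self-consistent

    labels = _leiden(_snn_graph(embedding, k_neighbors), resolution, seed)

    gene_ids = binned_grid.genes["gene_id"].to_numpy(dtype=object)
    return ClusterModel(
        hvg=gene_ids[hvg_idx],
        gene_means=means,
        gene_sds=sds,
        loadings=loadings,
        reference_embedding=embedding,
        reference_labels=labels,
        reference_bin_ids=binned_grid.bin_ids.copy(),
        normalization_scale=scale,
        clip=clip,
    )


def project(model: ClusterModel, binned: BinnedMatrix) -> np.ndarray:
    """Project query bins into the reference PCA space.

    The query is log-normalized with the model's scale, restricted to the
    model's HVGs (genes absent from the query count as zero), z-scored with
    the *reference* means/SDs (clipped), and multiplied by the reference
    loadings.  Projecting the reference track itself reproduces its stored
    embedding.
    """
    norm = normalize(binned, model.normalization_scale)
    query_ids = pd.Index(binned.genes["gene_id"])
    pos = query_ids.get_indexer(model.hvg)
    if (pos >= 0).sum() == 0:
        raise ValueError("query shares no genes with the model's HVG set")
    dense = np.zeros((binned.n_bins, len(model.hvg)))
    present = pos >= 0
    dense[:, present] = np.asarray(norm[:, pos[present]].todense())
    Z = _scale_features(dense, model.gene_means, model.gene_sds, model.clip)
    return Z @ model.loadings


def transfer_labels(model: ClusterModel, query_embedding: np.ndarray, k: int = 5) -> np.ndarray:
    """Assign each query bin the majority label of its ``k`` nearest reference
    bins (Euclidean distance in the embedding); a tied vote falls back to the
    single nearest neighbor's label."""
    query_embedding = np.asarray(query_embedding, dtype=float)
    if query_embedding.ndim != 2 or len(query_embedding) == 0:
        raise ValueError("query embedding must be a non-empty 2-D array")
    n_ref = len(model.reference_embedding)
    if k < 1 or k > n_ref:
        raise ValueError(f"k must be in [1, {n_ref}], got {k}")
    nn = NearestNeighbors(n_neighbors=k).fit(model.reference_embedding)
    _, idx = nn.kneighbors(query_embedding)
    votes = model.reference_labels[idx]  # (n_query, k), column 0 = nearest
    out = np.empty(len(votes), dtype=int)
    for i, row in enumerate(votes):
        labs, counts = np.unique(row, return_counts=True)
        winners = labs[counts == counts.max()]
        out[i] = winners[0] if len(winners) == 1 else row[0]
    return out
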