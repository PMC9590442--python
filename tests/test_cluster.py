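"""Two-track clustering tests: normalization, HVG selection, reference
fitting, out-of-sample projection and label transfer."""

import numpy as np
import pytest

from subspot.binning import BinSpec, simple_grid_bin, sliding_window_bin
from subspot.cluster import (
    ClusterModel,
    ZeroTotalError,
    fit_reference,
    normalize,
    project,
    select_hvg,
    transfer_labels,
)

from conftest import make_matrix


def _binned(coords, counts, side=10.0, **kwargs):
    m = make_matrix(coords, counts, **{k: v for k, v in kwargs.items() if k == "gene_names"})
    return simple_grid_bin(m, BinSpec(side, anchor=(0.0, 0.0)))


def three_blob_bins(n_per=300, n_genes=9, seed=0):
    """Bins from three spatial domains with disjoint marker genes."""
    rng = np.random.default_rng(seed)
    coords, counts, truth = [], [], []
    for d in range(3):
        for i in range(n_per):
            coords.append((d * 200.0 + rng.uniform(0, 100), rng.uniform(0, 100)))
            row = rng.poisson(0.5, n_genes)
            row[d * 3:(d + 1) * 3] += rng.poisson(20.0, 3)
            counts.append(row)
            truth.append(d)
    m = make_matrix(coords, counts)
    binned = simple_grid_bin(m, BinSpec(10.0, anchor=(0.0, 0.0)))
    # per-bin truth from the x position of the bin center
    bin_truth = (binned.centers[:, 0] // 200).astype(int)
    return binned, bin_truth


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def test_normalize_formula_and_invariances():
    binned = _binned(
        coords=[(1.0, 1.0), (21.0, 1.0)],
        counts=[[10, 90], [20, 180]],  # second bin = doubled proportions
    )
    norm = normalize(binned, scale=10_000).toarray()
    assert norm[0, 0] == pytest.approx(np.log1p(10_000 * 10 / 100))  # ~6.9088
    assert norm[0, 0] == pytest.approx(6.9088, abs=1e-4)
    assert np.allclose(norm[0], norm[1])  # scale invariance of proportions
    assert normalize(binned).toarray()[0, 1] != 0  # zeros stay zero, others don't
    zeros = _binned(coords=[(1.0, 1.0)], counts=[[5, 0]])
    assert normalize(zeros).toarray()[0, 1] == 0.0


def test_normalize_rejects_zero_total_bin():
    binned = _binned(coords=[(1.0, 1.0), (21.0, 1.0)], counts=[[1, 1], [0, 0]])
    with pytest.raises(ZeroTotalError, match="x20_y0_s10"):
        normalize(binned)


# ---------------------------------------------------------------------------
# HVG selection
# ---------------------------------------------------------------------------

def test_select_hvg_orders_by_variance():
    # columns engineered with variances ranking gene2 > gene0 > gene1
    X = np.array([[0.0, 1.0, 0.0], [1.0, 1.2, 2.0], [2.0, 1.1, 4.0], [1.0, 1.0, 0.0]])
    import scipy.sparse as sp

    idx = select_hvg(sp.csr_matrix(X), 2)
    assert idx.tolist() == [2, 0]
    assert select_hvg(sp.csr_matrix(X), 3).tolist() == [2, 0, 1]


def test_select_hvg_skips_constant_when_possible():
    import scipy.sparse as sp

    X = sp.csr_matrix(np.array([[1.0, 0.0], [1.0, 2.0], [1.0, 1.0]]))
    assert select_hvg(X, 1).tolist() == [1]  # constant gene 0 never chosen
    with pytest.raises(ValueError):
        select_hvg(X, 0)
    with pytest.raises(ValueError):
        select_hvg(X, 3)


# ---------------------------------------------------------------------------
# reference fitting
# ---------------------------------------------------------------------------

def test_rank_one_data_first_loading():
    """When the scaled data vary along a single direction, the first PC is
    +/- that direction and later PCs carry no variance."""
    coords = [(10.0 * i + 1, 1.0) for i in range(30)]
    v = np.where(np.arange(30) % 2 == 0, 20, 80)  # two profiles -> exactly rank 1
    counts = np.column_stack([v, 100 - v])  # constant totals, one free direction
    binned = _binned(coords, counts)
    model = fit_reference(binned, n_hvg=2, n_pcs=2, k_neighbors=5, seed=0)
    direction = np.array([1.0, -1.0]) / np.sqrt(2)
    first = model.loadings[:, 0]
    # z-scored anticorrelated pair: first loading is +/- (1, -1)/sqrt(2) in HVG order
    lookup = {g: i for i, g in enumerate(model.hvg)}
    first_in_gene_order = first[[lookup["id0"], lookup["id1"]]]
    assert np.allclose(np.abs(first_in_gene_order @ direction), 1.0, atol=1e-2)
    assert model.reference_embedding[:, 1].std() < 1e-6 * model.reference_embedding[:, 0].std()


def test_fit_reference_recovers_three_domains():
    binned, truth = three_blob_bins(seed=1)
    model = fit_reference(binned, n_pcs=5, seed=0)
    from sklearn.metrics import adjusted_rand_score

    assert model.n_clusters == 3
    assert adjusted_rand_score(truth, model.reference_labels) == 1.0


def test_fit_reference_deterministic_under_seed():
    binned, _ = three_blob_bins(seed=2)
    m1 = fit_reference(binned, n_pcs=5, seed=0)
    m2 = fit_reference(binned, n_pcs=5, seed=0)
    assert np.array_equal(m1.reference_labels, m2.reference_labels)
    assert np.allclose(m1.reference_embedding, m2.reference_embedding)


def test_fit_reference_dimension_errors():
    binned, _ = three_blob_bins(n_per=8)
    with pytest.raises(ValueError, match="n_pcs"):
        fit_reference(binned, n_pcs=1000)
    with pytest.raises(ValueError, match="k_neighbors"):
        fit_reference(binned, n_pcs=2, k_neighbors=1000)


def test_loadings_orthonormal():
    binned, _ = three_blob_bins(seed=3)
    model = fit_reference(binned, n_pcs=5, seed=0)
    gram = model.loadings.T @ model.loadings
    assert np.allclose(gram, np.eye(model.loadings.shape[1]), atol=1e-6)
    assert (model.gene_sds > 0).all()


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def test_project_self_consistency():
    binned, _ = three_blob_bins(seed=4)
    model = fit_reference(binned, n_pcs=5, seed=0)
    assert np.abs(project(model, binned) - model.reference_embedding).max() < 1e-8


def test_identical_profile_identical_embedding():
    binned, _ = three_blob_bins(seed=5)
    model = fit_reference(binned, n_pcs=5, seed=0)
    emb = project(model, binned)
    # a query equal to reference bin 0's raw profile embeds on top of it
    sub = type(binned)(
        bin_ids=binned.bin_ids[:1],
        centers=binned.centers[:1],
        spec=binned.spec,
        counts=binned.counts[:1],
        n_barcodes_per_bin=binned.n_barcodes_per_bin[:1],
        genes=binned.genes,
        source_layer=binned.source_layer,
    )
    assert np.allclose(project(model, sub)[0], emb[0])


def test_all_zero_on_hvg_projection_closed_form():
    """A query expressing none of the model's HVGs lands at the clipped
    (-mean/sd) point mapped through the loadings."""
    binned, _ = three_blob_bins(seed=6)
    model = fit_reference(binned, n_hvg=6, n_pcs=4, seed=0)
    gene_ids = binned.genes["gene_id"].tolist()
    off_hvg = [g for g in gene_ids if g not in set(model.hvg)]
    assert off_hvg, "fixture needs at least one non-HVG gene"
    # put all counts on a non-HVG gene
    dense = np.zeros((1, len(gene_ids)), dtype=int)
    dense[0, gene_ids.index(off_hvg[0])] = 50
    query = _binned(coords=[(1.0, 1.0)], counts=dense)
    expected = np.clip(-model.gene_means / model.gene_sds, -model.clip, model.clip) @ model.loadings
    assert np.allclose(project(model, query)[0], expected)


def test_project_requires_gene_overlap():
    binned, _ = three_blob_bins(seed=7)
    model = fit_reference(binned, n_pcs=5, seed=0)
    alien = binned
    alien = type(binned)(
        bin_ids=binned.bin_ids,
        centers=binned.centers,
        spec=binned.spec,
        counts=binned.counts,
        n_barcodes_per_bin=binned.n_barcodes_per_bin,
        genes=binned.genes.assign(gene_id=[f"other{i}" for i in range(len(binned.genes))]),
        source_layer=binned.source_layer,
    )
    with pytest.raises(ValueError, match="no genes"):
        project(model, alien)


# ---------------------------------------------------------------------------
# label transfer
# ---------------------------------------------------------------------------

def _toy_model(ref_points, labels):
    ref = np.asarray(ref_points, dtype=float)
    return ClusterModel(
        hvg=np.array(["id0"], dtype=object),
        gene_means=np.zeros(1),
        gene_sds=np.ones(1),
        loadings=np.ones((1, ref.shape[1])) / np.sqrt(ref.shape[1]),
        reference_embedding=ref,
        reference_labels=np.asarray(labels, dtype=int),
        reference_bin_ids=np.array([f"b{i}" for i in range(len(ref))], dtype=object),
    )


def test_transfer_exact_match_k1():
    model = _toy_model([[0.0], [10.0]], [3, 7])
    assert transfer_labels(model, [[10.0]], k=1).tolist() == [7]


def test_transfer_tie_breaks_to_nearest():
    model = _toy_model([[0.0], [2.000001]], [0, 1])
    # query slightly nearer ref 0: one vote each at k=2 -> nearest wins
    assert transfer_labels(model, [[1.0]], k=2).tolist() == [0]


def test_transfer_majority_wins():
    model = _toy_model([[0.0], [0.2], [0.4], [5.0]], [1, 1, 1, 2])
    assert transfer_labels(model, [[4.0]], k=4).tolist() == [1]


def test_transfer_validates_inputs():
    model = _toy_model([[0.0], [1.0]], [0, 1])
    with pytest.raises(ValueError, match="k must"):
        transfer_labels(model, [[0.0]], k=3)
    with pytest.raises(ValueError, match="non-empty"):
        transfer_labels(model, np.empty((0, 1)), k=1)


# ---------------------------------------------------------------------------
# model persistence and the fine-track workflow
# ---------------------------------------------------------------------------

def test_model_json_round_trip(tmp_path):
    binned, _ = three_blob_bins(seed=8)
    model = fit_reference(binned, n_pcs=5, seed=0)
    model.to_json(tmp_path / "model.json")
    again = ClusterModel.from_json(tmp_path / "model.json")
    assert np.array_equal(again.hvg, model.hvg)
    assert np.allclose(again.loadings, model.loadings)
    assert np.array_equal(again.reference_labels, model.reference_labels)


def test_two_track_labels_consistent_on_toy_domains():
    """Fine sliding-window bins inherit the coarse track's domain labels."""
    binned, truth = three_blob_bins(seed=9)
    model = fit_reference(binned, n_pcs=5, seed=0)
    # rebuild the underlying matrix for the fine track
    rng = np.random.default_rng(10)
    coords, counts = [], []
    for d in range(3):
        for i in range(80):
            coords.append((d * 200.0 + rng.uniform(0, 100), rng.uniform(0, 100)))
            row = rng.poisson(0.5, 9)
            row[d * 3:(d + 1) * 3] += rng.poisson(20.0, 3)
            counts.append(row)
    m = make_matrix(coords, counts)
    fine = sliding_window_bin(m, BinSpec(10.0, 5.0, anchor=(0.0, 0.0)))
    labels = transfer_labels(model, project(model, fine), k=5)
    fine_truth = (fine.centers[:, 0] // 200).astype(int)
    from sklearn.metrics import adjusted_rand_score

    assert adjusted_rand_score(fine_truth, labels) > 0.95
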