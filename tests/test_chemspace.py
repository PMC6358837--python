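"""Scaling, subsampling, PCA, t-SNE and neighbor lookup."""

import numpy as np
import pandas as pd
import pytest

from npprofiler import (
    minmax_scale,
    neighbor_report,
    pca,
    property_table,
    subsample,
    tsne_embed,
)
from npprofiler.fingerprints import FingerprintSet
from npprofiler.synthetic import LibrarySpec, generate_library

from conftest import make_library


# --- subsample --------------------------------------------------------------

def test_full_fraction_keeps_membership(synth_library):
    library, _ = synth_library
    sub = subsample(library, fraction=1.0, seed=0)
    assert sub.ids == library.ids


def test_count_one_is_deterministic(synth_library):
    library, _ = synth_library
    picks = {subsample(library, count=1, seed=4).ids[0] for _ in range(5)}
    assert len(picks) == 1


def test_fraction_floor_rounding(synth_library):
    library, _ = synth_library
    n = len(library)
    sub = subsample(library, fraction=0.4, seed=0)
    assert len(sub) == int(np.floor(0.4 * n))


def test_oversized_count_raises(synth_library):
    library, _ = synth_library
    with pytest.raises(ValueError):
        subsample(library, count=len(library) + 1)


def test_same_seed_same_sample(synth_library):
    library, _ = synth_library
    a = subsample(library, fraction=0.5, seed=123)
    b = subsample(library, fraction=0.5, seed=123)
    assert a.ids == b.ids


# --- minmax scaling ---------------------------------------------------------

def _table(values, cols=("MW",), lib="L"):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    if arr.shape[0] == 1 and len(cols) == 1:
        arr = arr.T
    return {lib: pd.DataFrame(arr, columns=list(cols))}


def test_simple_column_scaling():
    scaled = minmax_scale(_table([0.0, 5.0, 10.0]))
    assert np.allclose(scaled.frame["MW"], [0, 0.5, 1])
    assert scaled.bounds["MW"] == (0.0, 10.0)


def test_scaling_is_idempotent_on_scaled_table():
    scaled = minmax_scale(_table([0.0, 5.0, 10.0]))
    again = minmax_scale({"L": scaled.frame.droplevel("library")})
    assert np.allclose(scaled.frame.to_numpy(), again.frame.to_numpy())


def test_constant_column_maps_to_half():
    scaled = minmax_scale(_table([7.0, 7.0, 7.0]))
    assert np.allclose(scaled.frame["MW"], 0.5)


def test_union_scope_shares_bounds():
    tables = {
        "A": pd.DataFrame({"MW": [0.0, 10.0]}),
        "B": pd.DataFrame({"MW": [5.0, 20.0]}),
    }
    scaled = minmax_scale(tables, scope="union")
    assert scaled.bounds["MW"] == (0.0, 20.0)
    assert np.allclose(scaled.library("B")["MW"], [0.25, 1.0])


def test_scaling_is_monotone(synth_library):
    library, _ = synth_library
    table = property_table(library)
    scaled = minmax_scale({"L": table}).frame
    for col in table.columns:
        order_raw = np.argsort(table[col].to_numpy(), kind="stable")
        order_scaled = np.argsort(scaled[col].to_numpy(), kind="stable")
        assert np.array_equal(order_raw, order_scaled)
    assert ((scaled >= 0) & (scaled <= 1)).all().all()


# --- PCA --------------------------------------------------------------------

def test_collinear_data_one_component():
    x = np.linspace(0, 1, 10)
    frame = pd.DataFrame({"a": x, "b": 2 * x})
    result = pca(frame, k=2)
    assert result.explained_variance[0] == pytest.approx(1.0)


def test_isotropic_square_splits_evenly():
    frame = pd.DataFrame({"a": [0, 0, 1, 1], "b": [0, 1, 0, 1]})
    result = pca(frame, k=2)
    assert np.allclose(result.explained_variance, [0.5, 0.5])


def test_k_exceeding_columns_raises():
    frame = pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 0.0]})
    with pytest.raises(ValueError):
        pca(frame, k=3)


def test_reconstruction_with_all_components(synth_library):
    library, _ = synth_library
    scaled = minmax_scale({"L": property_table(library)})
    result = pca(scaled, k=6)
    X = scaled.frame.to_numpy()
    centered = X - X.mean(axis=0)
    reconstructed = result.scores() @ result.loadings.to_numpy().T
    assert np.max(np.abs(reconstructed - centered)) < 1e-8
    assert result.explained_variance.sum() == pytest.approx(1.0)
    assert np.all(np.diff(result.explained_variance) <= 1e-12)
    # loadings columns orthonormal
    L = result.loadings.to_numpy()
    assert np.allclose(L.T @ L, np.eye(6), atol=1e-10)


def test_pca_matches_eigendecomposition_oracle(synth_library):
    library, _ = synth_library
    scaled = minmax_scale({"L": property_table(library)})
    X = scaled.frame.to_numpy()
    C = np.cov(X, rowvar=False)
    eigvals = np.linalg.eigvalsh(C)[::-1]
    result = pca(scaled, k=6)
    assert np.allclose(
        result.explained_variance, eigvals / eigvals.sum(), atol=1e-10
    )


def test_pca_sign_convention():
    rng = np.random.default_rng(0)
    frame = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
    result = pca(frame, k=4)
    L = result.loadings.to_numpy()
    for i in range(4):
        assert L[np.argmax(np.abs(L[:, i])), i] > 0


# --- t-SNE ------------------------------------------------------------------

@pytest.fixture(scope="module")
def fps_150():
    spec = LibrarySpec(
        name="tsne",
        scaffold_templates=(
            "c1cc([*:1])ccc1[*:2]",
            "[*:1]C1CC(c2ccc([*:2])cc2)Oc2ccccc21",
        ),
        counts=(75, 75),
        n_acyclic=0,
        seed=23,
    )
    library, truth = generate_library(spec)
    return FingerprintSet.from_library(library), truth


def test_tsne_cardinality_and_determinism(fps_150):
    fps, _ = fps_150
    e1 = tsne_embed(fps, perplexity=10, seed=7, n_iter=300)
    e2 = tsne_embed(fps, perplexity=10, seed=7, n_iter=300)
    assert len(e1.coordinates) == len(fps)
    assert np.array_equal(e1.scores(), e2.scores())
    assert np.isfinite(e1.params["kl_divergence"])


def test_tsne_too_few_rows_raises():
    fps = FingerprintSet.from_library(make_library(["CCO", "CCN", "CCC"]))
    with pytest.raises(ValueError):
        tsne_embed(fps, perplexity=30)


def test_tsne_duplicates_embed_close(fps_150):
    fps, _ = fps_150
    matrix = np.vstack([fps.matrix, fps.matrix[0:1]])  # duplicate row 0
    ids = fps.ids + ["dup"]
    emb = tsne_embed(matrix, perplexity=10, seed=1, n_iter=500, ids=ids)
    pts = emb.scores()
    from scipy.spatial.distance import pdist, squareform
    D = squareform(pdist(pts))
    dup_dist = D[0, -1]
    assert dup_dist <= np.percentile(D[np.triu_indices(len(pts), k=1)], 1)


def test_tsne_tanimoto_metric_mode(fps_150):
    fps, _ = fps_150
    emb = tsne_embed(fps, perplexity=10, seed=2, n_iter=300, metric="tanimoto")
    assert emb.coordinates.shape == (len(fps), 2)
    assert emb.params["metric"] == "tanimoto"


# --- neighbor report --------------------------------------------------------

def test_neighbor_rank_one_for_duplicate(fps_150):
    fps, _ = fps_150
    matrix = np.vstack([fps.matrix, fps.matrix[0:1]])
    ids = fps.ids + ["dup"]
    emb = tsne_embed(matrix, perplexity=10, seed=1, n_iter=500, ids=ids)
    fps_map = {i: m for i, m in zip(ids, matrix)}
    rep = neighbor_report(emb, ["dup"], fps.ids, fingerprints=fps_map, k=1)
    assert rep.iloc[0]["reference"] == fps.ids[0]
    assert rep.iloc[0]["tanimoto"] == 1.0


def test_neighbor_k_larger_than_reference_set(fps_150):
    fps, _ = fps_150
    emb = tsne_embed(fps, perplexity=10, seed=7, n_iter=300)
    refs = fps.ids[:3]
    rep = neighbor_report(emb, [fps.ids[10]], refs, k=10)
    assert len(rep) == 3
    assert list(rep["rank"]) == [1, 2, 3]
    assert rep["distance"].is_monotonic_increasing


def test_neighbor_unknown_id_raises(fps_150):
    fps, _ = fps_150
    emb = tsne_embed(fps, perplexity=10, seed=7, n_iter=300)
    with pytest.raises(KeyError):
        neighbor_report(emb, ["nope"], fps.ids)


def test_cluster_queries_find_own_cluster(fps_150):
    fps, truth = fps_150
    emb = tsne_embed(fps, perplexity=10, seed=7, n_iter=500)
    labels = dict(zip(fps.ids, truth["labels"]))
    queries = fps.ids[::15]
    correct = 0
    for q in queries:
        refs = [i for i in fps.ids if i != q]
        rep = neighbor_report(emb, [q], refs, k=1)
        correct += labels[rep.iloc[0]["reference"]] == labels[q]
    assert correct == len(queries)
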