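"""Chemical-space embedding: scaling, PCA, t-SNE and neighbor lookup.

Property-based maps use the six physicochemical descriptors min-max scaled to
[0, 1] (per column, over the union of all compared libraries by default so
every set lives in one shared space) followed by PCA. Fingerprint-based maps
use a t-SNE embedding of the 166-bit key vectors, either as raw 0/1
coordinates under the Euclidean metric or through a precomputed 1 - Tanimoto
distance matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .fingerprints import FingerprintSet
from .records import CuratedLibrary


def subsample(
    library: CuratedLibrary,
    fraction: Optional[float] = None,
    count: Optional[int] = None,
    seed: int = 0,
) -> CuratedLibrary:
    """Uniform random sub-library without replacement, reproducible per seed.

    Exactly one of ``fraction`` (0 < f <= 1, size = floor(f * n)) or
    ``count`` must be given. Selection order follows the original library
    order. Uses numpy's seeded PCG64 generator, stable across platforms.
    """
    n = len(library)
    if (fraction is None) == (count is None):
        raise ValueError("give exactly one of fraction or count")
    if fraction is not None:
        if not 0 < fraction <= 1:
            raise ValueError(f"fraction must be in (0, 1], got {fraction}")
        count = int(np.floor(fraction * n))
    if count > n:
        raise ValueError(f"requested {count} records from a library of {n}")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=count, replace=False))
    records = [library.records[i] for i in keep]
    return CuratedLibrary(
        name=library.name,
        records=records,
        provenance={r.id: library.provenance.get(r.id, []) for r in records},
    )


@dataclass
class ScaledPropertyTable:
    """Property tables scaled column-wise to [0, 1], with recorded bounds.

    Rows are keyed by (library, id). ``bounds`` maps column -> (min, max) of
    the raw data in the chosen scope; applying the bounds to the raw values
    reproduces the table. A constant column maps to 0.5 everywhere.
    """

    frame: pd.DataFrame  # MultiIndex (library, id), columns = properties
    bounds: dict[str, tuple[float, float]]
    scope: str = "union"

    def library(self, name: str) -> pd.DataFrame:
        return self.frame.xs(name, level="library")


def minmax_scale(
    tables: dict[str, pd.DataFrame],
    scope: str = "union",
) -> ScaledPropertyTable:
    """Linear min-max transform of property tables from one or more libraries.

    scope="union" (default) shares one min/max per column across all
    libraries so values are comparable between sets; scope="per-library"
    scales each library by its own bounds (not cross-comparable).
    """
    if scope not in ("union", "per-library"):
        raise ValueError(f"unknown scope {scope!r}")
    if not tables or all(len(t) == 0 for t in tables.values()):
        raise ValueError("need at least one row to scale")

    stacked = pd.concat(
        tables.values(), keys=tables.keys(), names=["library", "id"]
    ).astype(float)

    def _scale(df: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
        lo, hi = df.min(axis=0), df.max(axis=0)
        span = hi - lo
        out = (df - lo) / span.replace(0.0, np.nan)
        out = out.fillna(0.5)  # constant column -> midpoint
        return out, {c: (float(lo[c]), float(hi[c])) for c in df.columns}

    if scope == "union":
        scaled, bounds = _scale(stacked)
    else:
        parts, bounds = [], {}
        for lib in tables:
            part, b = _scale(stacked.xs(lib, level="library", drop_level=False))
            parts.append(part)
            bounds[lib] = b
        scaled = pd.concat(parts)
    return ScaledPropertyTable(frame=scaled, bounds=bounds, scope=scope)


@dataclass
class EmbeddingResult:
    """Coordinates of a 2-D/3-D chemical-space projection plus method details."""

    method: str  # "PCA" | "TSNE"
    coordinates: pd.DataFrame  # index like the input rows; columns PC1.. / tsne1..
    loadings: Optional[pd.DataFrame] = None  # PCA: columns per component
    explained_variance: Optional[np.ndarray] = None  # fractions per component
    params: dict = field(default_factory=dict)

    def scores(self) -> np.ndarray:
        return self.coordinates.to_numpy()


def pca(scaled: Union[ScaledPropertyTable, pd.DataFrame], k: int = 2) -> EmbeddingResult:
    """Principal component analysis of a scaled property table.

    Components are eigenvectors of the column-centered covariance matrix,
    ordered by decreasing eigenvalue; scores are the centered data projected
    on them. Sign convention: each component's largest-magnitude loading is
    positive. Explained-variance fractions are relative to the total
    variance, so over all components they sum to 1.
    """
    from sklearn.decomposition import PCA

    frame = scaled.frame if isinstance(scaled, ScaledPropertyTable) else scaled
    X = frame.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 rows")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds the {X.shape[1]} columns")
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    components = model.components_  # (k, p), rows orthonormal
    # fix signs so the largest-|loading| entry of each component is positive
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1.0
            scores[:, i] *= -1.0
    pc_names = [f"PC{i + 1}" for i in range(k)]
    coords = pd.DataFrame(scores, index=frame.index, columns=pc_names)
    loadings = pd.DataFrame(components.T, index=frame.columns, columns=pc_names)
    return EmbeddingResult(
        method="PCA",
        coordinates=coords,
        loadings=loadings,
        explained_variance=model.explained_variance_ratio_.copy(),
        params={"k": k, "mean": model.mean_.tolist()},
    )


def tanimoto_distance_matrix(matrix: np.ndarray) -> np.ndarray:
    """Dense (m, m) matrix of 1 - Tanimoto over rows of a boolean matrix."""
    M = np.asarray(matrix, dtype=np.float64)
    c = M @ M.T
    on = M.sum(axis=1)
    denom = on[:, None] + on[None, :] - c
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(denom > 0, c / denom, 1.0)
    return 1.0 - sim


def tsne_embed(
    fps: Union[FingerprintSet, np.ndarray],
    perplexity: float = 30.0,
    seed: int = 0,
    n_iter: int = 1000,
    metric: str = "euclidean",
    ids: Optional[Sequence] = None,
) -> EmbeddingResult:
    """2-D t-SNE of fingerprint vectors (delegates to scikit-learn).

    metric="euclidean" treats the 166 bits as 0/1 coordinates;
    metric="tanimoto" embeds a precomputed 1 - Tanimoto distance matrix.
    Deterministic for a fixed seed. Requires at least ``3 * perplexity`` rows.
    """
    from sklearn.manifold import TSNE

    if isinstance(fps, FingerprintSet):
        X = fps.matrix.astype(np.float64)
        index = pd.Index(fps.ids, name="id")
    else:
        X = np.asarray(fps, dtype=np.float64)
        id_list = list(ids) if ids is not None else list(range(len(X)))
        if id_list and isinstance(id_list[0], tuple):
            index = pd.MultiIndex.from_tuples(id_list, names=["library", "id"])
        else:
            index = pd.Index(id_list, name="id")
    n = X.shape[0]
    if n < 3 * perplexity:
        raise ValueError(
            f"t-SNE needs >= 3 * perplexity = {3 * perplexity:.0f} rows, got {n}"
        )
    if metric == "tanimoto":
        D = tanimoto_distance_matrix(X)
        model = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=seed,
            max_iter=n_iter,
            metric="precomputed",
            init="random",
        )
        coords = model.fit_transform(D)
    elif metric == "euclidean":
        model = TSNE(
            n_components=2,
            perplexity=perplexity,
            random_state=seed,
            max_iter=n_iter,
            metric="euclidean",
            init="pca",
        )
        coords = model.fit_transform(X)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    frame = pd.DataFrame(coords, index=index, columns=["tsne1", "tsne2"])
    return EmbeddingResult(
        method="TSNE",
        coordinates=frame,
        params={
            "perplexity": perplexity,
            "seed": seed,
            "n_iter": n_iter,
            "metric": metric,
            "kl_divergence": float(model.kl_divergence_),
            "engine": "sklearn.manifold.TSNE",
        },
    )


def neighbor_report(
    embedding: EmbeddingResult,
    query_ids: Sequence,
    reference_ids: Sequence,
    fingerprints: Optional[dict] = None,
    k: int = 1,
) -> pd.DataFrame:
    """Nearest reference points (embedded Euclidean distance) per query.

    Returns one row per (query, rank) with the reference id, embedded
    distance, and — when ``fingerprints`` maps id -> bit vector — the
    Tanimoto similarity in the original fingerprint space.
    """
    from .fingerprints import tanimoto as _tanimoto

    coords = embedding.coordinates
    missing = [q for q in list(query_ids) + list(reference_ids) if q not in coords.index]
    if missing:
        raise KeyError(f"ids not in embedding: {missing[:5]}")
    Q = coords.loc[list(query_ids)].to_numpy()
    R = coords.loc[list(reference_ids)].to_numpy()
    from scipy.spatial.distance import cdist

    D = cdist(Q, R)
    k_eff = min(k, len(reference_ids))
    rows = []
    for qi, qid in enumerate(query_ids):
        order = np.argsort(D[qi], kind="stable")[:k_eff]
        for rank, ri in enumerate(order, start=1):
            rid = list(reference_ids)[ri]
            row = {
                "query": qid,
                "rank": rank,
                "reference": rid,
                "distance": float(D[qi, ri]),
            }
            if fingerprints is not None:
                row["tanimoto"] = _tanimoto(fingerprints[qid], fingerprints[rid])
            rows.append(row)
    return pd.DataFrame(rows)


def plot_embedding(
    embedding: EmbeddingResult,
    path: Optional[str] = None,
    color_by_level: str = "library",
):
    """Scatter plot of a 2-D embedding, colored by library when the index
    carries a library level. Writes SVG when ``path`` is given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coords = embedding.coordinates
    fig, ax = plt.subplots(figsize=(7, 6))
    cols = coords.columns[:2]
    if isinstance(coords.index, pd.MultiIndex) and color_by_level in coords.index.names:
        for lib, sub in coords.groupby(level=color_by_level):
            ax.scatter(sub[cols[0]], sub[cols[1]], s=12, alpha=0.7, label=str(lib))
        ax.legend(fontsize=8)
    else:
        ax.scatter(coords[cols[0]], coords[cols[1]], s=12, alpha=0.7)
    ax.set_xlabel(cols[0])
    ax.set_ylabel(cols[1])
    ax.set_title(f"{embedding.method} chemical space")
    fig.tight_layout()
    if path:
        fig.savefig(path, format="svg")
        plt.close(fig)
    return fig
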