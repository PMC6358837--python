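"""Consensus Diversity (CD) plots.

A CD plot compares whole libraries on one chart using four structural
representations at once:

- x-axis: median pairwise Tanimoto of the 166-bit structural keys
  (lower = larger fingerprint diversity);
- y-axis: area under the cyclic-system recovery curve
  (lower = higher scaffold diversity);
- color: whole-molecule property diversity, the mean (or median) pairwise
  Euclidean distance between the min-max-scaled six-property vectors
  (light = more diverse, dark = less);
- point size: number of compounds, area-proportional.

Neither axis statistic is re-scaled or inverted: the raw median Tanimoto and
raw AUC are plotted, so the lower-left quadrant holds the libraries that are
diverse by both criteria.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .chemspace import ScaledPropertyTable
from .fingerprints import FingerprintSet, pairwise_similarity_stats
from .scaffolds import ScaffoldProfile

DEFAULT_MAX_PAIRS = 2_000_000

METADATA = {
    "x": "median pairwise Tanimoto, MACCS 166-bit keys (raw, unreversed)",
    "y": "scaffold recovery-curve AUC (raw, unreversed)",
    "color": "pairwise Euclidean distance of union-scaled properties",
    "size": "compound count, area-proportional",
}


def property_diversity(
    scaled_rows: pd.DataFrame,
    statistic: str = "mean",
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> float:
    """Mean (or median) pairwise Euclidean distance between a library's
    scaled property vectors.

    The table must have been scaled with union scope across all compared
    libraries for the values to be comparable between sets. Exhaustive up to
    ``max_pairs`` pairs, then a seeded uniform pair sample.
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"unknown statistic {statistic!r}")
    X = np.asarray(scaled_rows, dtype=float)
    m = X.shape[0]
    if m < 2:
        raise ValueError("property diversity needs at least 2 rows")
    total_pairs = m * (m - 1) // 2
    if total_pairs <= max_pairs:
        from scipy.spatial.distance import pdist

        d = pdist(X)
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, m, size=max_pairs)
        j = rng.integers(0, m - 1, size=max_pairs)
        j = np.where(j >= i, j + 1, j)  # exclude self-pairs
        d = np.linalg.norm(X[i] - X[j], axis=1)
    return float(np.mean(d) if statistic == "mean" else np.median(d))


@dataclass
class CDPoint:
    """One library's coordinates on a consensus diversity plot."""

    library_name: str
    median_tanimoto: float
    scaffold_auc: float
    property_diversity: float
    n_compounds: int

    def as_dict(self) -> dict:
        return {
            "library": self.library_name,
            "median_tanimoto": self.median_tanimoto,
            "scaffold_auc": self.scaffold_auc,
            "property_diversity": self.property_diversity,
            "n_compounds": self.n_compounds,
        }


def cd_point(
    fingerprints: FingerprintSet,
    profile: ScaffoldProfile,
    scaled_rows: pd.DataFrame,
    statistic: str = "mean",
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
) -> CDPoint:
    """Bundle the three diversity statistics plus size for one library.

    The statistics themselves are passed through unmodified — no re-scaling.
    """
    sim = pairwise_similarity_stats(fingerprints, max_pairs=max_pairs, seed=seed)
    return CDPoint(
        library_name=fingerprints.library_name,
        median_tanimoto=sim.median,
        scaffold_auc=profile.auc,
        property_diversity=property_diversity(
            scaled_rows, statistic=statistic, max_pairs=max_pairs, seed=seed
        ),
        n_compounds=len(fingerprints),
    )


@dataclass
class CDPlotData:
    """Plot-ready CD data: points, quadrant thresholds and scale bounds."""

    points: list[CDPoint]
    x_threshold: Optional[float]
    y_threshold: Optional[float]
    color_bounds: tuple[float, float]
    size_bounds: tuple[int, int]
    quadrants: dict[str, str] = field(default_factory=dict)
    metadata: dict = field(default_factory=lambda: dict(METADATA))

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame([p.as_dict() for p in self.points])
        df["quadrant"] = [self.quadrants.get(p.library_name, "") for p in self.points]
        return df


def _quadrant(x: float, y: float, xt: float, yt: float) -> str:
    fp = "high fingerprint diversity" if x <= xt else "low fingerprint diversity"
    sc = "high scaffold diversity" if y <= yt else "low scaffold diversity"
    return f"{fp}, {sc}"


def cd_plot(
    points: list[CDPoint],
    x_threshold: Optional[float] = None,
    y_threshold: Optional[float] = None,
    path: Optional[str] = None,
) -> CDPlotData:
    """Assemble CD plot data and optionally render the SVG chart.

    Thresholds default to the median of each axis across the compared
    libraries (reference lines); with fewer than 2 points quadrants are
    undefined and a warning is issued.
    """
    if not points:
        raise ValueError("need at least one CD point")
    xs = np.array([p.median_tanimoto for p in points])
    ys = np.array([p.scaffold_auc for p in points])
    divs = np.array([p.property_diversity for p in points])
    sizes = np.array([p.n_compounds for p in points])

    quadrants: dict[str, str] = {}
    if len(points) >= 2:
        xt = float(np.median(xs)) if x_threshold is None else float(x_threshold)
        yt = float(np.median(ys)) if y_threshold is None else float(y_threshold)
        for p in points:
            quadrants[p.library_name] = _quadrant(
                p.median_tanimoto, p.scaffold_auc, xt, yt
            )
    else:
        warnings.warn(
            "quadrant thresholds need at least 2 libraries; point placed unclassified",
            stacklevel=2,
        )
        xt = yt = None

    data = CDPlotData(
        points=list(points),
        x_threshold=xt,
        y_threshold=yt,
        color_bounds=(float(divs.min()), float(divs.max())),
        size_bounds=(int(sizes.min()), int(sizes.max())),
        quadrants=quadrants,
    )
    if path:
        _render(data, path)
    return data


def _render(data: CDPlotData, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [p.median_tanimoto for p in data.points]
    ys = [p.scaffold_auc for p in data.points]
    divs = [p.property_diversity for p in data.points]
    # marker area proportional to set size
    sizes = [60.0 + 940.0 * p.n_compounds / max(1, data.size_bounds[1]) for p in data.points]

    fig, ax = plt.subplots(figsize=(7, 6))
    lo, hi = data.color_bounds
    sc = ax.scatter(
        xs, ys, s=sizes, c=divs,
        cmap="Blues_r",  # dark = low diversity, light = high
        vmin=lo, vmax=hi if hi > lo else lo + 1e-9,
        edgecolors="black", linewidths=0.5,
    )
    for p in data.points:
        ax.annotate(p.library_name, (p.median_tanimoto, p.scaffold_auc),
                    fontsize=8, xytext=(4, 4), textcoords="offset points")
    if data.x_threshold is not None:
        ax.axvline(data.x_threshold, color="gray", ls="--", lw=0.8)
        ax.axhline(data.y_threshold, color="gray", ls="--", lw=0.8)
    fig.colorbar(sc, ax=ax, label="property diversity (scaled-distance)")
    ax.set_xlabel("median Tanimoto (MACCS) — lower = more diverse")
    ax.set_ylabel("scaffold recovery AUC — lower = more diverse")
    ax.set_title("Consensus Diversity plot")
    fig.tight_layout()
    fig.savefig(path, format="svg")
    plt.close(fig)
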