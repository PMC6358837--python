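"""166-bit structural-key fingerprints and Tanimoto similarity statistics.

Each molecule is encoded as the classic 166-key substructure dictionary
(MACCS keys). The RDKit implementation emits 167 bits with bit 0 always
unset; positions 1..166 are exposed here as a length-166 boolean vector,
which :data:`ENGINE_METADATA` records.

Library fingerprint diversity is summarized by the distribution of pairwise
Tanimoto coefficients; its median is the x-axis of a consensus diversity
plot (lower median = larger fingerprint diversity).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from .records import CuratedLibrary

N_BITS = 166

#: Exhaustive-enumeration cap; above this many pairs a seeded uniform sample
#: of pairs is used and the result is flagged ``sampled``.
DEFAULT_MAX_PAIRS = 2_000_000

ENGINE_METADATA = {
    "fingerprint": "MACCS structural keys, 166 bits (rdkit MACCSkeys, bit 0 dropped)",
    "similarity": "Tanimoto c/(a+b-c); all-zero pair defined as 1.0",
}


def structural_keys(smiles: str, record_id: str = "?") -> np.ndarray:
    """166-position boolean key vector for one curated structure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"record {record_id}: cannot parse SMILES {smiles!r}")
    bv = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(N_BITS, dtype=bool)
    for bit in bv.GetOnBits():
        if bit >= 1:
            arr[bit - 1] = True
    return arr


@dataclass
class FingerprintSet:
    """Fingerprints for one library: an (m, 166) boolean matrix keyed by id."""

    library_name: str
    ids: list[str]
    matrix: np.ndarray  # (m, N_BITS) bool

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_library(cls, library: CuratedLibrary) -> "FingerprintSet":
        mats = [structural_keys(r.smiles, r.id) for r in library.records]
        matrix = (
            np.vstack(mats) if mats else np.zeros((0, N_BITS), dtype=bool)
        )
        return cls(library_name=library.name, ids=library.ids, matrix=matrix)

    def to_hex(self) -> list[str]:
        return [np.packbits(row).tobytes().hex() for row in self.matrix]


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto coefficient c/(a1 + b1 - c) between two equal-length bit
    vectors. The all-zero pair is defined as 1.0 (identical emptiness, avoids
    0/0) with a warning.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    c = int(np.count_nonzero(a & b))
    denom = int(np.count_nonzero(a)) + int(np.count_nonzero(b)) - c
    if denom == 0:
        warnings.warn("Tanimoto of two all-zero vectors defined as 1.0", stacklevel=2)
        return 1.0
    return c / denom


@dataclass
class SimilarityStats:
    """Summary of the pairwise Tanimoto distribution of one library."""

    n_pairs: int
    median: float
    mean: float
    min: float
    max: float
    histogram: Optional[tuple[np.ndarray, np.ndarray]] = None  # (edges, counts)
    sampled: bool = False
    seed: Optional[int] = None
    metadata: dict = field(default_factory=lambda: dict(ENGINE_METADATA))

    def as_dict(self) -> dict:
        d = {
            "n_pairs": self.n_pairs,
            "median": self.median,
            "mean": self.mean,
            "min": self.min,
            "max": self.max,
            "sampled": self.sampled,
            "seed": self.seed,
            "metadata": self.metadata,
        }
        if self.histogram is not None:
            edges, counts = self.histogram
            d["histogram"] = {
                "bin_edges": [float(e) for e in edges],
                "counts": [int(c) for c in counts],
            }
        return d


def _pair_similarities(matrix: np.ndarray, pairs: np.ndarray) -> np.ndarray:
    a = matrix[pairs[:, 0]]
    b = matrix[pairs[:, 1]]
    c = np.count_nonzero(a & b, axis=1).astype(float)
    denom = (
        np.count_nonzero(a, axis=1) + np.count_nonzero(b, axis=1) - c
    ).astype(float)
    sims = np.ones_like(c)
    np.divide(c, denom, where=denom > 0, out=sims)
    return sims


def pairwise_similarity_stats(
    fps: FingerprintSet,
    max_pairs: int = DEFAULT_MAX_PAIRS,
    seed: int = 0,
    histogram_bins: Optional[int] = None,
) -> SimilarityStats:
    """Summary statistics of the pairwise Tanimoto distribution.

    Exhaustive over all m(m-1)/2 unordered pairs when that count does not
    exceed ``max_pairs``; otherwise ``max_pairs`` pairs are drawn uniformly
    (with replacement over the pair index space, seeded) and the result is
    flagged ``sampled``.
    """
    m = len(fps)
    if m < 2:
        raise ValueError("need at least 2 fingerprints for pairwise statistics")
    total_pairs = m * (m - 1) // 2
    sampled = total_pairs > max_pairs
    if not sampled:
        iu = np.triu_indices(m, k=1)
        pairs = np.column_stack(iu)
    else:
        rng = np.random.default_rng(seed)
        flat = rng.integers(0, total_pairs, size=max_pairs, dtype=np.int64)
        # map flat upper-triangle index -> (i, j), vectorized
        i = (
            m - 2
            - np.floor(
                np.sqrt(-8.0 * flat + 4.0 * m * (m - 1) - 7.0) / 2.0 - 0.5
            )
        ).astype(np.int64)
        j = (flat + i + 1 - (i * (2 * m - i - 1)) // 2).astype(np.int64)
        pairs = np.column_stack([i, j])
    sims = _pair_similarities(fps.matrix, pairs)
    hist = None
    if histogram_bins:
        counts, edges = np.histogram(sims, bins=histogram_bins, range=(0.0, 1.0))
        hist = (edges, counts)
    return SimilarityStats(
        n_pairs=int(len(pairs)),
        median=float(np.median(sims)),
        mean=float(sims.mean()),
        min=float(sims.min()),
        max=float(sims.max()),
        histogram=hist,
        sampled=sampled,
        seed=seed if sampled else None,
    )
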