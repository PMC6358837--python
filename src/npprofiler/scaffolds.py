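"""Bemis-Murcko scaffold diversity analysis.

A molecular framework (Bemis-Murcko scaffold) is what remains of a molecule
after iteratively pruning acyclic terminal substituents: all ring systems,
the linkers connecting them, and atoms multiple-bonded directly to those
(e.g. exocyclic carbonyl oxygens). Atom types and bond orders are kept —
frameworks, not carbon skeletons.

Scaffold diversity of a library is summarized by the cyclic-system recovery
curve: scaffolds are ranked by frequency and the cumulative fraction of
compounds (y) is plotted against the cumulative fraction of scaffolds (x).
The area under this curve (trapezoidal) is 0.5 when every scaffold occurs
equally often (maximal diversity) and approaches 1 when a few scaffolds
dominate; lower AUC = higher scaffold diversity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .records import CuratedLibrary

#: Sentinel scaffold for acyclic (ring-free) molecules.
EMPTY = ""


class DegenerateProfileWarning(UserWarning):
    """A recovery curve with a single scaffold carries no ranking signal."""


def murcko_scaffold(smiles: str) -> str:
    """Canonical SMILES of the molecular framework, or ``EMPTY`` if acyclic."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse SMILES {smiles!r}")
    if mol.GetRingInfo().NumRings() == 0:
        return EMPTY
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(scaffold)


@dataclass
class ScaffoldProfile:
    """Ranked scaffold frequencies plus the recovery curve for one library."""

    library_name: str
    table: list[tuple[str, int]]  # (canonical scaffold SMILES, count) desc
    n_compounds: int
    n_scaffolds: int
    n_acyclic: int
    curve: np.ndarray = field(default=None)  # (k+1, 2) points incl. (0,0)
    auc: float = float("nan")

    @property
    def counts(self) -> list[int]:
        return [c for _, c in self.table]


def scaffold_frequencies(library: CuratedLibrary) -> ScaffoldProfile:
    """Count molecular frameworks over a curated library.

    Acyclic molecules contribute to ``n_acyclic`` and are excluded from the
    scaffold table (no ring = no cyclic system). Ties in count are broken by
    lexicographic order of the canonical scaffold SMILES so the ranking is
    deterministic.
    """
    if len(library) == 0:
        raise ValueError("cannot profile an empty library")
    counts: dict[str, int] = {}
    n_acyclic = 0
    for rec in library.records:
        scaf = murcko_scaffold(rec.smiles)
        if scaf == EMPTY:
            n_acyclic += 1
        else:
            counts[scaf] = counts.get(scaf, 0) + 1
    table = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    profile = ScaffoldProfile(
        library_name=library.name,
        table=table,
        n_compounds=len(library),
        n_scaffolds=len(table),
        n_acyclic=n_acyclic,
    )
    if table:
        profile.curve = recovery_curve(profile)
        profile.auc = recovery_auc(profile.curve)
    return profile


def recovery_curve(profile: ScaffoldProfile) -> np.ndarray:
    """Cyclic-system recovery curve points, ``(0, 0)`` prepended.

    Point i (1-based) is ``(i / n, C_i / N')`` with ``C_i`` the cumulative
    count of the i most frequent scaffolds and ``N'`` the number of
    scaffold-bearing compounds. Sorted-descending counts make the curve
    concave and non-decreasing from (0,0) to (1,1).
    """
    counts = np.asarray(profile.counts, dtype=float)
    if counts.size == 0:
        raise ValueError("profile has no scaffolds")
    n = counts.size
    total = counts.sum()
    x = np.arange(0, n + 1) / n
    y = np.concatenate([[0.0], np.cumsum(counts) / total])
    return np.column_stack([x, y])


def recovery_auc(curve: np.ndarray) -> float:
    """Trapezoidal area under a recovery curve; in [0.5, 1].

    0.5 iff all scaffold counts are equal; lower values indicate higher
    scaffold diversity. A two-point curve (single scaffold) is degenerate and
    warned: its area is trivially 0.5 but carries no diversity signal.
    """
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[1] != 2 or curve.shape[0] < 2:
        raise ValueError("curve must be an (k, 2) array with k >= 2")
    if curve.shape[0] == 2:
        warnings.warn(
            "single-scaffold profile: recovery AUC is degenerate",
            DegenerateProfileWarning,
            stacklevel=2,
        )
    return float(np.trapezoid(curve[:, 1], curve[:, 0]))


def top_n_coverage(profile: ScaffoldProfile, n: int) -> float:
    """Fraction of ALL compounds (acyclic included) covered by the n most
    frequent scaffolds — comparable to published whole-database percentages.
    """
    if not 1 <= n <= profile.n_scaffolds:
        raise ValueError(
            f"n must be in [1, {profile.n_scaffolds}], got {n}"
        )
    covered = sum(c for _, c in profile.table[:n])
    return covered / profile.n_compounds


def scaffold_table_frame(profile: ScaffoldProfile):
    """Rank/SMILES/count/percent table as a DataFrame for CSV export."""
    import pandas as pd

    rows = [
        {
            "rank": i + 1,
            "scaffold": smi,
            "count": c,
            "percent": 100.0 * c / profile.n_compounds,
        }
        for i, (smi, c) in enumerate(profile.table)
    ]
    return pd.DataFrame(rows, columns=["rank", "scaffold", "count", "percent"])
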