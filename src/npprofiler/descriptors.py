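"""Physicochemical property profiling.

Six descriptors of pharmaceutical interest are computed per molecule:

- MW: molecular weight from average atomic masses (g/mol)
- SlogP: Wildman-Crippen atom-contribution octanol/water logP
- TPSA: topological polar surface area (Angstrom^2)
- RB: rotatable bonds (single non-ring bonds between non-terminal heavy
  atoms, amide C-N excluded)
- HBD: H-bond donors (heavy atoms bearing at least one O-H or N-H)
- HBA: H-bond acceptors (N and O atoms excluding pyrrole-type N and some
  amide/other patterns, per the RDKit Lipinski definition)

The donor/acceptor and rotatable-bond conventions are the RDKit ones and are
recorded in :data:`ENGINE_METADATA` so that outputs state which definitions
produced them — count descriptors can differ by one or two between engines.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .records import CuratedLibrary

PROPERTY_NAMES = ("MW", "SlogP", "TPSA", "RB", "HBD", "HBA")

ENGINE_METADATA = {
    "engine": "rdkit",
    "MW": "Descriptors.MolWt (average atomic masses)",
    "SlogP": "Crippen.MolLogP (Wildman-Crippen)",
    "TPSA": "rdMolDescriptors.CalcTPSA (Ertl)",
    "RB": "Lipinski.NumRotatableBonds (strict: amide C-N excluded)",
    "HBD": "Lipinski.NumHDonors",
    "HBA": "Lipinski.NumHAcceptors",
}


class DescriptorError(ValueError):
    """Raised when a structure cannot be profiled; names the record id."""


def compute_properties(smiles: str, record_id: str = "?") -> dict[str, float]:
    """Compute the six-property vector for one curated structure.

    Deterministic: any SMILES spelling of the same molecule yields the same
    vector (descriptors operate on the parsed graph).
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise DescriptorError(f"record {record_id}: cannot parse SMILES {smiles!r}")
    # re-parse from canonical SMILES so atom order (hence floating-point
    # summation order) is identical for every spelling of the same molecule
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))
    return {
        "MW": float(Descriptors.MolWt(mol)),
        "SlogP": float(Crippen.MolLogP(mol)),
        "TPSA": float(rdMolDescriptors.CalcTPSA(mol)),
        "RB": int(Lipinski.NumRotatableBonds(mol)),
        "HBD": int(Lipinski.NumHDonors(mol)),
        "HBA": int(Lipinski.NumHAcceptors(mol)),
    }


def property_table(library: CuratedLibrary) -> pd.DataFrame:
    """One property vector per record, indexed by record id."""
    rows = {}
    for rec in library.records:
        rows[rec.id] = compute_properties(rec.smiles, rec.id)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(PROPERTY_NAMES))
    df.index.name = "id"
    return df


@dataclass
class PropertySummary:
    """Box-plot statistics for one numeric column.

    Quartiles use linear interpolation; whiskers are Tukey fences
    (Q1 - 1.5 IQR, Q3 + 1.5 IQR) clipped to the most extreme data points
    inside them (the "adjacent values"); outliers fall outside the whiskers.
    """

    n: int
    min: float
    max: float
    mean: float
    median: float
    sd: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list[float]

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "n", "min", "max", "mean", "median", "sd", "q1", "q3",
            "whisker_low", "whisker_high")}
        d["outliers"] = list(self.outliers)
        return d


def summarize(values) -> PropertySummary:
    """Summary statistics for one property column (box-plot geometry).

    Raises on an empty column rather than returning silent zeros. The
    standard deviation is the sample SD (ddof=1) for n >= 2, else 0.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise ValueError("cannot summarize an empty column")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    outliers = arr[(arr < lo_fence) | (arr > hi_fence)]
    return PropertySummary(
        n=int(arr.size),
        min=float(arr.min()),
        max=float(arr.max()),
        mean=float(arr.mean()),
        median=float(med),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        q1=float(q1),
        q3=float(q3),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=[float(x) for x in np.sort(outliers)],
    )


def summarize_table(table: pd.DataFrame) -> dict[str, PropertySummary]:
    """Per-property summaries for a property table."""
    return {col: summarize(table[col].to_numpy()) for col in table.columns}


def plot_boxplots(
    tables: dict[str, pd.DataFrame],
    path: Optional[str] = None,
    kind: str = "box",
):
    """Box or violin plots of the six properties across libraries.

    ``tables`` maps library label -> property table. Returns the figure;
    writes SVG when ``path`` is given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(tables)
    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, prop in zip(axes.ravel(), PROPERTY_NAMES):
        data = [tables[lbl][prop].to_numpy(dtype=float) for lbl in labels]
        if kind == "violin":
            ax.violinplot(data, showmedians=True)
        else:
            ax.boxplot(data, sym="r*")
        ax.set_xticks(range(1, len(labels) + 1))
        ax.set_xticklabels(labels, rotation=45, ha="right", fontsize=7)
        ax.set_title(prop)
    fig.tight_layout()
    if path:
        fig.savefig(path, format="svg")
        plt.close(fig)
    return fig
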