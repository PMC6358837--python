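"""Synthetic natural-product-like libraries with known ground truth.

Libraries are built from scaffold templates (frameworks with explicit
attachment points) by decorating each template with acyclic substituents, so
the designed scaffold-frequency vector, the closed-form recovery AUC, and the
per-molecule generative labels are all known exactly. Every pipeline stage —
curation, properties, scaffold ranking, fingerprints, embeddings, CD plots —
can then be tested against construction-time truth with no external data.

Substituents attach through single bonds and never introduce rings, so the
Bemis-Murcko framework of every generated molecule is, by construction, its
template's framework.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from rdkit import Chem

from .records import CompoundRecord, CuratedLibrary
from .scaffolds import murcko_scaffold

#: Hydrogen "substituent": leaves the attachment point bare.
H_SUBSTITUENT = "[H]"

#: Natural-product-flavored framework templates with [*:n] attachment points.
DEFAULT_TEMPLATES = (
    "c1ccc([*:1])cc1",                          # benzene
    "[*:1]C1CC(c2ccccc2)Oc2ccccc21",            # flavan core
    "c1cc([*:1])cc2c1OCO2",                     # 1,3-benzodioxole
    "c1ccc(CCc2ccccc2[*:1])cc1",                # dibenzyl
    "O=c1cc([*:1])oc2ccccc12",                  # chromone
    "c1cc2ccccc2n1[*:1]",                       # indole
    "C1CCC2([*:1])CCCCC2C1",                    # decalin
    "O=C1OC([*:1])Cc2ccccc21",                  # isochroman-1-one
)

#: Higher-capacity templates (two attachment points where the chemistry
#: allows) for libraries needing many distinct molecules per scaffold.
TEMPLATE_POOL = (
    "c1cc([*:1])ccc1[*:2]",
    "[*:1]C1CC(c2ccc([*:2])cc2)Oc2ccccc21",
    "c1c([*:1])cc2c(c1[*:2])OCO2",
    "[*:2]c1ccc(CCc2ccccc2[*:1])cc1",
    "O=c1cc([*:1])oc2ccc([*:2])cc12",
    "c1cc2ccccc2n1[*:1]",
    "C1CCC2([*:1])CCCCC2C1",
    "O=C1OC([*:1])Cc2ccccc21",
    "O=C1C=CC(=O)N1[*:1]",
    "[*:1]C1CCCN1C",
)

#: Acyclic substituents: mixed small/large and polar/apolar so property
#: spread differentiates libraries without rejection sampling.
DEFAULT_SUBSTITUENTS = (
    H_SUBSTITUENT,
    "C", "CC", "CCC", "CCCC", "CCCCC", "C(C)C", "CC(C)C", "C(C)(C)C",
    "O", "OC", "OCC", "OCCC", "OC(C)C", "CO", "CCO", "CCCO", "C(C)O",
    "N", "NC", "N(C)C", "CN", "CCN", "CN(C)C", "NCC",
    "C=C", "C=CC", "CC=C",
    "C(=O)C", "C(=O)CC", "C(=O)OC", "C(=O)OCC", "C(=O)O", "CC(=O)O",
    "OC(=O)C", "NC(=O)C", "C(=O)N", "C(=O)NC",
    "F", "Cl", "Br", "I", "C(F)(F)F", "CCl", "CCF",
    "S", "SC", "SCC", "S(=O)(=O)C", "C#N", "CC#N",
    "OCO", "OCC(C)C", "CCCC(C)C", "CCOC", "CCCN",
)

DEFAULT_GENERA = {
    "Plantae": ("Salvia", "Ageratina", "Piper", "Croton", "Bursera", "Datura"),
    "Fungi": ("Aspergillus", "Penicillium", "Xylaria", "Malbranchea"),
    "Other": ("Apis",),
}

DEFAULT_JOURNALS = (
    "J. Nat. Prod.", "Phytochemistry", "Tetrahedron Lett.", "Planta Med.",
)


@dataclass
class LibrarySpec:
    """Recipe for one synthetic library.

    ``counts[i]`` molecules are built on ``scaffold_templates[i]``;
    ``n_acyclic`` ring-free molecules are appended. Metadata (year, kingdom,
    genus, species, journal) is drawn from the configured pools. Fully
    reproducible per ``seed``.
    """

    name: str = "synthetic"
    scaffold_templates: tuple[str, ...] = DEFAULT_TEMPLATES
    counts: tuple[int, ...] = (24, 12, 8, 6, 4, 3, 2, 1)
    substituent_vocabulary: tuple[str, ...] = DEFAULT_SUBSTITUENTS
    n_acyclic: int = 5
    year_range: tuple[int, int] = (2000, 2018)
    kingdom_weights: dict = field(
        default_factory=lambda: {"Plantae": 0.75, "Fungi": 0.23, "Other": 0.02}
    )
    genus_pools: dict = field(default_factory=lambda: dict(DEFAULT_GENERA))
    seed: int = 0

    def validate(self) -> None:
        if len(self.counts) != len(self.scaffold_templates):
            raise ValueError("counts length must match scaffold_templates length")
        if any(c <= 0 for c in self.counts):
            raise ValueError("counts must be positive")
        if self.n_acyclic < 0:
            raise ValueError("n_acyclic must be >= 0")
        for t in self.scaffold_templates:
            if _attachment_labels(t) == []:
                raise ValueError(f"template {t!r} has no attachment point")
        for s in self.substituent_vocabulary:
            if s == H_SUBSTITUENT:
                continue
            frag = Chem.MolFromSmiles("[*:1]" + s)
            if frag is None:
                raise ValueError(f"invalid substituent {s!r}")
            if frag.GetRingInfo().NumRings() > 0:
                raise ValueError(
                    f"substituent {s!r} contains a ring and would corrupt the scaffold"
                )


def _attachment_labels(template: str) -> list[int]:
    mol = Chem.MolFromSmiles(template)
    if mol is None:
        raise ValueError(f"invalid template {template!r}")
    return sorted(
        a.GetAtomMapNum()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 0 and a.GetAtomMapNum() > 0
    )


def template_framework(template: str) -> str:
    """The Bemis-Murcko framework a template designs for: the template with
    every attachment point reduced to hydrogen."""
    bare = decorate(
        template, {lab: H_SUBSTITUENT for lab in _attachment_labels(template)}
    )
    return murcko_scaffold(bare)


def decorate(template: str, assignment: dict[int, str]) -> str:
    """Attach one substituent per attachment label; returns canonical SMILES."""
    pieces = [template]
    for label, sub in assignment.items():
        pieces.append(f"[*:{label}]{sub}" if sub != H_SUBSTITUENT else f"[*:{label}][H]")
    combined = Chem.MolFromSmiles(".".join(pieces), sanitize=False)
    zipped = Chem.molzip(combined)
    zipped = Chem.RemoveHs(zipped)
    Chem.SanitizeMol(zipped)
    return Chem.MolToSmiles(zipped)


def _distinct_decorations(
    template: str,
    n: int,
    vocabulary: tuple[str, ...],
    rng: np.random.Generator,
) -> list[str]:
    labels = _attachment_labels(template)
    seen: set[str] = set()
    out: list[str] = []
    # random sampling first (cheap, covers the common case) ...
    attempts = 0
    max_attempts = 30 * n + 50
    while len(out) < n and attempts < max_attempts:
        attempts += 1
        assignment = {
            lab: vocabulary[int(rng.integers(len(vocabulary)))] for lab in labels
        }
        smi = decorate(template, assignment)
        if smi not in seen:
            seen.add(smi)
            out.append(smi)
    # ... then exhaustive enumeration if the vocabulary is nearly spent
    if len(out) < n:
        for combo in itertools.product(vocabulary, repeat=len(labels)):
            smi = decorate(template, dict(zip(labels, combo)))
            if smi not in seen:
                seen.add(smi)
                out.append(smi)
            if len(out) >= n:
                break
    if len(out) < n:
        raise ValueError(
            f"substituent vocabulary exhausted for scaffold {template!r}: "
            f"needed {n} distinct molecules, built {len(out)}"
        )
    return out


def _acyclic_molecules(n: int, rng: np.random.Generator) -> list[str]:
    if n == 0:
        return []
    bodies = ["C" * i for i in range(2, 12)]
    tails = ["", "O", "N", "C(=O)O", "OC", "(C)C", "CO"]
    candidates = []
    for b in bodies:
        for t in tails:
            smi = b + t
            mol = Chem.MolFromSmiles(smi)
            if mol is not None and mol.GetRingInfo().NumRings() == 0:
                candidates.append(Chem.MolToSmiles(mol))
    candidates = sorted(set(candidates))
    if n > len(candidates):
        raise ValueError(f"cannot build {n} distinct acyclic molecules")
    picks = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in sorted(picks)]


def closed_form_auc(counts) -> float:
    """Recovery-curve AUC computed directly from a frequency vector.

    Counts are sorted descending; the curve point i is (i/n, C_i/N) and the
    area is the trapezoidal sum — no molecules involved. Serves as the exact
    oracle for :func:`npprofiler.scaffolds.recovery_auc`.
    """
    c = np.sort(np.asarray(counts, dtype=float))[::-1]
    if c.size == 0 or np.any(c <= 0):
        raise ValueError("counts must be non-empty and positive")
    y = np.concatenate([[0.0], np.cumsum(c) / c.sum()])
    x = np.arange(0, c.size + 1) / c.size
    return float(np.trapezoid(y, x))


def generate_library(spec: LibrarySpec) -> tuple[CuratedLibrary, dict]:
    """Build a synthetic library plus its ground-truth record.

    Ground truth holds the designed frequency vector, the designed framework
    per scaffold, the closed-form recovery AUC, and per-molecule generative
    labels (scaffold index, or -1 for acyclic fillers).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    frameworks = [template_framework(t) for t in spec.scaffold_templates]
    if len(set(frameworks)) != len(frameworks):
        raise ValueError("templates must design distinct frameworks")

    smiles_list: list[str] = []
    labels: list[int] = []
    for i, (template, count) in enumerate(zip(spec.scaffold_templates, spec.counts)):
        mols = _distinct_decorations(template, count, spec.substituent_vocabulary, rng)
        smiles_list.extend(mols)
        labels.extend([i] * count)
    for smi in _acyclic_molecules(spec.n_acyclic, rng):
        smiles_list.append(smi)
        labels.append(-1)

    kingdoms = list(spec.kingdom_weights)
    weights = np.array([spec.kingdom_weights[k] for k in kingdoms], dtype=float)
    weights = weights / weights.sum()

    records = []
    for idx, smi in enumerate(smiles_list):
        kingdom = kingdoms[int(rng.choice(len(kingdoms), p=weights))]
        genus_pool = spec.genus_pools.get(kingdom, ("Unknown",))
        genus = genus_pool[int(rng.integers(len(genus_pool)))]
        year = int(rng.integers(spec.year_range[0], spec.year_range[1] + 1))
        records.append(
            CompoundRecord(
                id=f"SYN{idx + 1:04d}",
                smiles=smi,
                name=f"{spec.name}-compound-{idx + 1}",
                journal=DEFAULT_JOURNALS[int(rng.integers(len(DEFAULT_JOURNALS)))],
                doi=f"10.9999/{spec.name}.{idx + 1}",
                year=year,
                kingdom=kingdom,
                genus=genus,
                species=f"{genus.lower()}ensis",
                location="synthetic",
            )
        )

    library = CuratedLibrary(
        name=spec.name,
        records=records,
        provenance={r.id: ["generated"] for r in records},
    )
    ground_truth = {
        "counts": list(spec.counts),
        "frameworks": frameworks,
        "closed_form_auc": closed_form_auc(spec.counts),
        "labels": labels,
        "n_acyclic": spec.n_acyclic,
        "seed": spec.seed,
    }
    return library, ground_truth
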