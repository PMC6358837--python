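"""Reading, writing, curating and summarizing compound libraries.

Supported formats: SMILES lists (one molecule per line, optional id), SDF, and
CSV following the natural-product record schema (id, name, smiles, journal,
doi, year, kingdom, genus, species, location, activity).

Curation ("washing") standardizes each structure: keep the largest organic
fragment, neutralize removable formal charges, canonicalize, and drop exact
canonical duplicates. Unparseable records are flagged, never silently dropped.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, TextIO, Union

import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

from .records import (
    SCHEMA_COLUMNS,
    CompoundRecord,
    CuratedLibrary,
    CurationReport,
    check_unique_ids,
)

RDLogger.DisableLog("rdApp.*")

FORMATS = ("smiles", "sdf", "csv")


class SchemaError(ValueError):
    """A tabular input is missing a required column."""


@dataclass
class CurationPolicy:
    """Options controlling the structure wash.

    neutralize
        Protonate anionic acids and deprotonate cationic amines where a neutral
        valid valence exists (RDKit Uncharger). Permanent charges, e.g.
        quaternary ammonium, are retained.
    strip_salts
        Reduce multi-fragment inputs to the largest organic fragment: most
        heavy atoms among carbon-containing fragments; ties broken by total
        atom count, then lexicographically smallest canonical SMILES.
    keep_stereo
        Duplicates are defined on the canonical SMILES of the curated parent
        including stereochemistry; two epimers are distinct compounds.
    """

    neutralize: bool = True
    strip_salts: bool = True
    deduplicate: bool = True
    keep_stereo: bool = True


def _mol_from_smiles(smiles: str) -> Optional[Chem.Mol]:
    if not smiles or not smiles.strip():
        return None
    return Chem.MolFromSmiles(smiles.strip())


def _coerce_year(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in ("nan", "none"):
        return None
    try:
        return int(float(s))
    except ValueError:
        return None


def _record_from_row(row: dict, index: int) -> CompoundRecord:
    def get(key: str) -> str:
        v = row.get(key, "")
        if v is None or (isinstance(v, float) and pd.isna(v)):
            return ""
        return str(v).strip()

    smiles = get("smiles")
    rid = get("id") or f"REC{index + 1:04d}"
    activity = get("activity") or None
    rec = CompoundRecord(
        id=rid,
        smiles=smiles,
        name=get("name"),
        journal=get("journal"),
        doi=get("doi"),
        year=_coerce_year(row.get("year")),
        kingdom=get("kingdom") or "Other",
        genus=get("genus"),
        species=get("species"),
        location=get("location"),
        activity=activity,
    )
    rec.valid = _mol_from_smiles(smiles) is not None
    return rec


def parse_library(
    source: Union[str, Path, TextIO],
    format: str = "csv",
    schema: Optional[dict[str, str]] = None,
) -> list[CompoundRecord]:
    """Read a compound library into records, preserving input order.

    Parameters
    ----------
    source
        Path or open text stream.
    format
        One of ``"smiles"``, ``"sdf"``, ``"csv"``.
    schema
        Optional mapping from schema field name to the column/property name
        used in the input (CSV and SDF only).

    Unparseable structures are retained with ``valid=False``. A CSV without a
    SMILES column raises :class:`SchemaError` naming the column.
    """
    fmt = format.lower()
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    mapping = {c: c for c in SCHEMA_COLUMNS}
    if schema:
        mapping.update(schema)

    if fmt == "csv":
        df = pd.read_csv(source, dtype=str, keep_default_na=False)
        df.columns = [c.strip() for c in df.columns]
        smiles_col = mapping["smiles"]
        if smiles_col not in df.columns:
            # tolerate common capitalizations before failing
            lower = {c.lower(): c for c in df.columns}
            if smiles_col.lower() in lower:
                smiles_col = lower[smiles_col.lower()]
            else:
                raise SchemaError(f"CSV is missing the SMILES column {smiles_col!r}")
        records = []
        for i, row in enumerate(df.to_dict(orient="records")):
            mapped = {field: row.get(col, "") for field, col in mapping.items()}
            mapped["smiles"] = row.get(smiles_col, "")
            records.append(_record_from_row(mapped, i))
        return records

    if fmt == "smiles":
        if isinstance(source, (str, Path)):
            with open(source, "rt", encoding="utf-8") as fh:
                lines = fh.read().splitlines()
        else:
            lines = source.read().splitlines()
        records = []
        for i, line in enumerate(lines):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            smiles = parts[0]
            rid = parts[1] if len(parts) > 1 else f"REC{i + 1:04d}"
            rec = CompoundRecord(id=rid, smiles=smiles)
            rec.valid = _mol_from_smiles(smiles) is not None
            records.append(rec)
        return records

    # SDF: map data fields to schema names; structures kept even if broken
    if isinstance(source, (str, Path)):
        supplier = Chem.SDMolSupplier(str(source), sanitize=True)
    else:
        supplier = Chem.ForwardSDMolSupplier(io.BytesIO(source.read().encode()), sanitize=True)
    records = []
    for i, mol in enumerate(supplier):
        if mol is None:
            records.append(
                CompoundRecord(id=f"REC{i + 1:04d}", smiles="", valid=False)
            )
            continue
        props = mol.GetPropsAsDict()
        row = {field: props.get(col, "") for field, col in mapping.items()}
        if not row.get("id"):
            row["id"] = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        row["smiles"] = Chem.MolToSmiles(mol)
        records.append(_record_from_row(row, i))
    return records


# --- curation ---------------------------------------------------------------

_UNCHARGER = rdMolStandardize.Uncharger()


def _fragment_key(frag: Chem.Mol) -> tuple:
    n_heavy = frag.GetNumHeavyAtoms()
    n_total = frag.GetNumAtoms()
    smi = Chem.MolToSmiles(frag)
    # sort descending on sizes, ascending lexicographic on canonical SMILES
    return (-n_heavy, -n_total, smi)


def largest_organic_fragment(mol: Chem.Mol) -> Optional[Chem.Mol]:
    """Pick the parent fragment: most heavy atoms among carbon-containing
    fragments; tie -> most total atoms, then smallest canonical SMILES.

    Returns None when no fragment contains carbon (salt-only input).
    """
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [
        f
        for f in frags
        if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())
    ]
    if not organic:
        return None
    return min(organic, key=_fragment_key)


def curate(
    records: list[CompoundRecord],
    policy: Optional[CurationPolicy] = None,
    name: str = "library",
) -> tuple[CuratedLibrary, CurationReport]:
    """Standardize structures and deduplicate, with a full audit trail.

    Returns the curated library together with a :class:`CurationReport` whose
    counts satisfy ``n_output = n_input - n_invalid - n_duplicates_removed``.
    """
    policy = policy or CurationPolicy()
    report = CurationReport(n_input=len(records))
    seen: dict[str, str] = {}  # canonical smiles -> first record id
    out: list[CompoundRecord] = []
    provenance: dict[str, list[str]] = {}

    for rec in records:
        actions: list[str] = []
        mol = _mol_from_smiles(rec.smiles)
        if mol is None:
            report.n_invalid += 1
            provenance[rec.id] = ["invalid_structure"]
            continue
        if policy.strip_salts and len(Chem.GetMolFrags(mol)) > 1:
            parent = largest_organic_fragment(mol)
            if parent is None:
                report.n_invalid += 1
                provenance[rec.id] = ["removed_salt_only"]
                continue
            parent = Chem.MolFromSmiles(Chem.MolToSmiles(parent))
            if parent is None:  # pragma: no cover - fragment of a valid mol
                report.n_invalid += 1
                provenance[rec.id] = ["invalid_structure"]
                continue
            mol = parent
            actions.append("stripped_fragments")
            report.n_salts_stripped += 1
        if policy.neutralize:
            before = Chem.MolToSmiles(mol)
            neutral = _UNCHARGER.uncharge(mol)
            after = Chem.MolToSmiles(neutral)
            if after != before:
                mol = neutral
                actions.append("neutralized")
                report.n_neutralized += 1
        canonical = Chem.MolToSmiles(mol, isomericSmiles=policy.keep_stereo)
        if policy.deduplicate and canonical in seen:
            report.n_duplicates_removed += 1
            provenance[rec.id] = [f"duplicate_of:{seen[canonical]}"]
            continue
        seen[canonical] = rec.id
        curated = rec.copy(smiles=canonical, valid=True)
        out.append(curated)
        provenance[rec.id] = actions or ["unchanged"]

    report.n_output = len(out)
    report.check()
    check_unique_ids(out)
    return CuratedLibrary(name=name, records=out, provenance=provenance), report


# --- metadata ---------------------------------------------------------------

def metadata_summary(library: CuratedLibrary) -> dict:
    """Counts by year and kingdom, plus distinct genera per kingdom.

    Missing metadata is grouped under ``"unknown"``; genus identity is
    case-insensitive after whitespace trimming.
    """
    by_year: dict = {}
    by_kingdom: dict[str, int] = {}
    genera: dict[str, set[str]] = {}
    for rec in library.records:
        year = rec.year if rec.year is not None else "unknown"
        by_year[year] = by_year.get(year, 0) + 1
        kingdom = rec.kingdom.strip() or "unknown"
        by_kingdom[kingdom] = by_kingdom.get(kingdom, 0) + 1
        genus = rec.genus.strip().lower()
        if genus:
            genera.setdefault(kingdom, set()).add(genus)
    return {
        "n_compounds": len(library),
        "by_year": dict(sorted(by_year.items(), key=lambda kv: str(kv[0]))),
        "by_kingdom": dict(sorted(by_kingdom.items())),
        "genera_per_kingdom": {k: len(v) for k, v in sorted(genera.items())},
    }


# --- writing ----------------------------------------------------------------

def write_library(
    library: CuratedLibrary,
    format: str = "csv",
    path: Union[str, Path, None] = None,
) -> Union[str, Path]:
    """Write a library; round-trip safe with :func:`parse_library`.

    CSV uses UTF-8, comma separation and the schema column names in fixed
    order; an absent activity is written as an empty cell.
    """
    fmt = format.lower()
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if path is None:
        raise ValueError("path is required")
    path = Path(path)
    if path.parent and not path.parent.exists():
        os.makedirs(path.parent, exist_ok=True)

    if fmt == "csv":
        rows = []
        for r in library.records:
            rows.append(
                {
                    "id": r.id,
                    "name": r.name,
                    "smiles": r.smiles,
                    "journal": r.journal,
                    "doi": r.doi,
                    "year": "" if r.year is None else r.year,
                    "kingdom": r.kingdom,
                    "genus": r.genus,
                    "species": r.species,
                    "location": r.location,
                    "activity": r.activity if r.activity is not None else "",
                }
            )
        df = pd.DataFrame(rows, columns=list(SCHEMA_COLUMNS))
        df.to_csv(path, index=False, encoding="utf-8")
        return path

    if fmt == "smiles":
        with open(path, "wt", encoding="utf-8") as fh:
            for r in library.records:
                fh.write(f"{r.smiles}\t{r.id}\n")
        return path

    writer = Chem.SDWriter(str(path))
    try:
        for r in library.records:
            mol = _mol_from_smiles(r.smiles)
            if mol is None:
                continue
            mol.SetProp("_Name", r.id)
            for field in SCHEMA_COLUMNS:
                if field == "smiles":
                    continue
                value = getattr(r, field)
                if value is None or value == "":
                    continue
                mol.SetProp(field, str(value))
            writer.write(mol)
    finally:
        writer.close()
    return path
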