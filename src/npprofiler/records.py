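"""Core record types shared across the pipeline.

A compound library is an ordered list of :class:`CompoundRecord` entries, each
carrying a SMILES structure plus the bibliographic/biological metadata used by
natural-product collections (journal, DOI, year, kingdom, genus, species,
collection location, optional reported activity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

#: Canonical column order for CSV round-trips.
SCHEMA_COLUMNS = (
    "id",
    "name",
    "smiles",
    "journal",
    "doi",
    "year",
    "kingdom",
    "genus",
    "species",
    "location",
    "activity",
)

KINGDOMS = ("Plantae", "Fungi", "Other")


@dataclass
class CompoundRecord:
    """One library entry: a structure plus its provenance metadata.

    ``valid`` is False when the SMILES could not be parsed; such records are
    retained (never silently dropped) so curation can report them.
    """

    id: str
    smiles: str
    name: str = ""
    journal: str = ""
    doi: str = ""
    year: Optional[int] = None
    kingdom: str = "Other"
    genus: str = ""
    species: str = ""
    location: str = ""
    activity: Optional[str] = None
    valid: bool = True

    def copy(self, **changes) -> "CompoundRecord":
        return replace(self, **changes)


@dataclass
class CuratedLibrary:
    """An ordered, deduplicated library of standardized parent structures.

    ``provenance`` maps record id -> list of curation actions applied to it
    (e.g. ``"stripped_fragments"``, ``"neutralized"``).
    """

    name: str
    records: list[CompoundRecord] = field(default_factory=list)
    provenance: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]


@dataclass
class CurationReport:
    """Audit counts for one curation run.

    Invariant: ``n_output == n_input - n_invalid - n_duplicates_removed``.
    ``n_invalid`` includes unparseable structures and records with no organic
    fragment (salt-only entries).
    """

    n_input: int = 0
    n_invalid: int = 0
    n_salts_stripped: int = 0
    n_neutralized: int = 0
    n_duplicates_removed: int = 0
    n_output: int = 0

    def check(self) -> None:
        counts = (
            self.n_input,
            self.n_invalid,
            self.n_salts_stripped,
            self.n_neutralized,
            self.n_duplicates_removed,
            self.n_output,
        )
        if any(c < 0 for c in counts):
            raise ValueError("curation counts must be non-negative")
        if self.n_output != self.n_input - self.n_invalid - self.n_duplicates_removed:
            raise ValueError(
                "inconsistent curation report: "
                f"{self.n_output} != {self.n_input} - {self.n_invalid} "
                f"- {self.n_duplicates_removed}"
            )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_invalid": self.n_invalid,
            "n_salts_stripped": self.n_salts_stripped,
            "n_neutralized": self.n_neutralized,
            "n_duplicates_removed": self.n_duplicates_removed,
            "n_output": self.n_output,
        }


def check_unique_ids(records: Iterable[CompoundRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if not r.id:
            raise ValueError("record with empty id")
        if r.id in seen:
            raise ValueError(f"duplicate record id: {r.id!r}")
        seen.add(r.id)
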