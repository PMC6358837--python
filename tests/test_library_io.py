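"""Parsing, curation, metadata summary and round-trip I/O."""

import io

import pytest
from hypothesis import given, settings, strategies as st

from npprofiler import (
    CompoundRecord,
    curate,
    metadata_summary,
    parse_library,
    write_library,
)
from npprofiler.library_io import SchemaError, largest_organic_fragment
from rdkit import Chem

from conftest import make_records


# --- parsing ----------------------------------------------------------------

def test_empty_csv_gives_empty_list(tmp_path):
    p = tmp_path / "empty.csv"
    p.write_text("id,name,smiles,journal,doi,year,kingdom,genus,species,location,activity\n")
    assert parse_library(p, format="csv") == []


def test_csv_row_parses_to_valid_record(tmp_path):
    p = tmp_path / "one.csv"
    p.write_text("id,smiles\nFQ1,c1ccccc1\n")
    (rec,) = parse_library(p, format="csv")
    assert rec.id == "FQ1" and rec.valid
    assert Chem.MolFromSmiles(rec.smiles) is not None


def test_unparseable_smiles_flagged_not_dropped(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("id,smiles\nOK1,CCO\nBAD1,C1CC\n")
    records = parse_library(p, format="csv")
    assert [r.id for r in records] == ["OK1", "BAD1"]
    assert records[0].valid and not records[1].valid


def test_missing_smiles_column_names_it(tmp_path):
    p = tmp_path / "noschema.csv"
    p.write_text("id,structure\nA,CCO\n")
    with pytest.raises(SchemaError, match="smiles"):
        parse_library(p, format="csv")


def test_smiles_list_parsing():
    stream = io.StringIO("CCO eth1\nc1ccccc1 benz1\n\nC1CC bad1\n")
    records = parse_library(stream, format="smiles")
    assert [r.id for r in records] == ["eth1", "benz1", "bad1"]
    assert [r.valid for r in records] == [True, True, False]


# --- curation ---------------------------------------------------------------

def test_salt_stripping_keeps_largest_organic_fragment():
    lib, rep = curate(make_records(["CCO.Cl"]))
    assert lib.smiles == ["CCO"]
    assert rep.n_salts_stripped == 1


def test_duplicate_smiles_spellings_collapse():
    lib, rep = curate(make_records(["C1=CC=CC=C1", "c1ccccc1"]))
    assert len(lib) == 1
    assert rep.n_duplicates_removed == 1


def test_sodium_acetate_neutralizes_to_acetic_acid():
    # expected parent verified against an independent standardizer
    lib, rep = curate(make_records(["CC(=O)[O-].[Na+]"]))
    assert lib.smiles == ["CC(=O)O"]
    assert rep.n_neutralized == 1


def test_quaternary_ammonium_charge_retained():
    lib, _ = curate(make_records(["C[N+](C)(C)C"]))
    mol = Chem.MolFromSmiles(lib.smiles[0])
    assert sum(a.GetFormalCharge() for a in mol.GetAtoms()) == 1


def test_inorganic_only_record_counted_invalid():
    lib, rep = curate(make_records(["[Na+].[Cl-]"]))
    assert len(lib) == 0
    assert rep.n_invalid == 1
    rep.check()


def test_epimers_are_distinct_compounds():
    lib, rep = curate(make_records(["C[C@H](O)CC", "C[C@@H](O)CC"]))
    assert len(lib) == 2 and rep.n_duplicates_removed == 0


def test_largest_organic_fragment_tiebreaks():
    # same heavy-atom count: propane vs propan-1-ol -> more total atoms wins? no:
    # CCC (3 heavy, 11 atoms incl H? heavy only) vs CCO (3 heavy) -> tie broken
    # by total atom count then lexicographic canonical SMILES
    mol = Chem.MolFromSmiles("CCC.CCO")
    frag = largest_organic_fragment(mol)
    assert Chem.MolToSmiles(frag) == "CCC"  # 11 vs 9 total atoms with Hs


def test_curate_is_idempotent(synth_library):
    library, _ = synth_library
    first, rep1 = curate(library.records)
    second, rep2 = curate(first.records)
    assert [r.smiles for r in first] == [r.smiles for r in second]
    assert rep2.n_duplicates_removed == 0
    assert rep2.n_salts_stripped == 0
    assert rep2.n_neutralized == 0


FUZZ_SMILES = st.sampled_from([
    "CCO", "c1ccccc1", "C1CC", "", "CC(=O)[O-].[Na+]", "not-a-smiles",
    "CCO.Cl", "[Na+].[Cl-]", "C[C@H](O)CC", "C[C@@H](O)CC", "CCN", "OCC",
    "C1=CC=CC=C1", "CC(C)(C)C", "c1ccccc1O.c1ccccc1O",
])


@settings(deadline=None, max_examples=60)
@given(st.lists(FUZZ_SMILES, max_size=12))
def test_count_identity_on_fuzzed_inputs(smiles_list):
    records = make_records(smiles_list)
    lib, rep = curate(records)
    rep.check()
    assert rep.n_output + rep.n_invalid + rep.n_duplicates_removed == rep.n_input
    assert rep.n_output == len(lib)


@settings(deadline=None, max_examples=30)
@given(st.permutations(["CCO", "OCC", "c1ccccc1", "Cc1ccccc1", "CCO.Cl", "C1CC"]))
def test_dedup_membership_is_order_independent(perm):
    lib, _ = curate(make_records(list(perm)))
    assert {r.smiles for r in lib} == {"CCO", "c1ccccc1", "Cc1ccccc1"}


# --- metadata ---------------------------------------------------------------

def test_metadata_summary_counts():
    records = [
        CompoundRecord(id="A", smiles="CCO", year=2001, kingdom="Plantae", genus="Salvia"),
        CompoundRecord(id="B", smiles="CCN", year=2001, kingdom="Plantae", genus=" salvia "),
        CompoundRecord(id="C", smiles="CCC", year=2005, kingdom="Fungi", genus="Xylaria"),
    ]
    lib, _ = curate(records)
    summary = metadata_summary(lib)
    assert summary["by_year"] == {2001: 2, 2005: 1}
    assert summary["by_kingdom"] == {"Fungi": 1, "Plantae": 2}
    # genus identity is case-insensitive after trimming
    assert summary["genera_per_kingdom"] == {"Fungi": 1, "Plantae": 1}


def test_metadata_summary_absent_kingdom_counts_zero():
    records = [CompoundRecord(id="A", smiles="CCO", kingdom="Fungi")]
    lib, _ = curate(records)
    summary = metadata_summary(lib)
    assert summary["by_kingdom"].get("Plantae", 0) == 0


def test_generated_metadata_totals_match_spec(synth_library):
    library, truth = synth_library
    summary = metadata_summary(library)
    assert summary["n_compounds"] == sum(truth["counts"]) + truth["n_acyclic"]
    assert sum(summary["by_kingdom"].values()) == summary["n_compounds"]
    assert sum(summary["by_year"].values()) == summary["n_compounds"]


# --- writing / round trip ---------------------------------------------------

@pytest.mark.parametrize("fmt,suffix", [("csv", ".csv"), ("sdf", ".sdf"), ("smiles", ".smi")])
def test_round_trip_preserves_structures(tmp_path, fmt, suffix):
    lib, _ = curate(make_records(
        ["CCO", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O", "CCN(CC)CC", "C1CCCCC1"]))
    path = tmp_path / f"lib{suffix}"
    write_library(lib, format=fmt, path=path)
    reread = parse_library(path, format=fmt)
    orig = sorted(Chem.MolToSmiles(Chem.MolFromSmiles(s)) for s in lib.smiles)
    back = sorted(Chem.MolToSmiles(Chem.MolFromSmiles(r.smiles)) for r in reread)
    assert orig == back


def test_csv_round_trip_preserves_schema_fields(tmp_path):
    records = [CompoundRecord(
        id="FQ1", smiles="CCO", name="ethanol", journal="J. Nat. Prod.",
        doi="10.1/x", year=2010, kingdom="Plantae", genus="Salvia",
        species="officinalis", location="Oaxaca", activity="antibacterial")]
    lib, _ = curate(records)
    path = tmp_path / "lib.csv"
    write_library(lib, format="csv", path=path)
    (rec,) = parse_library(path, format="csv")
    for fld in ("id", "name", "journal", "doi", "year", "kingdom",
                "genus", "species", "location", "activity"):
        assert getattr(rec, fld) == getattr(records[0], fld)


def test_empty_library_writes_header_only_csv(tmp_path):
    lib, _ = curate([])
    path = tmp_path / "empty.csv"
    write_library(lib, format="csv", path=path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1 and lines[0].startswith("id,")


def test_absent_activity_is_empty_cell_not_none(tmp_path):
    lib, _ = curate([CompoundRecord(id="A", smiles="CCO", activity=None)])
    path = tmp_path / "lib.csv"
    write_library(lib, format="csv", path=path)
    assert "None" not in path.read_text()
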