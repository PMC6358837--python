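import pytest
from rdkit import Chem

from npprofiler import CompoundRecord, CuratedLibrary, LibrarySpec, generate_library


def make_records(smiles_list, prefix="R"):
    return [
        CompoundRecord(id=f"{prefix}{i + 1}", smiles=smi)
        for i, smi in enumerate(smiles_list)
    ]


def make_library(smiles_list, name="toy"):
    """Curated-shape library from canonical SMILES, bypassing the washer."""
    records = []
    for i, smi in enumerate(smiles_list):
        canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
        records.append(CompoundRecord(id=f"T{i + 1}", smiles=canonical))
    return CuratedLibrary(name=name, records=records)


@pytest.fixture(scope="session")
def synth_library():
    """Default-condition synthetic library with its ground truth."""
    return generate_library(LibrarySpec(seed=11))


@pytest.fixture(scope="session")
def two_scaffold_library():
    spec = LibrarySpec(
        name="two-scaffold",
        scaffold_templates=(
            "c1ccc([*:1])cc1",
            "[*:1]C1CC(c2ccccc2)Oc2ccccc21",
        ),
        counts=(9, 1),
        n_acyclic=0,
        seed=5,
    )
    return generate_library(spec)
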