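"""Wash a raw compound list: salts, duplicates and broken entries.

Builds a small raw library in memory, curates it, and prints the audit
counts. The count identity n_output + n_invalid + n_duplicates = n_input
always holds, so nothing is ever silently dropped.
"""

from npprofiler import CompoundRecord, curate, metadata_summary

raw = [
    CompoundRecord(id="NP1", smiles="CC(=O)Oc1ccccc1C(=O)O", year=2005,
                   kingdom="Plantae", genus="Salix"),
    CompoundRecord(id="NP2", smiles="CCO.Cl", year=2007, kingdom="Fungi",
                   genus="Aspergillus"),            # hydrochloride salt
    CompoundRecord(id="NP3", smiles="CC(=O)[O-].[Na+]", year=2007,
                   kingdom="Plantae", genus="Salvia"),  # sodium carboxylate
    CompoundRecord(id="NP4", smiles="C1=CC=CC=C1", year=2010,
                   kingdom="Plantae", genus="Piper"),
    CompoundRecord(id="NP5", smiles="c1ccccc1", year=2011,
                   kingdom="Plantae", genus="Piper"),   # duplicate of NP4
    CompoundRecord(id="NP6", smiles="C1CC", year=2012),  # unparseable
]

library, report = curate(raw, name="demo")
print("curation report:", report.as_dict())
print("kept structures:", library.smiles)
print("per-record log:", library.provenance)
print("metadata:", metadata_summary(library))
# n_output 4 = 6 input - 1 invalid - 1 duplicate; the salt was stripped to
# ethanol and the carboxylate neutralized to acetic acid before dedup.
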