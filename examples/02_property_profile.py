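"""Six-property physicochemical profile of a generated library.

MW, SlogP, TPSA, RB, HBD and HBA are computed per molecule; the summary
holds box-plot geometry (median, quartiles, Tukey whiskers, outliers).
"""

from npprofiler import LibrarySpec, generate_library, property_table, summarize_table

library, _ = generate_library(LibrarySpec(name="demo", seed=4))
table = property_table(library)
print(table.head())

for prop, s in summarize_table(table).items():
    print(f"{prop:>6}: median {s.median:7.2f}  mean {s.mean:7.2f}  "
          f"sd {s.sd:6.2f}  outliers {len(s.outliers)}")
# The medians characterize the library's size (MW), lipophilicity (SlogP),
# polarity (TPSA, HBD, HBA) and flexibility (RB).
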