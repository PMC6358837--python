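"""Chemical-space maps: property PCA and fingerprint t-SNE.

Two libraries are projected into one shared space: properties are min-max
scaled over the union of both sets, PCA gives the linear property map, and
t-SNE embeds the 166-bit fingerprints nonlinearly.
"""

import numpy as np

from npprofiler import (
    FingerprintSet,
    LibrarySpec,
    generate_library,
    minmax_scale,
    pca,
    property_table,
    tsne_embed,
)
from npprofiler.synthetic import TEMPLATE_POOL

lib_a, _ = generate_library(LibrarySpec(
    name="A", scaffold_templates=TEMPLATE_POOL[:2], counts=(40, 35),
    n_acyclic=0, seed=1))
lib_b, _ = generate_library(LibrarySpec(
    name="B", scaffold_templates=TEMPLATE_POOL[4:6], counts=(40, 35),
    n_acyclic=0, seed=2))

tables = {"A": property_table(lib_a), "B": property_table(lib_b)}
scaled = minmax_scale(tables, scope="union")
embedding = pca(scaled, k=2)
print("PCA explained variance (PC1, PC2):",
      np.round(embedding.explained_variance, 3))
print("PC1 loadings:\n", embedding.loadings["PC1"].round(3))

fps = np.vstack([FingerprintSet.from_library(lib_a).matrix,
                 FingerprintSet.from_library(lib_b).matrix])
ids = [("A", i) for i in lib_a.ids] + [("B", i) for i in lib_b.ids]
tsne = tsne_embed(fps, perplexity=20, seed=0, n_iter=500, ids=ids)
print(f"t-SNE embedded {len(tsne.coordinates)} molecules, "
      f"KL divergence {tsne.params['kl_divergence']:.2f}")
# The PC1 loadings show which properties separate the libraries; the t-SNE
# map clusters molecules sharing substructure keys.
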