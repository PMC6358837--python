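# Methods

npprofiler quantifies the chemical content and diversity of compound
libraries — natural-product collections in particular — using four
complementary structure representations: whole-molecule physicochemical
properties, Bemis–Murcko scaffolds, 166-bit structural-key fingerprints, and
compound counts. This note records the models, conventions and numerical
choices behind each stage, and what the synthetic-data tests do and do not
demonstrate.

## Curation model

A library entry is a SMILES plus bibliographic/biological metadata (journal,
DOI, year, kingdom, genus, species, location, optional activity). Curation
("washing") standardizes each structure in a fixed order:

1. **Parse.** Unparseable SMILES are flagged invalid and excluded from the
   output but retained in the audit (never silently dropped).
2. **Salt stripping.** Multi-fragment inputs are reduced to the largest
   organic fragment: most heavy atoms among carbon-containing fragments; ties
   broken by total atom count, then by lexicographically smallest canonical
   SMILES. Records with no carbon-containing fragment are counted invalid
   with reason `removed_salt_only`.
3. **Neutralization.** Removable formal charges are neutralized (anionic
   acids protonated, cationic amines deprotonated) via RDKit's Uncharger.
   Permanent charges — quaternary ammonium, for example — are retained.
4. **Canonicalization and deduplication.** Duplicates are defined on the
   canonical isomeric SMILES of the curated parent, keeping the first
   occurrence. Stereochemistry is significant: epimers are distinct
   compounds. This is a deliberate choice — collections that ignore
   stereo-duplicates will report slightly smaller sizes.

The audit counts satisfy `n_output = n_input − n_invalid −
n_duplicates_removed` on every input, and curation is idempotent: washing a
washed library reports zero changes. Tautomer canonicalization, pH-dependent
protonation enumeration and 3D geometry are out of scope; all downstream
analyses are 2D.

## Physicochemical properties

Six descriptors of pharmaceutical interest per molecule: MW (g/mol, average
atomic masses), SlogP (Wildman–Crippen atom contributions), TPSA (Ertl, Å²),
RB, HBD, HBA (counts). The donor/acceptor and rotatable-bond rules are
RDKit's Lipinski definitions — HBD counts heavy atoms bearing O–H/N–H; HBA
counts N/O acceptors excluding pyrrole-type nitrogen; RB excludes amide C–N —
and are embedded in every output (`ENGINE_METADATA`), because count
descriptors can legitimately differ by ±1 between descriptor engines.
Descriptors are computed on a canonically re-ordered molecule so every SMILES
spelling of the same structure yields a bit-identical vector.

Summaries carry full box-plot geometry: median, linear-interpolation
quartiles, Tukey whiskers (Q1 − 1.5·IQR, Q3 + 1.5·IQR, clipped to the most
extreme data points inside the fences — the "adjacent values") and the
outliers beyond them. The standard deviation is the sample SD (ddof = 1);
a single observation has SD 0.

## Scaffold diversity

The molecular framework (Bemis–Murcko scaffold) keeps all ring systems, the
linkers connecting them, and atoms multiple-bonded to those (exocyclic
carbonyls and methylenes); atom types and bond orders are kept — frameworks,
not carbon skeletons. Acyclic molecules have no cyclic system: they are
excluded from the scaffold table but counted, and top-N coverage divides by
*all* compounds so published whole-database percentages are comparable.

Diversity is summarized by the cyclic-system recovery curve: with scaffolds
ranked by frequency (ties broken by lexicographic canonical SMILES so the
ranking is deterministic), point *i* is `(i/n, C_i/N′)` where `C_i` is the
cumulative count of the *i* most frequent scaffolds and `N′` the number of
scaffold-bearing compounds, with (0,0) prepended. The AUC is the trapezoidal
integral: exactly 0.5 when all frequencies are equal (maximal diversity),
approaching 1 when a few scaffolds dominate. Because counts are sorted
descending the curve is concave and the AUC lies in [0.5, 1]. A
single-scaffold profile is degenerate — its two-point curve trivially gives
0.5 while the library is maximally redundant — so it warns rather than
returning an arbitrary value.

## Fingerprint diversity

Molecules are encoded as the classic 166-key substructure dictionary (MACCS
keys; RDKit emits 167 bits with bit 0 unused — positions 1..166 are the
vector). Pairwise Tanimoto `T = c/(a+b−c)` is enumerated exhaustively up to
2×10⁶ pairs; beyond that a seeded uniform sample of pair indices is drawn
(with replacement — at that scale duplicate draws are negligible) and the
result is flagged `sampled`. The all-zero pair is defined as T = 1
(identical emptiness; avoids 0/0 and matches common toolkit behavior) with a
warning. The library statistic for consensus comparison is the *median*
pairwise Tanimoto, used raw and unreversed: lower median = more diverse.

## Chemical-space embeddings

Property maps: the six descriptors are min–max scaled to [0,1] per column.
For multi-library maps the default scope is the **union** of all compared
sets (one shared min/max per column), since points from different libraries
must live in one space; per-library scaling exists but is flagged
non-comparable. A constant column maps to 0.5. PCA runs on the scaled (not
z-scored) table; components are covariance eigenvectors ordered by
decreasing eigenvalue with a fixed sign convention (largest-magnitude
loading positive), so results are fully reproducible. Explained-variance
fractions are relative to total variance and sum to 1 over all components.

Fingerprint maps: 2-D t-SNE (scikit-learn), default perplexity 30, 1000
iterations, seeded. Two input modes are provided and recorded in the result
metadata — raw 0/1 bit coordinates under the Euclidean metric (PCA
initialization), or a precomputed 1 − Tanimoto distance matrix (random
initialization, as scikit-learn requires for precomputed distances). Both
are legitimate readings of fingerprint-based embedding; neither is canonical.

Subsampling of large sets is uniform without replacement with floor
rounding of fractional sizes, via numpy's seeded PCG64 generator (stable
across platforms).

## Consensus Diversity plots

Each library contributes one point: median Tanimoto on x, scaffold AUC on y,
property diversity as color, compound count as marker size (area
proportional). Property diversity is the **mean** pairwise Euclidean
distance between the library's union-scaled 6-D property vectors (median
selectable); the mean was chosen as the conventional intra-set distance
statistic for this plot family, and the choice is recorded in output
metadata. Quadrant reference lines default to the per-axis median across the
compared libraries (user-fixable); with a single library quadrants are
undefined and a warning is issued. No statistic is re-scaled or inverted, so
"low x, low y" is the doubly-diverse corner.

## Synthetic libraries and what they show

The generator builds libraries from framework templates with explicit
attachment points, decorated with acyclic substituents attached by single
bonds only (ring-forming substituents are rejected at validation). By
construction the Bemis–Murcko framework of every product equals its
template's framework, so the designed frequency vector, the closed-form
recovery AUC, and per-molecule generative labels are exact ground truth.
Metadata (year 2000–2018, kingdom weights 0.75/0.23/0.02 for
Plantae/Fungi/Other, genus pools) mirrors the shape of a small
natural-product collection. Property spread is controlled indirectly through
the substituent vocabulary (small/large, polar/apolar) rather than by
rejection sampling.

What passing tests show: scaffold extraction, ranking, curve integration,
fingerprint statistics and embeddings are internally consistent and agree
with independent oracles (brute-force terminal-atom pruning, closed-form
trapezoids, exhaustive pair enumeration, covariance eigendecomposition).
What they do not show: agreement with any specific published database's
numbers — real natural products carry fused polycyclic frameworks, dense
stereochemistry and glycosylation that template decoration does not emulate,
and real metadata is messier than the pools here.

## Problem sizes and numerics

Default test and acceptance-run sizes: 100 random frequency vectors (≤6
scaffolds × ≤10 compounds) for the AUC oracle; 50 random generator specs (≤10
scaffolds × ≤50 compounds) for parameter recovery; a 500-molecule library for
sampled-vs-exhaustive median comparison (20 000 sampled pairs, agreement
within 0.02); full-rank PCA reconstruction to <1e-8. Oracle AUC agreement is
exact to 1e-9 (both sides are the same trapezoid arithmetic on recovered
integer counts — any discrepancy would indicate a scaffold assignment
error, not rounding). All randomness flows from explicit seeds; derived
seeds stay below 2³¹.

## Known limitations

- One fingerprint dictionary (166 structural keys); ECFP-style fingerprints
  are not implemented, only pluggable.
- Neutralization follows one explicit rule set; proprietary washing tools
  apply additional (undocumented) rules, so curated counts can differ
  slightly from collections curated elsewhere.
- HBA/HBD medians can shift ±1 against tables computed with other engines.
- t-SNE coordinates are reproducible per seed but not comparable across
  seeds or library subsets; only neighborhood structure is meaningful.
- The scaffold model does not collapse frameworks to carbon skeletons and
  has no scaffold-tree hierarchy.
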