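# Methods

## Neighborhood model

A genome is a linear contig with an ordered list of protein-coding genes
(1-based inclusive coordinates, strand `+`/`-`, free-text product, and label
sets keyed by annotation namespace). The neighborhood of an anchor gene is
every gene whose interval is fully contained in the window
`[max(1, anchor.start − W), min(L, anchor.end + W)]`, where `W` is the
per-side window half-width (default 10 000 bp) and `L` the contig length.
Genes spanning either window edge are excluded — partial genes at the edge
of view would misrepresent gene content. Two deliberate choices where the
underlying idea admits alternatives:

- the window is anchored at the anchor's *boundaries*, not its midpoint, so
  the anchor can never exclude itself and "± W" holds per side;
- the edge-exclusion rule applies to neighbors only: a truncated window that
  would clip the anchor itself still keeps the anchor, because an empty
  neighborhood for a valid anchor is useless.

Contigs are treated as linear; circular replicons are not wrapped. A genome
with several homologs of a query yields one neighborhood per anchor gene.

Display orientation is handled by `flip` (reflection of coordinates inside
the window plus strand toggling — an involution, so source coordinates are
always recoverable) and `normalize_orientation` (flip every neighborhood
whose anchor is on the minus strand; idempotent).

## Label-vector alignment

Each neighborhood projects onto a *label vector*: the ordered list of
per-gene label sets in one namespace. Neighborhood comparison is a local
(Smith–Waterman-style) dynamic program over gene positions:

- positions *match* iff their label sets have a non-empty intersection
  (a gene may carry several domains; set intersection is the least
  surprising generalization of label equality);
- unannotated genes (empty sets) never match anything, including each
  other, which prevents spurious similarity between hypothetical proteins;
- scores default to match +1, mismatch −1, gap −1, with the usual cell
  floor of 0; all three are parameters, so any alternative scheme is
  recoverable;
- with `try_reverse` (default on), the second vector is also aligned in
  reversed orientation and the better score is kept, so inverted gene
  clusters are not penalized; strand itself is ignored by the match
  predicate — gene content, not orientation, defines similarity;
- traceback tie-breaking is fixed (best cell at the smallest `(i, j)`;
  diagonal preferred over up over left) so aligned pairs are reproducible.

An optional `anchored` mode additionally requires the two anchor positions
to be aligned to each other (the score decomposes at the anchor column into
a best prefix alignment, the anchor pair, and a best suffix alignment). It
is off by default: free local alignment is the more permissive and more
broadly useful contract.

Correctness is established against an independent exhaustive oracle that
enumerates every monotone matching between the two vectors (any gapped local
alignment is such a matching plus gap columns); the test suite and the
acceptance script both compare the DP to this oracle on thousands of random
vector pairs of length ≤ 6 over a 4-label alphabet, which is small enough
for exact enumeration yet covers matches, mismatches, gaps, empty sets and
multi-label sets.

## Similarity, distance, clustering

`sim(u, v) = S(u, v) / min(S(u, u), S(v, v))`, clipped to [0, 1], with
self-scores in forward orientation; `sim = 0` (with a warning) when both
vectors are fully unannotated. Normalizing by the *smaller* self-score makes
the measure scale-free in neighborhood length: a short conserved operon
embedded in a longer neighborhood still reaches similarity 1. Distance is
`1 − sim`.

Sets are ordered by average-linkage hierarchical clustering
(`scipy.cluster.hierarchy.linkage`) on the distance matrix. The displayed
track order is the dendrogram leaf order, recomputed deterministically: at
every merge the subtree containing the lower original index is placed first.
Consequences: identical label vectors are always adjacent, repeated runs
give identical orderings, and permuting the input permutes only the labels
of zero-distance groups, not their composition. Average linkage is a robust
default when no linkage is dictated by the problem; it is a parameter.

## Hit filtering

Homology hit lists are consumed from 12-column tabular alignment output,
optionally extended with `qcovhsp`/`scovhsp` and a GTDB taxonomy column.
Defaults follow the standard annotation-transfer criteria: E ≤ 1e-5,
identity ≥ 30%, and query-to-subject *and* subject-to-query coverage ≥ 70%.
When coverage columns are absent they default to 100 (non-restrictive, with
a warning) rather than failing, since plain 12-column output is the de facto
standard. Selection helpers: top-N by E-value (ties broken by larger
bitscore, then input order — deterministic) and lineage selection by exact,
case-insensitive (rank, name) match.

## File formats

GFF3 is read through gffutils (CDS features only; `##sequence-region`
pragmas give contig lengths, otherwise the maximum feature end is used with
a warning; labels come from `Dbxref`/`Ontology_term` prefixes `Pfam:`,
`KEGG:`/`KO:`, `TIGR:`/`TIGRFAM:` and from custom `kegg=`/`pfam=`/`tigrfam=`
attributes). GenBank is read through Biopython (labels from `/db_xref`,
translations kept; compound locations collapse to their outer span with a
warning). Non-CDS features (tRNA, rRNA, CRISPR) are skipped with a count
logged. Taxonomy is carried as GTDB-style rank-prefixed strings
(`d__;p__;c__;o__;f__;g__;s__`); it travels in the CSV dialect, not in the
flat files.

The CSV dialect is this package's canonical interchange format (header
mandatory, one row per gene, exactly one `is_anchor=1` row per
neighborhood). It includes `window_start`/`window_end`/`flipped` columns so
that `write_csv` and `read_csv` are mutually inverse; files without those
columns are accepted, with the window inferred as the gene extent. Every
reader raises a named error (with line/row numbers where applicable) rather
than silently truncating.

## Rendering

One horizontal track per neighborhood; each gene is a directional arrow
polygon at `px_per_kb` horizontal scale (default 40 px/kb), so a glyph's
horizontal extent is exactly `(end − start + 1) · px_per_kb / 1000` px.
With `center_on_anchor` (default) tracks are translated so all anchor
midpoints share one x-coordinate. Coloring is frequency-based: label counts
are accumulated per gene per distinct label across the whole set, and labels
with count ≥ `highlight_min_count` (default 3, i.e. occurring more than
twice) take colors from a fixed, documented 20-color qualitative palette in
descending-count order (ties alphabetical); other genes render in gray; the
palette recycles with a warning beyond 20 labels. Overlapping genes draw in
coordinate order with later genes on top — microbial CDS overlap is small
enough that collision layout is not worth its complexity. The SVG contains
no timestamps and no randomness, so identical inputs give byte-identical
documents; a hard cap of 500 tracks keeps figures tractable.

## Synthetic data generator

The generator emulates the structures the comparison machinery targets: a
conserved core operon (default five co-oriented genes with Pfam-style
labels) present in a stated fraction of neighborhoods, flanked by variable
accessory genes, with per-neighborhood probabilities of an in-place core
inversion (default 0.2) and of a neighborhood-unique annotated insertion
inside the core (default 0.1). Defaults: 12 neighborhoods of 8–12 genes,
gene lengths 300–900 bp, intergenic gaps 50–200 bp, lineages drawn from a
small fixed GTDB-style table. All randomness flows from one explicit seed;
the same seed yields byte-identical GFF3/GenBank/CSV files.

The planted-recovery fixture interleaves two variants with disjoint core
operons and *unannotated* accessory genes, so within-variant distances are
exactly 0 (the local alignment sees only the shared core; hypothetical
proteins contribute nothing) and across-variant distances are near 1 —
giving an unambiguous ground truth for the clustering check. The acceptance
checks run this at 4 neighborhoods per variant over 100–200 seeded
replicates, and the window/round-trip suites at 500–1000 random genomes and
5–6 neighborhood sets respectively — sizes chosen to exercise every code
path many times while keeping the whole suite fast.

What the generator does **not** emulate: real protein sequences (sequences
are N-filled or random strings), overlapping genes, pseudogenes, partial
edge genes in the raw fixture genomes, annotation noise (mislabeled or
missing domains within the core), and realistic taxonomic correlation of
gene content. Passing tests therefore demonstrate the correctness of the
window rule, alignment, clustering, I/O and rendering machinery — not that
the default scoring parameters are optimal for any particular real dataset.

## Known limitations

- Clustering is O(n²) pairwise alignments; fine for the 500-track display
  cap, not intended for thousands of neighborhoods.
- The CSV dialect is this package's own; other tools' neighborhood CSVs
  need column mapping.
- GenBank join locations are collapsed to their outer span.
- No protein-sequence alignment and no homology searching: hit lists are
  consumed from files produced by external search tools.
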