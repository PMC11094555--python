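# genectx

Extraction, comparison, clustering and visualization of microbial gene
neighborhoods.

In bacteria and archaea, the genes surrounding a gene of interest — its
*genomic context* — carry strong functional signal: conserved operons reveal
pathways and complexes, strain-specific insertions reveal mobile elements,
and rearrangements reveal evolutionary events. `genectx` is a library (plus a
thin CLI) for working with that signal offline, on user-supplied or synthetic
data:

- **Extract** gene neighborhoods around anchor genes from GFF3 or GenBank
  genomes: all protein-coding genes fully contained in a ±W bp window around
  the anchor (default W = 10 kb); genes spanning a window edge are excluded.
- **Compare** neighborhoods with a Smith–Waterman-style local alignment over
  *annotation-label vectors*: each gene becomes its set of labels (KEGG,
  Pfam, TIGRFAM, or any custom namespace), two positions match iff their
  sets intersect, and the alignment optionally also tries the reversed
  orientation so inverted clusters still score.
- **Cluster** sets of neighborhoods by normalized alignment similarity
  (average-linkage hierarchical clustering with a deterministic dendrogram
  leaf order) to group shared gene content.
- **Filter** tabular homology hit lists ("outfmt 6") with the standard
  annotation-transfer thresholds — E ≤ 1e-5, identity ≥ 30%, bidirectional
  coverage ≥ 70% — plus top-N and GTDB-taxonomy selection.
- **Render** a set as a deterministic multi-track SVG: one track per
  neighborhood, directional gene arrows to scale, anchors aligned on a
  common vertical, tracks labeled by a chosen taxonomy rank, and genes
  colored by annotation frequency (labels occurring more than twice get
  palette colors; everything else is gray). Up to 500 tracks per figure.

## The core statistic

For neighborhoods with label vectors `u` and `v`, the local alignment score
`S(u, v)` is the Smith–Waterman optimum (match +1, mismatch −1, gap −1 by
default, cell floor 0) where *match* means non-empty label-set
intersection; unannotated genes never match anything. Similarity is

    sim(u, v) = S(u, v) / min(S(u, u), S(v, v))   ∈ [0, 1]

with self-scores computed in the forward orientation, and the clustering
distance is `1 − sim`. This is length-free: a short neighborhood embedded
perfectly in a long one has similarity 1.

## Worked example

```python
from genectx import AlignParams, LabelVector, local_align, similarity

def vec(*labels):
    return LabelVector(tuple(frozenset({l}) for l in labels), 0)

u = vec("PF1", "PF2", "PF3", "PF4")   # conserved four-gene cluster
v = vec("PFX", "PF2", "PF3", "PFY")   # shares the middle two genes
w = vec("PF4", "PF3", "PF2", "PF1")   # same cluster, inverted

local_align(u, v, AlignParams(try_reverse=False))
# AlignmentResult(score=2.0, aligned_pairs=((1, 1), (2, 2)), reversed=False)
similarity(u, v)   # 0.5   (2 matched genes / self-score 4)
local_align(u, w)  # score=4.0, reversed=True — inversion fully recovered
similarity(u, w)   # 1.0
```

The `examples/` directory holds one short script per capability
(extraction, alignment, clustering + rendering, hit filtering); each prints
the numbers it computes and what they mean. For instance
`python examples/04_filter_hits.py` generates 1000 synthetic hits and
reports `176/1000 hits pass the default thresholds`, the 64 of them in the
genus *Methanosarcina*, and the top 5 by E-value.

## Command-line pipeline

```
genectx extract genome.gff3 --anchor-label PF02249 --namespace pfam -o nbh.csv
genectx cluster nbh.csv --namespace pfam -o ordered.csv
genectx render ordered.csv --namespace pfam -o figure.svg
genectx filter-hits hits.tsv --top-n 20 --taxon genus=Methanosarcina -o kept.tsv
```

Exit codes: 0 success, 2 input/validation error, 3 limit exceeded.
Neighborhoods travel between commands as a documented CSV dialect (one row
per gene: `neighborhood_id, genome_id, taxonomy, contig_id, gene_id, start,
end, strand, product, is_anchor, window_start, window_end, flipped,
kegg, pfam, tigrfam, …custom namespaces…, protein_seq`; taxonomy as a
GTDB-style `d__…;p__…;…` string). Coordinates are 1-based inclusive
everywhere.

In the SVG, every gene is a `<polygon class="gene">` carrying
`data-gene-id`, `data-neighborhood-id` and `data-labels` attributes, so
exported figures remain machine-readable and restylable in vector editors;
output is byte-identical across runs.

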