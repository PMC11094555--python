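"""Extract a gene neighborhood around an anchor gene.

Builds a small three-gene contig, extracts the +/-1 kb neighborhood around
the middle gene, and shows the edge-exclusion rule: a gene crossing the
window boundary is dropped.
"""

from genectx import Gene, GenomeRecord, NeighborhoodConfig, extract_neighborhood

genome = GenomeRecord(
    contig_id="ctg1",
    length=6000,
    genome_id="demo",
    genes=[
        Gene("mcrB", "ctg1", 100, 400, "+", product="MCR subunit beta"),
        Gene("mcrA", "ctg1", 900, 1200, "+", product="MCR subunit alpha"),
        Gene("edge", "ctg1", 2100, 2400, "-", product="crosses the window edge"),
        Gene("far", "ctg1", 5000, 5300, "+", product="outside the window"),
    ],
)

nbh = extract_neighborhood(genome, "mcrA", NeighborhoodConfig(window_bp=1000))
print(f"window on {genome.contig_id}: [{nbh.window_start}, {nbh.window_end}]")
for g in nbh.genes:
    tag = " (anchor)" if g.gene_id == nbh.anchor_id else ""
    print(f"  {g.gene_id}  {g.start}-{g.end} {g.strand}{tag}")
print(
    "The window spans anchor.start-1000 to anchor.end+1000, truncated at the "
    "contig edge; 'edge' (2100-2400) crosses the boundary at 2200 and 'far' "
    "lies outside, so both are excluded."
)
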