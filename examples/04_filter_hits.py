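"""Filter a homology hit list the way an annotation pipeline would.

Generates a synthetic tabular hit list, applies the default thresholds
(E <= 1e-5, identity >= 30%, both coverages >= 70%), then narrows to a genus
and to the top hits by E-value.
"""

from genectx import (
    filter_hits,
    generate_hits,
    select_by_taxonomy,
    select_top_by_evalue,
)

hits = generate_hits(1000, seed=7)
kept = filter_hits(hits)
print(f"{len(kept)}/{len(hits)} hits pass the default thresholds")

genus = select_by_taxonomy(kept, "genus", "Methanosarcina")
print(f"{len(genus)} of those are in the genus Methanosarcina")

top = select_top_by_evalue(kept, 5)
print("top 5 by E-value:")
for h in top:
    print(f"  {h.subject_id}  E={h.evalue:.2e}  bits={h.bitscore}")
print(
    "Selection by taxonomy explores one lineage; selection by E-value keeps "
    "only the closest homologs of the query."
)
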