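"""Independent brute-force oracles used to validate the fast implementations.

These deliberately share no code with the package: the local-alignment oracle
enumerates every monotone matching between the two vectors and scores it
directly, and the window oracle re-checks interval containment per gene.
"""

from functools import lru_cache
from itertools import combinations


@lru_cache(maxsize=None)
def _monotone_matchings(m: int, n: int):
    """All non-empty monotone matchings between positions 0..m-1 and 0..n-1."""
    out = []
    for k in range(1, min(m, n) + 1):
        for rows in combinations(range(m), k):
            for cols in combinations(range(n), k):
                out.append(tuple(zip(rows, cols)))
    return out


def brute_force_local_score(u, v, match=1.0, mismatch=-1.0, gap=-1.0):
    """Exhaustive local-alignment score over label-set vectors.

    Any gapped local alignment is a monotone matching of match/mismatch
    columns with gap columns between consecutive pairs, so maximizing the
    matching score (floor 0 for the empty alignment) is exact.
    """

    def s(a, b):
        return match if (a and b and a & b) else mismatch

    best = 0.0
    for pairs in _monotone_matchings(len(u), len(v)):
        score = 0.0
        prev = None
        for i, j in pairs:
            score += s(u[i], v[j])
            if prev is not None:
                score += gap * ((i - prev[0] - 1) + (j - prev[1] - 1))
            prev = (i, j)
        if score > best:
            best = score
    return best


def brute_force_window(genome, anchor, window_bp):
    """Per-gene interval-containment recount of the neighborhood rule."""
    ws = max(1, anchor.start - window_bp)
    we = min(genome.length, anchor.end + window_bp)
    kept = {
        g.gene_id
        for g in genome.genes
        if ws <= g.start and g.end <= we
    }
    kept.add(anchor.gene_id)  # exclusion rule applies to neighbors only
    return ws, we, kept
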