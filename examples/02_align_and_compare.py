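"""Compare two neighborhoods by local alignment of their label vectors.

Positions match when their annotation label sets intersect; the score is the
Smith-Waterman-style local optimum with a floor of zero, and similarity is
that score normalized by the smaller self-score.
"""

from genectx import AlignParams, LabelVector, local_align, similarity


def vec(*labels):
    return LabelVector(tuple(frozenset({l}) if l else frozenset() for l in labels), 0)


u = vec("PF1", "PF2", "PF3", "PF4")          # conserved four-gene cluster
v = vec("PFX", "PF2", "PF3", "PFY")          # shares the middle two genes
w = vec("PF4", "PF3", "PF2", "PF1")          # same cluster, inverted

r = local_align(u, v, AlignParams(try_reverse=False))
print(f"u vs v: score {r.score}, aligned pairs {r.aligned_pairs}")
print(f"similarity(u, v) = {similarity(u, v):.2f}  (2 matches / self-score 4)")

r = local_align(u, w, AlignParams(try_reverse=True))
print(f"u vs w: score {r.score}, reversed={r.reversed}")
print(f"similarity(u, w) = {similarity(u, w):.2f}")
print(
    "Trying the reversed orientation recovers a perfect alignment for the "
    "inverted cluster, so inversions do not hide conserved gene content."
)
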