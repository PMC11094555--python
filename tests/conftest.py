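import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from genectx import Gene, GenomeRecord, NeighborhoodSet

settings.register_profile(
    "genectx",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("genectx")

LABEL_ALPHABET = ("A", "B", "C", "D")


def random_genome(seed: int, max_genes: int = 30) -> GenomeRecord:
    """A random linear contig with possibly-overlapping CDSs and a mix of
    annotated and unannotated genes."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, max_genes + 1))
    genes = []
    pos = 1
    for j in range(n):
        start = pos + int(rng.integers(0, 500))
        end = start + int(rng.integers(50, 2000))
        labels = {}
        if rng.random() < 0.7:
            k = int(rng.integers(1, 3))
            labels = {"pfam": {f"PF{int(rng.integers(0, 8)):05d}" for _ in range(k)}}
        genes.append(
            Gene(
                gene_id=f"g{j}",
                contig_id="ctg",
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                product="hypothetical protein",
                labels=labels,
            )
        )
        # sometimes jump back to create overlaps
        pos = max(1, end + int(rng.integers(-300, 800)))
    length = max(g.end for g in genes) + int(rng.integers(1, 1000))
    return GenomeRecord(
        contig_id="ctg", length=length, genome_id=f"genome{seed}", genes=genes
    )


def random_label_vector(rng, max_len: int = 6) -> list[frozenset]:
    """Entries over a 4-letter alphabet; ~1 in 4 positions unannotated."""
    n = int(rng.integers(1, max_len + 1))
    out = []
    for _ in range(n):
        if rng.random() < 0.25:
            out.append(frozenset())
        else:
            k = int(rng.integers(1, 3))
            out.append(
                frozenset(
                    LABEL_ALPHABET[int(rng.integers(len(LABEL_ALPHABET)))]
                    for _ in range(k)
                )
            )
    return out


@pytest.fixture
def small_set() -> NeighborhoodSet:
    from genectx import FixtureSpec, generate_set

    return generate_set(FixtureSpec(n_neighborhoods=5, seed=7))
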