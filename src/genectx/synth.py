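"""Seeded generators of genomes, neighborhoods and homology-hit tables.

The generator emulates the structures the comparison machinery is built for:
a conserved core operon (a contiguous block of co-oriented, annotated genes)
shared by most neighborhoods, flanked by variable accessory genes, with
occasional inversions of the core block and occasional strain-specific
insertions inside it.  All randomness flows from the explicit seed in the
spec — the same seed always yields byte-identical files.

Protein content is not simulated; sequences, when requested, are random
strings.  See docs/methods.md for what these fixtures do and do not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import parse_taxonomy, write_csv, write_genbank, write_gff3
from .model import (
    Gene,
    GenomeRecord,
    HitRecord,
    Neighborhood,
    NeighborhoodConfig,
    NeighborhoodSet,
    extract_neighborhood,
)

#: Small fixed lineage table (GTDB-style) used for fixture taxonomy.
LINEAGES: tuple[str, ...] = (
    "d__Archaea;p__Halobacteriota;c__Methanosarcinia;o__Methanosarcinales;"
    "f__Methanosarcinaceae;g__Methanosarcina;s__Methanosarcina barkeri",
    "d__Archaea;p__Halobacteriota;c__Methanosarcinia;o__Methanosarcinales;"
    "f__Methanosarcinaceae;g__Methanosarcina;s__Methanosarcina mazei",
    "d__Bacteria;p__Pseudomonadota;c__Gammaproteobacteria;o__Enterobacterales;"
    "f__Pseudoalteromonadaceae;g__Pseudoalteromonas;s__Pseudoalteromonas tunicata",
    "d__Bacteria;p__Pseudomonadota;c__Gammaproteobacteria;o__Enterobacterales;"
    "f__Colwelliaceae;g__Cognaticolwellia;s__Cognaticolwellia mytili",
    "d__Bacteria;p__Bacillota;c__Bacilli;o__Bacillales;"
    "f__Bacillaceae;g__Bacillus;s__Bacillus subtilis",
    "d__Bacteria;p__Pseudomonadota;c__Gammaproteobacteria;o__Enterobacterales;"
    "f__Enterobacteriaceae;g__Escherichia;s__Escherichia coli",
)

#: Default 5-gene core operon labels (Pfam-style ids, methanogenesis-flavored).
DEFAULT_CORE = ("PF02249", "PF02745", "PF02241", "PF02783", "PF02240")

#: Common-domain pool for annotated accessory genes.
DEFAULT_NOISE_POOL = (
    "PF00005", "PF00072", "PF00106", "PF01370", "PF07690",
    "PF00440", "PF04542", "PF08281", "PF00126", "PF03466",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the planted-structure generator.

    ``core_fraction`` of neighborhoods carry the full core block (the rest
    keep only the anchor gene, which always carries ``core_labels[0]``);
    ``inversion_prob`` reverses a core block in place, ``insertion_prob``
    plants a neighborhood-unique annotated gene inside it.  When
    ``noise_label_pool`` is empty, accessory genes are unannotated
    (hypothetical proteins).
    """

    n_neighborhoods: int = 12
    genes_per_neighborhood: tuple[int, int] = (8, 12)
    core_labels: tuple[str, ...] = DEFAULT_CORE
    core_fraction: float = 1.0
    noise_label_pool: tuple[str, ...] = DEFAULT_NOISE_POOL
    inversion_prob: float = 0.2
    insertion_prob: float = 0.1
    namespace: str = "pfam"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("core_fraction", "inversion_prob", "insertion_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.genes_per_neighborhood
        if not (1 <= lo <= hi):
            raise ValueError("genes_per_neighborhood must be a valid range")
        if len(self.core_labels) < 1:
            raise ValueError("need at least one core label")


def _lay_out(rng, slots: list[dict], contig_id: str, prefix: str) -> list[Gene]:
    """Assign non-overlapping coordinates to planned genes in order."""
    genes = []
    pos = int(rng.integers(100, 400))
    for j, planned in enumerate(slots):
        length = int(rng.integers(100, 300)) * 3
        start, end = pos, pos + length - 1
        g = planned
        genes.append(
            Gene(
                gene_id=f"{prefix}_{j:02d}",
                contig_id=contig_id,
                start=start,
                end=end,
                strand=g["strand"],
                product=g["product"],
                labels=g["labels"],
            )
        )
        pos = end + 1 + int(rng.integers(50, 200))
    return genes


def generate_genomes(spec: FixtureSpec) -> list[tuple[GenomeRecord, str]]:
    """Generate one single-contig GenomeRecord per neighborhood, returning
    (record, anchor_gene_id) pairs.  Deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    ns = spec.namespace
    out = []
    for i in range(spec.n_neighborhoods):
        lo, hi = spec.genes_per_neighborhood
        n_genes = int(rng.integers(lo, hi + 1))
        has_core = bool(rng.random() < spec.core_fraction)
        core = list(spec.core_labels) if has_core else [spec.core_labels[0]]
        n_core = len(core)
        n_noise = max(0, n_genes - n_core)
        core_at = int(rng.integers(0, n_noise + 1))  # noise genes before block
        core_strand = "+" if rng.random() < 0.5 else "-"

        core_slots = [
            {
                "strand": core_strand,
                "product": f"core cluster protein {lab}",
                "labels": {ns: {lab}},
            }
            for lab in core
        ]
        if rng.random() < spec.inversion_prob and n_core > 1:
            flipped = "-" if core_strand == "+" else "+"
            core_slots = [dict(c, strand=flipped) for c in reversed(core_slots)]
        if rng.random() < spec.insertion_prob and n_core > 1:
            at = int(rng.integers(1, n_core))
            core_slots.insert(
                at,
                {
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "product": "mobile element protein",
                    "labels": {ns: {f"PFX{spec.seed % 1000:03d}{i:04d}"}},
                },
            )

        def noise_slot():
            labels = {}
            if spec.noise_label_pool:
                lab = spec.noise_label_pool[int(rng.integers(len(spec.noise_label_pool)))]
                labels = {ns: {lab}}
            return {
                "strand": "+" if rng.random() < 0.5 else "-",
                "product": "hypothetical protein",
                "labels": labels,
            }

        slots = (
            [noise_slot() for _ in range(core_at)]
            + core_slots
            + [noise_slot() for _ in range(n_noise - core_at)]
        )
        contig_id = f"ctg{i:03d}"
        genes = _lay_out(rng, slots, contig_id, f"g{i:03d}")
        # anchor = the gene carrying core_labels[0]
        anchor_id = next(
            g.gene_id
            for g in genes
            if spec.core_labels[0] in g.labels_in(ns)
        )
        length = genes[-1].end + int(rng.integers(100, 300))
        lineage = LINEAGES[int(rng.integers(len(LINEAGES)))]
        out.append(
            (
                GenomeRecord(
                    contig_id=contig_id,
                    length=length,
                    genome_id=f"genome{i:03d}",
                    taxonomy=tuple(parse_taxonomy(lineage)),
                    genes=genes,
                ),
                anchor_id,
            )
        )
    return out


def generate_set(
    spec: FixtureSpec = FixtureSpec(), out_dir: str | Path | None = None
) -> NeighborhoodSet:
    """Generate a NeighborhoodSet with planted structure.

    Neighborhoods are extracted from the generated genomes with a window
    covering each whole contig, so every planned gene is in scope.  When
    ``out_dir`` is given, the fixture is also written to disk as
    ``fixture.gff3``, ``fixture.gbk`` and ``fixture.csv`` (the three formats
    describe the same genes).
    """
    genomes = generate_genomes(spec)
    neighborhoods = [
        extract_neighborhood(
            gr, anchor, NeighborhoodConfig(window_bp=gr.length),
            neighborhood_id=f"nbh{i:03d}",
        )
        for i, (gr, anchor) in enumerate(genomes)
    ]
    s = NeighborhoodSet(neighborhoods=neighborhoods, active_namespace=spec.namespace)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        records = [gr for gr, _ in genomes]
        write_gff3(records, out_dir / "fixture.gff3")
        write_genbank(records, out_dir / "fixture.gbk")
        write_csv(s, out_dir / "fixture.csv")
    return s


def generate_planted_pair(
    n_per_variant: int = 6,
    inversion_prob: float = 0.3,
    seed: int = 0,
    core_a: tuple[str, ...] = DEFAULT_CORE,
    core_b: tuple[str, ...] = ("PF00318", "PF03719", "PF00203", "PF00189", "PF00410"),
) -> tuple[NeighborhoodSet, list[int]]:
    """Two interleaved core-operon variants with unannotated accessory genes.

    Within a variant every neighborhood shares the identical core block (some
    inverted), so within-variant alignment distances are exactly zero while
    across-variant distances are maximal — the ground truth for the
    planted-structure recovery check.  Returns the set (variants interleaved
    0,1,0,1,...) and the true variant index per neighborhood.
    """
    sets = []
    for k, core in enumerate((core_a, core_b)):
        sets.append(
            generate_set(
                FixtureSpec(
                    n_neighborhoods=n_per_variant,
                    core_labels=core,
                    noise_label_pool=(),  # hypothetical proteins only
                    inversion_prob=inversion_prob,
                    insertion_prob=0.0,
                    seed=seed * 2 + k,
                )
            )
        )
    neighborhoods, truth = [], []
    for i in range(n_per_variant):
        for k in (0, 1):
            nb = sets[k].neighborhoods[i]
            nb.neighborhood_id = f"v{k}_{nb.neighborhood_id}"
            neighborhoods.append(nb)
            truth.append(k)
    return (
        NeighborhoodSet(neighborhoods=neighborhoods, active_namespace="pfam"),
        truth,
    )


def generate_hits(n: int, seed: int = 0) -> list[HitRecord]:
    """Generate ``n`` synthetic homology hits: E-values log-uniform on
    [1e-50, 1], identities uniform on [20, 100], coverages uniform on
    [40, 100], lineages drawn from :data:`LINEAGES`."""
    rng = np.random.default_rng(seed)
    hits = []
    for i in range(n):
        evalue = float(10.0 ** rng.uniform(-50, 0))
        bitscore = float(np.round(60.0 - 8.0 * np.log10(evalue) + rng.uniform(-20, 20), 1))
        lineage = LINEAGES[int(rng.integers(len(LINEAGES)))]
        hits.append(
            HitRecord(
                query_id="query1",
                subject_id=f"subj{i:05d}",
                pct_identity=float(np.round(rng.uniform(20, 100), 1)),
                evalue=evalue,
                bitscore=bitscore,
                q_cov=float(np.round(rng.uniform(40, 100), 1)),
                s_cov=float(np.round(rng.uniform(40, 100), 1)),
                subject_taxonomy=tuple(parse_taxonomy(lineage)),
            )
        )
    return hits
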