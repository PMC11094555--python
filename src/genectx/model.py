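"""Domain types and neighborhood semantics.

A *gene neighborhood* is the set of protein-coding genes co-localized within a
fixed window around an anchor gene on one replicon.  This module holds the
in-memory types (:class:`Gene`, :class:`GenomeRecord`, :class:`Neighborhood`,
:class:`NeighborhoodSet`, :class:`HitRecord`) and the operations on them:
window extraction with the edge-exclusion rule, orientation flipping and
normalization, homology-hit filtering and selection, and free-text search.

Coordinates are 1-based and inclusive throughout, matching GFF3 and GenBank;
contigs are treated as linear (a window truncates at position 1 and at the
contig length, circular replicons are not wrapped).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import AnchorNotFoundError, DuplicateGeneIdError

#: Canonical taxonomy ranks, most to least inclusive (GTDB convention).
RANKS: tuple[str, ...] = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

Taxonomy = tuple[tuple[str, str], ...]


def _freeze_labels(labels: dict) -> dict[str, frozenset[str]]:
    frozen = {}
    for ns, vals in labels.items():
        fs = frozenset(vals)
        if "" in fs:
            raise ValueError(f"empty label string in namespace {ns!r}")
        frozen[ns] = fs
    return frozen


@dataclass(frozen=True)
class Gene:
    """One protein-coding feature on a contig.

    ``labels`` maps an annotation namespace (``"kegg"``, ``"pfam"``,
    ``"tigrfam"``, or any custom name) to a set of label strings; a gene may
    carry several labels per namespace (e.g. multiple Pfam domains) or none.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    labels: dict[str, frozenset[str]] = field(default_factory=dict)
    protein_seq: str | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: need 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be + or -")
        object.__setattr__(self, "labels", _freeze_labels(self.labels))

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def labels_in(self, namespace: str) -> frozenset[str]:
        return self.labels.get(namespace, frozenset())


@dataclass
class GenomeRecord:
    """One contig or replicon: an ordered gene list plus taxonomy metadata."""

    contig_id: str
    length: int
    genome_id: str
    taxonomy: Taxonomy = ()
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.taxonomy = tuple(tuple(pair) for pair in self.taxonomy)
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        if self.genes and self.genes[-1].end > self.length:
            raise ValueError(
                f"contig {self.contig_id!r}: gene end "
                f"{self.genes[-1].end} exceeds contig length {self.length}"
            )
        seen_ranks = [r for r, _ in self.taxonomy]
        if len(set(seen_ranks)) != len(seen_ranks):
            raise ValueError(f"contig {self.contig_id!r}: duplicate taxonomy rank")

    def find_genes(self, gene_id: str) -> list[Gene]:
        return [g for g in self.genes if g.gene_id == gene_id]


@dataclass(frozen=True)
class SourceRef:
    """Provenance of a neighborhood: which genome/contig it came from."""

    genome_id: str
    contig_id: str
    taxonomy: Taxonomy = ()

    def taxon_name(self, rank: str) -> str | None:
        for r, name in self.taxonomy:
            if r == rank and name:
                return name
        return None


@dataclass(frozen=True)
class NeighborhoodConfig:
    """Window half-width (bp per side of the anchor) and the display track cap."""

    window_bp: int = 10_000
    max_tracks: int = 500

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.max_tracks <= 0:
            raise ValueError("max_tracks must be positive")


@dataclass
class Neighborhood:
    """An anchor gene plus the genes fully inside its window, in display order.

    ``window_start``/``window_end`` are source-contig coordinates.  When
    ``flipped`` is true the gene coordinates have been reflected inside the
    window (``flip`` is an involution, so the source coordinates are always
    recoverable).
    """

    neighborhood_id: str
    anchor_id: str
    genes: list[Gene]
    window_start: int
    window_end: int
    flipped: bool = False
    source: SourceRef = SourceRef("", "")

    def __post_init__(self) -> None:
        if not any(g.gene_id == self.anchor_id for g in self.genes):
            raise ValueError(
                f"neighborhood {self.neighborhood_id!r}: anchor "
                f"{self.anchor_id!r} not among its genes"
            )
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))

    @property
    def anchor(self) -> Gene:
        for g in self.genes:
            if g.gene_id == self.anchor_id:
                return g
        raise AssertionError("unreachable: anchor validated in __post_init__")


@dataclass
class NeighborhoodSet:
    """An ordered collection of neighborhoods sharing an annotation namespace.

    ``active_namespace`` drives coloring and clustering;
    ``taxonomy_display_rank`` selects the rank shown as the track label.
    """

    neighborhoods: list[Neighborhood] = field(default_factory=list)
    active_namespace: str = "kegg"
    taxonomy_display_rank: str = "species"

    def __post_init__(self) -> None:
        if not self.active_namespace:
            raise ValueError("active_namespace must be a non-empty string")
        ids = [n.neighborhood_id for n in self.neighborhoods]
        if len(set(ids)) != len(ids):
            raise ValueError("neighborhood ids must be unique")

    def __len__(self) -> int:
        return len(self.neighborhoods)

    def __iter__(self):
        return iter(self.neighborhoods)


@dataclass(frozen=True)
class HitRecord:
    """One row of a tabular protein homology search result."""

    query_id: str
    subject_id: str
    pct_identity: float
    evalue: float
    bitscore: float
    q_cov: float = 100.0
    s_cov: float = 100.0
    subject_taxonomy: Taxonomy = ()

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        for name in ("pct_identity", "q_cov", "s_cov"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100], got {v}")


@dataclass(frozen=True)
class HitFilterConfig:
    """Homology-hit thresholds; defaults are the standard annotation-transfer
    criteria (E <= 1e-5, identity >= 30%, both coverages >= 70%)."""

    max_evalue: float = 1e-5
    min_identity: float = 30.0
    min_coverage: float = 70.0
    top_n: int | None = None

    def __post_init__(self) -> None:
        if self.max_evalue < 0:
            raise ValueError("max_evalue must be non-negative")
        for name in ("min_identity", "min_coverage"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name} must be in [0, 100]")
        if self.top_n is not None and self.top_n < 1:
            raise ValueError("top_n must be >= 1")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def extract_neighborhood(
    genome: GenomeRecord,
    anchor_id: str,
    config: NeighborhoodConfig = NeighborhoodConfig(),
    neighborhood_id: str | None = None,
) -> Neighborhood:
    """Extract the gene neighborhood around ``anchor_id``.

    The window spans ``[anchor.start - W, anchor.end + W]`` (W =
    ``config.window_bp``), truncated to the contig.  A neighbor is kept only
    if its interval is *fully contained* in the window — genes that span
    either window edge are excluded.  The anchor itself is always kept, even
    if a truncated window would clip it: the edge-exclusion rule applies to
    neighbors only.
    """
    matches = genome.find_genes(anchor_id)
    if not matches:
        raise AnchorNotFoundError(f"anchor not found: {anchor_id!r}")
    if len(matches) > 1:
        raise DuplicateGeneIdError(
            f"duplicate gene id {anchor_id!r} in contig {genome.contig_id!r}"
        )
    anchor = matches[0]
    window_start = max(1, anchor.start - config.window_bp)
    window_end = min(genome.length, anchor.end + config.window_bp)
    kept = [
        g
        for g in genome.genes
        if (window_start <= g.start and g.end <= window_end)
        or g.gene_id == anchor_id
    ]
    return Neighborhood(
        neighborhood_id=neighborhood_id or f"{genome.genome_id}|{anchor_id}",
        anchor_id=anchor_id,
        genes=kept,
        window_start=window_start,
        window_end=window_end,
        flipped=False,
        source=SourceRef(genome.genome_id, genome.contig_id, genome.taxonomy),
    )


def flip(n: Neighborhood) -> Neighborhood:
    """Reverse the display orientation of a neighborhood.

    Coordinates are reflected inside the window (``new_start = window_start +
    window_end - end`` and symmetrically for the end), strands toggle, the
    gene list is re-sorted, and the ``flipped`` bit toggles.  Applying
    ``flip`` twice returns the original neighborhood.
    """
    ws, we = n.window_start, n.window_end
    mirrored = [
        replace(
            g,
            start=ws + we - g.end,
            end=ws + we - g.start,
            strand="-" if g.strand == "+" else "+",
        )
        for g in n.genes
    ]
    return Neighborhood(
        neighborhood_id=n.neighborhood_id,
        anchor_id=n.anchor_id,
        genes=mirrored,
        window_start=ws,
        window_end=we,
        flipped=not n.flipped,
        source=n.source,
    )


def normalize_orientation(s: NeighborhoodSet) -> NeighborhoodSet:
    """Flip every neighborhood whose anchor is on the minus strand, so all
    anchors display on plus.  Order is preserved; idempotent."""
    out = [flip(n) if n.anchor.strand == "-" else n for n in s.neighborhoods]
    return NeighborhoodSet(
        neighborhoods=out,
        active_namespace=s.active_namespace,
        taxonomy_display_rank=s.taxonomy_display_rank,
    )


def filter_hits(
    hits: list[HitRecord], config: HitFilterConfig = HitFilterConfig()
) -> list[HitRecord]:
    """Keep hits with ``evalue <= max_evalue``, ``pct_identity >=
    min_identity`` and *both* coverages ``>= min_coverage``; stable order."""
    return [
        h
        for h in hits
        if h.evalue <= config.max_evalue
        and h.pct_identity >= config.min_identity
        and h.q_cov >= config.min_coverage
        and h.s_cov >= config.min_coverage
    ]


def select_top_by_evalue(hits: list[HitRecord], n: int) -> list[HitRecord]:
    """The ``n`` best hits ranked by ascending E-value; ties broken by larger
    bitscore, then input order.  The result is sorted by that same key."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(
        enumerate(hits), key=lambda t: (t[1].evalue, -t[1].bitscore, t[0])
    )
    return [h for _, h in ranked[:n]]


def select_by_taxonomy(
    hits: list[HitRecord], rank: str, name: str
) -> list[HitRecord]:
    """Hits whose subject lineage contains ``(rank, name)``; the name match is
    exact but case-insensitive.  Input order preserved."""
    rank_l, name_l = rank.lower(), name.lower()
    return [
        h
        for h in hits
        if any(r.lower() == rank_l and nm.lower() == name_l
               for r, nm in h.subject_taxonomy)
    ]


def search_term(s: NeighborhoodSet, term: str) -> list[tuple[str, str]]:
    """Find genes whose product or any annotation label contains ``term`` as a
    case-insensitive substring.  The empty term matches nothing."""
    if term == "":
        return []
    t = term.lower()
    out: list[tuple[str, str]] = []
    for n in s.neighborhoods:
        for g in n.genes:
            if t in g.product.lower() or any(
                t in lab.lower() for labs in g.labels.values() for lab in labs
            ):
                out.append((n.neighborhood_id, g.gene_id))
    return out
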