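"""Readers and writers for the formats the toolkit touches.

* GFF3 (read via gffutils, written directly) — CDS features only, 1-based
  inclusive coordinates, ``##sequence-region`` honored for contig length.
* GenBank flat files (Biopython) — one :class:`GenomeRecord` per LOCUS.
* The neighborhood CSV dialect — the package's canonical interchange format,
  one row per gene, grouped by ``neighborhood_id`` (columns documented on
  :data:`CSV_FIXED_COLUMNS`).
* 12-column tab-separated homology hit tables ("outfmt 6"), optionally
  extended with ``qcovhsp``/``scovhsp`` and a GTDB taxonomy column.
* GTDB-style rank-prefixed taxonomy strings (``d__...;p__...;...``).

Annotation labels are kept in lower-case namespaces ``kegg``, ``pfam`` and
``tigrfam`` (plus arbitrary custom namespaces); recognized cross-reference
prefixes are mapped onto them case-insensitively.
"""

from __future__ import annotations

import logging
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import FormatError
from .model import (
    Gene,
    GenomeRecord,
    Neighborhood,
    NeighborhoodSet,
    HitRecord,
    SourceRef,
    Taxonomy,
)

logger = logging.getLogger(__name__)

_RANK_PREFIX = {
    "d": "domain",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}
_PREFIX_RANK = {v: k for k, v in _RANK_PREFIX.items()}

# cross-reference prefixes (Dbxref / db_xref) mapped to label namespaces
_XREF_NAMESPACE = {
    "pfam": "pfam",
    "kegg": "kegg",
    "ko": "kegg",
    "tigr": "tigrfam",
    "tigrfam": "tigrfam",
}

_CUSTOM_ATTRS = ("kegg", "pfam", "tigrfam")

#: Fixed leading columns of the neighborhood CSV dialect, in order.  They are
#: followed by one column per annotation namespace (``kegg``, ``pfam``,
#: ``tigrfam``, then any custom namespaces alphabetically) and finally
#: ``protein_seq``.  ``window_start``/``window_end``/``flipped`` are optional
#: on input (window inferred from the gene extent when absent).
CSV_FIXED_COLUMNS = (
    "neighborhood_id",
    "genome_id",
    "taxonomy",
    "contig_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "product",
    "is_anchor",
    "window_start",
    "window_end",
    "flipped",
)

_CSV_MANDATORY = (
    "neighborhood_id",
    "genome_id",
    "contig_id",
    "gene_id",
    "start",
    "end",
    "strand",
    "is_anchor",
)

_STANDARD_NAMESPACES = ("kegg", "pfam", "tigrfam")


# ---------------------------------------------------------------------------
# Taxonomy strings
# ---------------------------------------------------------------------------


def parse_taxonomy(s: str) -> list[tuple[str, str]]:
    """Parse a GTDB-style lineage string into (rank, name) pairs.

    ``"d__Archaea;g__Methanosarcina"`` -> ``[("domain", "Archaea"),
    ("genus", "Methanosarcina")]``.  Empty names are kept; unknown rank
    prefixes raise :class:`FormatError`.
    """
    if not s or not s.strip():
        return []
    out = []
    for token in s.split(";"):
        token = token.strip()
        if not token:
            continue
        if len(token) < 3 or token[1:3] != "__" or token[0] not in _RANK_PREFIX:
            raise FormatError(f"unknown taxonomy prefix: {token!r}")
        out.append((_RANK_PREFIX[token[0]], token[3:]))
    return out


def format_taxonomy(taxonomy: Taxonomy) -> str:
    """Inverse of :func:`parse_taxonomy` (canonical rank order not enforced)."""
    return ";".join(f"{_PREFIX_RANK[r]}__{n}" for r, n in taxonomy)


def _labels_from_xrefs(values: list[str]) -> dict[str, set[str]]:
    labels: dict[str, set[str]] = {}
    for val in values:
        prefix, _, rest = val.partition(":")
        ns = _XREF_NAMESPACE.get(prefix.lower())
        if ns and rest:
            labels.setdefault(ns, set()).add(rest)
    return labels


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _prevalidate_gff3(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: unparseable GFF3 line {lineno}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                int(fields[3]), int(fields[4])
            except ValueError:
                raise FormatError(
                    f"{path}: unparseable GFF3 line {lineno}: "
                    "non-integer coordinates"
                ) from None


def read_gff3(path, fasta_path=None) -> list[GenomeRecord]:
    """Read CDS features from a GFF3 file into one GenomeRecord per contig.

    Gene ids come from the ``ID`` attribute (fallback ``locus_tag``, then
    ``contig:start-end``); products from ``product``; labels from
    ``Dbxref``/``Ontology_term`` entries with recognized prefixes and from
    the custom ``kegg=``/``pfam=``/``tigrfam=`` attributes.  Contig lengths
    come from ``##sequence-region`` pragmas; when absent the maximum feature
    end is used with a logged warning.  ``fasta_path`` may point to a protein
    FASTA keyed by gene id to populate ``protein_seq``.
    """
    path = Path(path)
    _prevalidate_gff3(path)
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    region_len: dict[str, int] = {}
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            region_len[parts[1]] = int(parts[3])

    proteins: dict[str, str] = {}
    if fasta_path is not None:
        proteins = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")
        }

    by_contig: dict[str, list[Gene]] = {}
    skipped = 0
    for feat in db.all_features(order_by=("seqid", "start", "end")):
        if feat.featuretype != "CDS":
            skipped += 1
            continue
        attrs = feat.attributes
        gene_id = (
            (attrs.get("ID") or attrs.get("locus_tag") or [None])[0]
            or f"{feat.seqid}:{feat.start}-{feat.end}"
        )
        labels: dict[str, set[str]] = {}
        for key in ("Dbxref", "Ontology_term"):
            for ns, vals in _labels_from_xrefs(attrs.get(key, [])).items():
                labels.setdefault(ns, set()).update(vals)
        for ns in _CUSTOM_ATTRS:
            vals = [v for v in attrs.get(ns, []) if v]
            if vals:
                labels.setdefault(ns, set()).update(vals)
        by_contig.setdefault(feat.seqid, []).append(
            Gene(
                gene_id=gene_id,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand="-" if feat.strand == "-" else "+",
                product=(attrs.get("product") or [""])[0],
                labels=labels,
                protein_seq=proteins.get(gene_id),
            )
        )
    if skipped:
        logger.info("%s: skipped %d non-CDS features", path, skipped)

    records = []
    for contig_id in sorted(set(by_contig) | set(region_len)):
        genes = by_contig.get(contig_id, [])
        if contig_id in region_len:
            length = region_len[contig_id]
        else:
            length = max((g.end for g in genes), default=1)
            logger.warning(
                "%s: no ##sequence-region for %s; inferred length %d",
                path, contig_id, length,
            )
        records.append(
            GenomeRecord(
                contig_id=contig_id,
                length=length,
                genome_id=path.stem,
                genes=genes,
            )
        )
    return records


def _esc_gff3(value: str) -> str:
    return (
        value.replace("%", "%25").replace(";", "%3B")
        .replace("=", "%3D").replace(",", "%2C").replace("\t", "%09")
    )


def write_gff3(records: list[GenomeRecord], path) -> None:
    """Write GenomeRecords as GFF3 (CDS features with the custom
    ``kegg``/``pfam``/``tigrfam`` label attributes read back by
    :func:`read_gff3`)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write(f"##sequence-region {rec.contig_id} 1 {rec.length}\n")
        for rec in records:
            for g in rec.genes:
                attrs = [f"ID={_esc_gff3(g.gene_id)}"]
                if g.product:
                    attrs.append(f"product={_esc_gff3(g.product)}")
                for ns in sorted(g.labels):
                    if g.labels[ns]:
                        joined = ",".join(sorted(g.labels[ns]))
                        attrs.append(f"{ns}={joined}")
                fh.write(
                    "\t".join(
                        (
                            rec.contig_id, "genectx", "CDS",
                            str(g.start), str(g.end), ".",
                            g.strand, "0", ";".join(attrs),
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------


def read_genbank(path) -> list[GenomeRecord]:
    """Read a GenBank flat file into one GenomeRecord per LOCUS.

    CDS features become genes; products from ``/product``, labels from
    ``/db_xref`` with recognized prefixes, translations stored as
    ``protein_seq``.  Compound (join) locations collapse to their outer span
    with a logged warning.
    """
    path = Path(path)
    records = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:
        raise FormatError(f"{path}: malformed GenBank file: {exc}") from exc
    for rec in parsed:
        try:
            genes = []
            for feat in rec.features:
                if feat.type != "CDS":
                    continue
                loc = feat.location
                if loc is None:
                    raise FormatError("CDS without location")
                if len(getattr(loc, "parts", [loc])) > 1:
                    logger.warning(
                        "%s: compound location in %s collapsed to outer span",
                        path, rec.name,
                    )
                quals = feat.qualifiers
                start, end = int(loc.start) + 1, int(loc.end)
                gene_id = (
                    quals.get("locus_tag", quals.get("protein_id", [None]))[0]
                    or f"{rec.id}:{start}-{end}"
                )
                labels = _labels_from_xrefs(quals.get("db_xref", []))
                genes.append(
                    Gene(
                        gene_id=gene_id,
                        contig_id=rec.id,
                        start=start,
                        end=end,
                        strand="-" if loc.strand == -1 else "+",
                        product=quals.get("product", [""])[0],
                        labels=labels,
                        protein_seq=quals.get("translation", [None])[0],
                    )
                )
            records.append(
                GenomeRecord(
                    contig_id=rec.id,
                    length=len(rec.seq),
                    genome_id=path.stem,
                    genes=genes,
                )
            )
        except FormatError:
            raise
        except Exception as exc:
            raise FormatError(
                f"{path}: malformed GenBank record {rec.name!r}: {exc}"
            ) from exc
    return records


def write_genbank(records: list[GenomeRecord], path) -> None:
    """Write GenomeRecords as a GenBank flat file (N-filled sequence; label
    namespaces serialized as ``/db_xref`` entries)."""
    seqrecords = []
    for rec in records:
        sr = SeqRecord(
            Seq("N" * rec.length),
            id=rec.contig_id,
            name=rec.contig_id[:16],
            description="synthetic contig",
            annotations={"molecule_type": "DNA"},
        )
        for g in rec.genes:
            quals: dict[str, list[str]] = {"locus_tag": [g.gene_id]}
            if g.product:
                quals["product"] = [g.product]
            xrefs = []
            for ns in sorted(g.labels):
                prefix = {"kegg": "KEGG", "pfam": "Pfam", "tigrfam": "TIGRFAM"}.get(ns)
                if prefix:
                    xrefs.extend(f"{prefix}:{lab}" for lab in sorted(g.labels[ns]))
            if xrefs:
                quals["db_xref"] = xrefs
            if g.protein_seq:
                quals["translation"] = [g.protein_seq]
            sr.features.append(
                SeqFeature(
                    SimpleLocation(g.start - 1, g.end,
                                   strand=-1 if g.strand == "-" else 1),
                    type="CDS",
                    qualifiers=quals,
                )
            )
        seqrecords.append(sr)
    SeqIO.write(seqrecords, str(path), "genbank")


# ---------------------------------------------------------------------------
# Neighborhood CSV dialect
# ---------------------------------------------------------------------------


def write_csv(s: NeighborhoodSet, path) -> None:
    """Write a NeighborhoodSet in the package's CSV dialect, one row per gene."""
    extra_ns = sorted(
        {
            ns
            for n in s.neighborhoods
            for g in n.genes
            for ns in g.labels
            if ns not in _STANDARD_NAMESPACES
        }
    )
    namespaces = list(_STANDARD_NAMESPACES) + extra_ns
    columns = list(CSV_FIXED_COLUMNS) + namespaces + ["protein_seq"]
    rows = []
    for n in s.neighborhoods:
        tax = format_taxonomy(n.source.taxonomy)
        for g in n.genes:
            row = {
                "neighborhood_id": n.neighborhood_id,
                "genome_id": n.source.genome_id,
                "taxonomy": tax,
                "contig_id": n.source.contig_id or g.contig_id,
                "gene_id": g.gene_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "product": g.product,
                "is_anchor": 1 if g.gene_id == n.anchor_id else 0,
                "window_start": n.window_start,
                "window_end": n.window_end,
                "flipped": 1 if n.flipped else 0,
                "protein_seq": g.protein_seq or "",
            }
            for ns in namespaces:
                row[ns] = ",".join(sorted(g.labels_in(ns)))
            rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)


def _split_labels(cell: str) -> set[str]:
    return {t.strip() for t in cell.split(",") if t.strip()} if cell else set()


def read_csv(path, active_namespace: str = "kegg") -> NeighborhoodSet:
    """Read a neighborhood CSV back into a NeighborhoodSet.

    Rows are grouped by ``neighborhood_id`` preserving file order; each group
    must contain exactly one ``is_anchor == 1`` row.  Unknown columns (other
    than the documented optional ones) are treated as annotation namespaces.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, header row is mandatory") from None
    for col in _CSV_MANDATORY:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    optional = set(CSV_FIXED_COLUMNS) | {"protein_seq"}
    namespaces = [c for c in df.columns if c not in optional]

    groups: dict[str, list[dict]] = {}
    for row in df.to_dict("records"):
        groups.setdefault(row["neighborhood_id"], []).append(row)

    neighborhoods = []
    for nid, rows in groups.items():
        anchors = [r for r in rows if r["is_anchor"].strip() == "1"]
        if len(anchors) != 1:
            raise FormatError(
                f"{path}: neighborhood {nid!r} has {len(anchors)} anchor rows, "
                "expected exactly one"
            )
        genes = []
        for r in rows:
            labels = {ns: _split_labels(r.get(ns, "")) for ns in namespaces}
            labels = {ns: v for ns, v in labels.items() if v}
            try:
                genes.append(
                    Gene(
                        gene_id=r["gene_id"],
                        contig_id=r["contig_id"],
                        start=int(r["start"]),
                        end=int(r["end"]),
                        strand=r["strand"],
                        product=r.get("product", ""),
                        labels=labels,
                        protein_seq=r.get("protein_seq") or None,
                    )
                )
            except ValueError as exc:
                raise FormatError(
                    f"{path}: invalid gene row in neighborhood {nid!r}: {exc}"
                ) from exc
        first = rows[0]
        window_start = (
            int(first["window_start"])
            if first.get("window_start", "").strip()
            else min(g.start for g in genes)
        )
        window_end = (
            int(first["window_end"])
            if first.get("window_end", "").strip()
            else max(g.end for g in genes)
        )
        neighborhoods.append(
            Neighborhood(
                neighborhood_id=nid,
                anchor_id=anchors[0]["gene_id"],
                genes=genes,
                window_start=window_start,
                window_end=window_end,
                flipped=first.get("flipped", "0").strip() == "1",
                source=SourceRef(
                    genome_id=first["genome_id"],
                    contig_id=first["contig_id"],
                    taxonomy=tuple(parse_taxonomy(first.get("taxonomy", ""))),
                ),
            )
        )
    return NeighborhoodSet(
        neighborhoods=neighborhoods, active_namespace=active_namespace
    )


# ---------------------------------------------------------------------------
# Tabular homology hits
# ---------------------------------------------------------------------------


def _parse_hit_fields(fields: list[str], lineno: int, path) -> HitRecord:
    if len(fields) not in (12, 14, 15):
        raise FormatError(
            f"{path}: row {lineno}: expected 12, 14 or 15 tab-separated "
            f"columns, got {len(fields)}"
        )
    try:
        pct = float(fields[2])
        evalue = float(fields[10])
        bitscore = float(fields[11])
        q_cov = float(fields[12]) if len(fields) >= 14 else 100.0
        s_cov = float(fields[13]) if len(fields) >= 14 else 100.0
    except ValueError as exc:
        raise FormatError(f"{path}: row {lineno}: {exc}") from exc
    taxonomy = (
        tuple(parse_taxonomy(fields[14])) if len(fields) == 15 else ()
    )
    return HitRecord(
        query_id=fields[0],
        subject_id=fields[1],
        pct_identity=pct,
        evalue=evalue,
        bitscore=bitscore,
        q_cov=q_cov,
        s_cov=s_cov,
        subject_taxonomy=taxonomy,
    )


def read_hits(path) -> list[HitRecord]:
    """Read a 12-column tabular homology hit file (optionally extended with
    ``qcovhsp``/``scovhsp`` and a taxonomy column).  When the coverage
    columns are absent both coverages default to 100 (non-restrictive) with
    a logged warning."""
    hits, raw = read_hits_with_lines(path)
    return hits


def read_hits_with_lines(path) -> tuple[list[HitRecord], list[str]]:
    """As :func:`read_hits`, also returning the raw input lines (same order)
    so callers can emit filtered subsets verbatim."""
    hits: list[HitRecord] = []
    lines: list[str] = []
    warned = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            hit = _parse_hit_fields(fields, lineno, path)
            if len(fields) == 12 and not warned:
                logger.warning(
                    "%s: no coverage columns; recording coverages as 100", path
                )
                warned = True
            hits.append(hit)
            lines.append(line)
    return hits, lines


def write_hits(hits: list[HitRecord], path) -> None:
    """Write HitRecords in the extended 15-column tabular format (alignment
    bookkeeping columns not represented by :class:`HitRecord` are zeroed)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    (
                        h.query_id, h.subject_id, f"{h.pct_identity:g}",
                        "0", "0", "0", "0", "0", "0", "0",
                        f"{h.evalue:g}", f"{h.bitscore:g}",
                        f"{h.q_cov:g}", f"{h.s_cov:g}",
                        format_taxonomy(h.subject_taxonomy),
                    )
                )
                + "\n"
            )


def read_genomes(path) -> list[GenomeRecord]:
    """Dispatch on file extension: ``.gff``/``.gff3`` -> GFF3, ``.gb``/
    ``.gbk``/``.gbff``/``.genbank`` -> GenBank."""
    suffix = Path(path).suffix.lower()
    if suffix in (".gff", ".gff3"):
        return read_gff3(path)
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        return read_genbank(path)
    raise FormatError(f"{path}: unrecognized genome file extension {suffix!r}")
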