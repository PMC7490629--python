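"""Genome FASTA and GFF3 ingestion into the ontology-typed feature graph.

Coordinates are converted from GFF3 (1-based, closed) to Chado interbase
(0-based, half-open) on the way in: ``fmin = start - 1``, ``fmax = end``.
Parent/child links become ``part_of`` relationships (``derives_from`` when a
Derives_from attribute says so), building the gene → mRNA → exon/CDS graph.

Load order is enforced: GFF3 lines reference the sequences of column 1, so
the genome FASTA must be loaded first; protein FASTA requires the matching
mRNAs from GFF3.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from Bio import SeqIO
from gffutils.feature import feature_from_line

from .datastore import (
    DuplicateRecordError,
    Feature,
    LoadOrderError,
    LoadReport,
    MissingTermError,
    Organism,
    Stopwatch,
    StoreHandle,
    get_feature,
)
from .ontology import resolve_term
from .parallel import parallel_map

__all__ = ["load_fasta", "load_gff3", "load_protein_fasta"]

_STRAND = {"+": 1, "-": -1, ".": 0, "?": 0}

# GFF3 reserved attributes handled structurally rather than as properties
_STRUCTURAL_ATTRS = {"ID", "Parent", "Derives_from"}
# attributes stored as the canonical "description" property
_DESCRIPTION_ATTRS = {"Note", "note", "description", "Description", "product"}


def _md5(text: str) -> str:
    return hashlib.md5(text.encode()).hexdigest()


def load_fasta(store: StoreHandle, fasta_stream, organism: Organism | str,
               sequence_type: str, *, on_duplicate: str = "error",
               threads: int = 1, progress=None) -> LoadReport:
    """Load a (multi-)FASTA as features of one Sequence Ontology type.

    The uniquename is the first whitespace-delimited token of the header;
    residues are stored verbatim (case preserved) with their length and MD5
    checksum.
    """
    watch = Stopwatch()
    org = store.get_organism(organism)
    type_term = resolve_term(store, sequence_type, "sequence")
    report = LoadReport()
    records = list(SeqIO.parse(fasta_stream, "fasta"))
    staged = parallel_map(
        lambda rec: (rec.id, str(rec.seq), _md5(str(rec.seq))),
        records, threads)
    with store.transaction():
        for uniquename, residues, checksum in staged:
            report.records_seen += 1
            existing = get_feature(store, org, uniquename, type_term.name)
            if existing is not None:
                if on_duplicate == "skip":
                    report.skipped += 1
                    continue
                raise DuplicateRecordError(
                    f"FASTA record {uniquename!r} already loaded as "
                    f"{type_term.name}")
            store.insert_feature(org, uniquename, type_term,
                                 residues=residues, checksum=checksum)
            report.created += 1
            if progress is not None:
                progress(1)
    report.elapsed = watch.elapsed()
    return report


@dataclass
class _GffRecord:
    lineno: int
    seqid: str
    type: str
    start: int
    end: int
    strand: int
    phase: int | None
    attributes: dict[str, list[str]]

    @property
    def fmin(self) -> int:
        return self.start - 1

    @property
    def fmax(self) -> int:
        return self.end


def _parse_gff_line(item: tuple[int, str]):
    """Stage one GFF3 feature line; returns (_GffRecord | None, error | None)."""
    lineno, line = item
    try:
        f = feature_from_line(line)
    except Exception as exc:
        return None, (lineno, f"unparseable GFF3 line: {exc}")
    if f.start is None or f.end is None:
        return None, (lineno, "missing start/end coordinate")
    if f.start > f.end:
        return None, (lineno, f"start > end ({f.start} > {f.end})")
    phase = int(f.frame) if f.frame in ("0", "1", "2") else None
    return _GffRecord(
        lineno=lineno,
        seqid=f.seqid,
        type=f.featuretype,
        start=f.start,
        end=f.end,
        strand=_STRAND.get(f.strand, 0),
        phase=phase,
        attributes={k: list(v) for k, v in f.attributes.items()},
    ), None


def load_gff3(store: StoreHandle, gff_stream, organism: Organism | str, *,
              on_duplicate: str = "error", threads: int = 1,
              progress=None) -> LoadReport:
    """Load GFF3 feature lines onto already-loaded reference sequences.

    Two-pass: features first, then Parent/Derives_from relationships, so
    forward references are legal.  Lines sharing one ID merge into a single
    feature with rank-ordered locations (split CDS).  An embedded ``##FASTA``
    section is honored as if its records had been loaded with
    :func:`load_fasta` beforehand.

    Raises :class:`LoadOrderError` (store unchanged) when a column-1
    sequence does not exist as a feature.
    """
    watch = Stopwatch()
    org = store.get_organism(organism)
    text = gff_stream.read() if hasattr(gff_stream, "read") else str(gff_stream)
    report = LoadReport()

    gff_part, _, fasta_part = text.partition("##FASTA")
    feature_lines: list[tuple[int, str]] = []
    for lineno, raw in enumerate(gff_part.splitlines(), 1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        feature_lines.append((lineno, line))

    parsed = parallel_map(_parse_gff_line, feature_lines, threads)

    with store.transaction():
        if fasta_part.strip():
            import io
            for rec in SeqIO.parse(io.StringIO(fasta_part.lstrip()), "fasta"):
                if get_feature(store, org, rec.id) is None:
                    seq_type = _reference_type(store)
                    store.insert_feature(org, rec.id, seq_type,
                                         residues=str(rec.seq),
                                         checksum=_md5(str(rec.seq)))

        records: list[_GffRecord] = []
        for rec, err in parsed:
            report.records_seen += 1
            if err is not None:
                report.add_error(*err)
                continue
            records.append(rec)

        # resolve reference sequences up front: load-order enforcement
        src_cache: dict[str, Feature] = {}
        for rec in records:
            if rec.seqid in src_cache:
                continue
            src = get_feature(store, org, rec.seqid)
            if src is None:
                raise LoadOrderError(
                    f"GFF3 references sequence {rec.seqid!r} which is not "
                    "loaded; load the genome FASTA first", "load-fasta")
            src_cache[rec.seqid] = src

        # group lines by ID (ID-less lines get a synthesized uniquename)
        groups: dict[str, list[_GffRecord]] = {}
        order: list[str] = []
        for rec in records:
            rec_id = rec.attributes.get("ID", [None])[0]
            if rec_id is None:
                rec_id = (f"{rec.type}:{rec.seqid}:{rec.fmin}..{rec.fmax}:"
                          f"{rec.strand}")
            if rec_id not in groups:
                groups[rec_id] = []
                order.append(rec_id)
            groups[rec_id].append(rec)

        created: dict[str, Feature] = {}
        for rec_id in order:
            group = sorted(groups[rec_id], key=lambda r: (r.fmin, r.fmax))
            first = group[0]
            try:
                type_term = resolve_term(store, first.type, "sequence")
            except MissingTermError:
                for rec in group:
                    report.add_error(
                        rec.lineno,
                        f"feature type {first.type!r} not in the sequence "
                        "ontology; line skipped")
                continue
            existing = get_feature(store, org, rec_id, type_term.name)
            if existing is not None:
                if on_duplicate == "skip":
                    report.skipped += len(group)
                    continue
                raise DuplicateRecordError(
                    f"GFF3 feature {rec_id!r} ({type_term.name}) already "
                    "loaded")
            name = first.attributes.get("Name", [None])[0]
            feat = store.insert_feature(org, rec_id, type_term, name=name)
            created[rec_id] = feat
            for rank, rec in enumerate(group):
                src = src_cache[rec.seqid]
                store.execute(
                    "INSERT INTO featureloc (feature_id, srcfeature_id, fmin,"
                    " fmax, strand, phase, rank) VALUES (?,?,?,?,?,?,?)",
                    (feat.feature_id, src.feature_id, rec.fmin, rec.fmax,
                     rec.strand, rec.phase, rank))
            _store_attributes(store, feat, first.attributes)
            report.created += 1
            report.skipped += len(group) - 1  # merged continuation lines
            if progress is not None:
                progress(len(group))

        # pass 2: relationships
        part_of = resolve_term(store, "part_of", "relationship")
        derives_from = resolve_term(store, "derives_from", "relationship")
        for rec_id in order:
            feat = created.get(rec_id)
            if feat is None:
                continue
            first = groups[rec_id][0]
            links = [(pid, part_of) for pid in first.attributes.get("Parent", [])]
            links += [(pid, derives_from)
                      for pid in first.attributes.get("Derives_from", [])]
            for parent_id, predicate in links:
                parent = created.get(parent_id)
                if parent is None:
                    parent = get_feature(store, org, parent_id)
                if parent is None:
                    report.add_error(
                        first.lineno,
                        f"Parent {parent_id!r} of {rec_id!r} is unknown")
                    continue
                store.execute(
                    "INSERT OR IGNORE INTO feature_relationship (subject_id,"
                    " type_id, object_id) VALUES (?,?,?)",
                    (feat.feature_id, predicate.cvterm_id, parent.feature_id))
    report.elapsed = watch.elapsed()
    return report


def _reference_type(store: StoreHandle):
    for candidate in ("chromosome", "contig", "region"):
        try:
            return resolve_term(store, candidate, "sequence")
        except MissingTermError:
            continue
    raise MissingTermError(
        "chromosome", "no reference sequence type in the sequence ontology; "
        "load the Sequence Ontology first (load-ontology)")


def _store_attributes(store: StoreHandle, feat: Feature,
                      attributes: dict[str, list[str]]) -> None:
    """Map GFF3 column-9 attributes onto featureprop / feature_dbxref rows.

    Name is the display name (already on the feature); Note/description/
    product become the canonical "description" property; Dbxref become
    cross-references; every other attribute becomes a property typed by the
    attribute name, auto-created in the feature_property vocabulary.
    """
    desc_rank = 0
    for attr, values in attributes.items():
        if attr in _STRUCTURAL_ATTRS or attr == "Name":
            continue
        if attr in _DESCRIPTION_ATTRS:
            dtype = store.property_type("description")
            for value in values:
                store.execute(
                    "INSERT INTO featureprop (feature_id, type_id, value,"
                    " rank) VALUES (?,?,?,?)",
                    (feat.feature_id, dtype.cvterm_id, value, desc_rank))
                desc_rank += 1
            continue
        if attr == "Dbxref":
            for value in values:
                if ":" not in value:
                    continue
                dbxref_id = store.get_or_create_dbxref(value)
                store.execute(
                    "INSERT OR IGNORE INTO feature_dbxref (feature_id,"
                    " dbxref_id) VALUES (?,?)",
                    (feat.feature_id, dbxref_id))
            continue
        ptype = store.property_type(attr)
        for rank, value in enumerate(values):
            store.execute(
                "INSERT INTO featureprop (feature_id, type_id, value, rank)"
                " VALUES (?,?,?,?)",
                (feat.feature_id, ptype.cvterm_id, value, rank))


def load_protein_fasta(store: StoreHandle, fasta_stream,
                       organism: Organism | str, *,
                       on_duplicate: str = "error", threads: int = 1,
                       progress=None) -> LoadReport:
    """Load protein FASTA records as polypeptides linked to their mRNAs.

    The header's first token must equal an existing mRNA uniquename (the
    cross-file ID consistency rule); each match creates a polypeptide
    feature plus a ``translation_of`` relationship.  Records with no
    matching mRNA become error entries.
    """
    watch = Stopwatch()
    org = store.get_organism(organism)
    poly_term = resolve_term(store, "polypeptide", "sequence")
    translation_of = resolve_term(store, "translation_of", "relationship")
    report = LoadReport()
    records = list(SeqIO.parse(fasta_stream, "fasta"))
    staged = parallel_map(
        lambda rec: (rec.id, str(rec.seq), _md5(str(rec.seq))),
        records, threads)
    with store.transaction():
        for idx, (uniquename, residues, checksum) in enumerate(staged, 1):
            report.records_seen += 1
            mrna = get_feature(store, org, uniquename, "mRNA")
            if mrna is None:
                report.add_error(
                    idx, f"protein {uniquename!r} has no matching mRNA "
                    "(run load-gff first)")
                continue
            existing = get_feature(store, org, uniquename, poly_term.name)
            if existing is not None:
                if on_duplicate == "skip":
                    report.skipped += 1
                    continue
                raise DuplicateRecordError(
                    f"polypeptide {uniquename!r} already loaded")
            poly = store.insert_feature(org, uniquename, poly_term,
                                        residues=residues, checksum=checksum)
            store.execute(
                "INSERT INTO feature_relationship (subject_id, type_id,"
                " object_id) VALUES (?,?,?)",
                (poly.feature_id, translation_of.cvterm_id, mrna.feature_id))
            report.created += 1
            if progress is not None:
                progress(1)
    report.elapsed = watch.elapsed()
    return report
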