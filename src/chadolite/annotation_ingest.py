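"""Loaders for computed evidence attached to existing features.

Similarity searches (BLAST tabular, outfmt 6), domain scans (InterProScan
TSV), GO term assignment, OrthoMCL-style ortholog groups, MCL coexpression
clusters and BibTeX publications.  Every loader records provenance through
an AnalysisRun where scores are involved, resolves incoming IDs against the
already-loaded feature graph (the cross-file consistency rule), and runs in
a single transaction.

Match representation: a hit is stored as a feature of type "match" located
on the QUERY feature; the subject lives in an external database and is kept
as text properties plus a cross-reference, never fabricated as a store
feature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .datastore import (
    DuplicateRecordError,
    Feature,
    LoadOrderError,
    LoadReport,
    MissingTermError,
    NotFoundError,
    Stopwatch,
    StoreHandle,
    now_iso,
)
from .ontology import resolve_term

__all__ = [
    "AnalysisMeta",
    "load_blast",
    "load_interproscan",
    "assign_go_terms",
    "load_ortholog_groups",
    "load_coexpression_clusters",
    "load_bibtex",
]


@dataclass(frozen=True)
class AnalysisMeta:
    """Provenance of a computed-evidence run (Chado analysis row)."""

    program: str
    programversion: str
    sourcename: str
    algorithm: str | None = None


def _read_lines(stream) -> list[str]:
    text = stream.read() if hasattr(stream, "read") else str(stream)
    return text.splitlines()


def _resolve_by_uniquename(store: StoreHandle, ident: str,
                           preferred_types: tuple[str, ...]) -> Feature | None:
    """Resolve an evidence-file ID to a feature across organisms.

    When several features share the uniquename the first matching type in
    ``preferred_types`` wins, keeping resolution deterministic.
    """
    rows = store.execute(
        "SELECT feature.*, cvterm.name AS type_name FROM feature"
        " JOIN cvterm ON feature.type_id = cvterm.cvterm_id"
        " WHERE uniquename=?", (ident,)).fetchall()
    if not rows:
        return None
    by_type = {row["type_name"]: row for row in rows}
    for type_name in preferred_types:
        if type_name in by_type:
            return store._feature_from_row(by_type[type_name])
    return store._feature_from_row(rows[0]) if len(rows) == 1 else None


def _create_analysis(store: StoreHandle, meta: AnalysisMeta,
                     on_duplicate: str) -> int:
    row = store.execute(
        "SELECT analysis_id FROM analysis WHERE program=? AND"
        " programversion=? AND sourcename=?",
        (meta.program, meta.programversion, meta.sourcename)).fetchone()
    if row is not None:
        if on_duplicate == "skip":
            return row[0]
        raise DuplicateRecordError(
            f"analysis ({meta.program}, {meta.programversion},"
            f" {meta.sourcename}) already loaded")
    return store.execute(
        "INSERT INTO analysis (program, programversion, sourcename,"
        " algorithm, timeexecuted) VALUES (?,?,?,?,?)",
        (meta.program, meta.programversion, meta.sourcename,
         meta.algorithm, now_iso())).lastrowid


def _match_feature(store: StoreHandle, query: Feature, meta: AnalysisMeta,
                   index: int, match_term, on_duplicate: str) -> Feature | None:
    """Create the match feature for evidence row ``index`` on ``query``;
    None means an identical row was already loaded (skip policy)."""
    uniquename = f"{query.uniquename}:match:{meta.sourcename}:{index:05d}"
    org = store.execute("SELECT * FROM organism WHERE organism_id=?",
                        (query.organism_id,)).fetchone()
    existing = store.execute(
        "SELECT feature_id FROM feature WHERE organism_id=? AND uniquename=?"
        " AND type_id=?",
        (query.organism_id, uniquename, match_term.cvterm_id)).fetchone()
    if existing is not None:
        if on_duplicate == "skip":
            return None
        raise DuplicateRecordError(f"match {uniquename!r} already loaded")
    fid = store.execute(
        "INSERT INTO feature (organism_id, uniquename, type_id) VALUES"
        " (?,?,?)", (org["organism_id"], uniquename,
                     match_term.cvterm_id)).lastrowid
    return store.feature_by_id(fid)


_BLAST_COLUMNS = 12  # qseqid sseqid pident length mismatch gapopen
#                      qstart qend sstart send evalue bitscore


def load_blast(store: StoreHandle, tabular_stream, analysis_meta: AnalysisMeta,
               min_significance: float | None = None, *,
               on_duplicate: str = "error", progress=None) -> LoadReport:
    """Load BLAST tabular (outfmt 6) hits as match features + scores.

    Per kept row: one match feature (type "match") located on the query via
    interbase coordinates, carrying the subject ID (and description when a
    13th column provides one) as properties; one score row with
    rawscore=bitscore, significance=E-value, identity=pident.  Rows with
    E-value above ``min_significance`` are skipped and counted.
    """
    watch = Stopwatch()
    report = LoadReport()
    match_term = resolve_term(store, "match", "sequence")
    with store.transaction():
        subject_type = store.property_type("match subject")
        desc_type = store.property_type("description")
        analysis_id = _create_analysis(store, analysis_meta, on_duplicate)
        for lineno, line in enumerate(_read_lines(tabular_stream), 1):
            if not line.strip() or line.startswith("#"):
                continue
            report.records_seen += 1
            cols = line.rstrip("\n").split("\t")
            if len(cols) == 1:
                cols = line.split()
            if len(cols) < _BLAST_COLUMNS:
                report.add_error(
                    lineno, f"expected >= {_BLAST_COLUMNS} tab-separated "
                    f"columns, got {len(cols)}")
                continue
            (qseqid, sseqid, pident, _length, _mismatch, _gapopen, qstart,
             qend, _sstart, _send, evalue, bitscore) = cols[:12]
            try:
                pident_f = float(pident)
                qstart_i, qend_i = int(qstart), int(qend)
                evalue_f = float(evalue)
                bitscore_f = float(bitscore)
            except ValueError as exc:
                report.add_error(lineno, f"unparseable numeric field: {exc}")
                continue
            if min_significance is not None and evalue_f > min_significance:
                report.skipped += 1
                continue
            query = _resolve_by_uniquename(
                store, qseqid, ("mRNA", "polypeptide", "gene"))
            if query is None:
                report.add_error(lineno, f"unknown query ID {qseqid!r}")
                continue
            match = _match_feature(store, query, analysis_meta,
                                   report.records_seen, match_term,
                                   on_duplicate)
            if match is None:
                report.skipped += 1
                continue
            store.execute(
                "INSERT INTO featureloc (feature_id, srcfeature_id, fmin,"
                " fmax, strand, phase, rank) VALUES (?,?,?,?,0,NULL,0)",
                (match.feature_id, query.feature_id,
                 min(qstart_i, qend_i) - 1, max(qstart_i, qend_i)))
            store.execute(
                "INSERT INTO featureprop (feature_id, type_id, value, rank)"
                " VALUES (?,?,?,0)",
                (match.feature_id, subject_type.cvterm_id, sseqid))
            if len(cols) > 12 and cols[12].strip():
                store.execute(
                    "INSERT INTO featureprop (feature_id, type_id, value,"
                    " rank) VALUES (?,?,?,0)",
                    (match.feature_id, desc_type.cvterm_id, cols[12].strip()))
            if ":" in sseqid:
                dbxref_id = store.get_or_create_dbxref(sseqid)
                store.execute(
                    "INSERT OR IGNORE INTO feature_dbxref (feature_id,"
                    " dbxref_id) VALUES (?,?)", (match.feature_id, dbxref_id))
            store.execute(
                "INSERT INTO analysisfeature (analysis_id, feature_id,"
                " rawscore, significance, identity) VALUES (?,?,?,?,?)",
                (analysis_id, match.feature_id, bitscore_f, evalue_f,
                 pident_f))
            report.created += 1
            if progress is not None:
                progress(1)
    report.elapsed = watch.elapsed()
    return report


_GO_TOKEN = re.compile(r"GO:\d{7}")


def load_interproscan(store: StoreHandle, tsv_stream,
                      analysis_meta: AnalysisMeta, *,
                      on_duplicate: str = "error",
                      progress=None) -> LoadReport:
    """Load InterProScan TSV rows as domain matches on polypeptides.

    Columns (1-based): 1 protein accession, 5/6 signature accession and
    description, 7/8 match start/stop, 9 score, 12/13 InterPro accession
    and description, 14 pipe-separated GO IDs.  GO IDs are dispatched to
    :func:`assign_go_terms`; if any row carries GO IDs while the Gene
    Ontology has not been loaded the whole load aborts with a load-order
    error, leaving the store unchanged.
    """
    watch = Stopwatch()
    report = LoadReport()
    lines = _read_lines(tsv_stream)

    has_go = any(_GO_TOKEN.search(line) for line in lines)
    if has_go:
        go_loaded = store.execute(
            "SELECT 1 FROM dbxref JOIN db USING (db_id) WHERE db.name='GO'"
            " LIMIT 1").fetchone()
        if go_loaded is None:
            raise LoadOrderError(
                "InterProScan rows carry GO IDs but the Gene Ontology is "
                "not loaded", "load-ontology")

    match_term = resolve_term(store, "match", "sequence")
    with store.transaction():
        sig_acc_type = store.property_type("signature accession")
        desc_type = store.property_type("description")
        ipr_type = store.property_type("interpro accession")
        analysis_id = _create_analysis(store, analysis_meta, on_duplicate)
        for lineno, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                continue
            report.records_seen += 1
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 11:
                report.add_error(
                    lineno, f"expected >= 11 columns, got {len(cols)}")
                continue
            protein_id = cols[0]
            poly = _resolve_by_uniquename(store, protein_id, ("polypeptide",))
            if poly is None or poly.type_name != "polypeptide":
                report.add_error(
                    lineno, f"unknown protein ID {protein_id!r}")
                continue
            try:
                start_i, stop_i = int(cols[6]), int(cols[7])
            except ValueError as exc:
                report.add_error(lineno, f"bad coordinates: {exc}")
                continue
            significance = None
            if cols[8].strip() not in ("-", ""):
                try:
                    significance = float(cols[8])
                except ValueError as exc:
                    report.add_error(lineno, f"bad score: {exc}")
                    continue
            match = _match_feature(store, poly, analysis_meta,
                                   report.records_seen, match_term,
                                   on_duplicate)
            if match is None:
                report.skipped += 1
                continue
            store.execute(
                "INSERT INTO featureloc (feature_id, srcfeature_id, fmin,"
                " fmax, strand, phase, rank) VALUES (?,?,?,?,0,NULL,0)",
                (match.feature_id, poly.feature_id, start_i - 1, stop_i))
            store.execute(
                "INSERT INTO featureprop (feature_id, type_id, value, rank)"
                " VALUES (?,?,?,0)",
                (match.feature_id, sig_acc_type.cvterm_id, cols[4]))
            desc_rank = 0
            if len(cols) > 5 and cols[5].strip() not in ("-", ""):
                store.execute(
                    "INSERT INTO featureprop (feature_id, type_id, value,"
                    " rank) VALUES (?,?,?,?)",
                    (match.feature_id, desc_type.cvterm_id, cols[5],
                     desc_rank))
                desc_rank += 1
            if len(cols) > 11 and cols[11].strip() not in ("-", ""):
                store.execute(
                    "INSERT INTO featureprop (feature_id, type_id, value,"
                    " rank) VALUES (?,?,?,0)",
                    (match.feature_id, ipr_type.cvterm_id, cols[11]))
                if len(cols) > 12 and cols[12].strip() not in ("-", ""):
                    store.execute(
                        "INSERT INTO featureprop (feature_id, type_id,"
                        " value, rank) VALUES (?,?,?,?)",
                        (match.feature_id, desc_type.cvterm_id, cols[12],
                         desc_rank))
            store.execute(
                "INSERT INTO analysisfeature (analysis_id, feature_id,"
                " significance) VALUES (?,?,?)",
                (analysis_id, match.feature_id, significance))
            if len(cols) > 13:
                go_ids = _GO_TOKEN.findall(cols[13])
                if go_ids:
                    try:
                        assign_go_terms(store, poly, go_ids,
                                        _in_transaction=True)
                    except MissingTermError as exc:
                        report.add_error(lineno, str(exc))
            report.created += 1
            if progress is not None:
                progress(1)
    report.elapsed = watch.elapsed()
    return report


def assign_go_terms(store: StoreHandle, feature: Feature,
                    go_accessions: list[str],
                    publication: str | None = None,
                    evidence: str | None = None, *,
                    _in_transaction: bool = False) -> int:
    """Attach GO terms to a feature; returns the number of novel
    (feature, term) pairs created.  Alternate GO IDs resolve to their
    primary term; duplicates are skipped silently (idempotent)."""
    pub_id = None
    if publication is not None:
        row = store.execute("SELECT pub_id FROM pub WHERE uniquename=?",
                            (publication,)).fetchone()
        if row is None:
            raise NotFoundError(f"publication {publication!r} not loaded")
        pub_id = row[0]
    terms = [resolve_term(store, acc) for acc in go_accessions]

    def _write() -> int:
        count = 0
        for term in terms:
            cur = store.execute(
                "INSERT OR IGNORE INTO feature_cvterm (feature_id,"
                " cvterm_id, pub_id, evidence) VALUES (?,?,?,?)",
                (feature.feature_id, term.cvterm_id, pub_id, evidence))
            count += cur.rowcount
        return count

    if _in_transaction:
        return _write()
    with store.transaction():
        return _write()


def _load_group_file(store: StoreHandle, stream, property_name: str,
                     group_id_of, member_ids_of, preferred_types,
                     progress=None) -> LoadReport:
    """Shared core of the ortholog and coexpression group loaders.

    One featureprop per resolvable member of every multi-member group;
    singleton groups are skipped entirely (a one-member group carries no
    grouping information and would pollute the search facets).
    """
    watch = Stopwatch()
    report = LoadReport()
    prop_type = store.property_type(property_name)
    with store.transaction():
        group_no = 0
        for lineno, line in enumerate(_read_lines(stream), 1):
            if not line.strip():
                continue
            group_no += 1
            group_id = group_id_of(line, group_no, lineno)
            if group_id is None:
                report.records_seen += 1
                report.add_error(lineno, "missing group ID before ':'")
                continue
            members = member_ids_of(line)
            report.records_seen += len(members)
            if len(members) < 2:
                report.skipped += len(members)
                continue
            for ident in members:
                feat = _resolve_by_uniquename(store, ident, preferred_types)
                if feat is None:
                    report.add_error(lineno, f"unknown member {ident!r}")
                    continue
                rank_row = store.execute(
                    "SELECT COALESCE(MAX(rank)+1, 0) FROM featureprop WHERE"
                    " feature_id=? AND type_id=?",
                    (feat.feature_id, prop_type.cvterm_id)).fetchone()
                store.execute(
                    "INSERT INTO featureprop (feature_id, type_id, value,"
                    " rank) VALUES (?,?,?,?)",
                    (feat.feature_id, prop_type.cvterm_id, group_id,
                     rank_row[0]))
                report.created += 1
            if progress is not None:
                progress(len(members))
    report.elapsed = watch.elapsed()
    return report


def load_ortholog_groups(store: StoreHandle, groups_stream, *,
                         progress=None) -> LoadReport:
    """Load OrthoMCL-style ``GROUPID: taxon|member ...`` lines.

    Members (after stripping the optional ``taxon|`` prefix) resolve to
    polypeptide features; each gets an "orthologous group" property with
    the group ID as value.
    """

    def group_id_of(line, _group_no, _lineno):
        head, sep, _ = line.partition(":")
        return head.strip() if sep and head.strip() else None

    def member_ids_of(line):
        _, _, tail = line.partition(":")
        return [tok.split("|")[-1] for tok in tail.split()]

    return _load_group_file(store, groups_stream, "orthologous group",
                            group_id_of, member_ids_of, ("polypeptide",),
                            progress=progress)


def load_coexpression_clusters(store: StoreHandle, mcl_stream,
                               analysis_meta: AnalysisMeta | None = None, *,
                               on_duplicate: str = "error",
                               progress=None) -> LoadReport:
    """Load MCL output (one whitespace-separated cluster per line).

    Cluster ``k`` (1-based over non-empty lines) assigns a "coexpression
    group" property with value ``CLUSTER<k>`` to each resolved member;
    member IDs resolve to mRNA features (clusters group transcripts).
    """
    if analysis_meta is not None:
        with store.transaction():
            _create_analysis(store, analysis_meta, on_duplicate)

    def group_id_of(_line, group_no, _lineno):
        return f"CLUSTER{group_no}"

    def member_ids_of(line):
        return line.split()

    return _load_group_file(store, mcl_stream, "coexpression group",
                            group_id_of, member_ids_of,
                            ("mRNA", "gene", "polypeptide"),
                            progress=progress)


# -- BibTeX ---------------------------------------------------------------

_ENTRY_START = re.compile(r"@(\w+)\s*\{", re.IGNORECASE)


def _split_top_level(body: str) -> list[str]:
    parts, depth, quoted, buf = [], 0, False, []
    for ch in body:
        if ch == '"' and depth == 0:
            quoted = not quoted
        elif ch == "{":
            depth += 1
        elif ch == "}":
            depth -= 1
        if ch == "," and depth == 0 and not quoted:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    if buf:
        parts.append("".join(buf))
    return parts


def _strip_value(value: str) -> str:
    value = value.strip()
    while (value.startswith("{") and value.endswith("}")) or \
            (value.startswith('"') and value.endswith('"')):
        value = value[1:-1].strip()
    return " ".join(value.split())


def _parse_bibtex(text: str):
    """Yield (lineno, entrytype, citekey-or-None, fields dict)."""
    for m in _ENTRY_START.finditer(text):
        entrytype = m.group(1).lower()
        if entrytype in ("comment", "string", "preamble"):
            continue
        lineno = text.count("\n", 0, m.start()) + 1
        depth, pos = 1, m.end()
        while pos < len(text) and depth:
            if text[pos] == "{":
                depth += 1
            elif text[pos] == "}":
                depth -= 1
            pos += 1
        body = text[m.end():pos - 1]
        parts = _split_top_level(body)
        citekey = parts[0].strip() if parts else ""
        if not citekey or "=" in citekey:
            yield lineno, entrytype, None, {}
            continue
        fields: dict[str, str] = {}
        for part in parts[1:]:
            name, eq, value = part.partition("=")
            if eq:
                fields[name.strip().lower()] = _strip_value(value)
        yield lineno, entrytype, citekey, fields


def load_bibtex(store: StoreHandle, bibtex_stream,
                link_to: list[str] | None = None, *,
                on_duplicate: str = "error", progress=None) -> LoadReport:
    """Load BibTeX entries as publications, optionally linked to features.

    One publication per entry, keyed by cite key; ``link_to`` attaches
    every loaded publication to the named features (surfaced as the
    feature page's related publications).
    """
    watch = Stopwatch()
    report = LoadReport()
    text = (bibtex_stream.read() if hasattr(bibtex_stream, "read")
            else str(bibtex_stream))
    with store.transaction():
        link_features: list[Feature] = []
        for ident in link_to or []:
            feat = _resolve_by_uniquename(
                store, ident, ("gene", "mRNA", "polypeptide"))
            if feat is None:
                report.add_error(0, f"unknown link target {ident!r}")
            else:
                link_features.append(feat)
        for lineno, _entrytype, citekey, fields in _parse_bibtex(text):
            report.records_seen += 1
            if citekey is None:
                report.add_error(lineno, "entry without cite key")
                continue
            existing = store.execute(
                "SELECT pub_id FROM pub WHERE uniquename=?",
                (citekey,)).fetchone()
            if existing is not None:
                if on_duplicate == "skip":
                    report.skipped += 1
                    continue
                raise DuplicateRecordError(
                    f"publication {citekey!r} already loaded")
            year = None
            if fields.get("year", "").strip().isdigit():
                year = int(fields["year"])
            pub_id = store.execute(
                "INSERT INTO pub (uniquename, title, authors, pyear, doi)"
                " VALUES (?,?,?,?,?)",
                (citekey, fields.get("title"), fields.get("author"),
                 year, fields.get("doi"))).lastrowid
            for feat in link_features:
                store.execute(
                    "INSERT OR IGNORE INTO feature_pub (feature_id, pub_id)"
                    " VALUES (?,?)", (feat.feature_id, pub_id))
            report.created += 1
            if progress is not None:
                progress(1)
    report.elapsed = watch.elapsed()
    return report
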