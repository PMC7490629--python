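"""OBO controlled-vocabulary loading and transitive-closure queries.

Terms type every feature and relationship in the store, so ontologies must
be loaded before sequences and annotation evidence.  The loader is a
tolerant stanza parser for OBO flat files 1.2/1.4: malformed stanzas become
error entries with line numbers instead of aborting the whole file, which
matters when ingesting third-party ontology dumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .datastore import (
    LoadReport,
    MissingTermError,
    NotFoundError,
    OntologyCycleError,
    Stopwatch,
    StoreHandle,
    Term,
)

__all__ = ["load_obo", "resolve_term", "ancestors"]


@dataclass
class _Stanza:
    kind: str              # "Term" or "Typedef"
    lineno: int
    tags: dict[str, list[str]] = field(default_factory=dict)

    def first(self, tag: str) -> str | None:
        values = self.tags.get(tag)
        return values[0] if values else None


def _iter_stanzas(text: str):
    """Yield (header_tags, stanzas).  Tolerant: unknown tags are kept,
    stray lines outside stanzas are ignored."""
    header: dict[str, list[str]] = {}
    stanzas: list[_Stanza] = []
    current: _Stanza | None = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("!", 1)[0].strip() if "!" in raw else raw.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            kind = line[1:-1]
            current = _Stanza(kind=kind, lineno=lineno)
            stanzas.append(current)
            continue
        if ":" not in line:
            if current is not None:
                current.tags.setdefault("__malformed__", []).append(
                    f"{lineno}:{line}")
            continue
        tag, value = line.split(":", 1)
        target = current.tags if current is not None else header
        target.setdefault(tag.strip(), []).append(value.strip())
    return header, stanzas


def _strip_quotes(value: str) -> str:
    if value.startswith('"'):
        end = value.find('"', 1)
        if end > 0:
            return value[1:end]
    return value


def load_obo(store: StoreHandle, obo_stream, *,
             default_vocabulary: str | None = None,
             on_duplicate: str = "error",
             progress=None) -> LoadReport:
    """Load an OBO file into the vocabulary graph.

    One term per ``[Term]`` stanza (obsolete stanzas are stored flagged);
    one relationship-type term per ``[Typedef]``; one term relationship per
    ``is_a`` and per ``relationship:`` line.  The stanza ``namespace`` tag
    (falling back to the header ``default-namespace``, then
    ``default_vocabulary``) chooses the vocabulary.

    Existing (vocabulary, name) rows — bootstrap terms or a previous load
    with ``on_duplicate="skip"`` — are upserted in place and counted as
    skipped.  All writes happen in one transaction.
    """
    watch = Stopwatch()
    if hasattr(obo_stream, "read"):
        text = obo_stream.read()
    else:
        text = str(obo_stream)
    header, stanzas = _iter_stanzas(text)
    fallback_cv = (header.get("default-namespace", [None])[0]
                   or default_vocabulary or "default")

    report = LoadReport()
    with store.transaction():
        terms_by_obo_id: dict[str, Term] = {}
        pending_edges: list[tuple[int, str, str, str]] = []  # lineno, subj, pred, obj
        for stanza in stanzas:
            if stanza.kind not in ("Term", "Typedef"):
                continue
            report.records_seen += 1
            if "__malformed__" in stanza.tags:
                bad = stanza.tags["__malformed__"][0]
                report.add_error(int(bad.split(":", 1)[0]),
                                 f"malformed line in stanza: {bad.split(':', 1)[1]!r}")
                continue
            obo_id = stanza.first("id")
            if obo_id is None:
                report.add_error(stanza.lineno, "stanza missing id:")
                continue
            name = stanza.first("name") or obo_id
            cv_name = stanza.first("namespace") or fallback_cv
            if stanza.kind == "Typedef":
                cv_name = stanza.first("namespace") or "relationship"
            definition = stanza.first("def")
            if definition:
                definition = _strip_quotes(definition)
            obsolete = (stanza.first("is_obsolete") or "").lower() == "true"
            accession = obo_id if ":" in obo_id else None
            term, created = store.upsert_term(
                cv_name, name, accession=accession, definition=definition,
                is_obsolete=obsolete,
                is_relationship_type=(stanza.kind == "Typedef"))
            if created:
                report.created += 1
            else:
                report.skipped += 1
            terms_by_obo_id[obo_id] = term
            if accession is None and stanza.kind == "Typedef":
                # typedefs like plain "part_of" resolve by name too
                terms_by_obo_id.setdefault(name, term)
            for alt in stanza.tags.get("alt_id", []):
                if ":" in alt:
                    dbxref_id = store.get_or_create_dbxref(alt)
                    store.execute(
                        "INSERT OR IGNORE INTO cvterm_dbxref (cvterm_id,"
                        " dbxref_id) VALUES (?,?)",
                        (term.cvterm_id, dbxref_id))
            for synonym in stanza.tags.get("synonym", []):
                store.execute(
                    "INSERT OR IGNORE INTO cvtermsynonym (cvterm_id, synonym)"
                    " VALUES (?,?)",
                    (term.cvterm_id, _strip_quotes(synonym)))
            for parent in stanza.tags.get("is_a", []):
                pending_edges.append((stanza.lineno, obo_id, "is_a", parent))
            for rel in stanza.tags.get("relationship", []):
                parts = rel.split()
                if len(parts) >= 2:
                    pending_edges.append(
                        (stanza.lineno, obo_id, parts[0], parts[1]))
                else:
                    report.add_error(stanza.lineno,
                                     f"malformed relationship line: {rel!r}")
            if progress is not None:
                progress(1)

        for lineno, subj_id, pred_name, obj_id in pending_edges:
            subject = terms_by_obo_id.get(subj_id)
            obj = terms_by_obo_id.get(obj_id)
            if obj is None:
                # forward reference to a term defined in another file:
                # create a placeholder in the same vocabulary
                obj, _ = store.upsert_term(
                    fallback_cv, obj_id,
                    accession=obj_id if ":" in obj_id else None)
                terms_by_obo_id[obj_id] = obj
            predicate = (terms_by_obo_id.get(pred_name)
                         or store.find_term(pred_name, "relationship"))
            if predicate is None:
                predicate, _ = store.upsert_term(
                    "relationship", pred_name, is_relationship_type=True)
            if subject is None:
                continue
            if pred_name == "is_a" and subject.cvterm_id == obj.cvterm_id:
                report.add_error(lineno, f"self is_a loop on {subj_id}")
                continue
            store.execute(
                "INSERT OR IGNORE INTO cvterm_relationship (subject_id,"
                " type_id, object_id) VALUES (?,?,?)",
                (subject.cvterm_id, predicate.cvterm_id, obj.cvterm_id))
    report.elapsed = watch.elapsed()
    return report


def resolve_term(store: StoreHandle, key: str,
                 vocabulary: str | None = None,
                 include_obsolete: bool = False) -> Term:
    """Resolve an accession (``SO:0000704``) or a name (``gene``) to a term.

    Accession lookup is exact and includes alternate ids; name lookup is
    exact within the given vocabulary.  Obsolete terms are excluded unless
    explicitly requested.  Raises :class:`MissingTermError` with a hint to
    load the ontology first when nothing matches.
    """
    term = None
    if ":" in key:
        term = store.find_term_by_accession(key, include_obsolete)
    if term is None:
        term = store.find_term(key, vocabulary, include_obsolete)
    if term is None:
        where = f" in vocabulary {vocabulary!r}" if vocabulary else ""
        raise MissingTermError(
            key, f"no such term{where}; load the ontology that defines it "
                 "first (load-ontology)")
    return term


def ancestors(store: StoreHandle, term: Term | str,
              predicates: set[str] | None = None) -> set[Term]:
    """Exact transitive closure of ``term`` over the chosen predicates.

    The term itself is excluded.  A cycle in the traversed subgraph aborts
    with :class:`OntologyCycleError` naming one member (OBO is_a graphs are
    DAGs; a cycle means corrupt input and silent looping would hide it).
    """
    if predicates is None:
        predicates = {"is_a"}
    if isinstance(term, str):
        term = resolve_term(store, term)
    pred_ids = []
    for name in sorted(predicates):
        row = store.execute(
            "SELECT cvterm_id FROM cvterm WHERE name=? AND"
            " is_relationship_type=1", (name,)).fetchone()
        if row is None:
            raise NotFoundError(f"unknown relationship predicate {name!r}")
        pred_ids.append(row[0])
    placeholders = ",".join("?" * len(pred_ids))
    sql = (f"SELECT object_id FROM cvterm_relationship WHERE subject_id=?"
           f" AND type_id IN ({placeholders})")

    closure: set[int] = set()
    # iterative DFS with a gray (on-stack) set for cycle detection
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[int, int] = {}
    stack: list[tuple[int, bool]] = [(term.cvterm_id, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            color[node] = BLACK
            continue
        state = color.get(node, WHITE)
        if state == BLACK:
            continue
        if state == GRAY:
            continue
        color[node] = GRAY
        stack.append((node, True))
        for (child,) in store.execute(sql, (node, *pred_ids)):
            child_state = color.get(child, WHITE)
            if child_state == GRAY:
                raise OntologyCycleError(store.term_by_id(child).name)
            if child_state == WHITE:
                stack.append((child, False))
            closure.add(child)
    closure.discard(term.cvterm_id)
    return {store.term_by_id(cid) for cid in closure}
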