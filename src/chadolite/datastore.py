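"""Embedded relational store mirroring the Chado 1.31 subset used by the loaders.

The store is a single SQLite file whose table and column names follow the
GMOD Chado schema (cv, cvterm, organism, feature, featureloc, ...), so that
in principle the same queries run against a real, already-populated Chado
instance.  Semantics are append-only: loaders insert inside one transaction
and never update or delete, so referential integrity cannot be broken after
the fact.

Every loader in the sibling modules returns a :class:`LoadReport` and obeys a
duplicate policy (``"error"`` aborts the whole load, ``"skip"`` counts the
record as skipped).
"""

from __future__ import annotations

import contextlib
import datetime
import re
import sqlite3
import time
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------


class ChadoError(Exception):
    """Base class for all store and loader errors."""


class SchemaMismatchError(ChadoError):
    """An existing database is not compatible with the expected schema."""

    def __init__(self, missing_table: str):
        self.missing_table = missing_table
        super().__init__(
            f"existing database is not schema-compatible: missing table "
            f"{missing_table!r}"
        )


class DuplicateRecordError(ChadoError):
    """A uniqueness key was violated under the default 'error' policy."""


class MissingTermError(ChadoError):
    """A controlled-vocabulary term could not be resolved.

    Carries a hint naming which ontology load must happen first, enforcing
    the required load order.
    """

    def __init__(self, key: str, hint: str = "load the required ontology first "
                 "(load-ontology)"):
        self.key = key
        super().__init__(f"term {key!r} not found; {hint}")


class LoadOrderError(ChadoError):
    """Prerequisite data for a loader is absent.

    The message names the command that must run first so batch pipelines can
    be corrected without guesswork.
    """

    def __init__(self, message: str, required_command: str):
        self.required_command = required_command
        super().__init__(f"{message} (run {required_command} first)")


class AmbiguousFeatureError(ChadoError):
    """A uniquename matches features of several types and no type was given."""

    def __init__(self, uniquename: str, types: Sequence[str]):
        self.uniquename = uniquename
        self.candidate_types = sorted(types)
        super().__init__(
            f"feature {uniquename!r} is ambiguous: candidate types "
            f"{self.candidate_types}; pass type_name to disambiguate"
        )


class NotFoundError(ChadoError):
    """A referenced entity does not exist in the store."""


class FormatError(ChadoError):
    """An input file does not follow the required dialect."""


class OntologyCycleError(ChadoError):
    """A relationship closure hit a cycle in the term graph."""

    def __init__(self, member: str):
        self.member = member
        super().__init__(f"cycle detected in term graph involving {member!r}")


class ExportError(ChadoError):
    """A feature cannot be exported (no residues and no resolvable location)."""


# --------------------------------------------------------------------------
# Report & domain records
# --------------------------------------------------------------------------


@dataclass
class LoadReport:
    """Uniform result of every loader.

    For record-per-entity loaders ``created + skipped + len(errors)``
    equals ``records_seen``.
    """

    records_seen: int = 0
    created: int = 0
    skipped: int = 0
    errors: list[tuple[int, str]] = field(default_factory=list)
    elapsed: float = 0.0

    def add_error(self, lineno: int, message: str) -> None:
        self.errors.append((lineno, message))


@dataclass(frozen=True)
class Organism:
    organism_id: int
    genus: str
    species: str
    infraspecific_name: str = ""
    abbreviation: str | None = None
    common_name: str | None = None

    @property
    def label(self) -> str:
        parts = [self.genus, self.species]
        if self.infraspecific_name:
            parts.append(self.infraspecific_name)
        return " ".join(parts)


@dataclass(frozen=True)
class Term:
    cvterm_id: int
    vocabulary: str
    name: str
    accession: str | None = None
    definition: str | None = None
    is_obsolete: bool = False
    is_relationship_type: bool = False


@dataclass(frozen=True)
class Feature:
    feature_id: int
    organism_id: int
    uniquename: str
    name: str | None
    type_name: str
    residues: str | None = None
    seqlen: int = 0
    checksum: str | None = None
    is_obsolete: bool = False


@dataclass(frozen=True)
class FeatureLocation:
    feature_id: int
    srcfeature_id: int
    fmin: int
    fmax: int
    strand: int
    phase: int | None
    rank: int


CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.]*:\S+$")

#: tables the other modules rely on; schema compatibility is checked against
#: this list when an existing file is opened.
REQUIRED_TABLES = (
    "db",
    "dbxref",
    "cv",
    "cvterm",
    "cvterm_dbxref",
    "cvtermsynonym",
    "cvterm_relationship",
    "organism",
    "feature",
    "featureloc",
    "feature_relationship",
    "featureprop",
    "feature_cvterm",
    "feature_dbxref",
    "analysis",
    "analysisfeature",
    "pub",
    "feature_pub",
    "assay",
    "expression_value",
)

_SCHEMA = """
CREATE TABLE IF NOT EXISTS db (
    db_id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE
);
CREATE TABLE IF NOT EXISTS dbxref (
    dbxref_id INTEGER PRIMARY KEY,
    db_id INTEGER NOT NULL REFERENCES db(db_id),
    accession TEXT NOT NULL,
    UNIQUE (db_id, accession)
);
CREATE TABLE IF NOT EXISTS cv (
    cv_id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE
);
CREATE TABLE IF NOT EXISTS cvterm (
    cvterm_id INTEGER PRIMARY KEY,
    cv_id INTEGER NOT NULL REFERENCES cv(cv_id),
    name TEXT NOT NULL,
    definition TEXT,
    dbxref_id INTEGER REFERENCES dbxref(dbxref_id),
    is_obsolete INTEGER NOT NULL DEFAULT 0,
    is_relationship_type INTEGER NOT NULL DEFAULT 0,
    UNIQUE (cv_id, name)
);
CREATE TABLE IF NOT EXISTS cvterm_dbxref (
    cvterm_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
    dbxref_id INTEGER NOT NULL REFERENCES dbxref(dbxref_id),
    UNIQUE (cvterm_id, dbxref_id)
);
CREATE TABLE IF NOT EXISTS cvtermsynonym (
    cvterm_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
    synonym TEXT NOT NULL,
    UNIQUE (cvterm_id, synonym)
);
CREATE TABLE IF NOT EXISTS cvterm_relationship (
    cvterm_relationship_id INTEGER PRIMARY KEY,
    subject_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
    type_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
    object_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
    UNIQUE (subject_id, type_id, object_id)
);
CREATE TABLE IF NOT EXISTS organism (
    organism_id INTEGER PRIMARY KEY,
    genus TEXT NOT NULL,
    species TEXT NOT NULL,
    infraspecific_name TEXT NOT NULL DEFAULT '',
    abbreviation TEXT,
    common_name TEXT,
    UNIQUE (genus, species, infraspecific_name)
);
CREATE TABLE IF NOT EXISTS feature (
    feature_id INTEGER PRIMARY KEY,
    organism_id INTEGER NOT NULL REFERENCES organism(organism_id),
    uniquename TEXT NOT NULL,
    name TEXT,
    type_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
    residues TEXT,
    seqlen INTEGER NOT NULL DEFAULT 0,
    md5checksum TEXT,
    is_obsolete INTEGER NOT NULL DEFAULT 0,
    UNIQUE (organism_id, uniquename, type_id)
);
CREATE INDEX IF NOT EXISTS feature_uniquename_idx ON feature(uniquename);
CREATE TABLE IF NOT EXISTS featureloc (
    featureloc_id INTEGER PRIMARY KEY,
    feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
    srcfeature_id INTEGER NOT NULL REFERENCES feature(feature_id),
    fmin INTEGER NOT NULL CHECK (fmin >= 0),
    fmax INTEGER NOT NULL,
    strand INTEGER NOT NULL DEFAULT 0,
    phase INTEGER,
    rank INTEGER NOT NULL DEFAULT 0,
    UNIQUE (feature_id, rank),
    CHECK (fmin <= fmax)
);
CREATE INDEX IF NOT EXISTS featureloc_src_idx
    ON featureloc(srcfeature_id, fmin, fmax);
CREATE TABLE IF NOT EXISTS feature_relationship (
    feature_relationship_id INTEGER PRIMARY KEY,
    subject_id INTEGER NOT NULL REFERENCES feature(feature_id),
    type_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
    object_id INTEGER NOT NULL REFERENCES feature(feature_id),
    UNIQUE (subject_id, type_id, object_id),
    CHECK (subject_id != object_id)
);
CREATE TABLE IF NOT EXISTS featureprop (
    featureprop_id INTEGER PRIMARY KEY,
    feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
    type_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
    value TEXT NOT NULL,
    rank INTEGER NOT NULL DEFAULT 0,
    UNIQUE (feature_id, type_id, rank)
);
CREATE TABLE IF NOT EXISTS feature_cvterm (
    feature_cvterm_id INTEGER PRIMARY KEY,
    feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
    cvterm_id INTEGER NOT NULL REFERENCES cvterm(cvterm_id),
    pub_id INTEGER REFERENCES pub(pub_id),
    evidence TEXT,
    UNIQUE (feature_id, cvterm_id)
);
CREATE TABLE IF NOT EXISTS feature_dbxref (
    feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
    dbxref_id INTEGER NOT NULL REFERENCES dbxref(dbxref_id),
    UNIQUE (feature_id, dbxref_id)
);
CREATE TABLE IF NOT EXISTS analysis (
    analysis_id INTEGER PRIMARY KEY,
    program TEXT NOT NULL,
    programversion TEXT NOT NULL,
    sourcename TEXT NOT NULL,
    algorithm TEXT,
    timeexecuted TEXT NOT NULL,
    UNIQUE (program, programversion, sourcename)
);
CREATE TABLE IF NOT EXISTS analysisfeature (
    analysisfeature_id INTEGER PRIMARY KEY,
    analysis_id INTEGER NOT NULL REFERENCES analysis(analysis_id),
    feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
    rawscore REAL,
    normscore REAL,
    significance REAL CHECK (significance IS NULL OR significance >= 0),
    identity REAL CHECK (identity IS NULL OR (identity >= 0 AND identity <= 100)),
    UNIQUE (analysis_id, feature_id)
);
CREATE TABLE IF NOT EXISTS pub (
    pub_id INTEGER PRIMARY KEY,
    uniquename TEXT NOT NULL UNIQUE,
    title TEXT,
    authors TEXT,
    pyear INTEGER,
    doi TEXT
);
CREATE TABLE IF NOT EXISTS feature_pub (
    feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
    pub_id INTEGER NOT NULL REFERENCES pub(pub_id),
    UNIQUE (feature_id, pub_id)
);
CREATE TABLE IF NOT EXISTS assay (
    assay_id INTEGER PRIMARY KEY,
    name TEXT NOT NULL UNIQUE,
    biomaterial TEXT NOT NULL,
    treatment TEXT NOT NULL
);
CREATE TABLE IF NOT EXISTS expression_value (
    feature_id INTEGER NOT NULL REFERENCES feature(feature_id),
    assay_id INTEGER NOT NULL REFERENCES assay(assay_id),
    value REAL NOT NULL CHECK (value >= 0),
    UNIQUE (feature_id, assay_id)
);
"""

#: minimal vocabulary seeded at initialization so that loaders relying on
#: relationship predicates and standard property types can run before the
#: full relations ontology is loaded; a later ontology load upserts onto
#: these rows.
BOOTSTRAP_TERMS = {
    "relationship": ("is_a", "part_of", "derives_from", "translation_of"),
    "feature_property": ("description", "orthologous group",
                         "coexpression group"),
}

_STATS_TABLES = {
    "vocabularies": "cv",
    "terms": "cvterm",
    "term_relationships": "cvterm_relationship",
    "organisms": "organism",
    "features": "feature",
    "feature_locations": "featureloc",
    "feature_relationships": "feature_relationship",
    "feature_properties": "featureprop",
    "feature_term_assignments": "feature_cvterm",
    "analyses": "analysis",
    "analysis_scores": "analysisfeature",
    "publications": "pub",
    "assays": "assay",
    "expression_values": "expression_value",
}


class StoreHandle:
    """Connection to an embedded Chado-subset database.

    Use :func:`initialize_store` to obtain one; it creates the schema on a
    fresh file and validates compatibility when the file already exists.
    """

    def __init__(self, conn: sqlite3.Connection, location: str):
        self.conn = conn
        self.location = location
        self._term_cache: dict[int, Term] = {}

    # -- plumbing ----------------------------------------------------------

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "StoreHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @contextlib.contextmanager
    def transaction(self) -> Iterator[sqlite3.Connection]:
        """All loader writes happen inside one transaction: a failed load
        rolls back and leaves the store unchanged."""
        try:
            yield self.conn
        except BaseException:
            self.conn.rollback()
            raise
        else:
            self.conn.commit()

    def execute(self, sql: str, params: Sequence = ()) -> sqlite3.Cursor:
        return self.conn.execute(sql, params)

    # -- vocabulary helpers ------------------------------------------------

    def get_or_create_cv(self, name: str) -> int:
        if not name:
            raise FormatError("vocabulary name must be non-empty")
        row = self.execute("SELECT cv_id FROM cv WHERE name=?", (name,)).fetchone()
        if row:
            return row[0]
        return self.execute("INSERT INTO cv (name) VALUES (?)", (name,)).lastrowid

    def get_or_create_dbxref(self, accession: str) -> int:
        """Accessions are CURIEs like ``SO:0000704``; the prefix becomes the db."""
        if not CURIE_RE.match(accession):
            raise FormatError(f"accession {accession!r} is not PREFIX:ID shaped")
        prefix, local = accession.split(":", 1)
        row = self.execute("SELECT db_id FROM db WHERE name=?", (prefix,)).fetchone()
        db_id = row[0] if row else self.execute(
            "INSERT INTO db (name) VALUES (?)", (prefix,)).lastrowid
        row = self.execute(
            "SELECT dbxref_id FROM dbxref WHERE db_id=? AND accession=?",
            (db_id, local)).fetchone()
        if row:
            return row[0]
        return self.execute(
            "INSERT INTO dbxref (db_id, accession) VALUES (?,?)",
            (db_id, local)).lastrowid

    def _term_from_row(self, row: sqlite3.Row) -> Term:
        return Term(
            cvterm_id=row["cvterm_id"],
            vocabulary=row["cv_name"],
            name=row["name"],
            accession=(f"{row['db_name']}:{row['accession']}"
                       if row["accession"] is not None else None),
            definition=row["definition"],
            is_obsolete=bool(row["is_obsolete"]),
            is_relationship_type=bool(row["is_relationship_type"]),
        )

    _TERM_SELECT = """
        SELECT cvterm.cvterm_id, cv.name AS cv_name, cvterm.name,
               cvterm.definition, cvterm.is_obsolete,
               cvterm.is_relationship_type,
               db.name AS db_name, dbxref.accession
        FROM cvterm
        JOIN cv USING (cv_id)
        LEFT JOIN dbxref ON cvterm.dbxref_id = dbxref.dbxref_id
        LEFT JOIN db ON dbxref.db_id = db.db_id
    """

    def term_by_id(self, cvterm_id: int) -> Term:
        cached = self._term_cache.get(cvterm_id)
        if cached is not None:
            return cached
        row = self.execute(
            self._TERM_SELECT + " WHERE cvterm.cvterm_id=?", (cvterm_id,)
        ).fetchone()
        if row is None:
            raise NotFoundError(f"no cvterm with id {cvterm_id}")
        term = self._term_from_row(row)
        self._term_cache[cvterm_id] = term
        return term

    def find_term(self, name: str, vocabulary: str | None = None,
                  include_obsolete: bool = False) -> Term | None:
        """Exact name lookup, optionally restricted to one vocabulary."""
        sql = self._TERM_SELECT + " WHERE cvterm.name=?"
        params: list = [name]
        if vocabulary is not None:
            sql += " AND cv.name=?"
            params.append(vocabulary)
        if not include_obsolete:
            sql += " AND cvterm.is_obsolete=0"
        rows = self.execute(sql, params).fetchall()
        if not rows:
            return None
        if len(rows) > 1:
            raise AmbiguousFeatureError(
                name, [r["cv_name"] for r in rows])
        return self._term_from_row(rows[0])

    def find_term_by_accession(self, accession: str,
                               include_obsolete: bool = False) -> Term | None:
        if ":" not in accession:
            return None
        prefix, local = accession.split(":", 1)
        sql = self._TERM_SELECT + """
            WHERE cvterm.cvterm_id IN (
                SELECT cvterm.cvterm_id FROM cvterm
                JOIN dbxref ON cvterm.dbxref_id = dbxref.dbxref_id
                JOIN db ON dbxref.db_id = db.db_id
                WHERE db.name=? AND dbxref.accession=?
                UNION
                SELECT cvterm_dbxref.cvterm_id FROM cvterm_dbxref
                JOIN dbxref ON cvterm_dbxref.dbxref_id = dbxref.dbxref_id
                JOIN db ON dbxref.db_id = db.db_id
                WHERE db.name=? AND dbxref.accession=?
            )
        """
        params = [prefix, local, prefix, local]
        if not include_obsolete:
            sql += " AND cvterm.is_obsolete=0"
        rows = self.execute(sql, params).fetchall()
        return self._term_from_row(rows[0]) if rows else None

    def upsert_term(self, vocabulary: str, name: str,
                    accession: str | None = None,
                    definition: str | None = None,
                    is_obsolete: bool = False,
                    is_relationship_type: bool = False) -> tuple[Term, bool]:
        """Insert a term, or update the existing (vocabulary, name) row in
        place (used when a real ontology refines a bootstrap term).

        Returns (term, created_flag).
        """
        cv_id = self.get_or_create_cv(vocabulary)
        dbxref_id = self.get_or_create_dbxref(accession) if accession else None
        row = self.execute(
            "SELECT cvterm_id FROM cvterm WHERE cv_id=? AND name=?",
            (cv_id, name)).fetchone()
        if row:
            cvterm_id = row[0]
            self.execute(
                "UPDATE cvterm SET definition=COALESCE(?, definition),"
                " dbxref_id=COALESCE(?, dbxref_id), is_obsolete=?,"
                " is_relationship_type=MAX(is_relationship_type, ?)"
                " WHERE cvterm_id=?",
                (definition, dbxref_id, int(is_obsolete),
                 int(is_relationship_type), cvterm_id))
            self._term_cache.pop(cvterm_id, None)
            return self.term_by_id(cvterm_id), False
        cvterm_id = self.execute(
            "INSERT INTO cvterm (cv_id, name, definition, dbxref_id,"
            " is_obsolete, is_relationship_type) VALUES (?,?,?,?,?,?)",
            (cv_id, name, definition, dbxref_id, int(is_obsolete),
             int(is_relationship_type))).lastrowid
        return self.term_by_id(cvterm_id), True

    def property_type(self, name: str) -> Term:
        """Auto-created property-type terms live in the feature_property cv."""
        term = self.find_term(name, "feature_property")
        if term is None:
            term, _ = self.upsert_term("feature_property", name)
        return term

    # -- organisms ---------------------------------------------------------

    def add_organism(self, genus: str, species: str,
                     infraspecific_name: str = "",
                     abbreviation: str | None = None,
                     common_name: str | None = None) -> Organism:
        try:
            oid = self.execute(
                "INSERT INTO organism (genus, species, infraspecific_name,"
                " abbreviation, common_name) VALUES (?,?,?,?,?)",
                (genus, species, infraspecific_name, abbreviation,
                 common_name)).lastrowid
        except sqlite3.IntegrityError as exc:
            raise DuplicateRecordError(
                f"organism {genus} {species} already registered") from exc
        self.conn.commit()
        return Organism(oid, genus, species, infraspecific_name,
                        abbreviation, common_name)

    def get_organism(self, key: "Organism | str") -> Organism:
        if isinstance(key, Organism):
            return key
        row = self.execute(
            "SELECT * FROM organism WHERE abbreviation=? OR common_name=?"
            " OR genus || ' ' || species = ?"
            " OR TRIM(genus || ' ' || species || ' ' || infraspecific_name) = ?",
            (key, key, key, key)).fetchone()
        if row is None:
            raise NotFoundError(
                f"organism {key!r} not registered (run load-organism first)")
        return Organism(row["organism_id"], row["genus"], row["species"],
                        row["infraspecific_name"], row["abbreviation"],
                        row["common_name"])

    # -- features ----------------------------------------------------------

    def _feature_from_row(self, row: sqlite3.Row) -> Feature:
        return Feature(
            feature_id=row["feature_id"],
            organism_id=row["organism_id"],
            uniquename=row["uniquename"],
            name=row["name"],
            type_name=self.term_by_id(row["type_id"]).name,
            residues=row["residues"],
            seqlen=row["seqlen"],
            checksum=row["md5checksum"],
            is_obsolete=bool(row["is_obsolete"]),
        )

    def feature_by_id(self, feature_id: int) -> Feature:
        row = self.execute(
            "SELECT * FROM feature WHERE feature_id=?", (feature_id,)).fetchone()
        if row is None:
            raise NotFoundError(f"no feature with id {feature_id}")
        return self._feature_from_row(row)

    def insert_feature(self, organism: Organism, uniquename: str,
                       type_term: Term, name: str | None = None,
                       residues: str | None = None,
                       checksum: str | None = None) -> Feature:
        seqlen = len(residues) if residues is not None else 0
        try:
            fid = self.execute(
                "INSERT INTO feature (organism_id, uniquename, name, type_id,"
                " residues, seqlen, md5checksum) VALUES (?,?,?,?,?,?,?)",
                (organism.organism_id, uniquename, name,
                 type_term.cvterm_id, residues, seqlen, checksum)).lastrowid
        except sqlite3.IntegrityError as exc:
            raise DuplicateRecordError(
                f"feature ({organism.label!r}, {uniquename!r},"
                f" {type_term.name!r}) already exists") from exc
        return self.feature_by_id(fid)


# --------------------------------------------------------------------------
# Module operations
# --------------------------------------------------------------------------


def initialize_store(location: str) -> StoreHandle:
    """Open or create an embedded store at ``location``.

    Idempotent on an existing store: a populated, schema-compatible file is
    opened without modification.  An existing file missing a required table
    raises :class:`SchemaMismatchError` naming the first missing table.
    """
    import os

    existing = os.path.exists(location) and os.path.getsize(location) > 0
    conn = sqlite3.connect(location)
    conn.row_factory = sqlite3.Row
    conn.execute("PRAGMA foreign_keys = ON")
    store = StoreHandle(conn, str(location))
    if existing:
        present = {r[0] for r in conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table'")}
        for table in REQUIRED_TABLES:
            if table not in present:
                conn.close()
                raise SchemaMismatchError(table)
        return store
    conn.executescript(_SCHEMA)
    for cv_name, names in BOOTSTRAP_TERMS.items():
        for name in names:
            store.upsert_term(cv_name, name,
                              is_relationship_type=(cv_name == "relationship"))
    conn.commit()
    return store


def stats(store: StoreHandle) -> dict[str, int]:
    """Exact table cardinalities at call time, keyed by entity name."""
    return {
        entity: store.execute(f"SELECT COUNT(*) FROM {table}").fetchone()[0]
        for entity, table in _STATS_TABLES.items()
    }


def get_feature(store: StoreHandle, organism: "Organism | str",
                uniquename: str,
                type_name: str | None = None) -> Feature | None:
    """Look up the unique feature for (organism, uniquename, type).

    When ``type_name`` is omitted and several types share the uniquename an
    :class:`AmbiguousFeatureError` lists the candidate types.
    """
    org = store.get_organism(organism)
    sql = "SELECT * FROM feature WHERE organism_id=? AND uniquename=?"
    params: list = [org.organism_id, uniquename]
    if type_name is not None:
        sql += (" AND type_id IN (SELECT cvterm_id FROM cvterm WHERE name=?)")
        params.append(type_name)
    rows = store.execute(sql, params).fetchall()
    if not rows:
        return None
    if len(rows) > 1:
        types = [store.term_by_id(r["type_id"]).name for r in rows]
        raise AmbiguousFeatureError(uniquename, types)
    return store._feature_from_row(rows[0])


def now_iso() -> str:
    return datetime.datetime.now(datetime.timezone.utc).isoformat()


class Stopwatch:
    """Fills LoadReport.elapsed."""

    def __init__(self) -> None:
        self.t0 = time.monotonic()

    def elapsed(self) -> float:
        return time.monotonic() - self.t0
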