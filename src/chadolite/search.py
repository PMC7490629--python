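"""In-process keyword search over the feature store.

A denormalized document is built for every gene, mRNA and polypeptide (the
indexable types shown on result pages).  The index supports the same
contracts as a faceted search service: a single query box with AND
semantics over tokens (each token matches an indexed keyword exactly or as
a prefix), prefix autocomplete over the extracted keyword set, and facet
counts for organism, type, orthology, coexpression, annotation (GO
namespaces), expression biomaterial and expression treatment.

Rebuilding the index is always authoritative: it is a pure function of
store state and can be persisted to a JSON file beside the store.
"""

from __future__ import annotations

import json
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field, asdict

from .datastore import StoreHandle

__all__ = [
    "SearchDocument", "SearchResultPage", "IndexReport", "SearchIndex",
    "build_index", "autocomplete", "search", "FACET_DIMENSIONS",
    "INDEXABLE_TYPES",
]

INDEXABLE_TYPES = ("gene", "mRNA", "polypeptide")

FACET_DIMENSIONS = ("organism", "type", "orthology", "coexpression",
                    "annotation", "biomaterial", "treatment")

_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")
_MIN_TOKEN_LEN = 2


def tokenize(text: str) -> list[str]:
    """Lowercase, split on non-alphanumerics, keep tokens of length >= 2."""
    return [tok for tok in _TOKEN_SPLIT.split(text.lower())
            if len(tok) >= _MIN_TOKEN_LEN]


@dataclass
class SearchDocument:
    """Denormalized per-feature index record."""

    key: str                      # uniquename
    feature_id: int
    organism: str
    type: str
    display_name: str
    text: str                     # name, uniquename, descriptions, GO names,
    #                               similarity-hit descriptions
    orthology: bool = False
    coexpression: bool = False
    annotation: list[str] = field(default_factory=list)   # GO namespaces
    biomaterials: list[str] = field(default_factory=list)
    treatments: list[str] = field(default_factory=list)
    token_counts: dict[str, int] = field(default_factory=dict)

    def facet_values(self, dimension: str) -> list:
        if dimension == "organism":
            return [self.organism]
        if dimension == "type":
            return [self.type]
        if dimension == "orthology":
            return [self.orthology]
        if dimension == "coexpression":
            return [self.coexpression]
        if dimension == "annotation":
            return list(self.annotation)
        if dimension == "biomaterial":
            return list(self.biomaterials)
        if dimension == "treatment":
            return list(self.treatments)
        raise KeyError(f"unknown facet dimension {dimension!r}; valid: "
                       f"{FACET_DIMENSIONS}")


@dataclass
class IndexReport:
    documents: int = 0
    keywords: int = 0
    elapsed: float = 0.0


@dataclass
class SearchResultPage:
    total: int
    page: int
    page_size: int
    rows: list[SearchDocument]
    facets: dict[str, dict]


class SearchIndex:
    """Documents plus an inverted keyword index.

    ``keywords`` maps token -> document frequency; ``postings`` maps
    token -> {document position -> term frequency}.
    """

    def __init__(self, documents: list[SearchDocument]):
        self.documents = documents
        self.postings: dict[str, dict[int, int]] = defaultdict(dict)
        for pos, doc in enumerate(documents):
            for token, count in doc.token_counts.items():
                self.postings[token][pos] = count
        self.keywords: dict[str, int] = {
            token: len(posting) for token, posting in self.postings.items()
        }
        self.sorted_keywords = sorted(self.keywords)
        self.report = IndexReport(documents=len(documents),
                                  keywords=len(self.keywords))

    # -- persistence -------------------------------------------------------

    def save(self, path: str) -> None:
        payload = {"documents": [asdict(d) for d in self.documents]}
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "SearchIndex":
        with open(path) as fh:
            payload = json.load(fh)
        return cls([SearchDocument(**d) for d in payload["documents"]])

    def __eq__(self, other) -> bool:
        return (isinstance(other, SearchIndex)
                and self.documents == other.documents)


def _document_for(store: StoreHandle, row, organisms: dict[int, str],
                  type_names: dict[int, str]) -> SearchDocument:
    fid = row["feature_id"]
    text_parts = [row["uniquename"]]
    if row["name"]:
        text_parts.append(row["name"])
    orthology = coexpression = False
    for prop in store.execute(
            "SELECT type_id, value FROM featureprop WHERE feature_id=?",
            (fid,)):
        type_name = type_names.get(prop["type_id"]) or \
            store.term_by_id(prop["type_id"]).name
        if type_name == "orthologous group":
            orthology = True
        elif type_name == "coexpression group":
            coexpression = True
        else:
            text_parts.append(prop["value"])
    namespaces = []
    for assignment in store.execute(
            "SELECT cvterm_id FROM feature_cvterm WHERE feature_id=?",
            (fid,)):
        term = store.term_by_id(assignment["cvterm_id"])
        text_parts.append(term.name)
        if term.vocabulary not in namespaces:
            namespaces.append(term.vocabulary)
    # descriptions of similarity hits located on this feature
    for hit in store.execute(
            "SELECT fp.value FROM featureloc fl"
            " JOIN featureprop fp ON fp.feature_id = fl.feature_id"
            " WHERE fl.srcfeature_id=? AND fp.type_id IN"
            " (SELECT cvterm_id FROM cvterm WHERE name IN"
            "  ('description', 'match subject'))", (fid,)):
        text_parts.append(hit["value"])
    biomaterials: list[str] = []
    treatments: list[str] = []
    for assay in store.execute(
            "SELECT DISTINCT a.biomaterial, a.treatment FROM"
            " expression_value ev JOIN assay a USING (assay_id)"
            " WHERE ev.feature_id=? ORDER BY a.biomaterial, a.treatment",
            (fid,)):
        if assay["biomaterial"] not in biomaterials:
            biomaterials.append(assay["biomaterial"])
        if assay["treatment"] not in treatments:
            treatments.append(assay["treatment"])
    text = " ".join(text_parts)
    return SearchDocument(
        key=row["uniquename"],
        feature_id=fid,
        organism=organisms[row["organism_id"]],
        type=type_names[row["type_id"]],
        display_name=row["name"] or row["uniquename"],
        text=text,
        orthology=orthology,
        coexpression=coexpression,
        annotation=sorted(namespaces),
        biomaterials=biomaterials,
        treatments=treatments,
        token_counts=dict(Counter(tokenize(text))),
    )


def build_index(store: StoreHandle) -> SearchIndex:
    """Build the search index from store state (the index command).

    Deterministic: documents are ordered by (organism, uniquename, type),
    so rebuilding on an unchanged store yields an identical index.  The
    build report (documents, keywords) is available as ``index.report``.
    """
    from .datastore import Stopwatch
    watch = Stopwatch()
    organisms = {
        row["organism_id"]:
            f"{row['genus']} {row['species']}".strip()
        for row in store.execute("SELECT * FROM organism")
    }
    type_names = {row["cvterm_id"]: row["name"]
                  for row in store.execute("SELECT cvterm_id, name FROM cvterm")}
    placeholders = ",".join("?" * len(INDEXABLE_TYPES))
    rows = store.execute(
        f"SELECT f.* FROM feature f JOIN cvterm t ON f.type_id=t.cvterm_id"
        f" WHERE t.name IN ({placeholders}) AND t.cv_id ="
        f" (SELECT cv_id FROM cv WHERE name='sequence')"
        f" ORDER BY f.organism_id, f.uniquename, t.name",
        INDEXABLE_TYPES).fetchall()
    documents = [_document_for(store, row, organisms, type_names)
                 for row in rows]
    index = SearchIndex(documents)
    index.report.elapsed = watch.elapsed()
    return index


def autocomplete(index: SearchIndex, prefix: str,
                 limit: int = 10) -> list[str]:
    """All indexed keywords with the case-folded prefix, ranked by
    document frequency (descending) then lexicographically."""
    if not prefix:
        raise ValueError("prefix must be at least one character")
    prefix = prefix.lower()
    hits = [kw for kw in index.sorted_keywords if kw.startswith(prefix)]
    hits.sort(key=lambda kw: (-index.keywords[kw], kw))
    return hits[:limit]


def _matching_positions(index: SearchIndex, token: str) -> dict[int, int]:
    """Documents matching one query token (exact keyword or prefix),
    with summed term frequencies."""
    scores: dict[int, int] = defaultdict(int)
    for keyword in index.sorted_keywords:
        if keyword == token or keyword.startswith(token):
            for pos, count in index.postings[keyword].items():
                scores[pos] += count
    return scores


def _query_match(index: SearchIndex, query: str) -> dict[int, int]:
    tokens = tokenize(query)
    if not tokens:
        return {pos: 0 for pos in range(len(index.documents))}
    per_token = [_matching_positions(index, tok) for tok in tokens]
    common = set(per_token[0])
    for scores in per_token[1:]:
        common &= set(scores)
    return {pos: sum(scores[pos] for scores in per_token) for pos in common}


def _normalize_filter_values(dimension: str, values) -> set:
    if not isinstance(values, (list, tuple, set)):
        values = [values]
    if dimension in ("orthology", "coexpression"):
        out = set()
        for v in values:
            if isinstance(v, str):
                out.add(v.strip().lower() in ("true", "yes", "1"))
            else:
                out.add(bool(v))
        return out
    return set(values)


def _passes(doc: SearchDocument, dimension: str, wanted: set) -> bool:
    return any(v in wanted for v in doc.facet_values(dimension))


def search(index: SearchIndex, query: str = "",
           filters: dict | None = None, page: int = 1,
           page_size: int = 25) -> SearchResultPage:
    """Keyword search with faceted filtering and stable pagination.

    A document matches when every query token matches (exact keyword or
    keyword prefix); an empty query matches everything, so filters alone
    can drive the result.  Facet counts for each dimension are computed on
    the query match set with all OTHER dimensions' filters applied
    (standard faceted navigation).  Rows are ordered by match score (sum
    of term frequencies) descending, then uniquename; pages are 1-based.
    """
    filters = filters or {}
    for dimension in filters:
        if dimension not in FACET_DIMENSIONS:
            raise KeyError(f"unknown facet dimension {dimension!r}; valid: "
                           f"{FACET_DIMENSIONS}")
    normalized = {dim: _normalize_filter_values(dim, vals)
                  for dim, vals in filters.items()}
    scores = _query_match(index, query)

    def apply_filters(positions, skip_dimension=None):
        out = []
        for pos in positions:
            doc = index.documents[pos]
            if all(_passes(doc, dim, wanted)
                   for dim, wanted in normalized.items()
                   if dim != skip_dimension):
                out.append(pos)
        return out

    kept = apply_filters(scores)
    facets: dict[str, dict] = {}
    for dimension in FACET_DIMENSIONS:
        counter: Counter = Counter()
        for pos in apply_filters(scores, skip_dimension=dimension):
            for value in index.documents[pos].facet_values(dimension):
                counter[value] += 1
        facets[dimension] = dict(counter)

    ordered = sorted(kept, key=lambda pos: (-scores[pos],
                                            index.documents[pos].key))
    lo = (page - 1) * page_size
    rows = [index.documents[pos] for pos in ordered[lo:lo + page_size]]
    return SearchResultPage(total=len(ordered), page=page,
                            page_size=page_size, rows=rows, facets=facets)
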