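"""Read-side data contracts: feature pages, genome-browser region queries,
group membership and sequence/table export.

Everything here is assembled by direct store queries — there is no derived
state — so each section of a feature page can be re-checked against the
tables it came from.  Coordinates stay interbase (0-based, half-open) at
this layer; converting back to 1-based display coordinates is a rendering
concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .datastore import (
    ExportError,
    Feature,
    NotFoundError,
    StoreHandle,
    get_feature,
)

__all__ = [
    "FeatureDetail",
    "RegionFeature",
    "feature_detail",
    "region_query",
    "group_members",
    "export_fasta",
    "export_table",
]


@dataclass
class FeatureDetail:
    """Everything the store knows about one feature, section by section.

    Empty sections are present but empty (collapsible cards)."""

    feature: Feature
    organism: str = ""
    relationships: list[dict] = field(default_factory=list)
    locations: list[dict] = field(default_factory=list)
    properties: list[dict] = field(default_factory=list)
    go_assignments: list[dict] = field(default_factory=list)
    similarity: list[dict] = field(default_factory=list)
    ortholog_group: str | None = None
    coexpression_group: str | None = None
    expression: list[dict] = field(default_factory=list)
    sequence: str | None = None
    publications: list[dict] = field(default_factory=list)

    @property
    def description(self) -> str | None:
        for prop in self.properties:
            if prop["type"] == "description":
                return prop["value"]
        return None


@dataclass
class RegionFeature:
    """One node of a genome-browser region response (interbase coords)."""

    uniquename: str
    type: str
    start: int
    end: int
    strand: int
    phase: int | None
    children: list["RegionFeature"] = field(default_factory=list)

    def flatten(self) -> list["RegionFeature"]:
        out = [self]
        for child in self.children:
            out.extend(child.flatten())
        return out


def _resolve(store: StoreHandle, feature) -> Feature:
    """Accepts a Feature, a feature_id, a uniquename, or a
    (uniquename, type_name) pair for uniquenames shared across types."""
    if isinstance(feature, Feature):
        return feature
    if isinstance(feature, int):
        return store.feature_by_id(feature)
    if isinstance(feature, tuple):
        uniquename, type_name = feature
        rows = store.execute(
            "SELECT * FROM feature WHERE uniquename=? AND type_id IN"
            " (SELECT cvterm_id FROM cvterm WHERE name=?)",
            (uniquename, type_name)).fetchall()
        if not rows:
            raise NotFoundError(
                f"feature {uniquename!r} of type {type_name!r} not found")
        return store._feature_from_row(rows[0])
    rows = store.execute(
        "SELECT * FROM feature WHERE uniquename=?", (feature,)).fetchall()
    if not rows:
        raise NotFoundError(f"feature {feature!r} not found")
    if len(rows) > 1:
        from .datastore import AmbiguousFeatureError
        raise AmbiguousFeatureError(
            feature, [store.term_by_id(r["type_id"]).name for r in rows])
    return store._feature_from_row(rows[0])


def feature_detail(store: StoreHandle, feature) -> FeatureDetail:
    """Assemble the feature-page payload for one feature.

    ``feature`` may be a Feature, a feature_id or a uniquename.
    """
    feat = _resolve(store, feature)
    org = store.execute("SELECT * FROM organism WHERE organism_id=?",
                        (feat.organism_id,)).fetchone()
    detail = FeatureDetail(feature=feat,
                           organism=f"{org['genus']} {org['species']}".strip(),
                           sequence=feat.residues)

    for row in store.execute(
            "SELECT fr.type_id, f.uniquename, f.type_id AS ftype"
            " FROM feature_relationship fr"
            " JOIN feature f ON fr.object_id = f.feature_id"
            " WHERE fr.subject_id=?", (feat.feature_id,)):
        detail.relationships.append({
            "predicate": store.term_by_id(row["type_id"]).name,
            "direction": "out",
            "other": row["uniquename"],
            "other_type": store.term_by_id(row["ftype"]).name,
        })
    for row in store.execute(
            "SELECT fr.type_id, f.uniquename, f.type_id AS ftype"
            " FROM feature_relationship fr"
            " JOIN feature f ON fr.subject_id = f.feature_id"
            " WHERE fr.object_id=?", (feat.feature_id,)):
        detail.relationships.append({
            "predicate": store.term_by_id(row["type_id"]).name,
            "direction": "in",
            "other": row["uniquename"],
            "other_type": store.term_by_id(row["ftype"]).name,
        })

    for row in store.execute(
            "SELECT fl.*, src.uniquename AS src_name FROM featureloc fl"
            " JOIN feature src ON fl.srcfeature_id = src.feature_id"
            " WHERE fl.feature_id=? ORDER BY rank", (feat.feature_id,)):
        detail.locations.append({
            "srcfeature": row["src_name"], "fmin": row["fmin"],
            "fmax": row["fmax"], "strand": row["strand"],
            "phase": row["phase"], "rank": row["rank"],
        })

    for row in store.execute(
            "SELECT type_id, value, rank FROM featureprop WHERE feature_id=?"
            " ORDER BY type_id, rank", (feat.feature_id,)):
        type_name = store.term_by_id(row["type_id"]).name
        entry = {"type": type_name, "value": row["value"]}
        if type_name == "orthologous group" and detail.ortholog_group is None:
            detail.ortholog_group = row["value"]
        elif (type_name == "coexpression group"
              and detail.coexpression_group is None):
            detail.coexpression_group = row["value"]
        else:
            detail.properties.append(entry)

    for row in store.execute(
            "SELECT cvterm_id, evidence, pub_id FROM feature_cvterm"
            " WHERE feature_id=?", (feat.feature_id,)):
        term = store.term_by_id(row["cvterm_id"])
        detail.go_assignments.append({
            "accession": term.accession, "name": term.name,
            "namespace": term.vocabulary, "evidence": row["evidence"],
        })

    # similarity: match features located ON this feature, with their scores
    for row in store.execute(
            "SELECT m.feature_id AS match_id, m.uniquename,"
            " af.rawscore, af.significance, af.identity,"
            " a.program, a.programversion, a.sourcename"
            " FROM featureloc fl"
            " JOIN feature m ON fl.feature_id = m.feature_id"
            " JOIN analysisfeature af ON af.feature_id = m.feature_id"
            " JOIN analysis a ON a.analysis_id = af.analysis_id"
            " WHERE fl.srcfeature_id=? ORDER BY m.uniquename",
            (feat.feature_id,)):
        props = {
            store.term_by_id(p["type_id"]).name: p["value"]
            for p in store.execute(
                "SELECT type_id, value FROM featureprop WHERE feature_id=?",
                (row["match_id"],))
        }
        detail.similarity.append({
            "match": row["uniquename"],
            "program": row["program"],
            "subject": props.get("match subject"),
            "description": props.get("description"),
            "rawscore": row["rawscore"],
            "significance": row["significance"],
            "identity": row["identity"],
        })

    for row in store.execute(
            "SELECT a.name, a.biomaterial, a.treatment, ev.value"
            " FROM expression_value ev JOIN assay a USING (assay_id)"
            " WHERE ev.feature_id=? ORDER BY a.name", (feat.feature_id,)):
        detail.expression.append({
            "assay": row["name"], "biomaterial": row["biomaterial"],
            "treatment": row["treatment"], "value": row["value"],
        })

    for row in store.execute(
            "SELECT p.uniquename, p.title, p.authors, p.pyear, p.doi"
            " FROM feature_pub fp JOIN pub p USING (pub_id)"
            " WHERE fp.feature_id=? ORDER BY p.uniquename",
            (feat.feature_id,)):
        detail.publications.append({
            "citekey": row["uniquename"], "title": row["title"],
            "authors": row["authors"], "year": row["pyear"],
            "doi": row["doi"],
        })
    return detail


def _part_of_children(store: StoreHandle) -> int:
    row = store.execute(
        "SELECT cvterm_id FROM cvterm WHERE name='part_of' AND"
        " is_relationship_type=1").fetchone()
    return row[0] if row else -1


def region_query(store: StoreHandle, srcfeature, start: int, end: int,
                 types: set[str] | None = None) -> list[RegionFeature]:
    """Features overlapping the half-open interbase window [start, end).

    Returns the overlapping top-level features — candidates whose part_of
    parent is not itself a candidate — each carrying its full part_of
    subtree (a genome browser renders a gene model whole even when only
    partially in view).  Touching endpoints do not overlap: the test is
    ``fmin < end AND fmax > start``.  Ordered by fmin then uniquename.
    """
    if start < 0 or start > end:
        raise ValueError(f"invalid window [{start}, {end})")
    src = _resolve(store, srcfeature)
    part_of_id = _part_of_children(store)

    rows = store.execute(
        "SELECT DISTINCT f.feature_id FROM featureloc fl"
        " JOIN feature f ON fl.feature_id = f.feature_id"
        " WHERE fl.srcfeature_id=? AND fl.fmin < ? AND fl.fmax > ?",
        (src.feature_id, end, start)).fetchall()
    candidates = {r[0] for r in rows}
    if not candidates:
        return []

    def parents_of(fid: int) -> list[int]:
        return [r[0] for r in store.execute(
            "SELECT object_id FROM feature_relationship WHERE subject_id=?"
            " AND type_id=?", (fid, part_of_id))]

    top = [fid for fid in candidates
           if not any(p in candidates for p in parents_of(fid))]

    def span(fid: int) -> tuple[int, int, int, int | None]:
        locs = store.execute(
            "SELECT fmin, fmax, strand, phase FROM featureloc WHERE"
            " feature_id=? AND srcfeature_id=? ORDER BY rank",
            (fid, src.feature_id)).fetchall()
        if not locs:
            return (0, 0, 0, None)
        return (min(l["fmin"] for l in locs), max(l["fmax"] for l in locs),
                locs[0]["strand"], locs[0]["phase"])

    def build(fid: int) -> RegionFeature:
        feat = store.feature_by_id(fid)
        fmin, fmax, strand, phase = span(fid)
        node = RegionFeature(uniquename=feat.uniquename,
                             type=feat.type_name, start=fmin, end=fmax,
                             strand=strand, phase=phase)
        child_ids = [r[0] for r in store.execute(
            "SELECT subject_id FROM feature_relationship WHERE object_id=?"
            " AND type_id=?", (fid, part_of_id))]
        children = [build(cid) for cid in child_ids]
        node.children = sorted(children,
                               key=lambda c: (c.start, c.uniquename))
        return node

    nodes = [build(fid) for fid in top]
    if types is not None:
        nodes = [n for n in nodes if n.type in types]
    return sorted(nodes, key=lambda n: (n.start, n.uniquename))


def group_members(store: StoreHandle, group_kind: str,
                  group_id: str) -> list[Feature]:
    """Features carrying the given group property value, ordered by
    (organism, uniquename).  Unknown group IDs yield an empty list."""
    if group_kind not in ("orthologous group", "coexpression group"):
        raise ValueError(f"unknown group kind {group_kind!r}")
    prop_type = store.find_term(group_kind, "feature_property")
    if prop_type is None:
        return []
    rows = store.execute(
        "SELECT f.* FROM featureprop fp"
        " JOIN feature f ON fp.feature_id = f.feature_id"
        " JOIN organism o ON f.organism_id = o.organism_id"
        " WHERE fp.type_id=? AND fp.value=?"
        " ORDER BY o.genus, o.species, f.uniquename",
        (prop_type.cvterm_id, group_id)).fetchall()
    return [store._feature_from_row(r) for r in rows]


def _wrap(seq: str, width: int = 60) -> str:
    return "\n".join(seq[i:i + width] for i in range(0, len(seq), width))


def feature_sequence(store: StoreHandle, feature) -> str:
    """Residues of a feature: stored directly, or sliced [fmin, fmax) from
    its single location's source sequence (reverse-complemented on the
    minus strand)."""
    feat = _resolve(store, feature)
    if feat.residues is not None:
        return feat.residues
    locs = store.execute(
        "SELECT * FROM featureloc WHERE feature_id=? ORDER BY rank",
        (feat.feature_id,)).fetchall()
    if len(locs) != 1:
        raise ExportError(
            f"feature {feat.uniquename!r} has no residues and "
            f"{len(locs)} locations; cannot derive a sequence")
    loc = locs[0]
    src = store.feature_by_id(loc["srcfeature_id"])
    if src.residues is None:
        raise ExportError(
            f"feature {feat.uniquename!r}: source {src.uniquename!r} "
            "has no residues")
    segment = src.residues[loc["fmin"]:loc["fmax"]]
    if loc["strand"] == -1:
        segment = str(Seq(segment).reverse_complement())
    return segment


def export_fasta(store: StoreHandle, features) -> str:
    """FASTA text for the given features (header = uniquename, 60-column
    wrapping).  Raises :class:`ExportError` naming the first feature with
    neither residues nor a resolvable location."""
    records = []
    for feature in features:
        feat = _resolve(store, feature)
        records.append(f">{feat.uniquename}\n"
                       f"{_wrap(feature_sequence(store, feat))}")
    return "\n".join(records) + ("\n" if records else "")


_TABLE_COLUMNS = ("organism", "uniquename", "name", "type", "description",
                  "orthologous_group", "coexpression_group")


def _clean_cell(value) -> str:
    """Tabs and newlines inside field values are replaced by single spaces
    so the TSV stays parseable."""
    if value is None:
        return ""
    return " ".join(str(value).split())


def export_table(store: StoreHandle, rows) -> str:
    """TSV text (header + one row per feature) for download.

    ``rows`` may be Features, feature ids or uniquenames.
    """
    lines = ["\t".join(_TABLE_COLUMNS)]
    for feature in rows:
        detail = feature_detail(store, feature)
        lines.append("\t".join(_clean_cell(v) for v in (
            detail.organism,
            detail.feature.uniquename,
            detail.feature.name,
            detail.feature.type_name,
            detail.description,
            detail.ortholog_group,
            detail.coexpression_group,
        )))
    return "\n".join(lines) + "\n"
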