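import io
import random

import pytest

from chadolite import (
    ExportError,
    NotFoundError,
    export_fasta,
    export_table,
    feature_detail,
    get_feature,
    group_members,
    load_fasta,
    load_gff3,
    region_query,
)
from chadolite.query import feature_sequence


# ---------------------------------------------------------------- detail

def test_detail_sections_match_direct_store_scans(loaded_store):
    store, _ = loaded_store
    poly = get_feature(store, "Arabidopsis thaliana", "mRNA0001",
                       "polypeptide")
    detail = feature_detail(store, poly)
    n_go = store.execute(
        "SELECT COUNT(*) FROM feature_cvterm WHERE feature_id=?",
        (poly.feature_id,)).fetchone()[0]
    assert len(detail.go_assignments) == n_go
    n_sim = store.execute(
        "SELECT COUNT(*) FROM featureloc fl JOIN analysisfeature af"
        " ON af.feature_id = fl.feature_id WHERE fl.srcfeature_id=?",
        (poly.feature_id,)).fetchone()[0]
    assert len(detail.similarity) == n_sim
    og = store.execute(
        "SELECT fp.value FROM featureprop fp JOIN cvterm t"
        " ON fp.type_id=t.cvterm_id WHERE fp.feature_id=? AND"
        " t.name='orthologous group'", (poly.feature_id,)).fetchone()
    assert detail.ortholog_group == (og["value"] if og else None)


def test_detail_of_bare_feature_has_empty_sections(so_store):
    load_fasta(so_store, io.StringIO(">chrA\nACGT\n"), "Atest", "chromosome")
    detail = feature_detail(so_store, "chrA")
    assert detail.go_assignments == []
    assert detail.similarity == []
    assert detail.expression == []
    assert detail.publications == []
    assert detail.ortholog_group is None


def test_detail_mrna_relationships_include_both_directions(loaded_store):
    store, _ = loaded_store
    detail = feature_detail(store, ("mRNA0002", "mRNA"))
    rels = {(r["predicate"], r["direction"], r["other_type"])
            for r in detail.relationships}
    assert ("part_of", "out", "gene") in rels            # mRNA part_of gene
    assert ("translation_of", "in", "polypeptide") in rels
    assert ("part_of", "in", "exon") in rels


def test_detail_unknown_feature_not_found(loaded_store):
    store, _ = loaded_store
    with pytest.raises(NotFoundError):
        feature_detail(store, "no-such-feature")


# ---------------------------------------------------------------- region

@pytest.fixture()
def two_gene_store(so_store):
    load_fasta(so_store, io.StringIO(">chrA\n" + "A" * 300 + "\n"),
               "Atest", "chromosome")
    gff = ("##gff-version 3\n"
           "chrA\tt\tgene\t1\t100\t.\t+\t.\tID=gA\n"
           "chrA\tt\tmRNA\t1\t100\t.\t+\t.\tID=mA;Parent=gA\n"
           "chrA\tt\tgene\t151\t200\t.\t+\t.\tID=gB\n")
    load_gff3(so_store, io.StringIO(gff), "Atest")
    return so_store


def test_overlapping_window_returns_both(two_gene_store):
    nodes = region_query(two_gene_store, "chrA", 90, 160)
    assert [n.uniquename for n in nodes] == ["gA", "gB"]
    assert nodes[0].children[0].uniquename == "mA"   # full subtree attached


def test_half_open_touching_intervals_excluded(two_gene_store):
    assert region_query(two_gene_store, "chrA", 100, 150) == []


def test_type_filter_keeps_all_genes(loaded_store, bundle):
    store, _ = loaded_store
    for chrom, length in bundle.chromosomes:
        nodes = region_query(store, chrom, 0, length, types={"gene"})
        expected = store.execute(
            "SELECT COUNT(*) FROM featureloc fl"
            " JOIN feature f ON fl.feature_id=f.feature_id"
            " JOIN cvterm t ON f.type_id=t.cvterm_id"
            " WHERE t.name='gene' AND fl.srcfeature_id ="
            " (SELECT feature_id FROM feature WHERE uniquename=?)",
            (chrom,)).fetchone()[0]
        assert len(nodes) == expected


def _region_oracle(store, src_name, start, end):
    """Brute-force reference: scan every location, find candidates, take
    whole part_of subtrees of top-level candidates, flatten."""
    src = get_feature(store, "Arabidopsis thaliana", src_name, "chromosome")
    locs = store.execute(
        "SELECT feature_id, fmin, fmax FROM featureloc WHERE"
        " srcfeature_id=?", (src.feature_id,)).fetchall()
    candidates = {l["feature_id"] for l in locs
                  if l["fmin"] < end and l["fmax"] > start}
    parent = {}
    for row in store.execute(
            "SELECT fr.subject_id, fr.object_id FROM feature_relationship fr"
            " JOIN cvterm t ON fr.type_id=t.cvterm_id"
            " WHERE t.name='part_of'"):
        parent.setdefault(row["subject_id"], []).append(row["object_id"])
    children = {}
    for child, parents in parent.items():
        for p in parents:
            children.setdefault(p, []).append(child)
    top = [fid for fid in candidates
           if not any(p in candidates for p in parent.get(fid, ()))]
    out = set()

    def collect(fid):
        out.add(fid)
        for c in children.get(fid, ()):
            collect(c)

    for fid in top:
        collect(fid)
    return {store.feature_by_id(f).uniquename for f in out}, \
        {store.feature_by_id(f).uniquename for f in top}


def test_region_query_agrees_with_brute_force_on_random_windows(loaded_store,
                                                                bundle):
    store, _ = loaded_store
    rng = random.Random(7)
    for chrom, length in bundle.chromosomes:
        for _ in range(150):
            a = rng.randrange(0, length)
            b = rng.randrange(a, min(a + rng.choice([50, 500, 5000]),
                                     length))
            nodes = region_query(store, chrom, a, b)
            got_top = {n.uniquename for n in nodes}
            got_all = {m.uniquename for n in nodes for m in n.flatten()}
            exp_all, exp_top = _region_oracle(store, chrom, a, b)
            assert got_top == exp_top, (chrom, a, b)
            assert got_all == exp_all, (chrom, a, b)


def test_region_ordering_and_boundaries_from_manifest(loaded_store, bundle):
    store, _ = loaded_store
    g = bundle.genes[0]
    # exact window: [fmin, fmax) overlaps, [fmax, fmax+1) does not
    hit = region_query(store, g["chrom"], g["fmin"], g["fmax"],
                       types={"gene"})
    assert g["gene_id"] in [n.uniquename for n in hit]
    starts = [n.start for n in region_query(store, g["chrom"], 0, 10 ** 6)]
    assert starts == sorted(starts)


def test_region_unknown_srcfeature(loaded_store):
    store, _ = loaded_store
    with pytest.raises(NotFoundError):
        region_query(store, "chr99", 0, 10)


# ---------------------------------------------------------------- groups

def test_group_members_match_group_by_oracle(loaded_store):
    store, _ = loaded_store
    for kind in ("orthologous group", "coexpression group"):
        expected = {}
        for row in store.execute(
                "SELECT fp.value, f.uniquename FROM featureprop fp"
                " JOIN cvterm t ON fp.type_id=t.cvterm_id"
                " JOIN feature f ON fp.feature_id=f.feature_id"
                " WHERE t.name=?", (kind,)):
            expected.setdefault(row["value"], set()).add(row["uniquename"])
        assert expected, kind
        for group_id, members in expected.items():
            got = group_members(store, kind, group_id)
            assert {f.uniquename for f in got} == members
            names = [f.uniquename for f in got]
            assert names == sorted(names)      # deterministic order


def test_unknown_group_is_empty_not_error(loaded_store):
    store, _ = loaded_store
    assert group_members(store, "orthologous group", "OG9999") == []


def test_invalid_group_kind_raises(loaded_store):
    store, _ = loaded_store
    with pytest.raises(ValueError):
        group_members(store, "secret club", "X")


# ---------------------------------------------------------------- export

def test_chromosome_roundtrip_is_byte_identical(loaded_store, bundle):
    store, _ = loaded_store
    with open(bundle.paths["genome"]) as fh:
        raw = fh.read()
    originals = {}
    for block in raw.strip().split(">")[1:]:
        lines = block.splitlines()
        originals[lines[0].split()[0]] = "".join(lines[1:])
    for chrom, seq in originals.items():
        out = export_fasta(store, [(chrom, "chromosome")])
        lines = out.strip().splitlines()
        assert lines[0] == f">{chrom}"
        assert "".join(lines[1:]) == seq
        assert all(len(l) <= 60 for l in lines[1:])


def test_minus_strand_slice_is_reverse_complemented(so_store):
    load_fasta(so_store, io.StringIO(">chrA\nACGTACGTACGTACGTACGT\n"),
               "Atest", "chromosome")
    gff = "##gff-version 3\nchrA\tt\tgene\t11\t16\t.\t-\t.\tID=gm\n"
    load_gff3(so_store, io.StringIO(gff), "Atest")
    # independent oracle: slice then reverse-complement by hand
    segment = "ACGTACGTACGTACGTACGT"[10:16]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    expected = "".join(comp[c] for c in reversed(segment))
    assert feature_sequence(so_store, ("gm", "gene")) == expected


def test_export_without_sequence_or_location_errors(so_store):
    org = so_store.get_organism("Atest")
    from chadolite.ontology import resolve_term
    gene = resolve_term(so_store, "gene", "sequence")
    so_store.insert_feature(org, "floating", gene)
    so_store.conn.commit()
    with pytest.raises(ExportError) as err:
        export_fasta(so_store, ["floating"])
    assert "floating" in str(err.value)


def test_export_table_shape_and_escaping(loaded_store):
    store, _ = loaded_store
    out = export_table(store, ["gene0001", "gene0002", "gene0003"])
    lines = out.splitlines()
    assert len(lines) == 4
    header = lines[0].split("\t")
    assert header[:4] == ["organism", "uniquename", "name", "type"]
    parsed = [l.split("\t") for l in lines[1:]]
    assert all(len(row) == len(header) for row in parsed)
    assert parsed[0][1] == "gene0001"
    assert parsed[0][4] == "protein kinase"


def test_export_table_empty_input_is_header_only(loaded_store):
    store, _ = loaded_store
    assert export_table(store, []).splitlines() == [
        "organism\tuniquename\tname\ttype\tdescription\t"
        "orthologous_group\tcoexpression_group"]


def test_tab_in_field_is_replaced_and_output_stays_parseable(so_store):
    load_fasta(so_store, io.StringIO(">chrA\nACGT\n"), "Atest", "chromosome")
    gff = ("##gff-version 3\n"
           "chrA\tt\tgene\t1\t4\t.\t+\t.\tID=gt;Note=has%09tab%0Anewline\n")
    load_gff3(so_store, io.StringIO(gff), "Atest")
    out = export_table(so_store, [("gt", "gene")])
    lines = out.splitlines()
    assert len(lines) == 2
    row = lines[1].split("\t")
    assert len(row) == 7
    assert row[4] == "has tab newline"
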