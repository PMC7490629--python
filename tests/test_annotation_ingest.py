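import io

import pytest

from chadolite import (
    AnalysisMeta,
    DuplicateRecordError,
    LoadOrderError,
    assign_go_terms,
    feature_detail,
    get_feature,
    load_bibtex,
    load_blast,
    load_coexpression_clusters,
    load_fasta,
    load_gff3,
    load_interproscan,
    load_obo,
    load_ortholog_groups,
    load_protein_fasta,
    stats,
)

META = AnalysisMeta("blastx", "2.14", "hits.tsv")

MINI_GO = """format-version: 1.2

[Term]
id: GO:0016301
name: kinase activity
namespace: molecular_function
alt_id: GO:0016302

[Term]
id: GO:0006468
name: protein phosphorylation
namespace: biological_process
"""


def _blast_row(query, evalue, subject="sbj1"):
    return (f"{query}\t{subject}\t95.5\t100\t4\t1\t1\t100\t1\t100\t"
            f"{evalue}\t200.5")


@pytest.fixture()
def gene_store(so_store):
    load_fasta(so_store, io.StringIO(">chrA\n" + "ACGT" * 100 + "\n"),
               "Atest", "chromosome")
    gff = ("##gff-version 3\n"
           "chrA\tt\tgene\t1\t300\t.\t+\t.\tID=g1\n"
           "chrA\tt\tmRNA\t1\t300\t.\t+\t.\tID=m1;Parent=g1\n"
           "chrA\tt\tgene\t301\t390\t.\t+\t.\tID=g2\n"
           "chrA\tt\tmRNA\t301\t390\t.\t+\t.\tID=m2;Parent=g2\n")
    load_gff3(so_store, io.StringIO(gff), "Atest")
    load_protein_fasta(so_store, io.StringIO(">m1\nMKT\n>m2\nMAV\n"), "Atest")
    return so_store


def test_blast_rows_become_match_features_with_scores(gene_store):
    rows = "\n".join([_blast_row("m1", "1e-10"), _blast_row("m2", "1e-20")])
    report = load_blast(gene_store, io.StringIO(rows), META)
    assert report.created == 2 and not report.errors
    counts = stats(gene_store)
    assert counts["analyses"] == 1
    assert counts["analysis_scores"] == 2
    score = gene_store.execute(
        "SELECT rawscore, significance, identity FROM analysisfeature"
    ).fetchone()
    assert (score["rawscore"], score["significance"], score["identity"]) == \
        (200.5, 1e-10, 95.5)


def test_blast_match_located_on_query_interbase(gene_store):
    load_blast(gene_store, io.StringIO(_blast_row("m1", "1e-10")), META)
    m1 = get_feature(gene_store, "Atest", "m1", "mRNA")
    loc = gene_store.execute(
        "SELECT fl.fmin, fl.fmax FROM featureloc fl"
        " JOIN feature f ON fl.feature_id=f.feature_id"
        " WHERE fl.srcfeature_id=? AND f.uniquename LIKE '%match%'",
        (m1.feature_id,)).fetchone()
    assert (loc["fmin"], loc["fmax"]) == (0, 100)     # qstart 1, qend 100


def test_blast_significance_threshold_counts_skipped(gene_store):
    rows = "\n".join([_blast_row("m1", "1e-10"), _blast_row("m1", "1e-3"),
                      _blast_row("m2", "1e-7")])
    report = load_blast(gene_store, io.StringIO(rows), META,
                        min_significance=1e-5)
    assert (report.created, report.skipped) == (2, 1)


def test_blast_unknown_query_and_bad_row_are_error_entries(gene_store):
    rows = "\n".join([_blast_row("ghost", "1e-10"),
                      "m1\tonly\tthree",
                      _blast_row("m1", "bad-evalue")])
    report = load_blast(gene_store, io.StringIO(rows), META)
    assert report.created == 0 and len(report.errors) == 3
    assert stats(gene_store)["analysis_scores"] == 0


def _ipr_row(protein, score="1e-17", ipr="IPR000001", desc="Kinase domain",
             go="-"):
    return "\t".join((protein, "md5", "3", "Pfam", "PF00069", desc,
                      "1", "3", score, "T", "2020-01-01", ipr, desc, go))


def test_interproscan_rows_and_go_dispatch(gene_store):
    load_obo(gene_store, MINI_GO)
    tsv = "\n".join([
        _ipr_row("m1", go="GO:0016301"),
        _ipr_row("m2", ipr="-", desc="-"),
    ])
    report = load_interproscan(gene_store, io.StringIO(tsv),
                               AnalysisMeta("interproscan", "5", "ipr.tsv"))
    assert report.created == 2 and not report.errors
    counts = stats(gene_store)
    assert counts["feature_term_assignments"] == 1
    poly = get_feature(gene_store, "Atest", "m1", "polypeptide")
    detail = feature_detail(gene_store, poly)
    assert detail.go_assignments[0]["accession"] == "GO:0016301"
    assert detail.go_assignments[0]["namespace"] == "molecular_function"


def test_interproscan_without_go_ontology_aborts_unchanged(gene_store):
    before = stats(gene_store)
    with pytest.raises(LoadOrderError) as err:
        load_interproscan(gene_store,
                          io.StringIO(_ipr_row("m1", go="GO:0016301")),
                          AnalysisMeta("interproscan", "5", "ipr.tsv"))
    assert err.value.required_command == "load-ontology"
    assert stats(gene_store) == before


def test_assign_go_terms_is_idempotent_and_counts_novel(gene_store):
    load_obo(gene_store, MINI_GO)
    poly = get_feature(gene_store, "Atest", "m1", "polypeptide")
    assert assign_go_terms(gene_store, poly,
                           ["GO:0016301", "GO:0006468"]) == 2
    assert assign_go_terms(gene_store, poly,
                           ["GO:0016301", "GO:0006468"]) == 0
    # alt_id resolves to the primary, which is already assigned
    assert assign_go_terms(gene_store, poly, ["GO:0016302"]) == 0


def test_ortholog_groups_assign_properties_and_skip_singletons(gene_store):
    groups = "OG1: a|m1 b|m2\nOG2: c|m1\n"
    report = load_ortholog_groups(gene_store, io.StringIO(groups))
    assert report.created == 2 and report.skipped == 1
    values = [r["value"] for r in gene_store.execute(
        "SELECT fp.value FROM featureprop fp JOIN cvterm t"
        " ON fp.type_id=t.cvterm_id WHERE t.name='orthologous group'")]
    assert values == ["OG1", "OG1"]


def test_ortholog_unknown_member_still_loads_others(gene_store):
    groups = "OG1: m1 ghost m2\n"
    report = load_ortholog_groups(gene_store, io.StringIO(groups))
    assert report.created == 2
    assert len(report.errors) == 1 and "ghost" in report.errors[0][1]


def test_group_property_total_matches_brute_force_recount(loaded_store, bundle):
    store, reports = loaded_store
    with open(bundle.paths["orthologs"]) as fh:
        expected = 0
        for line in fh:
            members = line.partition(":")[2].split()
            if len(members) >= 2:
                expected += len(members)   # all resolvable in the bundle
    n_props = store.execute(
        "SELECT COUNT(*) FROM featureprop fp JOIN cvterm t"
        " ON fp.type_id=t.cvterm_id WHERE t.name='orthologous group'"
    ).fetchone()[0]
    assert n_props == expected == reports["orthologs"].created


def test_coexpression_clusters_named_by_line_order(gene_store):
    mcl = "m1\tm2\n\nm2\tm1\n"
    report = load_coexpression_clusters(gene_store, io.StringIO(mcl))
    assert report.created == 4
    values = sorted(r["value"] for r in gene_store.execute(
        "SELECT fp.value FROM featureprop fp JOIN cvterm t"
        " ON fp.type_id=t.cvterm_id WHERE t.name='coexpression group'"))
    assert values == ["CLUSTER1", "CLUSTER1", "CLUSTER2", "CLUSTER2"]


def test_coexpression_singleton_line_writes_nothing(gene_store):
    report = load_coexpression_clusters(gene_store, io.StringIO("m1\n"))
    assert report.created == 0 and report.skipped == 1


BIB = """@article{alpha2020,
  author = {A. Author},
  title = {First paper},
  year = {2020},
  doi = {10.1/alpha}
}
@book{beta2021,
  author = {B. Writer},
  title = {Second paper},
  year = {2021}
}
"""


def test_bibtex_entries_created(gene_store):
    report = load_bibtex(gene_store, io.StringIO(BIB))
    assert report.created == 2 and not report.errors
    row = gene_store.execute(
        "SELECT * FROM pub WHERE uniquename='alpha2020'").fetchone()
    assert row["title"] == "First paper" and row["pyear"] == 2020


def test_bibtex_duplicate_citekey_aborts(gene_store):
    load_bibtex(gene_store, io.StringIO(BIB))
    before = stats(gene_store)
    with pytest.raises(DuplicateRecordError):
        load_bibtex(gene_store, io.StringIO(BIB))
    assert stats(gene_store) == before


def test_bibtex_entry_without_citekey_is_error_entry(gene_store):
    bad = "@article{,\n title = {No key}\n}\n"
    report = load_bibtex(gene_store, io.StringIO(bad))
    assert report.created == 0 and len(report.errors) == 1


def test_bibtex_links_surface_on_both_feature_pages(gene_store):
    load_bibtex(gene_store, io.StringIO(BIB), link_to=["g1", "g2"])
    for gene_id in ("g1", "g2"):
        detail = feature_detail(gene_store, (gene_id, "gene"))
        citekeys = {p["citekey"] for p in detail.publications}
        assert citekeys == {"alpha2020", "beta2021"}


def test_every_score_references_a_match_of_its_own_run(loaded_store):
    store, _ = loaded_store
    orphan = store.execute(
        "SELECT COUNT(*) FROM analysisfeature af JOIN feature f"
        " ON af.feature_id=f.feature_id JOIN cvterm t"
        " ON f.type_id=t.cvterm_id WHERE t.name != 'match'").fetchone()[0]
    assert orphan == 0
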