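import io
import random

import pytest

from chadolite import (
    autocomplete,
    build_index,
    initialize_store,
    load_fasta,
    search,
)
from chadolite.fixtures import generate_bundle, load_bundle
from chadolite.search import FACET_DIMENSIONS, SearchIndex, tokenize


@pytest.fixture(scope="module")
def index(loaded_store):
    store, _ = loaded_store
    return build_index(store)


def test_documents_cover_exactly_the_indexable_types(loaded_store, index):
    store, _ = loaded_store
    expected = store.execute(
        "SELECT COUNT(*) FROM feature f JOIN cvterm t"
        " ON f.type_id=t.cvterm_id"
        " WHERE t.name IN ('gene', 'mRNA', 'polypeptide')").fetchone()[0]
    assert index.report.documents == expected == 150
    assert {d.type for d in index.documents} == {"gene", "mRNA",
                                                 "polypeptide"}


def test_store_without_indexable_features_yields_no_documents(so_store):
    load_fasta(so_store, io.StringIO(">chrA\nACGT\n"), "Atest", "chromosome")
    assert build_index(so_store).report.documents == 0


def test_rebuild_is_deterministic(loaded_store, index):
    store, _ = loaded_store
    again = build_index(store)
    assert again == index
    assert again.keywords == index.keywords


def test_index_persistence_roundtrip(index, tmp_path):
    path = str(tmp_path / "idx.json")
    index.save(path)
    assert SearchIndex.load(path) == index


def test_tokenizer_rules():
    assert tokenize("Protein-Kinase 2B!") == ["protein", "kinase", "2b"]
    assert tokenize("a x") == []          # single characters dropped


def _linear_prefix_scan(index, prefix):
    hits = [k for k in index.keywords if k.startswith(prefix)]
    return sorted(hits, key=lambda k: (-index.keywords[k], k))


def test_autocomplete_equals_linear_scan(index):
    for prefix in ("kin", "kinas", "prot", "ge", "zzz"):
        assert autocomplete(index, prefix, limit=10 ** 6) == \
            _linear_prefix_scan(index, prefix)
    assert autocomplete(index, "zzz") == []


def test_autocomplete_contains_every_keyword_for_every_prefix(index):
    for keyword in list(index.keywords)[:50]:
        for cut in range(1, len(keyword) + 1):
            hits = autocomplete(index, keyword[:cut], limit=10 ** 6)
            assert keyword in hits


def test_query_tokens_and_with_prefix_match(index):
    kinase = search(index, "kinase", page_size=10 ** 6)
    kin = search(index, "kin", page_size=10 ** 6)
    assert kinase.total >= 1
    # prefix matching: "kin" matches at least everything "kinase" does
    assert {d.key for d in kinase.rows} <= {d.key for d in kin.rows}
    both = search(index, "protein kinase", page_size=10 ** 6)
    assert {d.key for d in both.rows} <= {d.key for d in kinase.rows}


def test_filtered_rows_all_carry_the_filter_values(index):
    result = search(index, "kinase",
                    {"organism": "Arabidopsis thaliana",
                     "type": "polypeptide"}, page_size=10 ** 6)
    assert result.total > 0
    for doc in result.rows:
        assert doc.organism == "Arabidopsis thaliana"
        assert doc.type == "polypeptide"


def test_empty_query_with_filters_returns_all_matching_documents(index):
    result = search(index, "", {"type": "gene"}, page_size=10 ** 6)
    assert result.total == sum(1 for d in index.documents
                               if d.type == "gene")


def test_unknown_dimension_is_error(index):
    with pytest.raises(KeyError):
        search(index, "kinase", {"flavour": "sweet"})


def _brute_force_facets(index, query, filters, dimension):
    """Group-by over a linear document scan, with the standard rule that a
    dimension's own filter is ignored for its counts."""
    from collections import Counter

    def matches_query(doc):
        tokens = tokenize(query)
        return all(any(k == t or k.startswith(t)
                       for k in doc.token_counts) for t in tokens)

    def matches_filters(doc, skip):
        for dim, wanted in filters.items():
            if dim == skip:
                continue
            values = doc.facet_values(dim)
            wanted_list = wanted if isinstance(wanted, list) else [wanted]
            if not any(v in wanted_list for v in values):
                return False
        return True

    counter = Counter()
    for doc in index.documents:
        if matches_query(doc) and matches_filters(doc, dimension):
            for value in doc.facet_values(dimension):
                counter[value] += 1
    return dict(counter)


def test_facet_counts_equal_full_scan_group_by(index):
    cases = [
        ("kinase", {}),
        ("", {}),
        ("protein", {"type": ["polypeptide"]}),
        ("", {"orthology": [True], "type": ["polypeptide"]}),
        ("", {"biomaterial": ["leaf"]}),
    ]
    for query, filters in cases:
        result = search(index, query, filters, page_size=1)
        for dimension in FACET_DIMENSIONS:
            assert result.facets[dimension] == \
                _brute_force_facets(index, query, filters, dimension), \
                (query, filters, dimension)


def test_organism_facet_totals_equal_hit_count(index):
    result = search(index, "kinase")
    assert sum(result.facets["organism"].values()) == result.total


def test_filter_composition_equals_set_intersection(index):
    query = "protein"
    unfiltered = {d.key + d.type
                  for d in search(index, query, page_size=10 ** 6).rows}
    for dimension, value in (("type", "gene"),
                             ("orthology", True),
                             ("treatment", "drought")):
        filtered = {d.key + d.type for d in search(
            index, query, {dimension: [value]}, page_size=10 ** 6).rows}
        by_hand = {d.key + d.type for d in index.documents
                   if value in d.facet_values(dimension)}
        assert filtered == unfiltered & by_hand, dimension


def test_pagination_partitions_the_ordered_result(index):
    full = search(index, "", page_size=10 ** 6)
    ordered = [d.key + d.type for d in full.rows]
    for page_size in (1, 7, 40):
        paged = []
        page = 1
        while True:
            result = search(index, "", page=page, page_size=page_size)
            if not result.rows:
                break
            assert len(result.rows) <= page_size
            paged.extend(d.key + d.type for d in result.rows)
            page += 1
        assert paged == ordered, page_size


def test_search_contracts_hold_across_random_fixture_stores(tmp_path):
    """Facet-count oracle + filter composition + pagination on many small
    randomized stores (different seeds change hit patterns)."""
    for seed in range(20):
        out = tmp_path / f"b{seed}"
        manifest = generate_bundle(seed=100 + seed, n_chromosomes=1,
                                   chrom_length=30_000, n_genes=8,
                                   n_assays=2, out_dir=str(out))
        store = initialize_store(":memory:")
        load_bundle(store, manifest)
        index = build_index(store)
        rng = random.Random(seed)
        query = rng.choice(["", "kinase", "protein", "gene"])
        result = search(index, query, page_size=10 ** 6)
        for dimension in FACET_DIMENSIONS:
            assert result.facets[dimension] == \
                _brute_force_facets(index, query, {}, dimension)
        # composition on a random concrete facet value
        for dimension in ("organism", "type", "biomaterial"):
            values = sorted({v for d in index.documents
                             for v in d.facet_values(dimension)})
            if not values:
                continue
            value = rng.choice(values)
            filtered = {d.key + d.type for d in search(
                index, query, {dimension: [value]}, page_size=10 ** 6).rows}
            unfiltered = {d.key + d.type for d in result.rows}
            by_hand = {d.key + d.type for d in index.documents
                       if value in d.facet_values(dimension)}
            assert filtered == unfiltered & by_hand
        store.close()
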