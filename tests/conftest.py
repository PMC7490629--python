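import pytest

from chadolite import initialize_store
from chadolite.fixtures import generate_bundle, load_bundle


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Reference synthetic bundle: 2 chromosomes x 100 kb, 50 genes, 4 assays."""
    out = tmp_path_factory.mktemp("bundle")
    return generate_bundle(seed=42, out_dir=str(out))


@pytest.fixture(scope="session")
def loaded_store(bundle, tmp_path_factory):
    """The bundle loaded in documented order.  Session-scoped and read-only:
    tests that write open their own store."""
    db = tmp_path_factory.mktemp("store") / "chado.db"
    store = initialize_store(str(db))
    reports = load_bundle(store, bundle)
    return store, reports


@pytest.fixture()
def fresh_store():
    """Throwaway in-memory store with bootstrap terms only."""
    store = initialize_store(":memory:")
    yield store
    store.close()


MINI_SO = """format-version: 1.2
default-namespace: sequence

[Term]
id: SO:0000001
name: region

[Term]
id: SO:0000340
name: chromosome
is_a: SO:0000001

[Term]
id: SO:0000704
name: gene
is_a: SO:0000001

[Term]
id: SO:0000234
name: mRNA
is_a: SO:0000001

[Term]
id: SO:0000147
name: exon
is_a: SO:0000001

[Term]
id: SO:0000316
name: CDS
is_a: SO:0000001

[Term]
id: SO:0000104
name: polypeptide
is_a: SO:0000001

[Term]
id: SO:0000343
name: match
is_a: SO:0000001

[Typedef]
id: part_of
name: part_of
"""


@pytest.fixture()
def so_store(fresh_store):
    """Fresh store with the miniature Sequence Ontology and one organism."""
    from chadolite import load_obo

    load_obo(fresh_store, MINI_SO, on_duplicate="skip")
    fresh_store.add_organism("Arabidopsis", "thaliana", abbreviation="Atest")
    return fresh_store
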