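# chadolite

An embedded, desk-scale genomics data-integration store built on the GMOD
**Chado** relational schema, with batch loaders for the common annotation
file formats, a query layer for feature pages and genome-browser region
queries, and an in-process faceted search index with autocomplete.

## Who this is for

Research groups that need to consolidate a genome project's artifacts —
assembly, gene models, functional annotation, orthology, coexpression,
expression matrices, literature — into one queryable database without
standing up a full web stack. Everything lives in a single SQLite file
whose tables and columns follow Chado 1.31 (`cv`, `cvterm`, `organism`,
`feature`, `featureloc`, `feature_relationship`, ...), so the same queries
are portable in principle to a real Chado instance.

## The model

Chado types everything with controlled vocabularies instead of fixed
tables. A **feature** is any sequence object — chromosome, gene, mRNA,
exon, CDS, polypeptide, similarity match — typed by a Sequence Ontology
term and connected through typed relationships:

```
polypeptide --translation_of--> mRNA --part_of--> gene
exon/CDS    --part_of--> mRNA
```

Genomic positions use **interbase coordinates** (0-based, half-open, the
Chado convention); GFF3's 1-based closed intervals are converted on input
(`fmin = start − 1`, `fmax = end`) and back on output. Functional
annotation attaches Gene Ontology terms to features; computed evidence
(BLAST, InterProScan) is stored as `match` features located on their query
with score rows carrying bitscore, E-value and percent identity; ortholog
and coexpression group membership are feature properties; expression is an
assay × feature value table with biomaterial/treatment metadata.

Loaders enforce the Chado load order — ontologies before sequences,
sequences before gene models, gene models before evidence — and run inside
one transaction each, so a failed load leaves the store unchanged.

## Worked example

```bash
# write a synthetic, mutually consistent demo bundle (2 chromosomes,
# 50 gene models, evidence files reusing the same feature IDs)
chadolite generate-fixture demo/
# bundle written to demo/ (50 genes)

chadolite --store demo.db init
chadolite --store demo.db load-ontology demo/sequence_ontology.obo
chadolite --store demo.db load-ontology demo/gene_ontology.obo
chadolite --store demo.db load-organism Arabidopsis thaliana
chadolite --store demo.db load-fasta demo/genome.fasta --organism "Arabidopsis thaliana"
chadolite --store demo.db load-gff demo/annotation.gff3 --organism "Arabidopsis thaliana"
chadolite --store demo.db load-protein-fasta demo/proteins.fasta --organism "Arabidopsis thaliana"
chadolite --store demo.db load-blast demo/blast.tsv --sourcename blast.tsv
chadolite --store demo.db load-interproscan demo/interproscan.tsv
chadolite --store demo.db load-orthologs demo/orthologs.txt
chadolite --store demo.db load-assays demo/assays.tsv
chadolite --store demo.db load-expression demo/expression.tsv
chadolite --store demo.db build-index
# indexed 150 documents, 178 keywords -> demo.db.searchindex.json

chadolite --store demo.db search kinase --filter type=polypeptide
```

The search prints a JSON result page; on the default bundle it reports
`"total": 9` polypeptides whose descriptions or GO annotations mention
kinase activity, with facet counts such as
`"organism": {"Arabidopsis thaliana": 9}` and
`"type": {"gene": 7, "polypeptide": 9}` (each facet ignores its own filter,
so the type facet also shows the 7 matching genes). Region queries return
nested gene models for a genome-browser track:

```bash
chadolite --store demo.db region chr1 0 5000
```

Every command is a thin wrapper over library functions
(`chadolite.load_gff3`, `chadolite.region_query`, `chadolite.search`, ...)
that can be used directly from Python.

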