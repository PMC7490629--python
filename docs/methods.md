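# Methods

## Data model

The store is a single-file SQLite database whose tables and columns follow
the Chado 1.31 naming for the subset the loaders populate: `db`/`dbxref`,
`cv`/`cvterm`/`cvterm_dbxref`/`cvtermsynonym`/`cvterm_relationship`,
`organism`, `feature`, `featureloc`, `feature_relationship`, `featureprop`,
`feature_cvterm`, `feature_dbxref`, `analysis`/`analysisfeature`,
`pub`/`feature_pub`, plus two minimal expression tables (`assay`,
`expression_value`). Keeping Chado names means queries written here remain
portable to a real, already-populated Chado instance; opening an existing
file validates the presence of every required table and reports the first
missing one rather than failing obscurely later. The expression module of
Chado (MAGE) is far larger than the contracts here need, so it is
deliberately collapsed to assay metadata (name, biomaterial, treatment)
and one value per (feature, assay) cell; values are stored exactly as
given, normalization being the concern of the upstream expression
pipeline.

Semantics are append-only: loaders only insert, each inside a single
transaction, so any aborting error rolls back to the pre-call state and
referential integrity cannot decay. Uniqueness keys (`(organism,
uniquename, type)` for features, `(cv, name)` for terms, etc.) are
enforced by the engine and surfaced as typed errors; the duplicate policy
is `error` by default with `skip` selectable per load for re-runs.

A fresh store seeds a minimal bootstrap vocabulary — the relationship
predicates `is_a`, `part_of`, `derives_from`, `translation_of` and the
property types `description`, `orthologous group`, `coexpression group` —
so loaders that only need those predicates can run before full ontologies
are loaded. A later ontology load upserts onto these rows in place
(counted as skipped, never duplicated), which resolves the bootstrap
chicken-and-egg without weakening the load-order checks that matter
(sequence types and GO terms are *not* bootstrapped).

## Coordinates

Interbase (0-based, half-open) throughout, the native Chado convention:
`fmin = start − 1`, `fmax = end` on GFF3 input, inverted on FASTA/region
output. Two properties follow and are asserted in the tests: segment
length is `fmax − fmin` with no ±1 bookkeeping, and interval overlap is the
clean half-open test `fmin < end and fmax > start`, under which touching
intervals do not overlap.

## Loaders

* **OBO** — a tolerant stanza parser: one term per `[Term]`, one
  relationship-type term per `[Typedef]`, one edge per `is_a`/
  `relationship:` line; synonyms and `alt_id`s (resolving to the primary
  term) are kept; malformed stanzas and stanzas missing `id:` become error
  entries with line numbers rather than aborting the file. The stanza
  `namespace` (header `default-namespace`, then an explicit fallback)
  selects the vocabulary, which is how the three GO namespaces become
  facet values later.
* **GFF3** — two passes: features first, then Parent/Derives_from links, so
  forward references are legal. Lines sharing one `ID` merge into a single
  feature with rank-ordered locations (split CDS). Parent links get the
  `part_of` predicate regardless of child type (explicit `Derives_from`
  excepted), mirroring the Chado bulk loaders rather than conditioning the
  predicate on SO types. ID-less leaf lines get the synthesized uniquename
  `<type>:<srcfeature>:<fmin>..<fmax>:<strand>`. `Name` becomes the display
  name; `Note`/`description`/`product` map to the canonical `description`
  property; `Dbxref` to cross-references; any other attribute to a property
  typed by the attribute name (auto-created), so the ingest is lossless for
  the search index. An embedded `##FASTA` section is honored as if loaded
  beforehand. A column-1 sequence that is not already a feature aborts the
  load with an error naming `load-fasta` (load-order enforcement).
* **Protein FASTA** — the header's first token must equal an existing mRNA
  uniquename (the cross-file ID-consistency rule); matches create a
  polypeptide plus a `translation_of` link, non-matches become error
  entries naming the prerequisite.
* **BLAST tabular (outfmt 6)** — 12 required columns; a 13th, when present,
  is kept as the subject description. Each kept row creates a `match`
  feature located on the *query* (the subject stays text + cross-reference:
  subjects live in external databases and fabricating organisms for them
  would be wrong), plus a score row (bitscore/E-value/identity). An
  optional E-value ceiling skips rows, counted as skipped.
* **InterProScan TSV** — match + score per row on the named polypeptide;
  signature and InterPro accessions/descriptions stored as properties; GO
  IDs in column 14 dispatch to the GO assigner. If any row carries GO IDs
  while no GO terms are loaded, the whole load aborts up front with a
  load-order error.
* **Ortholog groups / coexpression clusters** — group membership is a
  feature property (`orthologous group` / `coexpression group`). Ortholog
  members strip an optional `taxon|` prefix and resolve to polypeptides;
  cluster members resolve to mRNAs (coexpression clusters group
  transcripts). MCL output is unlabeled, so clusters are named
  `CLUSTER<k>` by 1-based non-empty-line order, keeping loads reproducible.
  Singleton groups are skipped entirely: a one-member group carries no
  grouping information and would pollute the orthology/coexpression
  facets. An unresolvable member is an error entry; the rest of its group
  still loads.
* **BibTeX** — a minimal entry parser (cite key, brace/quote-delimited
  fields, `@comment/@string/@preamble` ignored) feeding the `pub` table;
  `link_to` attaches the loaded publications to named features.
* **Expression** — assay metadata requires the exact columns
  `assay`/`biomaterial`/`treatment` (a missing column is a hard format
  error); the matrix requires every non-first header to be a registered
  assay (else a load-order error naming `load-assays`). Unknown feature
  rows and non-numeric cells are error entries; each valid cell is one
  value row, so `created + cell errors = known rows × assay columns`.

Record parsing/staging can fan out over a thread pool (`--threads`), but
results are consumed in input order and all writes stay on the calling
thread, so the final store state is byte-for-byte independent of the
worker count — the determinism contract the tests assert.

## Query layer

`feature_detail` assembles the feature page strictly from direct table
scans (relationships in both directions, locations, properties, GO
assignments, similarity hits with scores, group IDs, expression values
with assay metadata, sequence, publications); empty sections are present
but empty. `region_query(src, start, end)` returns the *top-level*
overlapping features — candidates whose `part_of` parent is not itself a
candidate — each carrying its complete `part_of` subtree, because a genome
browser renders a gene model whole even when only partially in view;
ordering is (fmin, uniquename) at every level. `export_fasta` writes
60-column records headed by the uniquename, deriving missing residues from
a single location on a residued source (reverse-complemented on the minus
strand). `export_table` writes a TSV with tabs/newlines inside fields
collapsed to single spaces so the output re-parses.

## Search

One denormalized document per gene, mRNA and polypeptide. Tokenization is
lowercase, split on non-alphanumerics, tokens of length ≥ 2. A document
matches a query when *every* token matches one of its keywords exactly or
as a prefix (AND semantics; the prefix rule applies to all tokens, which
subsumes last-token-only type-ahead). Facet dimensions are organism, type,
orthology and coexpression (boolean presence flags — the group *values*
are browsed via `group_members`, not facets), annotation (the GO
namespaces present on the feature), and expression biomaterial/treatment.
Facet counts follow standard faceted navigation: each dimension's counts
are computed with every *other* dimension's filters applied. Ranking is
summed term frequency, ties broken by uniquename; it is asserted for
determinism and pagination stability, not as a relevance claim. The index
is a pure function of store state — rebuilding is always authoritative —
and persists as JSON beside the store file.

## Synthetic bundle

The generator emulates the file set of a small genome project with
mutually consistent IDs: by default 2 chromosomes × 100 kb carrying 50
non-overlapping two-exon gene models, proteins for every transcript, 0–2
BLAST hits per transcript, InterProScan rows (some with GO IDs) for ~60%
of proteins, ortholog groups of size 2–4 over ~60% of proteins,
coexpression clusters of size 2–5 over ~50% of transcripts, three
publications, and a 4-assay expression matrix covering every transcript.
Proteins are generated first and back-translated through a fixed
one-codon-per-amino-acid table into the exon positions (minus-strand
models reverse-complemented), so CDS translation, phase bookkeeping
(`phase = (3 − cumulative length mod 3) mod 3` along the translation
direction) and sequence round trips are exact by construction. What it
does **not** emulate: codon bias, intron length distributions, UTRs,
alternative splicing, overlapping or nested genes, malformed real-world
file dialects beyond the deliberate "broken" variants (unknown Parent,
bad E-value, singleton group). Passing tests therefore demonstrate the
contracts on well-formed, consistently-identified inputs plus the specific
error paths exercised — not robustness to arbitrarily messy annotation
archives.

All generator randomness flows from one seed; identical seeds produce
byte-identical bundles (asserted), which is what makes the end-to-end
count checks meaningful.

## Numerical and procedural choices

* Ancestor closure runs an iterative DFS with an on-stack set; a cycle in
  the traversed subgraph raises an error naming a member, since OBO `is_a`
  graphs are DAGs and silently breaking a cycle would hide corrupt input.
* Evidence IDs resolve across organisms by uniquename with a fixed type
  preference per loader (e.g. mRNA before polypeptide for BLAST queries,
  polypeptide only for InterProScan), keeping resolution deterministic
  when a transcript and its protein share an ID.
* Match features are named `<query>:match:<sourcename>:<row>` so repeated
  loads of the same analysis are detectable and deterministic.
* Desk-scale problem sizes used by the test suite and the acceptance
  script: the 50-gene reference bundle, 1,000 region-query windows per
  chromosome (including windows abutting feature endpoints to pin the
  half-open boundary), 100 random DAGs of ≤ 100 nodes for closure checks,
  and 20 reseeded 10-gene stores for the search contracts.

## Known limitations

Single-writer embedded engine — no concurrent multi-user loading; no
update/delete workflows (reload into a fresh store instead); only the
Chado subset above, not the full schema; GFF2/GTF, GAF, OWL and BLAST XML
dialects are out of scope; search offers no fuzzy matching or relevance
model beyond token frequency; HSP coordinates are stored on the query side
only.
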