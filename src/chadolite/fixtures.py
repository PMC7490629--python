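"""Deterministic synthetic data bundle for exercising every loader.

The generator emits a mutually consistent set of files — genome FASTA,
GFF3 gene models, protein FASTA, BLAST tabular, InterProScan TSV, a
miniature Sequence-Ontology-like OBO, a miniature Gene Ontology, ortholog
groups, coexpression clusters, BibTeX and expression TSVs — in which the
same feature IDs recur across files, the consistency requirement a real
multi-file genome load has to satisfy.

Gene models are geometrically valid (exons inside the mRNA span inside the
gene span, CDS phases consistent with cumulative CDS length mod 3) and
proteins are back-translated into the chromosome sequence, so sequence
round trips through the store are exact.  Residues are otherwise
pseudo-random ACGT: there is no codon bias or intron length model, and no
attempt at biological realism beyond structural validity.

Everything is driven by one seed; the same seed yields byte-identical
bundles.
"""

from __future__ import annotations

import json
import os
import random
from dataclasses import dataclass, field, asdict

__all__ = ["BundleManifest", "generate_bundle", "generate_broken_bundle",
           "load_bundle", "LOAD_ORDER"]

_AA = "ACDEFGHIKLMNPQRSTVWY"
# one fixed codon per amino acid (standard genetic code) so proteins
# back-translate deterministically and re-translate exactly
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"

_DESCRIPTIONS = [
    "protein kinase",
    "kinesin motor protein",
    "serine threonine phosphatase",
    "ABC transporter family protein",
    "zinc finger transcription factor",
    "heat shock protein",
    "cytochrome P450 monooxygenase",
    "ribosomal protein L3",
]

_GO_TERMS = [
    ("GO:0016301", "kinase activity", "molecular_function"),
    ("GO:0003677", "DNA binding", "molecular_function"),
    ("GO:0006468", "protein phosphorylation", "biological_process"),
    ("GO:0016310", "phosphorylation", "biological_process"),
    ("GO:0005634", "nucleus", "cellular_component"),
    ("GO:0005737", "cytoplasm", "cellular_component"),
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneModel:
    """Ground-truth geometry of one synthetic gene (interbase coords)."""

    gene_id: str
    mrna_id: str
    cds_id: str
    chrom: str
    strand: int
    fmin: int
    fmax: int
    exons: list[tuple[int, int]]
    protein: str
    description: str


@dataclass
class BundleManifest:
    """Paths plus every ground-truth count the loaders should report."""

    seed: int
    out_dir: str
    genus: str
    species: str
    paths: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    chromosomes: list[tuple[str, int]] = field(default_factory=list)
    genes: list[dict] = field(default_factory=list)
    link_targets: list[str] = field(default_factory=list)

    @property
    def organism_label(self) -> str:
        return f"{self.genus} {self.species}"

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "BundleManifest":
        with open(path) as fh:
            raw = json.load(fh)
        raw["chromosomes"] = [tuple(c) for c in raw["chromosomes"]]
        return cls(**raw)


def _wrap60(seq: str) -> str:
    return "\n".join(seq[i:i + 60] for i in range(0, len(seq), 60))


def _mini_so_obo() -> str:
    terms = [
        ("SO:0000001", "region", []),
        ("SO:0000340", "chromosome", ["SO:0000001"]),
        ("SO:0000704", "gene", ["SO:0000001"]),
        ("SO:0000673", "transcript", ["SO:0000001"]),
        ("SO:0000234", "mRNA", ["SO:0000673"]),
        ("SO:0000147", "exon", ["SO:0000001"]),
        ("SO:0000316", "CDS", ["SO:0000001"]),
        ("SO:0000104", "polypeptide", ["SO:0000001"]),
        ("SO:0000343", "match", ["SO:0000001"]),
    ]
    out = ["format-version: 1.2", "default-namespace: sequence", ""]
    for accession, name, parents in terms:
        out += [f"[Term]", f"id: {accession}", f"name: {name}"]
        out += [f"is_a: {p}" for p in parents]
        out.append("")
    for typedef in ("part_of", "derives_from", "translation_of"):
        out += ["[Typedef]", f"id: {typedef}", f"name: {typedef}", ""]
    return "\n".join(out)


def _mini_go_obo() -> str:
    is_a = {"GO:0006468": ["GO:0016310"]}
    alt = {"GO:0016301": ["GO:0016302"]}
    out = ["format-version: 1.2", ""]
    for accession, name, namespace in _GO_TERMS:
        out += ["[Term]", f"id: {accession}", f"name: {name}",
                f"namespace: {namespace}"]
        out += [f"alt_id: {a}" for a in alt.get(accession, [])]
        out += [f"is_a: {p}" for p in is_a.get(accession, [])]
        out.append("")
    return "\n".join(out)


def _build_genes(rng: random.Random, n_chromosomes: int, chrom_length: int,
                 n_genes: int) -> tuple[dict[str, list[str]], list[GeneModel]]:
    """Place non-overlapping two-exon gene models on the chromosomes and
    back-translate a random protein into each."""
    chrom_names = [f"chr{i}" for i in range(1, n_chromosomes + 1)]
    chrom_seq = {name: [rng.choice("ACGT") for _ in range(chrom_length)]
                 for name in chrom_names}
    cursors = {name: 500 for name in chrom_names}
    genes: list[GeneModel] = []
    for i in range(1, n_genes + 1):
        chrom = chrom_names[(i - 1) % n_chromosomes]
        protein = "".join(rng.choice(_AA)
                          for _ in range(rng.randint(60, 150)))
        cds = "".join(_CODON[aa] for aa in protein) + _STOP
        intron = rng.randint(60, 200)
        e1 = rng.randint(30, len(cds) - 30)
        strand = rng.choice((1, -1))
        fmin = cursors[chrom]
        fmax = fmin + len(cds) + intron
        if fmax + 500 > chrom_length:
            raise ValueError(
                f"{n_genes} genes do not fit {n_chromosomes} chromosomes of "
                f"length {chrom_length}; increase chrom_length or drop genes")
        exon_a = (fmin, fmin + e1)
        exon_b = (fmin + e1 + intron, fmax)
        seq = chrom_seq[chrom]
        if strand == 1:
            seq[exon_a[0]:exon_a[1]] = cds[:e1]
            seq[exon_b[0]:exon_b[1]] = cds[e1:]
        else:
            n2 = exon_b[1] - exon_b[0]
            seq[exon_b[0]:exon_b[1]] = _revcomp(cds[:n2])
            seq[exon_a[0]:exon_a[1]] = _revcomp(cds[n2:])
        genes.append(GeneModel(
            gene_id=f"gene{i:04d}", mrna_id=f"mRNA{i:04d}",
            cds_id=f"cds{i:04d}", chrom=chrom, strand=strand,
            fmin=fmin, fmax=fmax, exons=[exon_a, exon_b],
            protein=protein,
            description=_DESCRIPTIONS[(i - 1) % len(_DESCRIPTIONS)]))
        cursors[chrom] = fmax + rng.randint(200, 600)
    return {name: "".join(seq) for name, seq in chrom_seq.items()}, genes


def _gff_lines(genes: list[GeneModel]) -> list[str]:
    lines = ["##gff-version 3"]
    for g in genes:
        strand = "+" if g.strand == 1 else "-"
        start, end = g.fmin + 1, g.fmax
        note = g.description.replace(" ", "%20")
        lines.append(
            f"{g.chrom}\tsynth\tgene\t{start}\t{end}\t.\t{strand}\t.\t"
            f"ID={g.gene_id};Name={g.gene_id.upper()};Note={note}")
        lines.append(
            f"{g.chrom}\tsynth\tmRNA\t{start}\t{end}\t.\t{strand}\t.\t"
            f"ID={g.mrna_id};Parent={g.gene_id}")
        for k, (a, b) in enumerate(g.exons, 1):
            lines.append(
                f"{g.chrom}\tsynth\texon\t{a + 1}\t{b}\t.\t{strand}\t.\t"
                f"ID=exon{g.gene_id[4:]}.{k};Parent={g.mrna_id}")
        # CDS covers both exons; phases follow translation direction
        (a1, b1), (a2, b2) = g.exons
        if g.strand == 1:
            phases = {0: 0, 1: (3 - (b1 - a1) % 3) % 3}
        else:
            phases = {1: 0, 0: (3 - (b2 - a2) % 3) % 3}
        for k, (a, b) in enumerate(g.exons):
            lines.append(
                f"{g.chrom}\tsynth\tCDS\t{a + 1}\t{b}\t.\t{strand}\t"
                f"{phases[k]}\tID={g.cds_id};Parent={g.mrna_id}")
    return lines


_BIBTEX = """@article{{synth2020genome,
  author = {{Doe, Jane and Roe, Riley}},
  title = {{A synthetic genome annotation test set}},
  journal = {{Journal of Reproducible Fixtures}},
  year = {{2020}},
  doi = {{10.0000/synth.2020}}
}}

@article{{synth2021kinase,
  author = {{Roe, Riley}},
  title = {{Kinase gene families in a synthetic plant genome}},
  journal = {{Journal of Reproducible Fixtures}},
  year = {{2021}},
  doi = {{10.0000/synth.2021}}
}}

@misc{{synth2022portal,
  author = {{Doe, Jane}},
  title = {{A demonstration data portal for {genus} {species}}},
  year = {{2022}}
}}
"""


def generate_bundle(seed: int = 42, n_chromosomes: int = 2,
                    chrom_length: int = 100_000, n_genes: int = 50,
                    n_assays: int = 4, out_dir: str = ".") -> BundleManifest:
    """Write the full file bundle and return its ground-truth manifest.

    Defaults describe the desk-scale reference dataset: 2 chromosomes of
    100 kb carrying 50 two-exon gene models and 4 expression assays.
    """
    rng = random.Random(seed)
    os.makedirs(out_dir, exist_ok=True)
    manifest = BundleManifest(seed=seed, out_dir=str(out_dir),
                              genus="Arabidopsis", species="thaliana")

    def path(name: str) -> str:
        p = os.path.join(out_dir, name)
        manifest.paths[name.split(".")[0]] = p
        return p

    chrom_seq, genes = _build_genes(rng, n_chromosomes, chrom_length, n_genes)
    manifest.chromosomes = [(name, len(seq))
                            for name, seq in chrom_seq.items()]
    manifest.genes = [
        {**asdict(g), "exons": [list(e) for e in g.exons]} for g in genes]

    with open(path("sequence_ontology.obo"), "w") as fh:
        fh.write(_mini_so_obo())
    with open(path("gene_ontology.obo"), "w") as fh:
        fh.write(_mini_go_obo())
    so_text = _mini_so_obo()
    manifest.counts["so_stanzas"] = so_text.count("[Term]") + \
        so_text.count("[Typedef]")
    # the 3 typedefs upsert onto bootstrap terms, so they count as skipped
    manifest.counts["so_created"] = so_text.count("[Term]")
    manifest.counts["so_skipped"] = so_text.count("[Typedef]")
    manifest.counts["so_relationships"] = so_text.count("is_a: ")
    manifest.counts["go_created"] = len(_GO_TERMS)

    with open(path("genome.fasta"), "w") as fh:
        for name, seq in chrom_seq.items():
            fh.write(f">{name} synthetic chromosome\n{_wrap60(seq)}\n")
    manifest.counts["chromosomes"] = n_chromosomes

    with open(path("annotation.gff3"), "w") as fh:
        fh.write("\n".join(_gff_lines(genes)) + "\n")
    manifest.counts["genes"] = n_genes
    manifest.counts["gff_lines"] = 6 * n_genes       # gene+mRNA+2 exon+2 CDS
    manifest.counts["gff_features"] = 5 * n_genes    # CDS lines merge
    manifest.counts["gff_locations"] = 6 * n_genes

    with open(path("proteins.fasta"), "w") as fh:
        for g in genes:
            fh.write(f">{g.mrna_id} {g.description}\n{_wrap60(g.protein)}\n")
    manifest.counts["proteins"] = n_genes

    # BLAST tabular: 0-2 hits per mRNA against a fake external database
    blast_rows = []
    for g in genes:
        for hit in range(rng.randint(0, 2)):
            length = rng.randint(80, 400)
            qstart = rng.randint(1, 50)
            evalue = 10 ** -rng.randint(3, 50)
            blast_rows.append("\t".join(map(str, (
                g.mrna_id, f"sp|Q{rng.randint(10000, 99999)}|SYNT_ARATH",
                round(rng.uniform(35, 99), 1), length, rng.randint(0, 30),
                rng.randint(0, 5), qstart, qstart + length - 1,
                rng.randint(1, 100), rng.randint(100, 500),
                f"{evalue:.1e}", round(rng.uniform(50, 900), 1)))))
    with open(path("blast.tsv"), "w") as fh:
        fh.write("\n".join(blast_rows) + ("\n" if blast_rows else ""))
    manifest.counts["blast_hits"] = len(blast_rows)

    # InterProScan TSV over a subset of proteins; some rows carry GO IDs
    ipr_rows = []
    go_pairs = set()
    for g in genes:
        if rng.random() > 0.6:
            continue
        n_rows = rng.randint(1, 2)
        for r in range(n_rows):
            start = rng.randint(1, 20)
            stop = min(start + rng.randint(30, 80), len(g.protein))
            with_go = rng.random() < 0.5
            go_ids = []
            if with_go:
                go_ids = sorted(rng.sample(
                    [t[0] for t in _GO_TERMS], rng.randint(1, 2)))
                for acc in go_ids:
                    go_pairs.add((g.mrna_id, acc))
            ipr = (f"IPR{rng.randint(1, 29999):06d}" if rng.random() < 0.7
                   else "-")
            ipr_rows.append("\t".join((
                g.mrna_id, "md5", str(len(g.protein)), "Pfam",
                f"PF{rng.randint(1, 19999):05d}", g.description,
                str(start), str(stop), f"{10 ** -rng.randint(2, 30):.1e}",
                "T", "2020-01-01", ipr,
                g.description if ipr != "-" else "-",
                "|".join(go_ids) if go_ids else "-")))
    with open(path("interproscan.tsv"), "w") as fh:
        fh.write("\n".join(ipr_rows) + ("\n" if ipr_rows else ""))
    manifest.counts["interpro_rows"] = len(ipr_rows)
    manifest.counts["go_assignments"] = len(go_pairs)

    # ortholog groups over proteins (taxon|id dialect), sizes 2-4
    proteins = [g.mrna_id for g in genes]
    shuffled = proteins[:]
    rng.shuffle(shuffled)
    ortho_lines, used = [], 0
    gi = 0
    while used + 2 <= int(len(shuffled) * 0.6):
        size = min(rng.randint(2, 4), int(len(shuffled) * 0.6) - used)
        if size < 2:
            break
        gi += 1
        members = shuffled[used:used + size]
        used += size
        ortho_lines.append(
            f"OG{gi:04d}: " + " ".join(f"atha|{m}" for m in members))
    with open(path("orthologs.txt"), "w") as fh:
        fh.write("\n".join(ortho_lines) + ("\n" if ortho_lines else ""))
    manifest.counts["ortholog_groups"] = len(ortho_lines)
    manifest.counts["ortholog_members"] = used

    # coexpression clusters over mRNAs, sizes 2-5
    mrnas = [g.mrna_id for g in genes]
    shuffled = mrnas[:]
    rng.shuffle(shuffled)
    coex_lines, used = [], 0
    while used + 2 <= int(len(shuffled) * 0.5):
        size = min(rng.randint(2, 5), int(len(shuffled) * 0.5) - used)
        if size < 2:
            break
        coex_lines.append("\t".join(shuffled[used:used + size]))
        used += size
    with open(path("coexpression.mcl"), "w") as fh:
        fh.write("\n".join(coex_lines) + ("\n" if coex_lines else ""))
    manifest.counts["coexpression_clusters"] = len(coex_lines)
    manifest.counts["coexpression_members"] = used

    with open(path("publications.bib"), "w") as fh:
        fh.write(_BIBTEX.format(genus=manifest.genus,
                                species=manifest.species))
    manifest.counts["publications"] = 3
    manifest.link_targets = [g.gene_id for g in genes[:2]]

    biomaterials = ["leaf", "root", "flower", "seed"]
    treatments = ["control", "drought", "cold", "heat"]
    with open(path("assays.tsv"), "w") as fh:
        fh.write("assay\tbiomaterial\ttreatment\n")
        for a in range(1, n_assays + 1):
            fh.write(f"assay{a:02d}\t{biomaterials[(a - 1) % 4]}\t"
                     f"{treatments[(a - 1) % 4]}\n")
    manifest.counts["assays"] = n_assays

    with open(path("expression.tsv"), "w") as fh:
        header = "feature" + "".join(
            f"\tassay{a:02d}" for a in range(1, n_assays + 1))
        fh.write(header + "\n")
        for g in genes:
            values = "".join(f"\t{round(rng.uniform(0, 500), 2)}"
                             for _ in range(n_assays))
            fh.write(f"{g.mrna_id}{values}\n")
    manifest.counts["expression_values"] = n_genes * n_assays

    manifest.save(os.path.join(out_dir, "manifest.json"))
    return manifest


def generate_broken_bundle(out_dir: str) -> dict[str, str]:
    """Deliberately inconsistent variants for negative tests: a GFF3 line
    with an unknown Parent, a BLAST row with an unparseable E-value, and a
    singleton ortholog group."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    paths["gff_unknown_parent"] = os.path.join(out_dir, "unknown_parent.gff3")
    with open(paths["gff_unknown_parent"], "w") as fh:
        fh.write("##gff-version 3\n"
                 "chr1\tsynth\tmRNA\t100\t400\t.\t+\t.\t"
                 "ID=orphan01;Parent=ghost-gene\n")
    paths["blast_bad_evalue"] = os.path.join(out_dir, "bad_evalue.tsv")
    with open(paths["blast_bad_evalue"], "w") as fh:
        fh.write("mRNA0001\tsbj1\t90.0\t100\t5\t1\t1\t100\t1\t100\t"
                 "not-a-number\t200.0\n")
    paths["singleton_group"] = os.path.join(out_dir, "singleton_groups.txt")
    with open(paths["singleton_group"], "w") as fh:
        fh.write("OG0001: atha|mRNA0001\n")
    return paths


#: documented load order: ontologies, then organism+genome, then gene
#: models, then proteins, then evidence, then expression
LOAD_ORDER = (
    "load-ontology (sequence + relations)",
    "load-ontology (gene ontology)",
    "load-organism",
    "load-fasta",
    "load-gff",
    "load-protein-fasta",
    "load-blast",
    "load-interproscan",
    "load-orthologs",
    "load-coexpression",
    "load-bibtex",
    "load-assays",
    "load-expression",
    "build-index",
)


def load_bundle(store, manifest: BundleManifest, *, threads: int = 1,
                progress=None) -> dict:
    """Load a generated bundle in the documented order; returns the
    LoadReport of every step keyed by a short name."""
    from . import annotation_ingest, expression_ingest, ontology, \
        sequence_ingest
    from .datastore import NotFoundError

    reports = {}
    with open(manifest.paths["sequence_ontology"]) as fh:
        reports["so"] = ontology.load_obo(store, fh, on_duplicate="skip",
                                          progress=progress)
    with open(manifest.paths["gene_ontology"]) as fh:
        reports["go"] = ontology.load_obo(store, fh, progress=progress)
    try:
        org = store.get_organism(manifest.organism_label)
    except NotFoundError:
        org = store.add_organism(manifest.genus, manifest.species)
    with open(manifest.paths["genome"]) as fh:
        reports["fasta"] = sequence_ingest.load_fasta(
            store, fh, org, "chromosome", threads=threads, progress=progress)
    with open(manifest.paths["annotation"]) as fh:
        reports["gff"] = sequence_ingest.load_gff3(
            store, fh, org, threads=threads, progress=progress)
    with open(manifest.paths["proteins"]) as fh:
        reports["proteins"] = sequence_ingest.load_protein_fasta(
            store, fh, org, threads=threads, progress=progress)
    with open(manifest.paths["blast"]) as fh:
        reports["blast"] = annotation_ingest.load_blast(
            store, fh, annotation_ingest.AnalysisMeta(
                "blastx", "2.x", "blast.tsv"), progress=progress)
    with open(manifest.paths["interproscan"]) as fh:
        reports["interpro"] = annotation_ingest.load_interproscan(
            store, fh, annotation_ingest.AnalysisMeta(
                "interproscan", "5.x", "interproscan.tsv"),
            progress=progress)
    with open(manifest.paths["orthologs"]) as fh:
        reports["orthologs"] = annotation_ingest.load_ortholog_groups(
            store, fh, progress=progress)
    with open(manifest.paths["coexpression"]) as fh:
        reports["coexpression"] = \
            annotation_ingest.load_coexpression_clusters(
                store, fh, annotation_ingest.AnalysisMeta(
                    "mcl", "14-137", "coexpression.mcl"), progress=progress)
    with open(manifest.paths["publications"]) as fh:
        reports["bibtex"] = annotation_ingest.load_bibtex(
            store, fh, link_to=manifest.link_targets, progress=progress)
    with open(manifest.paths["assays"]) as fh:
        reports["assays"] = expression_ingest.load_assays(
            store, fh, progress=progress)
    with open(manifest.paths["expression"]) as fh:
        reports["expression"] = expression_ingest.load_expression_matrix(
            store, fh, progress=progress)
    return reports
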