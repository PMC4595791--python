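"""Domain types and file formats.

Every stage of the pipeline works on :class:`AnnotatedGenome` objects — ordered
gene lists per scaffold with coding sequences attached. This module defines
those containers, plus strict readers/writers for FASTA, GFF3, FASTQ and
newick, and the packaged evidence-table fixtures.

Coordinates are GFF3 convention throughout: 1-based, inclusive. Minus-strand
CDS are stored already reverse-complemented into coding orientation at parse
time, so downstream codon arithmetic never needs to consider strand.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "GeneModel",
    "AnnotatedGenome",
    "SequencingRead",
    "SpeciesTree",
    "EvidenceFixtureRow",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "read_fastq",
    "write_fastq",
    "read_newick",
    "read_evidence_fixture",
    "read_duplication_fixture",
    "load_table1_fixture",
    "load_table2_fixture",
    "load_species_tree_fixture",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


class FormatError(ValueError):
    """Malformed input: readers reject rather than coerce."""


@dataclass
class GeneModel:
    """A single annotated protein-coding gene.

    ``cds`` is stored in coding orientation regardless of ``strand``.
    ``family`` is an optional gene-family label (e.g. ``"DRD1A"``) used by the
    presence/absence machinery; unlabeled background genes carry ``None``.
    """

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str = "+"
    family: Optional[str] = None
    cds: str = ""
    protein: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        self.cds = self.cds.upper()
        self.protein = self.protein.upper()
        if self.cds and self.protein and len(self.cds) % 3 == 0:
            translated = str(Seq(self.cds).translate()).rstrip("*")
            if translated != self.protein.rstrip("*"):
                raise FormatError(
                    f"gene {self.gene_id}: CDS does not translate to protein"
                )

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3

    def translated(self) -> str:
        """Translation of the stored CDS (terminal stop stripped)."""
        return str(Seq(self.cds).translate()).rstrip("*")


@dataclass
class AnnotatedGenome:
    """Per-species gene annotation: ordered gene lists keyed by scaffold.

    ``sequences`` optionally carries the scaffold nucleotide sequences (needed
    by read simulation and microsynteny checks). ``assembly_profile`` records
    contiguity/depth metadata of the underlying assembly.
    """

    species_id: str
    scaffolds: dict[str, list[GeneModel]] = field(default_factory=dict)
    sequences: Optional[dict[str, str]] = None
    assembly_profile: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for scaf, genes in self.scaffolds.items():
            prev = 0
            for g in genes:
                if g.scaffold_id != scaf:
                    raise FormatError(
                        f"gene {g.gene_id} filed under {scaf} but claims "
                        f"scaffold {g.scaffold_id}"
                    )
                if g.gene_id in seen:
                    raise FormatError(f"duplicate gene id {g.gene_id}")
                seen.add(g.gene_id)
                if g.start <= prev:
                    raise FormatError(
                        f"scaffold {scaf}: gene order not strictly increasing "
                        f"at {g.gene_id}"
                    )
                prev = g.start
        if self.sequences is not None:
            for scaf in self.scaffolds:
                if scaf not in self.sequences:
                    raise FormatError(f"no sequence for scaffold {scaf}")

    # -- convenience views used across the pipeline ---------------------------

    def genes(self) -> Iterable[GeneModel]:
        for genes in self.scaffolds.values():
            yield from genes

    @property
    def n_genes(self) -> int:
        return sum(len(g) for g in self.scaffolds.values())

    def gene(self, gene_id: str) -> GeneModel:
        for g in self.genes():
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def gene_index(self) -> dict[str, tuple[str, int]]:
        """gene_id -> (scaffold_id, position index within scaffold)."""
        out: dict[str, tuple[str, int]] = {}
        for scaf, genes in self.scaffolds.items():
            for i, g in enumerate(genes):
                out[g.gene_id] = (scaf, i)
        return out

    def proteins(self) -> dict[str, str]:
        """gene_id -> protein (translated from CDS when not stored)."""
        out = {}
        for g in self.genes():
            if g.protein:
                out[g.gene_id] = g.protein
            elif g.cds:
                out[g.gene_id] = g.translated()
        return out

    def cds_map(self) -> dict[str, str]:
        return {g.gene_id: g.cds for g in self.genes() if g.cds}

    def families(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {}
        for g in self.genes():
            if g.family:
                out.setdefault(g.family, []).append(g)
        return out


@dataclass
class SequencingRead:
    read_id: str
    sequence: str
    quality: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.quality:
            self.quality = "I" * len(self.sequence)
        if len(self.quality) != len(self.sequence):
            raise FormatError(f"read {self.read_id}: quality/sequence length mismatch")


class SpeciesTree:
    """Rooted species tree with unique leaf labels (thin dendropy wrapper)."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise FormatError("species tree has duplicate leaf labels")
        self._labels = labels

    @classmethod
    def from_newick(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(
                data=newick,
                schema="newick",
                preserve_underscores=True,
                rooting="force-rooted",
            )
        except Exception as exc:  # dendropy raises several error types
            raise FormatError(f"malformed newick: {exc}") from exc
        return cls(tree)

    @property
    def leaf_labels(self) -> list[str]:
        return list(self._labels)

    def mrca(self, labels: Iterable[str]) -> dendropy.Node:
        labels = list(labels)
        missing = set(labels) - set(self._labels)
        if missing:
            raise KeyError(f"labels not in tree: {sorted(missing)}")
        if len(labels) == 1:
            return self.tree.find_node_with_taxon_label(labels[0])
        return self.tree.mrca(taxon_labels=labels)

    def is_root(self, node: dendropy.Node) -> bool:
        return node is self.tree.seed_node

    def leaf_set(self, node: dendropy.Node) -> frozenset[str]:
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


@dataclass
class EvidenceFixtureRow:
    """One missing-gene record of the per-species evidence table.

    ``missing_gene`` is None for species with a complete annotation; then both
    evidence fields are "NA". "Poor" coverage carries the observed covered
    fraction of the query.
    """

    species_id: str
    common_name: str
    missing_gene: Optional[str]
    microsynteny: str  # Absent | Unidentified | NA
    blast_coverage: str  # Good | Poor | NA
    poor_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.microsynteny not in ("Absent", "Unidentified", "NA"):
            raise FormatError(f"bad microsynteny value {self.microsynteny!r}")
        if self.blast_coverage not in ("Good", "Poor", "NA"):
            raise FormatError(f"bad coverage value {self.blast_coverage!r}")
        if self.missing_gene is None:
            if self.microsynteny != "NA" or self.blast_coverage != "NA":
                raise FormatError(
                    f"{self.species_id}: no missing gene but evidence recorded"
                )
        else:
            if self.microsynteny == "NA" and self.blast_coverage == "NA":
                raise FormatError(
                    f"{self.species_id}/{self.missing_gene}: missing gene "
                    "without any evidence"
                )
        if self.blast_coverage == "Poor":
            if self.poor_fraction is None or not (0 < self.poor_fraction < 1):
                raise FormatError(
                    f"{self.species_id}/{self.missing_gene}: Poor coverage "
                    "requires a fraction in (0,1)"
                )
        elif self.poor_fraction is not None:
            raise FormatError("poor_fraction only valid with Poor coverage")


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> uppercase-sequence map."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty FASTA record {rec.id!r} in {path}")
        out[rec.id] = seq
    if not out:
        raise FormatError(f"no FASTA records in {path}")
    return out


def write_fasta(sequences: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    records = [
        SeqRecord(Seq(seq.upper()), id=name, description="")
        for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return path


def read_fastq(path: str | Path) -> list[SequencingRead]:
    reads = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            reads.append(
                SequencingRead(
                    rec.id,
                    str(rec.seq),
                    "".join(
                        chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                    ),
                )
            )
    except ValueError as exc:
        raise FormatError(f"malformed FASTQ in {path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[SequencingRead], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality}\n")
    return path


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            raise FormatError(f"bad GFF attribute {part!r}")
        k, v = part.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def read_gff(
    path: str | Path,
    cds_fasta: Optional[str | Path] = None,
    species_id: Optional[str] = None,
) -> AnnotatedGenome:
    """Build an :class:`AnnotatedGenome` from GFF3 gene features.

    Only ``gene`` features are used; each needs an ``ID`` attribute and may
    carry a ``family`` attribute. If ``cds_fasta`` is given, CDS sequences are
    attached by gene id; minus-strand CDS in the FASTA are assumed to be in
    genome (plus-strand) orientation and are reverse-complemented into coding
    orientation here.
    """
    import gffutils

    path = Path(path)
    cds = read_fasta(cds_fasta) if cds_fasta else {}
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    scaffolds: dict[str, list[GeneModel]] = {}
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [None])[0]
        if gene_id is None:
            raise FormatError(f"gene feature without ID at {feat.seqid}:{feat.start}")
        family = feat.attributes.get("family", [None])[0]
        seq = cds.get(gene_id, "")
        if seq and feat.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        gene = GeneModel(
            gene_id=gene_id,
            scaffold_id=feat.seqid,
            start=feat.start,
            end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
            family=family,
            cds=seq,
            protein=str(Seq(seq).translate()).rstrip("*") if seq else "",
        )
        scaffolds.setdefault(feat.seqid, []).append(gene)
    for genes in scaffolds.values():
        genes.sort(key=lambda g: g.start)
    return AnnotatedGenome(
        species_id=species_id or path.stem,
        scaffolds=scaffolds,
    )


def write_gff(genome: AnnotatedGenome, path: str | Path) -> Path:
    """Write gene features (one ``gene`` line per GeneModel)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaf, genes in genome.scaffolds.items():
            for g in genes:
                attrs = f"ID={g.gene_id}"
                if g.family:
                    attrs += f";family={g.family}"
                fh.write(
                    f"{scaf}\twgdscan\tgene\t{g.start}\t{g.end}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )
    return path


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------


def read_newick(path: str | Path) -> SpeciesTree:
    text = Path(path).read_text()
    return SpeciesTree.from_newick(text)


# ---------------------------------------------------------------------------
# Fixture tables
# ---------------------------------------------------------------------------


def read_evidence_fixture(path: str | Path) -> list[EvidenceFixtureRow]:
    """Read a per-species missing-gene evidence TSV.

    Columns: species_id, common_name, missing_gene, microsynteny,
    blast_coverage (``Poor(0.34)`` style for Poor cells). Species with several
    missing genes contribute one row per gene.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("NA")
    rows = []
    for _, r in df.iterrows():
        cov = r["blast_coverage"]
        frac = None
        if cov.startswith("Poor"):
            if "(" not in cov:
                raise FormatError(
                    f"{r['species_id']}: Poor coverage without a fraction"
                )
            frac = float(cov[cov.index("(") + 1 : cov.index(")")])
            cov = "Poor"
        missing = r["missing_gene"] if r["missing_gene"] != "NA" else None
        rows.append(
            EvidenceFixtureRow(
                species_id=r["species_id"],
                common_name=r["common_name"],
                missing_gene=missing,
                microsynteny=r["microsynteny"],
                blast_coverage=cov,
                poor_fraction=frac,
            )
        )
    return rows


def read_duplication_fixture(path: str | Path) -> pd.DataFrame:
    """Read the pairwise duplication-evidence TSV (Y/N grid).

    Index: family pair ("DRD1A/DRD1B"); columns: micro_2Mb, micro_12Mb,
    synfind, synmap_colinear, synmap_density, paralogy.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).set_index("pair")
    expected = [
        "micro_2Mb",
        "micro_12Mb",
        "synfind",
        "synmap_colinear",
        "synmap_density",
        "paralogy",
    ]
    if list(df.columns) != expected:
        raise FormatError(f"duplication fixture columns must be {expected}")
    bad = df[~df.isin(["Y", "N"]).all(axis=1)]
    if len(bad):
        raise FormatError(f"non-Y/N cells in rows {list(bad.index)}")
    return df


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("wgdscan") / "data" / name)


def load_table1_fixture() -> list[EvidenceFixtureRow]:
    """The packaged 43-species missing-gene evidence table."""
    return read_evidence_fixture(_data_path("table1_evidence.tsv"))


def load_table2_fixture() -> pd.DataFrame:
    """The packaged pairwise duplication-evidence grid."""
    return read_duplication_fixture(_data_path("table2_evidence.tsv"))


def load_species_tree_fixture() -> SpeciesTree:
    """The packaged 43-species rooted tree."""
    return read_newick(_data_path("figure2_species_tree.nwk"))
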