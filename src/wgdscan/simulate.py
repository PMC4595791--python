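"""Synthetic genomes with a planted duplication-and-loss history.

The generator emulates the evolutionary scenario the pipeline is built to
detect: a single ancestral gene complement passes through one whole-genome
duplication at a controlled synonymous depth, loses duplicate copies through
fractionation, speciates along a given tree accumulating per-branch Ks, and
finally suffers lineage-specific gene deletions, annotation dropouts (sequence
retained, gene model lost), assembly fragmentation, and shotgun read
sampling. Every stage records ground truth so downstream calls can be scored.

Sequence evolution is per-codon single-nucleotide substitution: proposals are
uniform over positions and alternative bases, changes creating stop codons are
rejected, synonymous changes are always accepted and nonsynonymous ones with
probability omega (= Ka/Ks). The number of accepted synonymous events is drawn
as Poisson(target_ks x synonymous sites), which makes the NG86 + Jukes-Cantor
estimator asymptotically unbiased for the planted Ks at moderate divergence.
"""

from __future__ import annotations

import copy
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .formats import AnnotatedGenome, GeneModel, SequencingRead, SpeciesTree
from .ksdist import synonymous_sites

__all__ = [
    "SimulationConfig",
    "HomeologPair",
    "SimulatedTruth",
    "LossEvent",
    "derive_rng",
    "generate_ancestral_genome",
    "evolve_cds",
    "apply_wgd",
    "fractionate",
    "speciate",
    "degrade",
    "assemble_sequences",
    "run_simulation",
    "SimulationResult",
]

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_CODON_TABLE = {}


def _aa(codon: str) -> str:
    from Bio.Seq import Seq

    if codon not in _CODON_TABLE:
        _CODON_TABLE[codon] = str(Seq(codon).translate())
    return _CODON_TABLE[codon]


_SAFE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS
]

MAX_TARGET_KS = 3.0  # saturation guard of the mutation process

DEFAULT_FAMILIES = ["DRD1A", "DRD1B", "DRD1C", "DRD1E", "DRD2", "DRD3", "DRD4"]


def derive_rng(seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-stage generator from one global seed."""
    sub = (int(seed) ^ zlib.crc32(tag.encode())) % (2**31)
    return np.random.default_rng(sub)


@dataclass(frozen=True)
class HomeologPair:
    gene_a: str
    gene_b: str
    target_ks: float


@dataclass(frozen=True)
class LossEvent:
    species: frozenset[str]
    family: str
    mode: str  # delete_sequence | drop_annotation

    def __post_init__(self) -> None:
        if self.mode not in ("delete_sequence", "drop_annotation"):
            raise ValueError(f"bad loss mode {self.mode!r}")


@dataclass
class SimulatedTruth:
    """Ground truth: per-species family status plus the homeolog registry."""

    statuses: dict[str, dict[str, str]] = field(default_factory=dict)
    pairs: list[HomeologPair] = field(default_factory=list)


@dataclass
class SimulationConfig:
    """The planted history. Defaults mirror the study's inferred scenario:
    one ancient WGD (desk-scale Ks depth 1.0), moderate duplicate retention,
    two sister species at ortholog divergence Ks ~ 0.16, receptor-like focal
    families among a background gene complement, 20x error-free shotgun
    reads."""

    seed: int = 0
    n_scaffolds: int = 2
    genes_per_scaffold: int = 20
    gene_length_codons: int = 200
    family_labels: list[str] = field(default_factory=lambda: list(DEFAULT_FAMILIES))
    wgd_ks: float = 1.0
    retention_prob: float = 0.7
    species_tree: str = "(sp1,sp2);"
    branch_ks: dict[str, float] = field(
        default_factory=lambda: {"sp1": 0.08, "sp2": 0.08}
    )
    omega: float = 0.2
    loss_events: list[LossEvent] = field(default_factory=list)
    read_length: int = 100
    read_depth: float = 20.0
    fragmentation_rate: float = 0.0
    spacer_bp: int = 300
    read_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.retention_prob <= 1.0:
            raise ValueError("retention_prob must be in [0,1]")
        if self.wgd_ks <= 0:
            raise ValueError("wgd_ks must be > 0")
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError("omega must be in [0,1]")
        leaves = set(SpeciesTree.from_newick(self.species_tree).leaf_labels)
        for ev in self.loss_events:
            unknown = set(ev.species) - leaves
            if unknown:
                raise ValueError(f"loss event species not in tree: {unknown}")


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def evolve_cds(
    cds: str,
    target_ks: float,
    omega: float,
    rng: np.random.Generator,
) -> str:
    """Mutate a CDS to an expected synonymous divergence of ``target_ks``."""
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    if target_ks > MAX_TARGET_KS:
        raise ValueError(
            f"target_ks {target_ks} beyond saturation guard {MAX_TARGET_KS}"
        )
    if target_ks == 0 and omega == 0:
        return cds
    s_sites = synonymous_sites(cds)
    n_syn_target = int(rng.poisson(target_ks * s_sites)) if target_ks > 0 else 0
    seq = list(cds)
    n_codons = len(cds) // 3
    accepted_syn = 0
    guard = 0
    max_iter = 1000 * (n_syn_target + 1) + 10_000
    while accepted_syn < n_syn_target and guard < max_iter:
        guard += 1
        pos = int(rng.integers(0, 3 * n_codons))
        ci = pos // 3
        codon = "".join(seq[3 * ci : 3 * ci + 3])
        cur = seq[pos]
        alt = _BASES[int(rng.integers(0, 4))]
        if alt == cur:
            continue
        mut = codon[: pos % 3] + alt + codon[pos % 3 + 1 :]
        if mut in _STOPS:
            continue
        if _aa(mut) == _aa(codon):
            seq[pos] = alt
            accepted_syn += 1
        elif omega > 0 and rng.random() < omega:
            seq[pos] = alt
    return "".join(seq)


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    idx = rng.integers(0, len(_SAFE_CODONS), size=n_codons)
    return "".join(_SAFE_CODONS[i] for i in idx)


def _relayout(genes: list[GeneModel], spacer_bp: int) -> list[GeneModel]:
    """Reassign 1-based coordinates: genes separated by spacer_bp gaps."""
    out = []
    cursor = spacer_bp + 1
    for g in genes:
        length = len(g.cds)
        out.append(replace(g, start=cursor, end=cursor + length - 1))
        cursor += length + spacer_bp
    return out


def _build_genome(
    species_id: str,
    scaffolds: dict[str, list[GeneModel]],
    spacer_bp: int,
    profile: Optional[dict] = None,
) -> AnnotatedGenome:
    laid = {
        scaf: _relayout(genes, spacer_bp) for scaf, genes in scaffolds.items()
    }
    return AnnotatedGenome(
        species_id=species_id,
        scaffolds=laid,
        assembly_profile=profile or {},
    )


def generate_ancestral_genome(config: SimulationConfig) -> AnnotatedGenome:
    """Random ancestral gene complement with focal families planted at
    evenly spaced positions; deterministic under the config seed."""
    rng = derive_rng(config.seed, "ancestor")
    total_slots = config.n_scaffolds * config.genes_per_scaffold
    n_fam = len(config.family_labels)
    if n_fam > total_slots:
        raise ValueError(
            f"{n_fam} family labels need at least {n_fam} gene slots, "
            f"got {total_slots}"
        )
    # families at evenly spaced positions of the flattened slot grid
    flat: list[Optional[str]] = [None] * total_slots
    for fi, fam in enumerate(config.family_labels):
        pos = ((fi + 1) * total_slots) // (n_fam + 1)
        while flat[pos] is not None:
            pos = (pos + 1) % total_slots
        flat[pos] = fam
    per_scaffold = {
        f"s{si}": flat[
            si * config.genes_per_scaffold : (si + 1) * config.genes_per_scaffold
        ]
        for si in range(config.n_scaffolds)
    }
    scaffolds: dict[str, list[GeneModel]] = {}
    for scaf, fams in per_scaffold.items():
        genes = []
        for gi, fam in enumerate(fams):
            cds = _random_cds(config.gene_length_codons, rng)
            genes.append(
                GeneModel(
                    gene_id=f"{scaf}g{gi:03d}",
                    scaffold_id=scaf,
                    start=1,
                    end=len(cds),
                    family=fam,
                    cds=cds,
                )
            )
        scaffolds[scaf] = genes
    return _build_genome("ancestor", scaffolds, config.spacer_bp)


def apply_wgd(
    genome: AnnotatedGenome,
    wgd_ks: float,
    rng: np.random.Generator,
    omega: float = 0.2,
    spacer_bp: int = 300,
) -> tuple[AnnotatedGenome, list[HomeologPair]]:
    """Duplicate every scaffold; evolve each copy to half the target depth so
    homeolog pairs sit at mutual Ks ~ wgd_ks. Returns the pair registry."""
    scaffolds: dict[str, list[GeneModel]] = {}
    registry: list[HomeologPair] = []
    for scaf, genes in genome.scaffolds.items():
        for suffix in ("A", "B"):
            new = []
            for g in genes:
                cds = evolve_cds(g.cds, wgd_ks / 2.0, omega, rng)
                new.append(
                    replace(
                        g,
                        gene_id=f"{g.gene_id}_{suffix}",
                        scaffold_id=f"{scaf}_{suffix}",
                        cds=cds,
                        protein="",
                    )
                )
            scaffolds[f"{scaf}_{suffix}"] = new
        for g in genes:
            registry.append(
                HomeologPair(f"{g.gene_id}_A", f"{g.gene_id}_B", wgd_ks)
            )
    out = _build_genome(genome.species_id, scaffolds, spacer_bp)
    return out, registry


def fractionate(
    genome: AnnotatedGenome,
    retention_prob: float,
    rng: np.random.Generator,
    registry: Sequence[HomeologPair],
    spacer_bp: int = 300,
) -> AnnotatedGenome:
    """Post-WGD duplicate loss: with probability 1 - retention_prob a pair
    loses one copy, chosen uniformly at random — never both, so family
    presence is preserved (lineage losses are modeled separately)."""
    if not 0.0 <= retention_prob <= 1.0:
        raise ValueError("retention_prob must be in [0,1]")
    present = {g.gene_id for g in genome.genes()}
    doomed: set[str] = set()
    for pair in registry:
        if pair.gene_a not in present or pair.gene_b not in present:
            continue
        if rng.random() < 1.0 - retention_prob:
            victim = pair.gene_a if rng.random() < 0.5 else pair.gene_b
            doomed.add(victim)
    scaffolds = {
        scaf: [g for g in genes if g.gene_id not in doomed]
        for scaf, genes in genome.scaffolds.items()
    }
    return _build_genome(genome.species_id, scaffolds, spacer_bp)


def speciate(
    genome: AnnotatedGenome,
    species_tree: SpeciesTree | str,
    branch_ks: dict[str, float],
    rng: np.random.Generator,
    omega: float = 0.2,
    spacer_bp: int = 300,
) -> dict[str, AnnotatedGenome]:
    """Evolve the genome along every branch of the tree; one genome per leaf.

    ``branch_ks`` is keyed by node label (leaf taxon label, or internal node
    label when present); unlisted branches accumulate zero synonymous
    divergence. Root-to-leaf Ks is additive in expectation. Leaf gene ids are
    prefixed ``species|``; family labels are preserved.
    """
    if isinstance(species_tree, str):
        species_tree = SpeciesTree.from_newick(species_tree)
    out: dict[str, AnnotatedGenome] = {}

    def node_label(node) -> Optional[str]:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    def recurse(node, genes_by_scaffold: dict[str, list[GeneModel]]) -> None:
        label = node_label(node)
        ks = float(branch_ks.get(label, 0.0)) if label else 0.0
        if ks > 0:
            genes_by_scaffold = {
                scaf: [
                    replace(g, cds=evolve_cds(g.cds, ks, omega, rng), protein="")
                    for g in genes
                ]
                for scaf, genes in genes_by_scaffold.items()
            }
        if node.is_leaf():
            sp = label
            scaffolds = {
                f"{sp}|{scaf}": [
                    replace(
                        g,
                        gene_id=f"{sp}|{g.gene_id}",
                        scaffold_id=f"{sp}|{scaf}",
                    )
                    for g in genes
                ]
                for scaf, genes in genes_by_scaffold.items()
            }
            out[sp] = _build_genome(sp, scaffolds, spacer_bp)
            return
        for child in node.child_nodes():
            child_genes = {
                scaf: [copy.copy(g) for g in genes]
                for scaf, genes in genes_by_scaffold.items()
            }
            recurse(child, child_genes)

    recurse(species_tree.tree.seed_node, dict(genome.scaffolds))
    return out


# ---------------------------------------------------------------------------
# degradation: losses, assembly, fragmentation, reads
# ---------------------------------------------------------------------------


def assemble_sequences(
    genome: AnnotatedGenome,
    rng: np.random.Generator,
    spacer_bp: int = 300,
) -> AnnotatedGenome:
    """Attach scaffold nucleotide sequences: gene CDS joined by random
    intergenic spacers, with coordinates updated to match."""
    scaffolds: dict[str, list[GeneModel]] = {}
    sequences: dict[str, str] = {}
    for scaf, genes in genome.scaffolds.items():
        parts = []
        new_genes = []
        cursor = 0
        for g in genes:
            spacer = "".join(
                _BASES[i] for i in rng.integers(0, 4, size=spacer_bp)
            )
            parts.append(spacer)
            cursor += spacer_bp
            new_genes.append(replace(g, start=cursor + 1, end=cursor + len(g.cds)))
            parts.append(g.cds)
            cursor += len(g.cds)
        tail = "".join(_BASES[i] for i in rng.integers(0, 4, size=spacer_bp))
        parts.append(tail)
        scaffolds[scaf] = new_genes
        sequences[scaf] = "".join(parts)
    return AnnotatedGenome(
        species_id=genome.species_id,
        scaffolds=scaffolds,
        sequences=sequences,
        assembly_profile=dict(genome.assembly_profile),
    )


def _fragment(
    assembly: AnnotatedGenome,
    rate_per_mb: float,
    rng: np.random.Generator,
) -> AnnotatedGenome:
    """Insert scaffold breaks at Poisson-distributed intergenic positions."""
    if rate_per_mb <= 0:
        return assembly
    scaffolds: dict[str, list[GeneModel]] = {}
    sequences: dict[str, str] = {}
    for scaf, genes in assembly.scaffolds.items():
        seq = assembly.sequences[scaf]
        n_breaks = int(rng.poisson(rate_per_mb * len(seq) / 1e6))
        # breaks land only in intergenic gaps so no gene model is bisected
        gaps = []
        prev_end = 0
        for g in genes:
            if g.start - 1 > prev_end:
                gaps.append((prev_end, g.start - 1))
            prev_end = g.end
        if prev_end < len(seq):
            gaps.append((prev_end, len(seq)))
        if not gaps:
            n_breaks = 0
        cuts = sorted(
            {
                int(rng.integers(lo + 1, hi))
                for lo, hi in (
                    gaps[int(rng.integers(0, len(gaps)))] for _ in range(n_breaks)
                )
                if hi - lo > 1
            }
        )
        pieces = []
        start = 0
        for cut in cuts + [len(seq)]:
            pieces.append((start, cut))
            start = cut
        for pi, (lo, hi) in enumerate(pieces):
            name = scaf if len(pieces) == 1 else f"{scaf}.{pi}"
            piece_genes = [
                replace(g, scaffold_id=name, start=g.start - lo, end=g.end - lo)
                for g in genes
                if g.start > lo and g.end <= hi
            ]
            scaffolds[name] = piece_genes
            sequences[name] = seq[lo:hi]
    return AnnotatedGenome(
        species_id=assembly.species_id,
        scaffolds=scaffolds,
        sequences=sequences,
        assembly_profile=dict(assembly.assembly_profile),
    )


def degrade(
    genome: AnnotatedGenome,
    loss_events: Sequence[LossEvent],
    fragmentation_rate: float,
    read_length: int,
    read_depth: float,
    rng: np.random.Generator,
    spacer_bp: int = 300,
    read_error_rate: float = 0.0,
) -> tuple[AnnotatedGenome, list[SequencingRead], dict[str, str]]:
    """Turn an evolved genome into an (assembly, reads, truth) triple.

    delete_sequence removes the gene's bases from scaffold and reads;
    drop_annotation removes only the gene model (the sequence stays and is
    recoverable from reads); fragmentation splits scaffolds at intergenic
    positions; reads are sampled uniformly from the degraded scaffolds.
    """
    truth = {fam: "present_annotated" for fam in genome.families()}
    mine = [ev for ev in loss_events if genome.species_id in ev.species]

    deleted_fams = {ev.family for ev in mine if ev.mode == "delete_sequence"}
    dropped_fams = {ev.family for ev in mine if ev.mode == "drop_annotation"}
    scaffolds = {
        scaf: [g for g in genes if g.family not in deleted_fams]
        for scaf, genes in genome.scaffolds.items()
    }
    for fam in deleted_fams:
        if fam in truth:
            truth[fam] = "absent"
    assembly = assemble_sequences(
        AnnotatedGenome(genome.species_id, scaffolds), rng, spacer_bp
    )
    if dropped_fams:
        assembly = AnnotatedGenome(
            species_id=assembly.species_id,
            scaffolds={
                scaf: [g for g in genes if g.family not in dropped_fams]
                for scaf, genes in assembly.scaffolds.items()
            },
            sequences=assembly.sequences,
        )
        for fam in dropped_fams:
            if fam in truth:
                truth[fam] = "present_unannotated"
    assembly = _fragment(assembly, fragmentation_rate, rng)

    total = sum(len(s) for s in assembly.sequences.values())
    n_reads = math.ceil(read_depth * total / read_length)
    names = sorted(assembly.sequences)
    weights = np.array([len(assembly.sequences[n]) for n in names], dtype=float)
    weights /= weights.sum()
    reads: list[SequencingRead] = []
    picks = rng.choice(len(names), size=n_reads, p=weights)
    for ri, si in enumerate(picks):
        seq = assembly.sequences[names[si]]
        if len(seq) <= read_length:
            frag = seq
        else:
            start = int(rng.integers(0, len(seq) - read_length + 1))
            frag = seq[start : start + read_length]
        if read_error_rate > 0:
            frag = list(frag)
            for i in range(len(frag)):
                if rng.random() < read_error_rate:
                    frag[i] = _BASES[int(rng.integers(0, 4))]
            frag = "".join(frag)
        reads.append(SequencingRead(f"{genome.species_id}_r{ri}", frag))
    profile = dict(assembly.assembly_profile)
    lens = sorted((len(s) for s in assembly.sequences.values()), reverse=True)
    acc, n50 = 0, 0
    for L in lens:
        acc += L
        if acc * 2 >= total:
            n50 = L
            break
    profile.update({"scaffold_n50": n50, "read_coverage_depth": read_depth})
    assembly.assembly_profile = profile
    return assembly, reads, truth


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    config: SimulationConfig
    ancestor: AnnotatedGenome
    wgd_genome: AnnotatedGenome  # post-WGD, post-fractionation, pre-speciation
    pre_wgd_registry: list[HomeologPair]
    species_genomes: dict[str, AnnotatedGenome]
    assemblies: dict[str, AnnotatedGenome]
    reads: dict[str, list[SequencingRead]]
    truth: SimulatedTruth

    def surviving_base_pairs(self) -> list[HomeologPair]:
        """Registry pairs with both members surviving fractionation.

        Measured on :attr:`wgd_genome`, the pair's mutual Ks targets the
        planted ``wgd_ks``; at the leaves it additionally carries twice the
        root-to-leaf branch Ks, since both homeologs keep evolving.
        """
        present = {g.gene_id for g in self.wgd_genome.genes()}
        return [
            p
            for p in self.truth.pairs
            if p.gene_a in present and p.gene_b in present
        ]

    def surviving_pairs(self, species: str) -> list[HomeologPair]:
        """Registry pairs with both members present in a species' genome."""
        present = {g.gene_id for g in self.species_genomes[species].genes()}
        out = []
        for p in self.truth.pairs:
            a, b = f"{species}|{p.gene_a}", f"{species}|{p.gene_b}"
            if a in present and b in present:
                out.append(HomeologPair(a, b, p.target_ks))
        return out


def run_simulation(config: SimulationConfig) -> SimulationResult:
    """Full planted history: ancestor -> WGD -> fractionation -> speciation
    -> per-species degradation and read sampling. Deterministic under
    (config, seed)."""
    ancestor = generate_ancestral_genome(config)
    g, registry = apply_wgd(
        ancestor,
        config.wgd_ks,
        derive_rng(config.seed, "wgd"),
        omega=config.omega,
        spacer_bp=config.spacer_bp,
    )
    g = fractionate(
        g,
        config.retention_prob,
        derive_rng(config.seed, "fractionate"),
        registry,
        spacer_bp=config.spacer_bp,
    )
    species_genomes = speciate(
        g,
        config.species_tree,
        config.branch_ks,
        derive_rng(config.seed, "speciate"),
        omega=config.omega,
        spacer_bp=config.spacer_bp,
    )
    truth = SimulatedTruth(pairs=list(registry))
    assemblies: dict[str, AnnotatedGenome] = {}
    reads: dict[str, list[SequencingRead]] = {}
    for sp in sorted(species_genomes):
        assembly, sp_reads, sp_truth = degrade(
            species_genomes[sp],
            config.loss_events,
            config.fragmentation_rate,
            config.read_length,
            config.read_depth,
            derive_rng(config.seed, f"degrade:{sp}"),
            spacer_bp=config.spacer_bp,
            read_error_rate=config.read_error_rate,
        )
        assemblies[sp] = assembly
        reads[sp] = sp_reads
        truth.statuses[sp] = sp_truth
    return SimulationResult(
        config=config,
        ancestor=ancestor,
        wgd_genome=g,
        pre_wgd_registry=list(registry),
        species_genomes=species_genomes,
        assemblies=assemblies,
        reads=reads,
        truth=truth,
    )
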