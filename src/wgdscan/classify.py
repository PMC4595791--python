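"""Three-state presence calling, the species x family matrix, and Dollo
ancestral reconstruction.

Evidence integration follows one rule: an annotated gene is Present; an
unannotated gene is called Absent only when *both* independent negative lines
agree — microsynteny finds the locus intact but empty AND raw-read coverage
of known orthologs is Poor. Any positive or ambiguous evidence (Good
coverage, similarity at the locus, an unassembled region) keeps the gene as
UnannotatedPresent. This conjunction is the only rule consistent with every
recorded evidence combination in the packaged species table.

Ancestral family counts use Dollo parsimony: each family is gained exactly
once (at the MRCA of the species carrying it) and may be lost any number of
times; the minimal loss set is one loss per maximal all-absent clade below
the gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .formats import EvidenceFixtureRow, SpeciesTree

__all__ = [
    "PresenceCall",
    "AncestralReconstruction",
    "call_presence",
    "build_matrix",
    "matrix_from_calls",
    "dollo_root_count",
    "losses_non_nested",
    "check_family_monophyly",
    "STATES",
    "FAMILIES",
]

STATES = ("Present", "UnannotatedPresent", "Absent")
FAMILIES = ["DRD1A", "DRD1B", "DRD1C", "DRD1E", "DRD2", "DRD3", "DRD4"]

_MICRO_VALUES = ("Absent", "Unidentified", "FoundUnannotated", "NA")
_COVERAGE_VALUES = ("Good", "Poor", "Inconclusive", "NA")


@dataclass
class PresenceCall:
    species: str
    family: str
    state: str
    annotated: bool = False
    microsynteny: str = "NA"
    coverage: str = "NA"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"bad state {self.state!r}")
        if self.annotated and self.state != "Present":
            raise ValueError("annotated gene must be Present")
        if self.state == "Absent" and not (
            self.microsynteny == "Absent" and self.coverage == "Poor"
        ):
            raise ValueError("Absent requires negative microsynteny AND Poor coverage")


def call_presence(
    annotated: bool, microsynteny_outcome: str, coverage_class: str
) -> str:
    """Total, deterministic decision rule over the evidence space."""
    if microsynteny_outcome not in _MICRO_VALUES:
        raise ValueError(f"bad microsynteny outcome {microsynteny_outcome!r}")
    if coverage_class not in _COVERAGE_VALUES:
        raise ValueError(f"bad coverage class {coverage_class!r}")
    if annotated:
        return "Present"
    if microsynteny_outcome == "NA" and coverage_class == "NA":
        raise ValueError("no evidence gathered for an unannotated gene")
    if microsynteny_outcome == "Absent" and coverage_class == "Poor":
        return "Absent"
    return "UnannotatedPresent"


def build_matrix(
    rows: Sequence[EvidenceFixtureRow],
    species_list: Optional[Sequence[str]] = None,
    family_list: Sequence[str] = tuple(FAMILIES),
) -> pd.DataFrame:
    """Presence matrix (species x family) from an evidence table.

    Cells without a recorded missing-gene row are annotated, hence Present;
    recorded rows go through :func:`call_presence`.
    """
    species = list(species_list) if species_list else []
    for r in rows:
        if r.species_id not in species:
            species.append(r.species_id)
    matrix = pd.DataFrame("Present", index=species, columns=list(family_list))
    for r in rows:
        if r.missing_gene is None:
            continue
        if r.missing_gene not in matrix.columns:
            raise KeyError(f"unknown family {r.missing_gene!r}")
        state = call_presence(False, r.microsynteny, r.blast_coverage)
        matrix.loc[r.species_id, r.missing_gene] = state
    return matrix


def matrix_from_calls(
    calls: Sequence[PresenceCall],
    species_list: Sequence[str],
    family_list: Sequence[str],
) -> pd.DataFrame:
    matrix = pd.DataFrame(
        "Present", index=list(species_list), columns=list(family_list)
    )
    for c in calls:
        matrix.loc[c.species, c.family] = c.state
    return matrix


@dataclass
class AncestralReconstruction:
    root_count: int
    root_families: list[str]
    gains: dict[str, frozenset[str]] = field(default_factory=dict)
    losses: dict[str, list[frozenset[str]]] = field(default_factory=dict)


def dollo_root_count(
    matrix: pd.DataFrame, tree: SpeciesTree
) -> AncestralReconstruction:
    """Single-gain / minimal-loss reconstruction per family.

    Present and UnannotatedPresent both count as present. The gain sits at
    the MRCA of all present leaves; the family is ancestral iff that MRCA is
    the root. Losses are one per maximal clade of absent leaves below the
    gain; each is reported as the clade's leaf set.
    """
    missing = set(matrix.index) - set(tree.leaf_labels)
    if missing:
        raise KeyError(f"matrix species not in tree: {sorted(missing)}")
    recon = AncestralReconstruction(root_count=0, root_families=[])
    for family in matrix.columns:
        present = [
            sp for sp in matrix.index if matrix.loc[sp, family] != "Absent"
        ]
        if not present:
            recon.losses[family] = []
            continue
        gain_node = tree.mrca(present)
        recon.gains[family] = tree.leaf_set(gain_node)
        if tree.is_root(gain_node):
            recon.root_count += 1
            recon.root_families.append(family)
        absent = {
            sp for sp in matrix.index if matrix.loc[sp, family] == "Absent"
        }
        losses: list[frozenset[str]] = []

        def walk(node) -> None:
            leaves = tree.leaf_set(node)
            scored = leaves & set(matrix.index)
            if scored and scored <= absent:
                losses.append(frozenset(leaves))
                return
            for child in node.child_nodes():
                walk(child)

        walk(gain_node)
        recon.losses[family] = losses
    return recon


def losses_non_nested(
    recon: AncestralReconstruction, family_a: str, family_b: str
) -> bool:
    """True when no loss clade of one family contains a loss clade of the
    other — the losses happened on independent branches."""
    for la in recon.losses.get(family_a, []):
        for lb in recon.losses.get(family_b, []):
            if la <= lb or lb <= la:
                return False
    return True


# ---------------------------------------------------------------------------
# family monophyly (distance NJ)
# ---------------------------------------------------------------------------


def _p_distance(a: str, b: str) -> float:
    if len(a) == len(b):
        if not a:
            return 0.0
        return sum(x != y for x, y in zip(a, b)) / len(a)
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = next(iter(aligner.align(a, b)))
    matches = total = 0
    for (qs, qe), (ss, se) in zip(aln.aligned[0], aln.aligned[1]):
        for k in range(qe - qs):
            total += 1
            if a[qs + k] == b[ss + k]:
                matches += 1
    return 1.0 - matches / total if total else 1.0


def check_family_monophyly(
    proteins_by_family: dict[str, dict[str, str]],
) -> dict[str, Optional[bool]]:
    """Does each family form a clade in a p-distance NJ tree of all members?

    Monophyly is read off the unrooted tree: a family is monophyletic iff
    some edge bipartition separates exactly its members. Families involved in
    zero-distance ties across family boundaries are reported as None.
    """
    from Bio.Phylo.TreeConstruction import DistanceTreeConstructor, DistanceMatrix

    names, seqs, fam_of = [], [], {}
    for fam, members in proteins_by_family.items():
        for name, seq in members.items():
            names.append(name)
            seqs.append(seq)
            fam_of[name] = fam
    n = len(names)
    dist = [[0.0] * (i + 1) for i in range(n)]
    for i in range(n):
        for j in range(i):
            dist[i][j] = _p_distance(seqs[i], seqs[j])
    ties = {
        fam: None
        for fam in proteins_by_family
        if any(
            dist[max(i, j)][min(i, j)] == 0.0 and fam_of[names[i]] != fam_of[names[j]]
            and fam in (fam_of[names[i]], fam_of[names[j]])
            for i in range(n)
            for j in range(i)
        )
    }
    tree = DistanceTreeConstructor().nj(DistanceMatrix(names, dist))
    bipartitions = []
    all_leaves = frozenset(names)
    for clade in tree.get_nonterminals() + tree.get_terminals():
        side = frozenset(t.name for t in clade.get_terminals())
        bipartitions.append(side)
        bipartitions.append(all_leaves - side)
    out: dict[str, Optional[bool]] = {}
    for fam, members in proteins_by_family.items():
        if fam in ties:
            out[fam] = None
            continue
        fam_set = frozenset(members)
        out[fam] = fam_set in bipartitions
    return out
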