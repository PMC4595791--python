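"""Syntenic block detection and targeted microsynteny checks.

Two genome-wide detectors over homolog anchors mapped to gene-order indices:

* **colinear** — maximal chains of anchors monotone on both genomes (either
  orientation) with adjacent index gaps no larger than the window on either
  axis; chains shorter than ``min_anchors`` are dropped. This is the classic
  "4 collinear genes within a 40 gene window" criterion.
* **density** — window pairs (``window`` consecutive genes on each genome)
  holding at least ``min_anchors`` anchors in any order; qualifying window
  pairs sharing anchors merge into one block. Order-free, so it survives the
  local rearrangements that erode collinearity after a WGD.

On top of the blocks: a per-gene syntenic lookup (find the region/gene in
another genome via flanking anchors) and a microsynteny check that decides
whether a locus where an annotation is missing is truly empty (Absent), holds
unannotated sequence (FoundUnannotated), or is unassembled (Unidentified).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import homology
from .formats import AnnotatedGenome

__all__ = [
    "SyntenyParams",
    "Anchor",
    "SyntenyBlock",
    "MicrosyntenyCall",
    "LookupResult",
    "anchors_from_pairs",
    "detect_collinear_blocks",
    "detect_density_blocks",
    "syntenic_lookup",
    "microsynteny_check",
]

MICRO_WINDOW_2MB = 2_000_000
MICRO_WINDOW_12MB = 12_000_000


@dataclass
class SyntenyParams:
    min_anchors: int = 4
    window: int = 40
    mode: str = "colinear"  # or "density"
    micro_window: int = MICRO_WINDOW_2MB

    def __post_init__(self) -> None:
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")
        if self.window < self.min_anchors:
            raise ValueError("window must be >= min_anchors")
        if self.mode not in ("colinear", "density"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class Anchor:
    """A homolog pair located by scaffold and gene-order index."""

    gene_a: str
    gene_b: str
    scaffold_a: str
    index_a: int
    scaffold_b: str
    index_b: int


@dataclass
class SyntenyBlock:
    scaffold_a: str
    scaffold_b: str
    anchors: list[Anchor]
    mode: str
    span_a: tuple[int, int] = (0, 0)
    span_b: tuple[int, int] = (0, 0)
    orientation: Optional[str] = None  # "same"|"inverted" (colinear only)

    def __post_init__(self) -> None:
        ia = [a.index_a for a in self.anchors]
        ib = [a.index_b for a in self.anchors]
        self.span_a = (min(ia), max(ia))
        self.span_b = (min(ib), max(ib))

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class MicrosyntenyCall:
    species: str
    family: str
    outcome: str  # FoundUnannotated | Absent | Unidentified
    flank_support: int

    def __post_init__(self) -> None:
        if self.outcome not in ("FoundUnannotated", "Absent", "Unidentified"):
            raise ValueError(f"bad outcome {self.outcome!r}")
        if self.outcome in ("FoundUnannotated", "Absent") and self.flank_support < 2:
            raise ValueError("anchored outcomes need flank_support >= 2")


def anchors_from_pairs(
    pairs: Sequence[tuple[str, str]],
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
) -> list[Anchor]:
    """Map gene-id pairs to gene-order anchors; unknown genes are an error."""
    idx_a = genome_a.gene_index()
    idx_b = genome_b.gene_index()
    anchors = []
    for ga, gb in pairs:
        if ga not in idx_a:
            raise KeyError(f"anchor gene {ga!r} not in genome {genome_a.species_id}")
        if gb not in idx_b:
            raise KeyError(f"anchor gene {gb!r} not in genome {genome_b.species_id}")
        (sa, ia), (sb, ib) = idx_a[ga], idx_b[gb]
        anchors.append(Anchor(ga, gb, sa, ia, sb, ib))
    return anchors


# ---------------------------------------------------------------------------
# colinear chaining
# ---------------------------------------------------------------------------


def _chain_key(chain: Sequence[Anchor]) -> tuple:
    return tuple((a.index_a, a.index_b) for a in chain)


def _best_chain(
    anchors: list[Anchor], window: int, sign: int
) -> list[Anchor]:
    """Longest strictly-monotone chain (index_b ascending if sign=+1, else
    descending) with adjacent gaps <= window on both axes; ties resolved to
    the lexicographically smallest (index_a, index_b) sequence."""
    if not anchors:
        return []
    pts = sorted(anchors, key=lambda a: (a.index_a, sign * a.index_b))
    n = len(pts)

    def successor(i: int, j: int) -> bool:
        a, b = pts[i], pts[j]
        if b.index_a <= a.index_a:
            return False
        if b.index_a - a.index_a > window:
            return False
        db = sign * (b.index_b - a.index_b)
        return 0 < db <= window

    # f[i] = longest chain starting at i (reverse DP over sorted order)
    f = [1] * n
    for i in range(n - 1, -1, -1):
        for j in range(i + 1, n):
            if successor(i, j) and 1 + f[j] > f[i]:
                f[i] = 1 + f[j]
    best = max(f)
    # greedy reconstruction: smallest start among max-length chains, then
    # smallest next anchor keeping the remaining length achievable
    start = min(
        (i for i in range(n) if f[i] == best),
        key=lambda i: (pts[i].index_a, pts[i].index_b),
    )
    chain = [start]
    need = best - 1
    while need > 0:
        i = chain[-1]
        nxt = min(
            (j for j in range(n) if successor(i, j) and f[j] == need),
            key=lambda j: (pts[j].index_a, pts[j].index_b),
        )
        chain.append(nxt)
        need -= 1
    return [pts[i] for i in chain]


def detect_collinear_blocks(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    anchors: Sequence[Anchor] | Sequence[tuple[str, str]],
    params: Optional[SyntenyParams] = None,
) -> list[SyntenyBlock]:
    """Maximal collinear chains per scaffold pair, extracted best-first.

    Chain score is the anchor count; overlaps are resolved by repeatedly
    extracting the best remaining chain (same orientation preferred on ties,
    then lexicographic anchor order), so each anchor belongs to at most one
    colinear block.
    """
    params = params or SyntenyParams()
    if anchors and not isinstance(anchors[0], Anchor):
        anchors = anchors_from_pairs(anchors, genome_a, genome_b)
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.scaffold_a, a.scaffold_b), []).append(a)

    blocks: list[SyntenyBlock] = []
    for (sa, sb), group in sorted(groups.items()):
        remaining = list(group)
        while True:
            fwd = _best_chain(remaining, params.window, +1)
            rev = _best_chain(remaining, params.window, -1)
            if len(fwd) >= len(rev):
                chain, orient = fwd, "same"
            else:
                chain, orient = rev, "inverted"
            if len(chain) < params.min_anchors:
                break
            blocks.append(
                SyntenyBlock(
                    scaffold_a=sa,
                    scaffold_b=sb,
                    anchors=chain,
                    mode="colinear",
                    orientation=orient,
                )
            )
            used = set(_chain_key(chain))
            remaining = [
                a for a in remaining if (a.index_a, a.index_b) not in used
            ]
    blocks.sort(
        key=lambda b: (b.scaffold_a, b.scaffold_b, b.span_a, b.span_b)
    )
    return blocks


# ---------------------------------------------------------------------------
# density windows
# ---------------------------------------------------------------------------


def detect_density_blocks(
    genome_a: AnnotatedGenome,
    genome_b: AnnotatedGenome,
    anchors: Sequence[Anchor] | Sequence[tuple[str, str]],
    params: Optional[SyntenyParams] = None,
) -> list[SyntenyBlock]:
    """Order-free window detection: any ``window`` x ``window`` gene-index
    window pair holding >= min_anchors anchors qualifies; qualifying window
    pairs sharing anchors merge into one block.

    Only window positions whose left edges sit on anchor coordinates are
    enumerated — every qualifying window's anchor set is preserved under
    shifting its edges right to the first contained anchor, so this produces
    the same merged blocks as scanning every integer start.
    """
    params = params or SyntenyParams()
    if anchors and not isinstance(anchors[0], Anchor):
        anchors = anchors_from_pairs(anchors, genome_a, genome_b)
    groups: dict[tuple[str, str], list[Anchor]] = {}
    for a in anchors:
        groups.setdefault((a.scaffold_a, a.scaffold_b), []).append(a)

    blocks: list[SyntenyBlock] = []
    w = params.window
    for (sa, sb), group in sorted(groups.items()):
        n = len(group)
        if n < params.min_anchors:
            continue
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        def union(i: int, j: int) -> None:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[rj] = ri

        starts_a = sorted({a.index_a for a in group})
        starts_b = sorted({a.index_b for a in group})
        qualified = [False] * n
        for a0 in starts_a:
            for b0 in starts_b:
                members = [
                    k
                    for k, a in enumerate(group)
                    if a0 <= a.index_a < a0 + w and b0 <= a.index_b < b0 + w
                ]
                if len(members) >= params.min_anchors:
                    for k in members[1:]:
                        union(members[0], k)
                    for k in members:
                        qualified[k] = True
        comps: dict[int, list[Anchor]] = {}
        for k, a in enumerate(group):
            if qualified[k]:
                comps.setdefault(find(k), []).append(a)
        for members in comps.values():
            members.sort(key=lambda a: (a.index_a, a.index_b))
            blocks.append(
                SyntenyBlock(
                    scaffold_a=sa,
                    scaffold_b=sb,
                    anchors=members,
                    mode="density",
                )
            )
    blocks.sort(key=lambda b: (b.scaffold_a, b.scaffold_b, b.span_a, b.span_b))
    return blocks


# ---------------------------------------------------------------------------
# per-gene syntenic lookup
# ---------------------------------------------------------------------------


@dataclass
class LookupResult:
    """Outcome of a per-gene syntenic lookup.

    status: "found" (ortholog located), "empty_slot" (region located via
    flanking anchors, no homolog of the query inside), or "no_block" (the
    query's scaffold has no syntenic block covering it).
    """

    status: str
    scaffold_b: Optional[str] = None
    region_b: Optional[tuple[int, int]] = None
    gene_b: Optional[str] = None


def syntenic_lookup(
    query_gene: str,
    query_genome: AnnotatedGenome,
    target_genome: AnnotatedGenome,
    anchors: Sequence[Anchor] | Sequence[tuple[str, str]],
    params: Optional[SyntenyParams] = None,
) -> LookupResult:
    """Locate a gene's syntenic region (and ortholog, if retained) in another
    genome via the colinear block containing its flanking anchors."""
    params = params or SyntenyParams()
    if anchors and not isinstance(anchors[0], Anchor):
        anchors = anchors_from_pairs(anchors, query_genome, target_genome)
    idx = query_genome.gene_index()
    if query_gene not in idx:
        raise KeyError(query_gene)
    scaf, pos = idx[query_gene]
    blocks = detect_collinear_blocks(query_genome, target_genome, anchors, params)
    for block in blocks:
        if block.scaffold_a != scaf:
            continue
        if not block.span_a[0] <= pos <= block.span_a[1]:
            continue
        for anchor in block.anchors:
            if anchor.gene_a == query_gene:
                return LookupResult(
                    status="found",
                    scaffold_b=block.scaffold_b,
                    region_b=(anchor.index_b, anchor.index_b),
                    gene_b=anchor.gene_b,
                )
        left = [a for a in block.anchors if a.index_a < pos]
        right = [a for a in block.anchors if a.index_a > pos]
        if left and right:
            lo = max(left, key=lambda a: a.index_a)
            hi = min(right, key=lambda a: a.index_a)
            region = tuple(sorted((lo.index_b, hi.index_b)))
            return LookupResult(
                status="empty_slot",
                scaffold_b=block.scaffold_b,
                region_b=region,
            )
    return LookupResult(status="no_block")


# ---------------------------------------------------------------------------
# microsynteny locus check
# ---------------------------------------------------------------------------


def microsynteny_check(
    assembly: AnnotatedGenome,
    family_cds: str,
    flank_cds: dict[str, str],
    species: str,
    family: str,
    micro_window: int = MICRO_WINDOW_2MB,
    search_params: Optional[homology.SearchParams] = None,
    min_hsp_coverage: float = 0.5,
    min_flank_coverage: float = 0.3,
) -> MicrosyntenyCall:
    """Decide Absent / FoundUnannotated / Unidentified for one locus.

    The reference locus is the family's CDS plus >= 2 flanking-gene CDS from a
    species where the locus is intact. Flanks are nucleotide-searched against
    the assembly; if fewer than two anchor on one scaffold the region is
    unassembled (Unidentified). Otherwise the family CDS is searched against
    the interval between the outermost flank hits (clipped to micro_window):
    similarity covering >= min_hsp_coverage of the CDS means the sequence is
    there but unannotated (FoundUnannotated); no such similarity with intact
    flanks means the gene is truly gone (Absent).
    """
    if len(flank_cds) < 2:
        raise ValueError("need at least two flanking genes")
    if assembly.sequences is None:
        raise ValueError("assembly must carry scaffold sequences")
    params = search_params or homology.megablast_params()
    hits = []
    try:
        hits = homology.search(flank_cds, assembly.sequences, params)
    except ValueError:
        hits = []
    anchored: dict[str, list[tuple[int, int]]] = {}
    seen_flanks: dict[str, set[str]] = {}
    for h in hits:
        if h.query_coverage < min_flank_coverage:
            continue
        for qs, qe, ss, se, _ in h.hsps:
            anchored.setdefault(h.subject_id, []).append((ss, se))
        seen_flanks.setdefault(h.subject_id, set()).add(h.query_id)
    best_scaf = None
    for scaf, flanks in seen_flanks.items():
        if len(flanks) >= 2 and (
            best_scaf is None or len(flanks) > len(seen_flanks[best_scaf])
        ):
            best_scaf = scaf
    if best_scaf is None:
        return MicrosyntenyCall(species, family, "Unidentified", 0)
    support = len(seen_flanks[best_scaf])
    spans = anchored[best_scaf]
    lo = min(s for s, _ in spans)
    hi = max(e for _, e in spans)
    center = (lo + hi) // 2
    lo = max(1, max(lo, center - micro_window // 2))
    hi = min(len(assembly.sequences[best_scaf]), min(hi, center + micro_window // 2))
    interval = assembly.sequences[best_scaf][lo - 1 : hi]
    if len(interval) < params.word_size:
        return MicrosyntenyCall(species, family, "Absent", support)
    try:
        fam_hits = homology.search({family: family_cds}, {"interval": interval}, params)
    except ValueError:
        fam_hits = []
    covered = any(h.query_coverage >= min_hsp_coverage for h in fam_hits)
    outcome = "FoundUnannotated" if covered else "Absent"
    return MicrosyntenyCall(species, family, outcome, support)
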