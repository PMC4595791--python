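"""Within-genome paralogon detection and the duplication-evidence matrix.

A whole-genome duplication leaves *paralogons*: pairs of regions in one
genome that still share enough duplicated genes to be recognisable long
after most duplicate copies were fractionated away. Region pairs retaining
more than 6 paired proteins are statistically unlikely to arise by chance,
so detection applies an order-free density window over within-genome
homolog pairs and keeps blocks above a paired-protein threshold (7 by
default; 12 for a stricter map).

The evidence matrix integrates six independent detectors per gene-family
pair — microsynteny at two panel widths, per-gene syntenic lookup, genome-
wide colinear and density synteny, and paralogon overlap — into a verdict:
``WGD`` when the strongest signals agree (a colinear block or a paralogon,
or density synteny corroborated by wide-panel microsynteny),
``none`` when every line is negative, else ``segmental_or_unresolved``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from . import synteny
from .formats import AnnotatedGenome

__all__ = [
    "ParalogonBlock",
    "detect_paralogons",
    "gene_pair_in_paralogon",
    "verdict_for_row",
    "build_evidence_matrix_from_fixture",
    "compute_pair_evidence",
    "EVIDENCE_COLUMNS",
    "PARALOGON_THRESHOLD",
    "PARALOGON_THRESHOLD_STRICT",
]

EVIDENCE_COLUMNS = [
    "micro_2Mb",
    "micro_12Mb",
    "synfind",
    "synmap_colinear",
    "synmap_density",
    "paralogy",
]

PARALOGON_THRESHOLD = 7
PARALOGON_THRESHOLD_STRICT = 12


@dataclass
class ParalogonBlock:
    scaffold_a: str
    scaffold_b: str
    anchors: list[synteny.Anchor]
    span_a: tuple[int, int]
    span_b: tuple[int, int]

    @property
    def paired_protein_count(self) -> int:
        return len(self.anchors)


def _canonical_pairs(
    self_hits: Sequence[tuple[str, str]],
) -> list[tuple[str, str]]:
    """Dedupe unordered within-genome pairs; drop self-diagonal matches."""
    seen = set()
    out = []
    for a, b in self_hits:
        if a == b:
            continue
        key = (a, b) if a <= b else (b, a)
        if key not in seen:
            seen.add(key)
            out.append(key)
    return out


def detect_paralogons(
    genome: AnnotatedGenome,
    self_hits: Sequence[tuple[str, str]],
    min_paired_proteins: int = PARALOGON_THRESHOLD,
    window: int = 40,
) -> list[ParalogonBlock]:
    """Density-window block detection of a genome against itself.

    ``self_hits`` are within-genome homolog pairs (gene-id tuples; order and
    duplicates are ignored, self-matches dropped). Blocks with fewer than
    ``min_paired_proteins`` pairs are discarded, so the block set at a higher
    threshold is always a subset of the set at a lower one.
    """
    pairs = _canonical_pairs(self_hits)
    if not pairs:
        return []
    params = synteny.SyntenyParams(
        min_anchors=min_paired_proteins, window=window, mode="density"
    )
    blocks = synteny.detect_density_blocks(genome, genome, pairs, params)
    return [
        ParalogonBlock(
            scaffold_a=b.scaffold_a,
            scaffold_b=b.scaffold_b,
            anchors=b.anchors,
            span_a=b.span_a,
            span_b=b.span_b,
        )
        for b in blocks
        if b.n_anchors >= min_paired_proteins
    ]


def gene_pair_in_paralogon(
    gene_a: str,
    gene_b: str,
    blocks: Sequence[ParalogonBlock],
    genome: AnnotatedGenome,
) -> str:
    """Y iff both genes fall strictly within one block's paired spans."""
    idx = genome.gene_index()
    if gene_a not in idx or gene_b not in idx:
        return "N"
    (sa, ia), (sb, ib) = idx[gene_a], idx[gene_b]
    for blk in blocks:
        for (s1, i1), (s2, i2) in (((sa, ia), (sb, ib)), ((sb, ib), (sa, ia))):
            if (
                blk.scaffold_a == s1
                and blk.scaffold_b == s2
                and blk.span_a[0] <= i1 <= blk.span_a[1]
                and blk.span_b[0] <= i2 <= blk.span_b[1]
            ):
                return "Y"
    return "N"


def verdict_for_row(cells: dict[str, str]) -> str:
    """WGD / segmental_or_unresolved / none from one row of Y/N cells."""
    missing = set(EVIDENCE_COLUMNS) - set(cells)
    if missing:
        raise KeyError(f"missing evidence columns: {sorted(missing)}")
    if all(cells[c] == "N" for c in EVIDENCE_COLUMNS):
        return "none"
    if (
        cells["synmap_colinear"] == "Y"
        or cells["paralogy"] == "Y"
        or (cells["synmap_density"] == "Y" and cells["micro_12Mb"] == "Y")
    ):
        return "WGD"
    return "segmental_or_unresolved"


def build_evidence_matrix_from_fixture(fixture: pd.DataFrame) -> pd.DataFrame:
    """Attach verdicts to a transcribed Y/N evidence grid."""
    out = fixture.copy()
    out["verdict"] = [
        verdict_for_row(row.to_dict()) for _, row in fixture.iterrows()
    ]
    return out


def _flanks_of(
    genome: AnnotatedGenome, gene_id: str, n_flanks: int = 2
) -> dict[str, str]:
    scaf, pos = genome.gene_index()[gene_id]
    genes = genome.scaffolds[scaf]
    picked = {}
    for offset in range(1, len(genes)):
        for j in (pos - offset, pos + offset):
            if 0 <= j < len(genes) and genes[j].gene_id != gene_id:
                g = genes[j]
                if g.cds and g.gene_id not in picked:
                    picked[g.gene_id] = g.cds
        if len(picked) >= 2 * n_flanks:
            break
    return picked


def _intragenomic_microsynteny(
    assembly: AnnotatedGenome,
    gene_a: str,
    gene_b: str,
    micro_window: int,
) -> str:
    """Y iff >= 2 flanking genes of one region find similarity near the
    other region's scaffold position (order-free flank anchoring)."""
    from . import homology

    idx = assembly.gene_index()
    if gene_a not in idx or gene_b not in idx:
        return "N"
    flanks = _flanks_of(assembly, gene_a)
    if len(flanks) < 2 or assembly.sequences is None:
        return "N"
    scaf_b, _ = idx[gene_b]
    target = assembly.gene(gene_b)
    center = (target.start + target.end) // 2
    seq = assembly.sequences[scaf_b]
    lo = max(0, center - micro_window // 2)
    hi = min(len(seq), center + micro_window // 2)
    window_seq = seq[lo:hi]
    params = homology.megablast_params()
    try:
        hits = homology.search(flanks, {"w": window_seq}, params)
    except ValueError:
        return "N"
    anchored = {h.query_id for h in hits if h.query_coverage >= 0.3}
    return "Y" if len(anchored) >= 2 else "N"


def compute_pair_evidence(
    genome: AnnotatedGenome,
    gene_a: str,
    gene_b: str,
    self_hits: Sequence[tuple[str, str]],
    clustering=None,
    window: int = 40,
    min_anchors: int = 4,
    paralogon_threshold: int = PARALOGON_THRESHOLD,
) -> dict[str, str]:
    """All six evidence cells for one within-genome gene pair.

    ``self_hits`` are within-genome homolog pairs used as synteny anchors;
    as in the dot-plot analyses this emulates, the pair under test is itself
    an anchor (the block thresholds still demand min_anchors - 1 independent
    corroborating pairs). The two microsynteny columns need scaffold
    sequences on the genome; without them those cells are N.
    """
    pairs = _canonical_pairs(self_hits)
    params = synteny.SyntenyParams(min_anchors=min_anchors, window=window)
    colinear = synteny.detect_collinear_blocks(genome, genome, pairs, params)
    density = synteny.detect_density_blocks(
        genome,
        genome,
        pairs,
        synteny.SyntenyParams(min_anchors=min_anchors, window=window, mode="density"),
    )
    paralogons = detect_paralogons(
        genome, pairs, min_paired_proteins=paralogon_threshold, window=window
    )

    idx = genome.gene_index()
    (sa, ia), (sb, ib) = idx[gene_a], idx[gene_b]

    def in_blocks(blocks) -> str:
        for blk in blocks:
            for (s1, i1), (s2, i2) in (
                ((sa, ia), (sb, ib)),
                ((sb, ib), (sa, ia)),
            ):
                if (
                    blk.scaffold_a == s1
                    and blk.scaffold_b == s2
                    and blk.span_a[0] <= i1 <= blk.span_a[1]
                    and blk.span_b[0] <= i2 <= blk.span_b[1]
                ):
                    return "Y"
        return "N"

    def synfind_cell() -> str:
        for query, other_scaf, other_idx in (
            (gene_a, sb, ib),
            (gene_b, sa, ia),
        ):
            res = synteny.syntenic_lookup(query, genome, genome, pairs, params)
            found = (
                res.status in ("found", "empty_slot")
                and res.scaffold_b == other_scaf
                and res.region_b is not None
                and res.region_b[0] - window
                <= other_idx
                <= res.region_b[1] + window
            )
            if not found:
                return "N"
        return "Y"

    if genome.sequences is not None:
        micro2 = _intragenomic_microsynteny(
            genome, gene_a, gene_b, synteny.MICRO_WINDOW_2MB
        )
        micro12 = (
            "Y"
            if micro2 == "Y"
            else _intragenomic_microsynteny(
                genome, gene_a, gene_b, synteny.MICRO_WINDOW_12MB
            )
        )
    else:
        micro2 = micro12 = "N"

    return {
        "micro_2Mb": micro2,
        "micro_12Mb": micro12,
        "synfind": synfind_cell(),
        "synmap_colinear": in_blocks(colinear),
        "synmap_density": in_blocks(density),
        "paralogy": gene_pair_in_paralogon(gene_a, gene_b, paralogons, genome),
    }


def build_evidence_matrix(
    genome: AnnotatedGenome,
    gene_pairs: Sequence[tuple[str, str]],
    self_hits: Sequence[tuple[str, str]],
    **kwargs,
) -> pd.DataFrame:
    """Evidence matrix + verdict for a list of within-genome gene pairs."""
    rows = {}
    for ga, gb in gene_pairs:
        cells = compute_pair_evidence(genome, ga, gb, self_hits, **kwargs)
        cells["verdict"] = verdict_for_row(cells)
        rows[f"{ga}/{gb}"] = cells
    return pd.DataFrame.from_dict(rows, orient="index")[
        EVIDENCE_COLUMNS + ["verdict"]
    ]
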