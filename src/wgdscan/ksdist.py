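"""Synonymous-divergence (Ks) estimation and Ks-distribution clustering.

Ks — synonymous substitutions per synonymous site — acts as a relative
molecular clock for syntenic gene pairs: ortholog pairs created by a
speciation share one Ks depth, homeolog pairs created by a whole-genome
duplication share another (older) depth, and spurious matches pile up at
implausibly large values. This module computes per-pair Ks with the
Nei-Gojobori (1986) counting method plus Jukes-Cantor multiple-hit
correction, and labels the clusters of the log10-Ks distribution
(ortholog-divergence, WGD, noise) with a seeded 1-D Gaussian mixture.

The NG86 estimator is deterministic and self-contained: synonymous and
nonsynonymous site fractions come from single-mutation enumeration per codon,
pairwise differences are averaged over minimal mutational pathways (pathways
through stop codons excluded), and pS is corrected as
ks = -(3/4) ln(1 - (4/3) pS), undefined (saturated) once pS >= 0.74.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "KsEstimate",
    "KsClustering",
    "AlignmentTooShort",
    "align_codons",
    "estimate_ks_ng86",
    "ks_for_blocks",
    "cluster_ks",
    "pair_in_wgd_region",
    "synonymous_sites",
    "log10_to_linear",
    "linear_to_log10",
    "round_sig",
    "SATURATION_PS",
    "MIN_ALIGNED_CODONS",
]

SATURATION_PS = 0.74  # domain bound of the Jukes-Cantor correction (3/4 * ...)
MIN_ALIGNED_CODONS = 30

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


_CODONS = [
    a + b + c
    for a, b, c in itertools.product(_BASES, repeat=3)
    if a + b + c not in _STOPS
]
_AA = {c: _translate(c) for c in _CODONS}


def _site_fractions() -> dict[str, float]:
    """NG86 synonymous-site count per codon (0..3).

    Each codon position contributes the fraction of its three possible
    nucleotide changes that are synonymous; changes creating stop codons
    count as nonsynonymous.
    """
    out = {}
    for codon in _CODONS:
        s = 0.0
        for pos in range(3):
            for alt in _BASES:
                if alt == codon[pos]:
                    continue
                mut = codon[:pos] + alt + codon[pos + 1 :]
                if mut in _STOPS:
                    continue
                if _AA[mut] == _AA[codon]:
                    s += 1.0 / 3.0
        out[codon] = s
    return out


_SYN_SITES = _site_fractions()


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons.

    Averaged over all orderings of the differing positions; pathways passing
    through a stop codon are excluded (all-blocked pairs fall back to
    averaging over every pathway).
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                blocked = True
            if _translate(cur) == _translate(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((blocked, sd, nd))
    open_paths = [(sd, nd) for blocked, sd, nd in paths if not blocked]
    if not open_paths:
        open_paths = [(sd, nd) for _, sd, nd in paths]
    sd = sum(p[0] for p in open_paths) / len(open_paths)
    nd = sum(p[1] for p in open_paths) / len(open_paths)
    return sd, nd


_PATHWAY_CACHE: dict[tuple[str, str], tuple[float, float]] = {}


def _diff_counts(c1: str, c2: str) -> tuple[float, float]:
    key = (c1, c2)
    if key not in _PATHWAY_CACHE:
        _PATHWAY_CACHE[key] = _pathway_counts(c1, c2)
    return _PATHWAY_CACHE[key]


def synonymous_sites(cds: str) -> float:
    """Total NG86 synonymous sites of an in-frame CDS (stops skipped)."""
    total = 0.0
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        if codon in _SYN_SITES:
            total += _SYN_SITES[codon]
    return total


class AlignmentTooShort(ValueError):
    """Fewer aligned codons than the reporting minimum."""


@dataclass
class KsEstimate:
    """Per-pair synonymous/nonsynonymous divergence."""

    pair: tuple[str, str]
    ks: float
    ka: float
    aligned_codons: int
    saturated: bool = False

    def __post_init__(self) -> None:
        if not self.saturated and self.ks < 0:
            raise ValueError("ks must be >= 0 unless saturated")


def align_codons(cds_a: str, cds_b: str) -> list[tuple[str, str]]:
    """Codon alignment of two CDS via global protein alignment.

    Incomplete terminal codons are trimmed, the translations are aligned
    globally with affine gap penalties (BLOSUM62), the alignment is mapped
    back to codons, and gap columns are dropped.
    """
    cds_a = cds_a.upper()[: len(cds_a) - len(cds_a) % 3]
    cds_b = cds_b.upper()[: len(cds_b) - len(cds_b) % 3]
    codons_a = [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)]
    # drop terminal stops from the alignment problem
    if codons_a and codons_a[-1] in _STOPS:
        codons_a = codons_a[:-1]
    if codons_b and codons_b[-1] in _STOPS:
        codons_b = codons_b[:-1]
    prot_a = "".join(_AA.get(c, "X") for c in codons_a)
    prot_b = "".join(_AA.get(c, "X") for c in codons_b)
    if not prot_a or not prot_b:
        return []
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = next(iter(aligner.align(prot_a, prot_b)))
    pairs: list[tuple[str, str]] = []
    for (qs, qe), (ss, se) in zip(aln.aligned[0], aln.aligned[1]):
        for k in range(qe - qs):
            pairs.append((codons_a[qs + k], codons_b[ss + k]))
    return pairs


def estimate_ks_ng86(
    alignment: Sequence[tuple[str, str]],
    pair: tuple[str, str] = ("a", "b"),
) -> KsEstimate:
    """Nei-Gojobori (1986) Ks/Ka with Jukes-Cantor correction.

    Raises :class:`AlignmentTooShort` below ``MIN_ALIGNED_CODONS`` aligned
    codons. ``saturated`` is set (with ``ks = inf``) once pS reaches the
    correction's domain bound.
    """
    codons = [
        (a, b)
        for a, b in alignment
        if a in _SYN_SITES and b in _SYN_SITES
    ]
    if len(codons) < MIN_ALIGNED_CODONS:
        raise AlignmentTooShort(
            f"{len(codons)} aligned codons < {MIN_ALIGNED_CODONS}"
        )
    s_sites = sum((_SYN_SITES[a] + _SYN_SITES[b]) / 2.0 for a, b in codons)
    n_sites = 3.0 * len(codons) - s_sites
    sd = nd = 0.0
    for a, b in codons:
        d_s, d_n = _diff_counts(a, b)
        sd += d_s
        nd += d_n
    p_s = sd / s_sites if s_sites > 0 else 0.0
    p_n = nd / n_sites if n_sites > 0 else 0.0

    def _jc(p: float) -> tuple[float, bool]:
        if p >= SATURATION_PS:
            return math.inf, True
        return -0.75 * math.log(1.0 - (4.0 / 3.0) * p), False

    ks, sat_s = _jc(p_s)
    ka, _ = _jc(p_n)
    return KsEstimate(
        pair=pair,
        ks=ks,
        ka=ka,
        aligned_codons=len(codons),
        saturated=sat_s,
    )


def ks_for_pairs(
    gene_pairs: Sequence[tuple[str, str]],
    cds_a: dict[str, str],
    cds_b: dict[str, str],
) -> list[KsEstimate]:
    """Ks estimate per gene-id pair; pairs too short to estimate are skipped."""
    out = []
    for ga, gb in gene_pairs:
        try:
            aln = align_codons(cds_a[ga], cds_b[gb])
            out.append(estimate_ks_ng86(aln, pair=(ga, gb)))
        except AlignmentTooShort:
            continue
    return out


def ks_for_blocks(blocks, genome_a, genome_b) -> list[KsEstimate]:
    """One Ks estimate per anchor pair of each (colinear) synteny block."""
    cds_a = genome_a.cds_map()
    cds_b = genome_b.cds_map()
    pairs = []
    for block in blocks:
        for anchor in block.anchors:
            pairs.append((anchor.gene_a, anchor.gene_b))
    return ks_for_pairs(pairs, cds_a, cds_b)


# ---------------------------------------------------------------------------
# log10-Ks clustering
# ---------------------------------------------------------------------------

_KS_FLOOR = 1e-4  # identical pairs enter the log-scale histogram at this Ks


@dataclass
class KsClustering:
    """Labeled clusters of the log10-Ks distribution.

    ``assignments[i]`` labels ``estimates[i]`` as ``ortholog_divergence``,
    ``wgd`` or ``noise``. ``cluster_means`` are the finite-cluster means on
    the log10 scale, ascending; the lowest is always the ortholog-divergence
    cluster.
    """

    estimates: list[KsEstimate]
    values: list[float]
    cluster_means: list[float]
    assignments: list[str]
    labels: dict[int, str]
    noise_threshold: float = 80.0

    def linear_cluster_means(self) -> list[float]:
        return [log10_to_linear(m) for m in self.cluster_means]

    def mean_of(self, label: str) -> Optional[float]:
        """Mean log10 Ks over estimates carrying ``label`` (None if absent)."""
        vals = [
            math.log10(max(e.ks, _KS_FLOOR))
            for e, a in zip(self.estimates, self.assignments)
            if a == label and not e.saturated
        ]
        return float(np.mean(vals)) if vals else None

    def classify_value(self, ks: float) -> str:
        """Label a single Ks value by nearest cluster mean."""
        if not math.isfinite(ks) or ks > self.noise_threshold:
            return "noise"
        v = math.log10(max(ks, _KS_FLOOR))
        idx = int(np.argmin([abs(v - m) for m in self.cluster_means]))
        return self.labels[idx]


def cluster_ks(
    estimates: Sequence[KsEstimate],
    n_clusters: int = 3,
    noise_threshold: float = 80.0,
    seed: int = 0,
) -> KsClustering:
    """Cluster finite log10-Ks values with a 1-D Gaussian mixture.

    Values above ``noise_threshold`` (and saturated estimates) are pre-labeled
    noise; the remainder are fitted with k <= n_clusters components selected
    by BIC under a fixed seed. The lowest-mean cluster is labeled
    ortholog_divergence, any higher cluster wgd.
    """
    estimates = list(estimates)
    finite_idx = [
        i
        for i, e in enumerate(estimates)
        if not e.saturated and e.ks <= noise_threshold
    ]
    if len(finite_idx) < 20:
        raise ValueError("need at least 20 finite Ks estimates to cluster")
    values = [math.log10(max(estimates[i].ks, _KS_FLOOR)) for i in finite_idx]
    x = np.asarray(values).reshape(-1, 1)

    if float(np.ptp(x)) < 1e-12:
        means = [float(x[0, 0])]
        comp = np.zeros(len(values), dtype=int)
    else:
        from sklearn.mixture import GaussianMixture

        # parsimonious BIC: an extra component must buy a clear improvement,
        # otherwise tight unimodal clusters get split spuriously
        best = None
        for k in range(1, min(n_clusters, len(np.unique(x))) + 1):
            gm = GaussianMixture(
                n_components=k, random_state=seed, n_init=3, covariance_type="full"
            ).fit(x)
            bic = gm.bic(x)
            if best is None or bic < best[0] - 10.0:
                best = (bic, gm)
        gm = best[1]
        order = np.argsort(gm.means_.ravel())
        rank = {int(old): new for new, old in enumerate(order)}
        comp = np.array([rank[int(c)] for c in gm.predict(x)])
        means = sorted(float(m) for m in gm.means_.ravel())

    labels = {0: "ortholog_divergence"}
    for j in range(1, len(means)):
        labels[j] = "wgd"

    assignments = ["noise"] * len(estimates)
    for pos, i in enumerate(finite_idx):
        assignments[i] = labels[int(comp[pos])]
    return KsClustering(
        estimates=estimates,
        values=values,
        cluster_means=means,
        assignments=assignments,
        labels=labels,
        noise_threshold=noise_threshold,
    )


def pair_in_wgd_region(
    gene_a: str,
    gene_b: str,
    blocks,
    clustering: KsClustering,
    genome_a,
    genome_b,
) -> tuple[str, str]:
    """Is the pair inside a synteny block whose Ks depth is the WGD cluster?

    Returns ("Y"|"N", reason): Y iff a block contains both genes within its
    spans and the median anchor Ks of that block classifies into the wgd
    cluster. A pair in no block is N with reason "no block".
    """
    idx_a = genome_a.gene_index()
    idx_b = genome_b.gene_index()
    if gene_a not in idx_a or gene_b not in idx_b:
        return "N", "no block"
    (scaf_a, ia), (scaf_b, ib) = idx_a[gene_a], idx_b[gene_b]
    by_pair = {e.pair: e for e in clustering.estimates}
    for block in blocks:
        fits = (
            block.scaffold_a == scaf_a
            and block.scaffold_b == scaf_b
            and block.span_a[0] <= ia <= block.span_a[1]
            and block.span_b[0] <= ib <= block.span_b[1]
        )
        if not fits:
            continue
        ks_vals = []
        for anchor in block.anchors:
            est = by_pair.get((anchor.gene_a, anchor.gene_b)) or by_pair.get(
                (anchor.gene_b, anchor.gene_a)
            )
            if est is not None and not est.saturated:
                ks_vals.append(est.ks)
        if not ks_vals:
            continue
        median_ks = float(np.median(ks_vals))
        label = clustering.classify_value(median_ks)
        return ("Y", "wgd block") if label == "wgd" else ("N", f"{label} block")
    return "N", "no block"


# ---------------------------------------------------------------------------
# scale conversions
# ---------------------------------------------------------------------------


def log10_to_linear(x: float) -> float:
    return 10.0 ** x


def linear_to_log10(x: float) -> float:
    return math.log10(x)


def round_sig(x: float, digits: int = 2) -> float:
    """Round to ``digits`` significant figures (display convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (digits - 1))
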