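"""Significance-filtered homology search between (or within) sequence sets.

A deliberately small seed-and-extend search: exact k-mer seeding decides which
query/subject pairs are worth aligning (two hits on one diagonal for proteins,
one hit for nucleotides), Smith-Waterman extension with affine gap penalties
produces HSPs, and Karlin-Altschul statistics with fixed per-scheme constants
turn raw scores into bit scores and e-values. Pairs failing the e-value or
HSP-coverage thresholds are discarded.

Two parameter presets mirror the two search flavours the pipeline needs:
protein searches (gene finding, BLOSUM62, word size 3) and megablast-like
nucleotide searches (read mapping and microsynteny: word size 16, match/
mismatch +1/-2, gap open 5 / extend 2, expect threshold 5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "SearchParams",
    "HomologPair",
    "protein_params",
    "megablast_params",
    "search",
    "reciprocal_best_hits",
    "filter_hits",
]

# Fixed Karlin-Altschul constants per scoring scheme. E-values here only feed
# a threshold; absolute calibration against NCBI BLAST is not attempted.
_KA_CONSTANTS = {
    "BLOSUM62": (0.267, 0.041),
    "nucleotide": (1.28, 0.46),
}

_NUC_LETTERS = set("ACGTN")


@dataclass
class SearchParams:
    """Knobs of the seed-and-extend search."""

    word_size: int = 3
    gap_open: float = 11.0
    gap_extend: float = 1.0
    expect_threshold: float = 1e-5
    min_hsp_coverage: float = 0.0
    substitution_scores: str | tuple[float, float] = "BLOSUM62"
    two_hit: bool = True
    max_hsps: int = 4

    def __post_init__(self) -> None:
        if self.word_size < 3:
            raise ValueError("word_size must be >= 3")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if not 0.0 <= self.min_hsp_coverage <= 1.0:
            raise ValueError("min_hsp_coverage must be in [0,1]")


def protein_params(**overrides) -> SearchParams:
    """BLOSUM62 protein search with two-hit seeding (gene finding default)."""
    return replace(SearchParams(), **overrides)


def megablast_params(**overrides) -> SearchParams:
    """Megablast-like nucleotide search: word 16, +1/-2, gaps 5/2, expect 5."""
    p = SearchParams(
        word_size=16,
        gap_open=5.0,
        gap_extend=2.0,
        expect_threshold=5.0,
        min_hsp_coverage=0.0,
        substitution_scores=(1.0, -2.0),
        two_hit=False,
    )
    return replace(p, **overrides)


@dataclass
class HomologPair:
    """One significant query/subject match with its merged HSP list.

    HSP tuples are (q_start, q_end, s_start, s_end, score) with 1-based
    inclusive coordinates on the original sequences.
    """

    query_id: str
    subject_id: str
    bit_score: float
    evalue: float
    query_coverage: float
    hsps: list[tuple[int, int, int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.query_coverage <= 1.0 + 1e-9:
            raise ValueError("query_coverage out of [0,1]")


def _alphabet(sequences: dict[str, str]) -> str:
    letters = set()
    for seq in sequences.values():
        letters |= set(seq)
    return "nucleotide" if letters <= _NUC_LETTERS else "protein"


def _make_aligner(params: SearchParams, alphabet: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if isinstance(params.substitution_scores, str):
        aligner.substitution_matrix = substitution_matrices.load(
            params.substitution_scores
        )
    else:
        match, mismatch = params.substitution_scores
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = -params.gap_open - params.gap_extend
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def _ka_constants(params: SearchParams) -> tuple[float, float]:
    key = (
        params.substitution_scores
        if isinstance(params.substitution_scores, str)
        else "nucleotide"
    )
    return _KA_CONSTANTS.get(key, _KA_CONSTANTS["nucleotide"])


def _bit_score(raw: float, lam: float, k: float) -> float:
    return (lam * raw - math.log(k)) / math.log(2.0)


def _evalue(bits: float, m: int, n: int) -> float:
    return m * n * 2.0 ** (-bits)


def _seed_candidates(
    queries: dict[str, str], subjects: dict[str, str], params: SearchParams
) -> dict[tuple[str, str], list[tuple[int, int]]]:
    """Exact k-mer seed hits per (query, subject) pair."""
    w = params.word_size
    index: dict[str, list[tuple[str, int]]] = {}
    for sid, seq in subjects.items():
        for i in range(len(seq) - w + 1):
            index.setdefault(seq[i : i + w], []).append((sid, i))
    hits: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for qid, qseq in queries.items():
        for i in range(len(qseq) - w + 1):
            for sid, j in index.get(qseq[i : i + w], ()):
                hits.setdefault((qid, sid), []).append((i, j))
    return hits


def _passes_two_hit(seeds: list[tuple[int, int]], word: int, span: int = 64) -> bool:
    """Two non-overlapping seeds on the same diagonal within ``span``."""
    import bisect

    by_diag: dict[int, list[int]] = {}
    for q, s in seeds:
        by_diag.setdefault(s - q, []).append(q)
    for positions in by_diag.values():
        positions.sort()
        for a in positions:
            j = bisect.bisect_left(positions, a + word)
            if j < len(positions) and positions[j] - a <= span:
                return True
    return False


def _seed_windows(
    seeds: list[tuple[int, int]], qlen: int, slen: int
) -> list[tuple[int, int]]:
    """Subject windows around diagonal clusters of seed hits."""
    pad = qlen + 64
    spans = sorted(s for _, s in seeds)
    windows: list[list[int]] = []
    for s in spans:
        if windows and s - windows[-1][1] <= pad:
            windows[-1][1] = s
        else:
            windows.append([s, s])
    return [(max(0, a - pad), min(slen, b + pad)) for a, b in windows]


def _extend_in_window(
    aligner: Align.PairwiseAligner,
    qseq: str,
    sseq: str,
    offset: int,
    params: SearchParams,
    lam: float,
    k: float,
    m: int,
    n: int,
) -> list[tuple[int, int, int, int, float]]:
    """Iterated local alignment with query masking -> HSP list."""
    mask_char = "N" if set(qseq) <= _NUC_LETTERS else "X"
    # an HSP must at least contain one seed word: for numeric (nucleotide)
    # scoring that bounds the raw score from below by word_size matches
    if isinstance(params.substitution_scores, tuple):
        min_raw = params.word_size * params.substitution_scores[0]
    else:
        min_raw = 0.0
    work = list(qseq)
    hsps = []
    for _ in range(params.max_hsps):
        query = "".join(work)
        score = aligner.score(query, sseq)
        if score <= 0 or score < min_raw:
            break
        bits = _bit_score(score, lam, k)
        if _evalue(bits, m, n) > params.expect_threshold:
            break
        aln = next(iter(aligner.align(query, sseq)))
        q_blocks, s_blocks = aln.aligned
        qs, qe = int(q_blocks[0][0]), int(q_blocks[-1][1])
        ss, se = int(s_blocks[0][0]), int(s_blocks[-1][1])
        hsps.append((qs + 1, qe, offset + ss + 1, offset + se, float(score)))
        for i in range(qs, qe):
            work[i] = mask_char
    return hsps


def search(
    queries: dict[str, str],
    subjects: dict[str, str],
    params: Optional[SearchParams] = None,
) -> list[HomologPair]:
    """Seed-and-extend similarity search of ``queries`` against ``subjects``.

    Returns pairs passing both the e-value and query-coverage thresholds,
    sorted by query id, descending bit score, then subject id.
    """
    if not queries or not subjects:
        raise ValueError("empty sequence set")
    queries = {k: v.upper() for k, v in queries.items()}
    subjects = {k: v.upper() for k, v in subjects.items()}
    qalpha, salpha = _alphabet(queries), _alphabet(subjects)
    if qalpha != salpha:
        raise ValueError(f"mixed alphabets: query {qalpha}, subject {salpha}")
    if params is None:
        params = protein_params() if qalpha == "protein" else megablast_params()

    aligner = _make_aligner(params, qalpha)
    lam, k = _ka_constants(params)
    n_total = sum(len(s) for s in subjects.values())

    results: list[HomologPair] = []
    for (qid, sid), seeds in _seed_candidates(queries, subjects, params).items():
        qseq, sseq = queries[qid], subjects[sid]
        if params.two_hit and len(qseq) > 2 * params.word_size:
            if not _passes_two_hit(seeds, params.word_size):
                continue
        if len(sseq) > 4 * len(qseq) + 256:
            windows = _seed_windows(seeds, len(qseq), len(sseq))
        else:
            windows = [(0, len(sseq))]
        hsps: list[tuple[int, int, int, int, float]] = []
        for lo, hi in windows:
            hsps.extend(
                _extend_in_window(
                    aligner, qseq, sseq[lo:hi], lo, params, lam, k,
                    len(qseq), n_total,
                )
            )
        hsps = sorted(set(hsps), key=lambda h: (-h[4], h[:4]))
        if not hsps:
            continue
        best_raw = max(h[4] for h in hsps)
        bits = _bit_score(best_raw, lam, k)
        ev = _evalue(bits, len(qseq), n_total)
        covered: set[int] = set()
        for qs, qe, *_ in hsps:
            covered.update(range(qs, qe + 1))
        coverage = len(covered) / len(qseq)
        pair = HomologPair(qid, sid, round(bits, 2), ev, coverage, hsps)
        if ev <= params.expect_threshold and coverage >= params.min_hsp_coverage:
            results.append(pair)
    results.sort(key=lambda p: (p.query_id, -p.bit_score, p.subject_id))
    return results


def reciprocal_best_hits(
    pairs_ab: list[HomologPair], pairs_ba: list[HomologPair]
) -> list[tuple[str, str]]:
    """Mutual-best pairs from the two directed hit lists.

    Best subject per query is the highest bit score, ties broken by
    lexicographic subject id, so output is deterministic.
    """

    def best_map(pairs: list[HomologPair]) -> dict[str, str]:
        best: dict[str, HomologPair] = {}
        for p in pairs:
            cur = best.get(p.query_id)
            if (
                cur is None
                or p.bit_score > cur.bit_score
                or (p.bit_score == cur.bit_score and p.subject_id < cur.subject_id)
            ):
                best[p.query_id] = p
        return {q: p.subject_id for q, p in best.items()}

    ab, ba = best_map(pairs_ab), best_map(pairs_ba)
    return sorted((a, b) for a, b in ab.items() if ba.get(b) == a)


def filter_hits(
    pairs: list[HomologPair],
    expect_threshold: float,
    min_hsp_coverage: float,
) -> list[HomologPair]:
    """Keep pairs meeting both the e-value and coverage predicates."""
    return [
        p
        for p in pairs
        if p.evalue <= expect_threshold and p.query_coverage >= min_hsp_coverage
    ]
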