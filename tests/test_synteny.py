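"""Synteny detection against brute-force oracles, plus lookup and
microsynteny outcomes on simulated assemblies."""

import itertools

import numpy as np
import pytest

from wgdscan import synteny
from wgdscan.formats import AnnotatedGenome, GeneModel
from wgdscan.synteny import Anchor, SyntenyParams


def toy_genome(name, n_genes, scaffold="s"):
    genes = [
        GeneModel(f"{name}{scaffold}g{i}", scaffold, 1 + i * 100, 50 + i * 100)
        for i in range(n_genes)
    ]
    return AnnotatedGenome(name, {scaffold: genes})


def mk_anchors(pairs, scaf_a="s", scaf_b="s"):
    return [
        Anchor(f"a{ia}", f"b{ib}", scaf_a, ia, scaf_b, ib) for ia, ib in pairs
    ]


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def all_chains(points, window, sign):
    """Every strictly-monotone chain with adjacent gaps <= window."""
    chains = []

    def extend(chain):
        chains.append(chain)
        last = chain[-1]
        for p in points:
            da = p[0] - last[0]
            db = sign * (p[1] - last[1])
            if 0 < da <= window and 0 < db <= window:
                extend(chain + [p])

    for p in points:
        extend([p])
    return chains


def oracle_collinear(pairs, window, min_anchors):
    """Iterated extraction of the best maximal chain, by enumeration.

    Output sorted like the implementation: by (span_a, span_b)."""
    remaining = sorted(set(pairs))
    blocks = []
    while True:
        fwd = all_chains(remaining, window, +1)
        rev = all_chains(remaining, window, -1)
        best_len = max((len(c) for c in fwd + rev), default=0)
        if best_len < min_anchors:
            break
        fwd_best = sorted(c for c in fwd if len(c) == best_len)
        rev_best = sorted(c for c in rev if len(c) == best_len)
        chain = fwd_best[0] if fwd_best else rev_best[0]
        blocks.append(tuple(chain))
        remaining = [p for p in remaining if p not in chain]

    def span_key(chain):
        ia = [p[0] for p in chain]
        ib = [p[1] for p in chain]
        return ((min(ia), max(ia)), (min(ib), max(ib)))

    return sorted(blocks, key=span_key)


def oracle_density(pairs, window, min_anchors):
    """Exhaustive integer window scan + merge of qualifying windows."""
    pairs = sorted(set(pairs))
    n = len(pairs)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    qualified = [False] * n
    ia_values = [p[0] for p in pairs]
    ib_values = [p[1] for p in pairs]
    for a0 in range(min(ia_values) - window, max(ia_values) + 1):
        for b0 in range(min(ib_values) - window, max(ib_values) + 1):
            members = [
                k
                for k, (ia, ib) in enumerate(pairs)
                if a0 <= ia < a0 + window and b0 <= ib < b0 + window
            ]
            if len(members) >= min_anchors:
                for k in members[1:]:
                    parent[find(k)] = find(members[0])
                for k in members:
                    qualified[k] = True
    comps = {}
    for k, p in enumerate(pairs):
        if qualified[k]:
            comps.setdefault(find(k), []).append(p)
    return sorted(tuple(sorted(v)) for v in comps.values())


def random_anchor_sets(n_sets, max_anchors=12, coord_max=30, seed=99):
    rng = np.random.default_rng(seed)
    for _ in range(n_sets):
        n = int(rng.integers(2, max_anchors + 1))
        pts = set()
        while len(pts) < n:
            pts.add((int(rng.integers(0, coord_max)), int(rng.integers(0, coord_max))))
        yield sorted(pts)


class TestCollinear:
    def test_self_synteny_full_diagonal_per_scaffold(self):
        g = AnnotatedGenome(
            "g",
            {
                s: [
                    GeneModel(f"{s}g{i}", s, 1 + i * 100, 50 + i * 100)
                    for i in range(10)
                ]
                for s in ("s1", "s2")
            },
        )
        anchors = [(gm.gene_id, gm.gene_id) for gm in g.genes()]
        blocks = synteny.detect_collinear_blocks(g, g, anchors)
        assert len(blocks) == 2
        for b in blocks:
            assert b.n_anchors == 10
            assert b.orientation == "same"
            assert b.scaffold_a == b.scaffold_b

    def test_spec_toy_matches_oracle(self):
        pairs = [(1, 1), (2, 2), (3, 7), (4, 4), (5, 5)]
        ga, gb = toy_genome("a", 10), toy_genome("b", 10)
        blocks = synteny.detect_collinear_blocks(
            ga, gb, mk_anchors(pairs), SyntenyParams(min_anchors=4, window=40)
        )
        got = [tuple((a.index_a, a.index_b) for a in b.anchors) for b in blocks]
        assert got == oracle_collinear(pairs, 40, 4)
        assert got == [((1, 1), (2, 2), (4, 4), (5, 5))]

    def test_inverted_blocks_detected(self):
        pairs = [(1, 9), (2, 8), (3, 7), (4, 6)]
        ga, gb = toy_genome("a", 10), toy_genome("b", 10)
        blocks = synteny.detect_collinear_blocks(
            ga, gb, mk_anchors(pairs), SyntenyParams(min_anchors=4, window=40)
        )
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_unknown_anchor_gene_rejected(self):
        ga, gb = toy_genome("a", 5), toy_genome("b", 5)
        with pytest.raises(KeyError):
            synteny.detect_collinear_blocks(ga, gb, [("nope", "bsg0")])

    @pytest.mark.parametrize("window,min_anchors", [(40, 4), (5, 2), (8, 3)])
    def test_matches_chain_enumeration_on_random_toys(self, window, min_anchors):
        ga, gb = toy_genome("a", 40), toy_genome("b", 40)
        for pairs in random_anchor_sets(15):
            blocks = synteny.detect_collinear_blocks(
                ga,
                gb,
                mk_anchors(pairs),
                SyntenyParams(min_anchors=min_anchors, window=window),
            )
            got = [
                tuple((a.index_a, a.index_b) for a in b.anchors) for b in blocks
            ]
            assert got == oracle_collinear(pairs, window, min_anchors), pairs

    def test_deterministic(self):
        pairs = [(1, 1), (2, 2), (3, 3), (4, 4), (1, 4), (2, 3), (3, 2), (4, 1)]
        ga, gb = toy_genome("a", 10), toy_genome("b", 10)
        params = SyntenyParams(min_anchors=4, window=40)
        b1 = synteny.detect_collinear_blocks(ga, gb, mk_anchors(pairs), params)
        b2 = synteny.detect_collinear_blocks(ga, gb, mk_anchors(pairs), params)
        assert [
            [(a.index_a, a.index_b) for a in b.anchors] for b in b1
        ] == [[(a.index_a, a.index_b) for a in b.anchors] for b in b2]


class TestDensity:
    def test_scrambled_order_found_by_density_not_collinear(self):
        pairs = [(1, 4), (2, 1), (3, 3), (4, 2)]
        ga, gb = toy_genome("a", 10), toy_genome("b", 10)
        params_c = SyntenyParams(min_anchors=4, window=10)
        params_d = SyntenyParams(min_anchors=4, window=10, mode="density")
        assert (
            synteny.detect_collinear_blocks(ga, gb, mk_anchors(pairs), params_c)
            == []
        )
        blocks = synteny.detect_density_blocks(ga, gb, mk_anchors(pairs), params_d)
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 4

    def test_zero_anchors_empty(self):
        ga, gb = toy_genome("a", 5), toy_genome("b", 5)
        assert synteny.detect_density_blocks(ga, gb, []) == []

    @pytest.mark.parametrize("window,min_anchors", [(5, 2), (6, 3), (40, 4)])
    def test_matches_window_scan_on_random_toys(self, window, min_anchors):
        ga, gb = toy_genome("a", 40), toy_genome("b", 40)
        for pairs in random_anchor_sets(12, coord_max=20, seed=5):
            blocks = synteny.detect_density_blocks(
                ga,
                gb,
                mk_anchors(pairs),
                SyntenyParams(min_anchors=min_anchors, window=window, mode="density"),
            )
            got = sorted(
                tuple(sorted((a.index_a, a.index_b) for a in b.anchors))
                for b in blocks
            )
            assert got == oracle_density(pairs, window, min_anchors), pairs

    def test_collinear_anchor_sets_contained_in_density_blocks(self, small_history):
        """On window-dense simulated anchors every colinear block's anchor
        set lies inside some density block under equal parameters."""
        pairs = [(p.gene_a, p.gene_b) for p in small_history.surviving_base_pairs()]
        g = small_history.wgd_genome
        col = synteny.detect_collinear_blocks(g, g, pairs)
        dens = synteny.detect_density_blocks(g, g, pairs)
        dens_sets = [
            {(a.gene_a, a.gene_b) for a in b.anchors} for b in dens
        ]
        for b in col:
            anchors = {(a.gene_a, a.gene_b) for a in b.anchors}
            assert any(anchors <= ds for ds in dens_sets)


class TestSyntenicLookup:
    def test_retained_ortholog_found(self, small_history):
        from conftest import ortholog_pairs

        sp1, sp2 = sorted(small_history.species_genomes)
        g1 = small_history.species_genomes[sp1]
        g2 = small_history.species_genomes[sp2]
        pairs = ortholog_pairs(small_history, sp1, sp2)
        query, partner = pairs[5]
        res = synteny.syntenic_lookup(query, g1, g2, pairs)
        assert res.status == "found"
        assert res.gene_b == partner

    def test_deleted_ortholog_gives_empty_slot(self, small_history):
        from conftest import ortholog_pairs

        sp1, sp2 = sorted(small_history.species_genomes)
        g1 = small_history.species_genomes[sp1]
        g2 = small_history.species_genomes[sp2]
        pairs = ortholog_pairs(small_history, sp1, sp2)
        # delete one mid-scaffold ortholog from the target genome
        scaf = next(iter(g2.scaffolds))
        victim = g2.scaffolds[scaf][len(g2.scaffolds[scaf]) // 2]
        pruned = AnnotatedGenome(
            g2.species_id,
            {
                s: [g for g in genes if g.gene_id != victim.gene_id]
                for s, genes in g2.scaffolds.items()
            },
        )
        kept = [(a, b) for a, b in pairs if b != victim.gene_id]
        query = next(a for a, b in pairs if b == victim.gene_id)
        res = synteny.syntenic_lookup(query, g1, pruned, kept)
        assert res.status == "empty_slot"
        assert res.region_b is not None

    def test_gene_without_blocks_signals_no_block(self):
        ga, gb = toy_genome("a", 10), toy_genome("b", 10)
        res = synteny.syntenic_lookup("asg0", ga, gb, [])
        assert res.status == "no_block"


class TestMicrosynteny:
    def _flanks(self, genome, family):
        gene = genome.families()[family][0]
        scaf, pos = genome.gene_index()[gene.gene_id]
        genes = genome.scaffolds[scaf]
        flanks = {}
        for j in (pos - 2, pos - 1, pos + 1, pos + 2):
            if 0 <= j < len(genes):
                flanks[genes[j].gene_id] = genes[j].cds
        return gene, flanks

    def test_dropped_annotation_found_unannotated(self, loss_history):
        gB = loss_history.species_genomes["spB"]
        gene, flanks = self._flanks(gB, "DRD4")
        call = synteny.microsynteny_check(
            loss_history.assemblies["spA"], gene.cds, flanks, "spA", "DRD4"
        )
        assert call.outcome == "FoundUnannotated"
        assert call.flank_support >= 2

    def test_deleted_sequence_absent_with_intact_flanks(self, loss_history):
        gB = loss_history.species_genomes["spB"]
        gene, flanks = self._flanks(gB, "DRD1E")
        call = synteny.microsynteny_check(
            loss_history.assemblies["spA"], gene.cds, flanks, "spA", "DRD1E"
        )
        assert call.outcome == "Absent"
        assert call.flank_support >= 2

    def test_unassembled_region_unidentified(self, loss_history):
        """Flanks that never anchor (locus missing from the assembly)."""
        gB = loss_history.species_genomes["spB"]
        gene, flanks = self._flanks(gB, "DRD1A")
        tiny = AnnotatedGenome("empty", {}, sequences={})
        call = synteny.microsynteny_check(tiny, gene.cds, flanks, "empty", "DRD1A")
        assert call.outcome == "Unidentified"
        assert call.flank_support == 0

    def test_fewer_than_two_flanks_rejected(self, loss_history):
        gB = loss_history.species_genomes["spB"]
        gene, flanks = self._flanks(gB, "DRD1A")
        one = dict(itertools.islice(flanks.items(), 1))
        with pytest.raises(ValueError):
            synteny.microsynteny_check(
                loss_history.assemblies["spA"], gene.cds, one, "spA", "DRD1A"
            )
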