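# Methods

This note documents the models and procedures wgdscan implements, the
parameters that matter, the design choices that were genuinely open, and
what the simulation-based validation does and does not demonstrate.

## The inference problem

Given per-species annotated genomes, raw sequencing reads, and a rooted
species tree, the pipeline answers two questions for a set of focal gene
families (built around the seven avian dopamine-receptor families):

* the **presence state** of each family in each species — Present
  (annotated), UnannotatedPresent (sequence present, annotation missing),
  or Absent (genuinely lost) — and, via Dollo parsimony, how many families
  the common ancestor carried;
* the **duplication origin** of each family pair — whole-genome duplication
  (WGD), segmental/unresolved, or no shared origin — from synteny,
  synonymous-divergence (Ks) clustering, and paralogon evidence.

## Homology search (`homology`)

A compact seed-and-extend search stands in for an external aligner so the
pipeline is self-contained and deterministic.

* **Seeding.** Exact k-mer matches. Proteins: word size 3 with a two-hit
  rule (two non-overlapping seeds on one diagonal within 64 residues).
  Nucleotides: word size 16, single hit. Only seeded query/subject pairs are
  aligned, and for long subjects alignment is restricted to windows around
  seed clusters.
* **Extension.** Smith–Waterman with affine gaps (Bio.Align
  PairwiseAligner). Multiple HSPs per pair are obtained by masking the
  aligned query interval and re-aligning (up to 4 rounds). In nucleotide
  mode an HSP must score at least one seed word (word_size × match score),
  mirroring the requirement that reported alignments contain a seed.
* **Statistics.** Bit scores and e-values use the Karlin–Altschul form with
  fixed per-scheme constants (BLOSUM62: λ=0.267, K=0.041; nucleotide +1/−2:
  λ=1.28, K=0.46). These feed thresholds only; no absolute calibration to
  any external tool is claimed. Defaults: proteins e ≤ 1e−5; read mapping
  uses the megablast-like set word 16, gaps 5/2, expect 5.

Deviation from convention worth noting: e-values are computed against the
raw search-space product m·n without finite-size edge corrections; at the
sequence lengths used here the difference is immaterial to any threshold
decision.

## Synteny (`synteny`)

Anchors are homolog pairs mapped to gene-order indices per scaffold.

* **Colinear blocks** — maximal chains, strictly monotone on both genomes
  (both orientations; anti-diagonals are real signal), adjacent anchor gaps
  ≤ `window` (default 40 genes) on both axes, at least `min_anchors`
  (default 4) anchors. Chains are extracted best-first (score = anchor
  count; ties broken toward the same orientation, then the lexicographically
  smallest anchor sequence), so each anchor belongs to at most one colinear
  block and output is deterministic. Both choices — count-based scoring and
  single-membership — keep the later per-block Ks assignment unambiguous.
* **Density blocks** — any `window`×`window` gene-index window pair holding
  ≥ `min_anchors` anchors in any order; qualifying window pairs sharing
  anchors merge. Implementation enumerates only windows whose left edges sit
  on anchor coordinates, which provably yields the same merged blocks as an
  exhaustive scan (tests compare against the exhaustive oracle).
* The window is applied symmetrically on both genomes (the convention was
  ambiguous; symmetric is the stricter reading and is what the tests pin).
* **Containment caveat.** For window-dense anchor sets every colinear
  block's anchors lie inside a density block (property-tested on simulated
  data). An adversarial chain whose adjacent gaps approach the window size
  can satisfy the colinear rule while no single window pair reaches
  `min_anchors`; such sparse chains do not arise from the simulated (or any
  plausibly WGD-derived) histories.
* **Microsynteny check** for one locus: ≥2 flanking-gene CDS are
  nucleotide-searched against the assembly; <2 anchored flanks ⇒
  `Unidentified` (region unassembled); otherwise the family CDS is searched
  against the inter-flank interval clipped to the panel width (presets 2 Mb
  and 12 Mb) — coverage ≥ 0.5 ⇒ `FoundUnannotated`, else `Absent`.

## Ks estimation and clustering (`ksdist`)

* **Codon alignment**: global protein alignment (BLOSUM62, gap open 10,
  extend 0.5) back-mapped to codons; gap columns dropped; ≥30 aligned codons
  required for an estimate.
* **NG86**: per-codon synonymous-site fractions by single-mutation
  enumeration (mutations to stop codons count as nonsynonymous); pairwise
  differences averaged over minimal mutational pathways, pathways through
  stops excluded; Jukes–Cantor correction Ks = −(3/4)·ln(1 − (4/3)·pS),
  flagged saturated at pS ≥ 0.74 (the correction's domain bound). The
  estimator is deterministic and symmetric, and is cross-checked in the
  tests against an independent library implementation
  (Bio.codonalign, NG86 mode). A maximum-likelihood codon model was
  deliberately not used: the pipeline needs Ks only to separate clusters,
  not for absolute dating, and counting methods are self-contained and
  reproducible. Note that pathway averaging attributes small fractional Ka
  even to purely synonymous multi-step histories (e.g. TTA↔CTC); at Ks ≤ 1
  this bias stays below 0.01.
* **Clustering** replaces reading the Ks histogram by eye: estimates with
  Ks > 80 (the printed noise magnitude) or saturated are pre-labeled noise;
  remaining log₁₀ values are fitted with a 1-D Gaussian mixture, k ≤ 3
  selected by BIC under a fixed seed, with a parsimony margin (an extra
  component must improve BIC by > 10) so tight unimodal clusters are not
  split. The lowest-mean cluster is ortholog divergence; higher finite
  clusters are WGD. Identical values short-circuit to a single cluster.
  Zero-Ks pairs enter the log scale at a floor of 1e−4.
* A gene pair is "in a WGD region" when its containing synteny block's
  median anchor Ks classifies into the WGD cluster.

## Read-coverage confirmation (`readcheck`)

Queries are 5–6 known ortholog CDS for the family; covered positions are
the union of HSP query intervals over all reads under the megablast-like
parameters. The classified statistic is the **best** coverage across
queries (any single well-covered ortholog demonstrates presence — the mean
would punish diverged queries). Good ⇔ coverage ≥ 0.5 (closed bound): every
observed Poor value in the packaged data is ≤ 0.35 and Good is
near-complete, so 0.5 splits the gap with margin on both sides; the
threshold is configurable. A family known present in all species serves as
positive control; a Poor target under a failed control is Inconclusive.

## Presence calling and ancestral reconstruction (`classify`)

The decision rule is the unique conjunction consistent with every recorded
evidence combination in the packaged species table: Absent requires
negative microsynteny **and** Poor coverage; every other unannotated
combination (Good coverage, similarity at the locus, unassembled region,
inconclusive control) keeps the gene as UnannotatedPresent. The full
2×4×3 evidence space is asserted in tests.

Dollo parsimony (single gain, arbitrary losses) formalizes the "present in
the ancestor, independently lost" argument: the gain sits at the MRCA of
carrier species; a family is ancestral iff that MRCA is the root; losses
are one per maximal carrier-free clade below the gain. Leaves outside the
gain subtree never carried the family and contribute no loss. The packaged
43-species table and tree yield a root count of 7 with the DRD1C and DRD1E
losses on mutually non-nested (terminal) branches.

The monophyly check is intentionally lightweight — p-distance
neighbor-joining (Bio.Phylo) with monophyly read off edge bipartitions of
the unrooted tree; zero-distance ties across family boundaries are reported
as undecidable rather than resolved arbitrarily. It is a sanity check on
family labels, not a substitute for likelihood phylogenetics, which is out
of scope.

## Paralogons and verdicts (`wgd_evidence`)

Within-genome homolog pairs (self-matches removed, unordered duplicates
collapsed) feed the density detector genome-against-itself; blocks below
`min_paired_proteins` are dropped. The default threshold 7 adopts the
published ">6 paired proteins is unlikely by chance" criterion; 12 is the
stricter preset. Thresholding is monotone (blocks at 12 are sub-blocks of
those at 7).

The verdict per gene pair integrates six columns — microsynteny at 2 Mb and
12 Mb, syntenic lookup in both directions, colinear and density synteny,
paralogon overlap: **WGD** if colinear or paralogon evidence is positive,
or density synteny is corroborated by wide-panel microsynteny; **none** if
all columns are negative; otherwise **segmental_or_unresolved**. The rules
are exposed as configuration; only the all-positive and all-negative
endpoints are treated as fixed points. The pair under test counts as an
anchor of its own region (as in dot-plot practice); the thresholds still
demand 3–6 additional independent pairs.

## Simulator (`simulate`)

The generator emulates the assumed history: ancestral complement → one WGD
→ fractionation → speciation → per-lineage degradation.

* **Mutation model**: per-codon single-nucleotide proposals, uniform over
  positions and alternative bases; stop-creating changes rejected;
  synonymous changes always accepted, nonsynonymous accepted with
  probability ω (default 0.2, purifying selection); the number of
  synonymous events is Poisson(target_Ks × NG86 synonymous sites). Because
  proposal symmetry matches the Jukes–Cantor assumption, NG86+JC recovers
  the planted Ks nearly unbiasedly below saturation (upward convexity bias
  ~2–5% near Ks 1–2). A guard rejects targets > 3.0.
* **WGD** duplicates every scaffold and evolves each copy to half the
  target depth, so homeolog pairs sit at mutual Ks ≈ `wgd_ks` (default 1.0,
  a desk-scale stand-in for the deep vertebrate event, chosen below the
  estimator's saturation). After speciation homeologs keep diverging, so
  leaf-level homeolog Ks equals `wgd_ks` plus twice the root-to-leaf branch
  Ks; parameter-recovery checks therefore measure homeologs at the
  pre-speciation stage.
* **Fractionation**: with probability 1 − retention a pair loses one copy,
  chosen uniformly — never both, so family presence stays interpretable and
  the surviving-duplicate fraction is exactly Binomial(n, retention).
  Lineage losses are injected explicitly as loss events instead.
* **Speciation**: branches keyed by node label accumulate the given Ks;
  divergence is additive in expectation (two sisters at 0.08 each meet at
  ortholog Ks ≈ 0.16, the study condition for the ortholog cluster).
* **Degradation**: `delete_sequence` removes a gene's bases from assembly
  and reads; `drop_annotation` removes only the gene model; fragmentation
  breaks scaffolds at Poisson-placed intergenic positions (gene models are
  never bisected); reads are sampled uniformly at the configured depth
  (default 20×, 100 bp), error-free by default with an optional uniform
  substitution rate — the read check is a coverage argument, not an
  error-model argument. Ground truth per family per species is recorded and
  verified against the emitted files.

What the simulator does **not** model: indels, inversions/translocations
beyond scaffold breaks, paired-end reads, GC/rate heterogeneity, tandem
duplication. Passing validation therefore demonstrates the pipeline's
correctness under the planted model, not robustness to every artifact of
real assemblies; the fixture tables carry the real-data behaviour.

## Validation conditions (problem sizes)

The packaged validation runs use: parameter recovery on 6 scaffolds × 30
genes × 300 codons at retention 0.7 (≥100 ortholog and ≥100 homeolog
pairs); WGD verdict rates on 3 × 20-gene genomes over retention
{0.7, 0.5, 0.3, 0.1} with 10 seeds each (≥ 90% WGD verdicts at retention
≥ 0.5, monotone decline below); presence-call recovery on 2 × 8-gene
genomes at 20× depth over 20 seeds (≥ 95% cell agreement with truth); and a
false-positive control of 10 unduplicated genomes (zero paralogon blocks at
threshold 7). These sizes are the package's validation conditions; the
acceptance script re-runs scaled versions of the same loops from a single
seed.

## Fixture notes

* The packaged species table records one row per (species, missing gene);
  species with complete annotations carry NA evidence. The Adelie penguin
  row keeps no coverage note (the source table's stray "Good" cell has no
  gene attached), and the little egret row is reconstructed (see the file
  header) — both species carry no missing gene, so no count depends on
  them.
* The packaged species tree encodes the consortium phylogeny at the
  resolution the reconstruction needs; all receptor losses are terminal, so
  the root count is insensitive to fine placement within Neoaves.
* In the duplication-evidence grid the cells are transcribed in printed
  column order; the middle rows' column alignment is ambiguous in the
  source, and only the all-positive and all-negative rows are used as fixed
  anchors in tests.
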