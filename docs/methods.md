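# Methods

This note documents the models, defaults, and design choices behind each
pipeline stage, what the synthetic data does and does not emulate, and the
numerical conventions that make runs reproducible.

## Profile search

A gene family's model is a position-specific scoring matrix over the 20
canonical residues plus X. From an aligned seed family, columns with more
than 50% gaps are dropped, and per-column frequencies receive
background-proportional pseudocounts with weight α (default 1.0):

    f'_i(a) = (c_i(a) + α·bg(a)) / (n_i + α),    score(i,a) = ln(f'_i(a)/bg(a))

against the Robinson–Robinson amino-acid background. X scores 0 everywhere
(neutral, the common treatment of ambiguous residues); with α = 0, unseen
residues are capped at a floor of −20 nats rather than −∞.

Queries are scored by Smith–Waterman local alignment against the profile
columns with affine gaps: the first gap residue costs `gap_open` (−11 nats),
each extension `gap_extend` (−1 nat) — the BLAST-like convention. Gap states
may open from any predecessor state; the zero floor of local alignment
applies. Ties among maximal cells resolve to the smallest (query_end,
profile_end) pair, and traceback prefers diagonal over profile-consuming over
query-consuming moves. Percent identity counts aligned columns where the
query residue equals the column's modal seed residue. A numba-compiled
score-only kernel screens whole proteomes; the full traceback runs only for
proteins that clear the E-value cutoff (the two paths compute the identical
recurrence, asserted in the tests).

E-values come from extreme-value statistics of local alignment scores. The
null is built by scoring `n_shuffles` (default 200, minimum 100) i.i.d.
background sequences of the mean seed length and fitting a Gumbel by the
method of moments: λ = π/(σ√6), and K solves μ = ln(K·m·n)/λ with m the
profile length and n the shuffle length. A hit scoring S against a proteome
of N residues then has E = K·m·N·exp(−λS). The default cutoff is 1e−10 at
synthetic scale; the much stricter cutoffs used with full profile-HMM
pipelines on real genome collections are configurable per family. A PSSM
deliberately replaces a full profile HMM (match/insert/delete states): the
pipeline's subject is the screening procedure, and a PSSM preserves
profile-search semantics at a scale where every stage can be verified against
enumeration oracles.

## Pathway calls

The pathway rule is data, not code: a boolean expression over family
literals with `&`, `|` and parentheses ('&' binds tighter). The default is
the minimum viable gud/gar pathway `(gudD|garD)&(gudL|garL)&garR`. garK is an
*excluded* family: its hits are carried in reports and catalogs but never
influence the verdict, reflecting the independent recruitment of glycerate
kinases. Per (genome, family) the single best hit is kept — lowest E-value,
ties broken by higher raw score, then lexicographic locus tag. Calls are
monotone in the hit set: adding hits can only flip a verdict from negative to
positive.

## Neighborhood analysis

An operon is a maximal run of positionally consecutive genes on one contig
and strand with intergenic gaps (next.start − prev.end − 1, overlaps counted
as 0) of at most `max_gap_bp`. The default of 500 bp is a conventional
prokaryotic operon gap; the underlying manual procedure never defined one, so
the threshold is exposed in the configuration. Genes are ordered by position,
not grouped per strand first: an intervening opposite-strand gene always
splits an operon, which is the stricter of the two readings of "same operon".

Candidate discovery emits, for every operon containing at least one
pathway-family hit, each member lacking a hit, ranked by (pathway co-members
descending, operon size ascending, locus tag). This reproduces the discovery
logic that found the alternative aldolase and ABC transporter: searching an
ABC-layout genome with homolog profiles only leaves exactly the transporter
and aldolase genes unannotated inside a hit-rich operon.

Cluster similarity links two gene clusters by greedy one-to-one matching on
global pairwise percent identity (descending identity, each gene used once,
pairs under `min_identity` = 30% dropped) — the behavior of clinker-style
synteny diagrams. Greedy matching can in principle fall below the optimal
assignment's total weight (never below half of it); the test suite checks it
against exhaustive optimal matching on small instances and asserts the pair
count matches. Identity uses direct column comparison for equal-length
sequences (the indel-free synthetic case) and a Needleman–Wunsch alignment
with match +1 / mismatch 0 / linear gap −1 otherwise.

## Phylogenetics

Distances are Poisson-corrected, d = −ln(1 − p), with p the mismatch fraction
over mutually non-gap columns; saturated pairs are capped at `d_max` = 10.
Trees are built with neighbor joining (Saitou–Nei Q-criterion,
Studier–Keppler updates, three-point formulas for the final join). Negative
branch lengths are clamped to zero with the deficit moved to the sibling, and
Q-ties resolve to the lexicographically smallest pair of subtree keys, so
output is deterministic. NJ is exact on additive inputs (topology and branch
lengths), which the suite verifies on random trees.

Distance/NJ plus Fitch parsimony deliberately replace maximum-likelihood tree
inference and ML ancestral reconstruction. The pipeline's downstream calls —
a foreign clade nesting inside another phylum's clade, and clade-diagnostic
residues — are topology-level signals that distance and parsimony methods
express at desk scale with fully checkable behavior; users needing ML trees
can feed their own Newick files into the same detection functions.

Alignment trimming removes columns whose gap fraction strictly exceeds 0.97
(a column at exactly 97% gaps is kept) and reports the kept-column
provenance.

Fitch parsimony runs on a rooted binary version of the tree (polytomies are
resolved deterministically in child order): bottom-up set intersection/union
with unit cost per union, top-down assignment preferring the parent's state,
lexicographic tie-breaks, and missing leaf states treated as the full
alphabet (uninformative).

Clade-diagnostic residues: per column, the focal clade's modal residue and
conservation (modal count over non-gap focal residues) are compared with the
Fitch state set at the focal clade's parent. The focal leaves are masked as
uninformative for that Fitch pass, so the ancestral state is driven by the
rest of the tree — including the focal clade would put the derived residue
into its own ancestor's set and hide every genuine change. A change is
reported when conservation ≥ 0.9 and the modal residue is absent from the
ancestral set. Per-column Shannon entropy over non-gap residues accompanies
the report. Focal clade selection is a user input (a leaf list, checked for
monophyly): no robust automatic branch-length rule exists for delineating a
derived enzyme clade.

HGT detection reports each maximal clade C pure in group g whose smallest
proper ancestor P with ≥ `min_host` (4) leaves has ≥ `host_purity` (0.9) of
its non-C leaves in one group h ≠ g, with C's subtending support ≥
`support_min` (75) when supports are present. Two refinements implement
"nested" rather than merely "adjacent": P must not be the root (a root-level
split between pure groups is the concordant topology), and the context
immediately above P must also be majority-h, excluding the reciprocal
flagging of the host's own subclade sitting next to the foreign clade.
Unrooted trees are midpoint-rooted first; an outgroup rooting helper is
provided, as is an optional column-resampling NJ bootstrap that writes
percent supports onto internal nodes.

## Abundance profiling

Reads are assigned to catalog families by k-mer voting (k = 21, odd to avoid
palindromic self-matches): both read strands are considered, each matching
k-mer votes for the families carrying it, and the read is assigned to the
family with a strict plurality of at least `min_frac` = 0.5 of the read's
k-mers — ties and weak votes leave the read unassigned, and sub-k reads are
tallied separately. This preserves the semantics of mapping reads to a gene
catalog without an external aligner binary.

Samples below `min_total_reads` (default 5,000,000; synthetic runs configure
~10⁴) are dropped; the threshold is strict ("less than"). CPM divides by the
sample's *total* reads, not the mapped subset, so per-sample catalog CPM sums
to at most 10⁶ with equality exactly when every read maps.

Group comparisons sum CPM over a gene subset (all families, the
`homolog_set` preset gudD/garD/garR/garL, or `gudL_only`), report Shapiro–Wilk
normality per group, and run the three pairwise two-sided Mann–Whitney U
tests (CD vs nonIBD, UC vs nonIBD, UC vs CD). U is the statistic of the
first-named group. The exact rank-sum null is used when n₁·n₂ ≤ 10,000 and
the pooled data are tie-free; otherwise a normal approximation with
tie-corrected variance and continuity correction applies (both via
scipy.stats.mannwhitneyu, cross-checked against full permutation enumeration
in the tests). P-values are reported unadjusted by default — the output
header says so — with optional Holm adjustment.

## Synthetic data: what it emulates, and what it does not

The generator defines the study conditions for every test:

- **Species trees** are pure-birth (Yule) trees, ultrametric, with the two
  clades flanking the root labeled as two "phyla". An optional
  `clade_separation` lengthens both root-child stems equally (staying
  ultrametric), emulating the deep divergence between phyla; the HGT study
  uses separation 1.0 so clades are well separated, with the donor drawn from
  the larger phylum and `min_foreign` = 1 (a transfer seeds a single foreign
  leaf).
- **Protein families** evolve indel-free: per branch each site substitutes
  with probability 1 − exp(−rate·length), the replacement drawn from the
  background excluding the current residue. The true alignment is therefore
  the identity map, isolating tree and ancestry logic from aligner quality
  (multiple alignment is out of scope). The default rate of 0.15
  substitutions/site/unit-time yields mean within-family identities near
  60–65% on the default tree — the divergence regime the screen is designed
  for, where search recall against planted families is complete.
- **Genomes** are single contigs of 50–200 genes: one copy of each of 24
  distractor families (evolved along the same tree), random filler proteins,
  and optionally a planted cluster — complete in the permease layout
  (`gudP–gudD–garL–garR`) or the ABC-transporter layout
  (`garABC–gudD–gudL–garR`), or a decoy missing one grammar-critical family.
  Within-cluster gaps are 20–150 bp and the cluster shares a strand, so it
  forms one operon at the default threshold; other gaps are 600–5000 bp.
  Nucleotide sequences are back-translated with a fixed codon table and
  seeded synonymous choice (only k-mer matching consumes them, so codon-bias
  realism is unnecessary).
- **Counts** are negative-binomial with dispersion r (variance μ + μ²/r); UC
  and CD means are scaled by 2^log2FC for pathway families. Expected counts
  scale with each sample's library size relative to the geometric-mean depth,
  the structure CPM normalization is meant to remove; a degenerate library
  range recovers plain NB(μ, r) for moment checks.
- **Reads** are drawn from catalog genes proportional to abundance × length,
  with uniform starts and flat per-base substitution errors; names carry the
  true source gene.

Not emulated: indels, codon and site-rate heterogeneity, strain pangenomes,
quality-score structure, chimeric reads, and real-data contamination. Passing
tests therefore demonstrate the correctness of the algorithms under their
stated models, not robustness to alignment error or sequencing artifacts.

## Reproducibility and problem sizes

Every stochastic operation takes an explicit integer seed; `RunConfig`
carries one global seed from which each module derives a CRC32 sub-seed, so a
serialized configuration reproduces a run byte-for-byte. The standard study
sizes are: 50 genomes (20 complete clusters across both layouts, 10 decoys,
20 negatives) for pathway recovery; 20-taxon trees with 100 replicates per
arm for HGT detection; 10-leaf random additive matrices (100 trees) for NJ;
trees of ≤ 7 leaves and ≤ 4 states (hundreds of instances) for the Fitch
oracle; and n = 50 per group with 200–1000 replicates for Mann–Whitney power
and calibration. These sizes make every stage verifiable against exhaustive
oracles while the full suite and the acceptance script each run in about a
minute.
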