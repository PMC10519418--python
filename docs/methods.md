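# Methods

This note documents the models and procedures orthosweep implements,
the defaults it ships with, and the design choices taken where more
than one reasonable convention exists.

## The filtering model

The filter treats an ortholog cluster as a set of CDS that should be
(a) translatable in one reading frame, (b) of similar length, (c) of
moderate pairwise divergence, and (d) largely complete. Violations of
each assumption map to a distinct contaminant class and a distinct
step:

| step | statistic | removes | default threshold |
|---|---|---|---|
| prep | frame / internal stop | frameshifts, misassemblies | — |
| length_set | length vs cluster mean | truncations, chimeras | 30% variation |
| distance | mean uncorrected p-distance | paralogs, misassigned orthologs | 25% |
| missingness | (N + gap) / row length | N-masked, gappy sequences | 0.25 |
| occupancy | samples per cluster | uninformative clusters | 30 samples |

Conventions, fixed deliberately:

- **Single pass per step.** The length band is computed from the mean
  of the prep-surviving records and applied once (no recomputation
  after removals); the distance filter likewise removes all offenders
  of one matrix simultaneously. Iterating to a fixed point is
  available (`iterate=True` / `--iterate`, off by default) but changes
  semantics: the single pass keeps each step's audit trail
  interpretable against one set of statistics.
- **Strict inequalities everywhere.** A record exactly at a threshold
  survives ("more than x% is excluded").
- **Undefined distances exceed every threshold.** Two rows with zero
  pairwise-comparable ACGT sites cannot be verified as orthologs and
  are treated as infinitely distant.
- **Trimming runs inside every alignment round**, and distances are
  always measured on the trimmed codon alignment of the current
  survivor set.
- The occupancy label is reported as round(100·k/N) to match the usual
  "k of N samples (x% occupancy)" phrasing.
- Threshold monotonicity holds per step: relaxing a step's own
  threshold, with its input fixed, can only grow its survivor set.
  It does *not* hold end-to-end: admitting an extra diverged sequence
  at step 1 raises other sequences' mean distances at step 2. The test
  suite asserts the per-step form.

Threshold selection follows the distribution of per-cluster maximum
p-distances: `distance_threshold_stats` reports its mean, sample SD
and median, the intended anchor being the median when the SD is large
relative to the mean (heterogeneous clusters).

## Alignment protocol

Filtering operates on codon alignments produced by translate → align →
trim → back-translate:

- Standard genetic code; codons containing N translate to X; one
  terminal stop codon is tolerated and trimmed; an internal stop is a
  hard failure routed to the filter report.
- The built-in protein aligner is progressive: fractional common 3-mer
  distances, UPGMA guide tree (leaves pre-sorted lexicographically so
  ties resolve deterministically), profile–profile global alignment
  under BLOSUM62 expected scores with affine gaps (open −10, extend
  −1, Gotoh three-state DP). It is deterministic byte-for-byte for
  fixed input, which the tests rely on. Any external FASTA→FASTA
  aligner (e.g. mafft) can be substituted via `aligner_cmd` when
  bit-parity with a published pipeline matters.
- Column trimming keeps a column iff its gap fraction ≤ 0.2 **and**
  the modal residue fraction among non-gap cells is ≥ 0.25 (X never
  counts toward the mode). This is an explicit, testable approximation
  of "remove poorly aligned regions"; it is not a re-derivation of any
  specific published trimmer's heuristic.
- Back-translation maps retained protein column *j* to codon *j* of
  the CDS counting non-gap cells, so ungapping any output row yields
  the retained codons of the original CDS in order — an exact string
  invariant under test.

## Tree statistics

Bipartitions and clades are bitmask sets over a shared taxon index.
RF(unrooted) is the symmetric difference of non-trivial bipartition
sets; RF(rooted) of internal non-root clade sets; both can restrict to
the common leaf set first. gCF counts a gene tree as *decisive* for a
branch when both restricted sides keep ≥ 2 taxa, *concordant* when the
restricted bipartition occurs in the gene tree — so a polytomy is
decisive but discordant, matching the usual gCF semantics. Quartet
support enumerates the quartets spanning a branch's four adjacent
clusters exhaustively up to a cap (default 1000 per branch) and
samples uniformly with a caller seed beyond it; unresolved gene-tree
quartets count toward none of q1/q2/q3. Local posterior probabilities
are not computed; the quartet frequencies that would feed them are
exported.

## Species-tree estimation

The quartet-agreement score of a candidate topology is the number of
(gene tree, 4-leaf subset) pairs inducing the same resolved quartet.
Exhaustive search enumerates all unrooted binary topologies by
stepwise leaf addition (≤ 8 taxa; ties broken by lexicographically
smallest canonical Newick, co-optima reported). Greedy search inserts
leaves in seeded random order at the score-maximising edge and then
hill-climbs with NNI, accepting only strict improvements, so
termination and determinism are guaranteed. Missing taxa contribute
only the quartets they appear in. Branch lengths are not estimated.

## Subsampling experiment

Subsets are drawn **with replacement** (a subset may repeat a tree),
but the coverage rule — every specimen present in ≥ 2 drawn trees —
counts *distinct* trees only, since a duplicated copy adds no
information. A draw failing coverage is redrawn up to 1000 times;
exhaustion is an error, never a silent relaxation. The reference tree
is rooted on the named outgroup and the outgroup is then pruned, so
comparisons measure ingroup topology only; rooted RF and per-clade
recovery are summarised per size as the clade-recovery proportion and
the RF median/IQR. Each (size, replicate) cell owns a counter-derived
RNG stream, making the full table reproducible independent of
execution order.

## Locus independence

Loci are 1-based point coordinates (the first base); length and strand
are ignored and inter-chromosomal pairs are never neighbours. A locus
is isolated when its nearest neighbour is *strictly* beyond the
independence distance (default 100 kbp; a locus alone on its
chromosome is isolated); clusters join at ≤ that distance
(single-linkage, computed as consecutive runs along each sorted
chromosome, which is equivalent on a line). Bins are half-open
0-based windows of 500 kbp by default: position p maps to bin
⌊(p−1)/bin⌋, so counts always conserve the locus total.

## The simulator

The generator emulates exactly the study conditions the toolkit is
meant for:

- **Species tree**: Yule process (birth rate 1.0), branch lengths in
  coalescent units, leaves contemporaneous; `min_internal_branch`
  optionally stretches short internal branches for recovery tests.
- **Gene trees**: the standard MSC — within a species-tree branch of
  length t, j lineages coalesce at rate j(j−1)/2. The closed form for
  a 3-taxon tree, P(concordant) = 1 − (2/3)e^(−t), is the simulator's
  independent calibration and is asserted at t ∈ {0, 0.5, 1, 2} within
  3 binomial SE at 3000 genes.
- **Sequences**: 300 sense codons by default, Jukes–Cantor-like
  single-rate substitution at 0.01 substitutions/site/coalescent unit
  (keeping typical ingroup p-distances under ~10%, comfortably inside
  the default 25% distance threshold), with any mutation creating an
  in-frame stop rejected and resampled so every output is a valid ORF.
- **Contaminants** (each 4% per record, at most one per record):
  frameshift (one deleted base), truncation (trailing 50% of codons),
  paralog (root sequence re-evolved with 2.0 extra substitutions/site,
  i.e. near-saturation ~70% p-distance, twice the default distance
  threshold), and masking (a contiguous *interior* run of whole codons
  covering 50% of sites — terminal runs would be trimmed as missing
  ends and read as truncations, and real assembly gaps are interior
  runs). Cluster size defaults to 12 species so that a single paralog
  cannot drag clean sequences' mean distance over the threshold
  (with ~7% baseline and one ~70% outlier among 12, a clean row's mean
  stays well under 25%).
- All randomness flows from one seed through per-cluster
  `SeedSequence` spawn keys, so cluster outputs are order-independent.

What the simulator does **not** emulate: introgression (discordance is
ILS-only), rate heterogeneity across sites or lineages, codon usage or
dN/dS structure, alignment-fragmenting indels, and real assembly error
processes. Passing the recovery tests therefore demonstrates that the
filters remove what they are specified to remove under clean
violations of each assumption — not that the thresholds are optimal
for any particular empirical dataset.

## Problem sizes used in the shipped checks

Bookkeeping identities run at their published scales (they are
arithmetic). Simulation-backed checks run at desk scale, chosen as the
smallest sizes at which the tested signal is unambiguous: 12 clusters
× 12 species × 300 codons × 20 seeds for artifact recovery; 300 gene
trees × 8 species × 10 seeds for species-tree recovery; 123 gene trees
× 10 species with 100 replicates of sizes 10–110 for the subsampling
saturation check; 3000 gene trees per point for the MSC calibration.

## Known limitations

- The built-in aligner is a reproducible stand-in, not a drop-in
  replacement for muscle/mafft output; use the external hook for
  parity work.
- Quartet support for a branch adjacent to a polytomy in the species
  tree is skipped (the four-cluster decomposition requires binary
  context).
- The exhaustive species-tree search is capped at 8 taxa by design;
  the greedy search has no optimality guarantee (it is validated
  against the exhaustive oracle on small instances).
- p-distances are uncorrected by definition; saturated pairs compress
  toward 75%, which is why the paralog filter thresholds on the mean
  rather than attempting model-based distances.
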