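# Methods

This note documents the models and procedures implemented in `foldspace`,
the parameters that matter, the synthetic data the tests run on, and the
numerical choices made where the design was genuinely open.  No empirical
claim is made here that the test suite or `scripts/acceptance.py` does not
itself compute.

## Structural distance

The comparison metric is the TM-score of an optimal structural alignment,
symmetrized and converted to a distance.

* **Score.**  For aligned residue pairs at CA–CA distances dᵢ under a
  superposition, `TM(L) = max over superpositions of (1/L) Σ 1/(1+(dᵢ/d₀(L))²)`
  with `d₀(L) = max(1.24 (L−15)^⅓ − 1.8, 0.5)` Å.  The d₀ scale makes the
  score length-independent; the floor at 0.5 Å keeps very short chains
  finite.  This is the standard convention behind the widely used
  similarity thresholds (TM > 0.5 ≈ same fold, TM > 0.4 ≈ similar).
* **Symmetrization.**  TM-score is normalized by one chain length and is
  therefore asymmetric.  Clustering and the shared-folds statistic need a
  metric-like quantity, so the package uses
  `TM_sym = (TM(L_A) + TM(L_B)) / 2` and `distance = 1 − TM_sym`.
  The mean was chosen over min- or max-length normalization because it is
  symmetric, bounded, and reduces to the ordinary score for equal lengths;
  both single-sided scores are always reported so users can re-threshold
  under a different convention.  Symmetry of the distance is additionally
  enforced exactly by canonical (lexicographic by id) argument ordering.
* **Alignment search.**  A fragment-seeded heuristic in the spirit of
  fragment-based TM-aligners, with no claim of bit-compatibility with any
  published program:
  1. seeds from (a) gapless threading at all offsets subsampled with
     stride ⌈L/20⌉, (b) the best-RMSD pair of contiguous 8-residue
     fragments (batched Kabsch over subsampled fragment starts), and
     (c) a dynamic-programming alignment of 3-state secondary-structure
     strings assigned from CA pseudo-dihedrals;
  2. each seed is refined by iterating {Kabsch superposition on the
     current pairs → score matrix S(i,j) = 1/(1+(d_ij/d₀)²) → sequential
     DP → new pairs} until the pair set repeats (cycle detection on the
     hashed pair list) or 30 iterations;
  3. every distinct refined candidate is evaluated under both
     normalizations by the exact given-alignment scorer, and the
     candidate maximizing TM_sym is reported.
  The DP uses a constant gap penalty of −0.6 per gap column, free
  terminal gaps, and a deterministic tie-break (diagonal, then up, then
  left), so results are platform-independent.  The given-alignment scorer
  performs the Max search by seeding superpositions from contiguous
  aligned fragments of lengths L_ali, L_ali/2, L_ali/4 (minimum 4) and
  growing an inclusion cutoff until the superposed subset is stable.
  The inner DP is JIT-compiled (numba); superpositions use the proper
  (reflection-corrected) Kabsch solution via
  `scipy.spatial.transform.Rotation.align_vectors`.
* **Known limitations.**  Alignment is sequential only (no circular
  permutations, no non-sequential topologies); the search is heuristic,
  so the reported score is a lower bound on the true optimum.  The test
  suite bounds it from below by exhaustive gapless-offset oracles on
  short chains.

## Input handling

PDB text is parsed by fixed-column rules: first MODEL only, `ATOM`/CA
records, altloc blank or 'A', residues without a CA skipped,
insertion-code residues kept as distinct residues, HETATM ignored.
Lengths are those of the parsed CA trace (resolved coordinates), not
SEQRES.  Domain decomposition is out of scope: the package consumes
pre-cut domains.  Classification tables follow the ASTRAL `dir.cla`
dialect (sid, PDB code, residue description, sccs, sunid); the fold
identifier is the `class.fold` prefix of the sccs string.

Length filters default to ≥ 80 residues (short peptides assume trivial
topologies) and optionally ≤ 600 residues (to compare sets of comparable
size); both bounds follow the stated conventions — 80 inclusive, strictly
greater than 600 removed.

## Redundancy filtering

Pairwise identity is computed from a global Needleman–Wunsch alignment
(match +1, mismatch 0, linear gap −1, free terminal gaps; via
`Bio.Align.PairwiseAligner`) and normalized by the **shorter** sequence —
the conservative domain-level convention, which removes more.  Culling is
greedy longest-first (ties lexicographic by id): a domain is kept iff its
identity to every kept domain is below the threshold (default 40%).  The
retained set is an antichain under the threshold and every removed domain
has a retained culprit; both properties are asserted in tests.

## Clustering the focus set

Unweighted average linkage (UPGMA, `scipy.cluster.hierarchy.linkage`) on
the structural distance matrix.  The partition is chosen by scanning
k = 1, 2, … — cutting the dendrogram into k clusters means undoing its
last k−1 merges — and taking the first k for which **every**
within-cluster pairwise distance in the original matrix is strictly below
the criterion (default 0.6; boundary equality counts as a violation).
k = n always satisfies the criterion, so the scan terminates.  Checks use
original distances rather than cophenetic heights.  Each cluster is
reduced to its medoid, the member minimizing the **total** distance to
co-members (min-sum rather than min-max; ties resolve to the
lexicographically smallest id).  Cluster separation is summarized by the
count and fraction of inter-cluster pairs closer than a probe cutoff
(default 0.4).

## Shared folds and the permutation null

Non-focus domains are summarized by the distance to their nearest
neighbor among the focus representatives.  Those below the cutoff are the
focus class's relatives; the statistic is the number of distinct folds
they cover.  Unlabeled relatives count as relatives but contribute no
fold.

The null re-partitions the total set (representatives plus non-focus
domains) uniformly at random into a pseudo-focus set A of the same size
and its complement B, and counts B's shared folds **excluding self folds**
(folds already covered by A) — a conservative lower bound on folds shared
with non-self proteins, since same-family members of A would otherwise be
counted as relatives trivially.  Permutations are independent draws from a
seeded generator.  Small counts are the alternative of interest, so the
p-value is left-tailed with the "≤ observed" convention, reported both as
the raw fraction and as (b+1)/(n_perm+1); when no null count reaches the
observed value the honest report is the upper bound `p < 1/n_perm`.

The observed statistic is computed **without** self-fold exclusion by
default (a fold shared by the focus class and its relatives is still a
shared fold of the real comparison), while the null uses exclusion; both
flags are configurable and logged.  Since exclusion can only lower null
counts, this default is conservative for the left-tailed test.

The functional-class entry point runs the identical machinery with an
arbitrary id list as the focus set and no clustering reduction — class
members are compared directly, matching how reference classes are used.

## Synthetic data

Two generators define the study conditions for the tests.

**Latent fold-family datasets.**  Families are isotropic Gaussian clouds
(within-family s.d. σ_w, default 0.1) around centers drawn at scale 0.45
in an 8-dimensional latent space; Euclidean distances e are squashed to
`d = e/(e+c)` (c = 1), which is smooth, order-preserving and maps to
[0, 1).  With these defaults, typical within-family distances fall below
0.4 and typical cross-family distances just above 0.6 — mirroring the
empirical fold-similarity thresholds while leaving a realistic minority
of cross-family pairs below the 0.6 cutoff, as in real fold space where
many folds have close topological neighbors.  A designated focus subset
is displaced along a fixed latent direction; a displacement of ≥ 10× the
center scale puts it beyond 0.7 of everything else (the segregated
regime).  Defaults of 24 families × 3 members echo a fold-classified set
in which most folds retain few members after identity filtering.

**Toy CA-trace templates.**  Ideal-geometry backbones for four secondary
structure arrangements: a four-helix bundle (1.5 Å rise, 100° twist,
2.3 Å radius), a five-strand β meander (3.3 Å rise, 4.8 Å strand
spacing), an eight-strand two-sheet β sandwich with jelly-roll-style
sheet alternation, and a mixed α/β plait.  Loops are circular-arc bridges
with equal CA steps; all adjacent CA–CA distances lie in [2.8, 4.2] Å
before noise.  Copies are perturbed by isotropic coordinate noise and
integer loop-length jitter.  These are geometric motifs, not physical
models: no side chains, no energetics, no sequence realism — they
exercise alignment topology and nothing more.  Consequently, passing
tests demonstrate correct behavior of the alignment/clustering/statistic
machinery, not performance on experimental structures, which have
flexible loops, domain motions and density-dependent errors the
generators do not emulate.

## Statistical calibration check

Under an exchangeable null (focus set drawn uniformly at random, no
displacement), the permutation p-value should be uniform up to the
conservatism introduced by discreteness.  The calibration experiment uses
200 replicates, each with its own latent landscape of 250 singleton
families (center scale 0.8) and a random 25-domain focus set, 99
permutations per replicate.  Many singleton families keep the shared-fold
count fine-grained (its null spread covers many integer values), so the
Kolmogorov–Smirnov comparison against uniformity is meaningful; with few
large families the statistic is too coarse and its tie-induced
conservatism dominates.  The suite asserts the KS statistic stays below
the 1% critical value (1.628/√200 ≈ 0.115).

## Problem sizes and determinism

The packaged experiments use desk-scale sizes chosen to exercise every
code path: 72-domain latent datasets for the pipeline, 24 structures
(4 templates × 6 copies, 100 residues, σ = 1 Å) for structure-level
recovery, 10,000 permutations for the headline run, and 200 × 99
permutations for calibration.  All randomness flows from explicit seeds;
pipeline stages draw from named substreams of the single run seed, and
rerunning a configuration reproduces its JSON summary byte for byte.
Floating-point score comparisons in tests use an absolute tolerance of
1e-3 unless a tighter bound is stated.
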