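# Methods

## The analysis in brief

`phylotrace` reconstructs and interrogates *trees of life* built from
genomic censuses of protein fold superfamilies (FSFs).  A census is a
taxa × FSF matrix of domain abundances.  Two summaries recur throughout:
FSF **use** (the number of distinct FSFs in a proteome — the vocabulary)
and FSF **reuse** (total domain count — the database size).  The pipeline:

1. **Filtering.** Characters can be restricted to the *universal* set —
   FSFs present in at least one member of every supergroup (Archaea A,
   Bacteria B, Eukarya E, Viruses V) — which concentrates signal in the
   deep branches.
2. **Encoding.** Abundances are log-rescaled per character to an ordered
   alphanumeric scale of S ∈ {24, 32, 64} states:
   `s_ij = round((S−1) · ln(a_ij + 1) / ln(m_j + 1))`, with `m_j` the
   character's maximum abundance and half-away-from-zero rounding.
   The map is monotone within a character, so the ordering of taxa by
   abundance is preserved exactly.  All-zero characters are dropped.
3. **Unrooted Wagner parsimony.** Ordered (additive) characters cost
   |a − b| per change.  Tree length is exact via the Farris interval
   algorithm, vectorized over characters.  The heuristic search uses
   random-addition starts, steepest-descent NNI/SPR/TBR rearrangements
   with bounded sideways ("plateau") moves, and returns all distinct
   equally-parsimonious topologies found.
4. **A-posteriori Lundberg rooting.** A hypothetical ancestral vector —
   all-minimum or all-maximum states, the two polarizations of ordered
   characters — is attached to every branch; the cheapest attachment of
   the polarization with the shorter rooted tree places the root.  The
   ingroup topology is untouched; rooting never changes unrooted length.
   Under the generality criterion, data with genuine accretion structure
   select the all-minimum ancestor; the inverse polarization is reported
   and is never shorter.
5. **Diagnostics.** Retention index RI = (G − L)/(G − M) with M the sum of
   character ranges and G the star-tree (median) length; Farris's f (sum of
   patristic-minus-Manhattan distances over pairs, non-negative by
   construction); g1 length-distribution skewness over uniformly sampled
   topologies; per-branch gain/loss tallies from one minimal assignment
   (root clamped to the ancestral end of its Farris interval, a
   deterministic tie-break).
6. **Stability.** Bootstrap tree sets (characters resampled with
   replacement, one best tree per replicate, first in deterministic
   Newick order among ties), strict/majority consensus (via dendropy),
   quartet leaf-stability indices LS_max / LS_difference / LS_entropy,
   Explicitly-Agree similarity, the Mesquite-style taxon instability index
   TII(t) = Σ_{tree pairs (x,y)} Σ_{l≠t} |D_x − D_y| / (D_x + D_y)², and a
   greedy RBIC-like rogue detector.
7. **Timelines and tracing.** Node distance nd(v) counts internal nodes
   from the root (root included), min–max normalized to [0, 1] over the
   target nodes.  Size-vs-nd traces are smoothed with robust LOWESS
   (tricube local linear fits, bisquare reweighting).
8. **evoPCO.** The occurrence matrix weighted by domain age,
   x = occurrence · (1 − nd), ordinated by classical PCoA (Euclidean
   distances, Gower double-centering, eigendecomposition).  Negative
   eigenvalues (numerical noise for Euclidean input) are excluded from
   variance normalization; each axis is sign-fixed so its largest-magnitude
   coordinate is positive.
9. **Heaps and Zipf fits.** Per supergroup, OLS of log₁₀(use) on
   log₁₀(reuse) gives the Heaps exponent β with R², F(1, n−2) and a
   two-sided p; rank–frequency OLS within a proteome gives the Zipf
   exponent γ (β = 1/γ under asymptotic conditions).

## Conventions and numerical choices

- **Quartet frequencies** are normalized over the trees that resolve the
  quartet; quartets resolved in no tree score 0.  Quartet resolution is
  decided by the four-point condition on node-count path distances, which
  handles multifurcating trees.
- **Patristic distances** default to node counts (all branches weight 1),
  avoiding dependence on which minimal assignment produced branch lengths;
  a `steps` variant uses stored branch lengths.  The degree-2 "virtual"
  root of the internal edge-rooted representation is bypassed, so paths are
  counted on the unrooted shape.
- **TII scale** is treated as arbitrary; only relative comparisons
  (percent decreases, rank orders) are meaningful.
- **Rogue score**: the sum of majority-rule bipartition frequencies
  normalized by (n_leaves − 3), so the greedy criterion is comparable as
  leaves are dropped.  This is deliberately simpler than RogueNaRok's exact
  RBIC optimization and is labeled as such in report metadata.
- **Ties.** Polarization ties go to all-minimum (recorded); equally small
  taxa in the deletion test are taken lexicographically (logged);
  equally-parsimonious trees are ordered by their Newick strings.
- **64-state alphabet.** Digits + uppercase + lowercase letters provide 62
  glyphs; two extra symbols ("!@") complete the 64-state alphabet.  The
  24-state alphabet is the conventional `0–9` + `A–N`.
- **LOWESS `i`** is interpreted as robustifying iterations.  Published
  parameter sets of q = 0.1 with i = 100 are accepted, though the
  robustifying loop converges long before 100 iterations; defaults for the
  desk-scale synthetic traces use q = 0.5–0.7 and i ≤ 3 because 16-taxon
  traces have too few points for a 10% window.

## The synthetic data and what it does (not) show

Two generators provide all test data; nothing is downloaded.

**Composition sampler** (`GeneratorConfig`).  Emulates the cross-sectional
statistics of real censuses: each group draws proteome sizes N log-uniform
from overlapping ranges (defaults: V 100–1,000, A 800–8,000, B
1,500–20,000, E 3,000–50,000) and vocabularies V = c·N^β·e^ε with the
planted universal-FSF regime exponents β = 0.81 / 0.36 / 0.19 / 0.03 for
V/A/B/E and lognormal scatter σ = 0.05.  Composition is drawn
kernel-first from a scored pool (60 ancient kernel FSFs, 30 per-group
FSFs interleaved into the upper ranks, 90 shared extras) with per-group
preference offsets and Brownian rank drift along a within-group Yule
tree; abundances are Zipf-ranked weights modulated by a per-group
lognormal profile and a Brownian log-abundance walk, allocated by
multinomial draws that keep use and reuse exactly at their targets.  The
default preset is the 4 × 4-group, 16-taxon design used by the deletion
experiment.  Because each chosen FSF is guaranteed one copy, Heaps fits on
generator output recover the planted exponents; because vocabulary
cutoffs are size-dependent, small unrelated proteomes share absences —
realistic convergence that makes this the *hard* regime for parsimony.

**Accretion walk** (`AccretionConfig`).  Evolves every abundance along one
global tree with backbone (V, (A, (B, E))): the root carries only a
Zipf-ranked ancient kernel (~2,000 domains over 60 FSFs), each group's
entry branch applies a lognormal growth jump (the V < A < B < E size
ladder), within-clade evolution is pure Brownian on log-abundance,
group-specific FSFs can be gained only inside their own clade, shared
extras are gained anywhere at a low rate and lost even more rarely.  Gains
therefore outnumber losses on every path, rooting falls on the kernel
side, and the characters are consistent with a single genealogy — the
high-signal regime used for the deletion test, gain/loss tallies and
polarization checks.

Neither generator simulates SCOP annotation error, horizontal transfer
networks, or genuinely reticulate histories; passing tests demonstrate
correctness of the algorithms under the stated models, not performance on
real proteome annotations.

## Known limitations

- **Deletion-test joint stability.** Individual deletion steps preserve
  the optimal topology in roughly 92–95% of cases on accretion-mode data,
  but all four steps jointly succeed in only ~70% of random seeds: flips
  are near-optimum rearrangements (margins ≤ ~0.3% of tree length) caused
  by the 24-state encoding quantizing away part of the continuous
  within-group signal, plus occasional parallel gains.  The experiment
  reports RF per step, so a user sees exactly where and by how much a
  topology moved.  The packaged example scenario (fixed seed) is stable
  across all four removals.
- Heuristic search carries no optimality certificate beyond ≤7 taxa, where
  it is validated against exhaustive enumeration.
- The g1 null distribution samples topologies uniformly via sequential
  edge addition; other samplers would shift the absolute value (its sign
  and magnitude ordering are what the analysis uses).
- Desk-scale problem sizes throughout: default searches use 16–24 taxa,
  bootstraps tens of replicates, and the Heaps preset 402 taxa; all
  analyses scale to larger inputs at the cost of search time.
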