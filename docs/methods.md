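# Methods

## Scope and model

`structphylo` implements a structure-first homology analysis for
α-helical folds: pairwise Cα structural alignment, conversion of
similarity scores to distances, distance-matrix phylogenetics with
consensus, extraction of a matched helix core between two structures,
measurement of inter-block hinge rotations, and geometric evaluation of
ligand-contact conservation.  All computation is on Cα coordinates in
Ångström; full-atom detail enters only through the optional all-atom
contact mode on parsed PDB files.

## Pairwise alignment

**Fragments.**  An aligned fragment pair (AFP) is a gapless pair of
`afp_len = 8` residue windows whose least-squares superposition RMSD is
≤ `afp_rmsd_max = 3.0 Å`.  All window pairs are screened at once with the
batched singular-value identity `rmsd² = (G_A + G_B − 2·(σ₁+σ₂±σ₃))/L`.

**Rigid alignment.**  Up to `n_seeds = 12` AFP superpositions seed an
iterated refinement (3 rounds): superpose, build the per-position score
matrix `s(i,j) = max(0, 1 − (d_ij/d_c)²)` with `d_c = 5 Å`, find the best
strictly-increasing matching by dynamic programming (O(n·m) with prefix
maxima; only cells with `s > 0`, i.e. deviation < d_c, may match), then
re-superpose on the matched set.  Seed candidates are ranked by the
*support* of their diagonal (the number of AFPs sharing the same i→j
offset) before window RMSD: long alignable runs beat isolated
helix-on-helix coincidences, which matters in all-α proteins where every
helix superposes on every other.  Matched runs shorter than 4 consecutive
equivalences are discarded — the equivalence list is kept at fragment
granularity, and the unaligned intervals that flexible alignment needs
are not fragmented by one-residue coincidences.  `gap_max = 30` applies to
fragment chaining; the refinement DP leaves gap length free (a stretch
farther than d_c from its counterpart cannot match regardless).

**Flexible alignment.**  Starting from the rigid solution, leftover
sequence-interval pairs are realigned rigidly and accepted as new blocks
("twists") while the score gain exceeds the twist penalty, up to
`max_twists = 5`.  Because a block is only ever added when it improves the
score, the flexible score is never below the rigid one.

**Score and P-value.**  `raw_score = s0 · Σ_k s_k − t0 · n_twists`
(`s0 = 4.0`, `t0 = 50`, floored at 0), so 250 perfectly superposed
positions score 1000 — the scale on which scores are capped and
converted to distances.  Significance is calibrated on a null of random
helix-bundle pairs drawn from one architecture distribution (5–9 helices
of 6–16 residues, loops 4–9, 0.8 Å noise): both members share the fold
class but no descent, so their scores measure exactly the "fortuitous
overlap" a P-value should exclude.  Varying the helix count between
members is what gives the null its right-skewed, extreme-value shape; a
null of same-architecture pairs shares genuine fold similarity and is
left-skewed.  A Gumbel is fitted by maximum likelihood and
`p = 1 − exp(−exp(−(S − μ)/β))`.

**Symmetry.**  The aligner, like fragment-chaining aligners generally, is
not intrinsically symmetric in its inputs.  Each unordered pair is
therefore computed in a canonical order (a rigid-invariant key: length,
total step length, sequence) and mirrored, making
`score(A,B) = score(B,A)` exact.

**Block rotation.**  Given the matched core, the reference block
(default c4–c6) of A is superposed onto that of B; the same transform is
applied to A's moving block (default c1–c3), and the residual Kabsch
rotation onto B's moving block is reported as axis–angle (angle in
[0°, 180°], right-handed axis).  Matched helices are truncated to common
length from their N-terminal ends; each block must contain ≥ 9 residues.

## Helix detection and core assignment

A five-residue window starting at i passes when the smoothed distances
d(i,i+2), d(i,i+3), d(i,i+4) all fall within windows centred on the
package's canonical α-helix geometry (rise 1.5 Å/residue, radius 2.3 Å,
100°/residue turn → 5.43, 5.05, 6.20 Å) with half-widths 0.6/0.7/0.8 Å.
Three design points matter:

- the profiles are smoothed along the sequence with a 1-2-1 kernel —
  inside a helix they are constant, so smoothing suppresses coordinate
  noise without shifting the signal;
- every residue covered by a passing window is helical, so an isolated
  window failure (one displaced atom corrupts all windows containing it)
  leaves at most a short gap instead of fragmenting the helix; gaps of up
  to two residues are bridged;
- a run becomes a segment only when it spans ≥ 5 residues *and* contains
  ≥ 2 passing windows: random chains produce single isolated passing
  windows, real helices several, and this requirement is what keeps the
  false-call rate on 50-residue random walks below 0.5 segments per
  chain while exact helix counts survive 0.3 Å coordinate noise.

Window gating uses genuine chain discontinuities only (Cα steps > 6 Å or
< 1.5 Å).  The trace-level QC window of [2.0, 4.5] Å is recorded on the
`CaTrace` for reporting, but it fires on ordinary coordinate noise and
must not fragment geometry-based calls.

Two helices match through an alignment when ≥ 60% of the shorter
segment's residues are equivalenced into the other segment; the *core* is
the longest run of matches consecutive in both structures, labelled
c1..cK from the N-terminus.  The conventional NR helix names
(H3, H4/5, H6/H7, H8, H9, H10/11, H12) are carried as annotation only.

## Distances and trees

`d = |min(S, 1000)/1000 − 1|` maps capped scores to [0, 1] ("rectify"
equals clamping at 0 after capping; negative scores are a domain error).
UPGMA is implemented directly (lowest-index tie-break, so an equal-matrix
input yields a deterministic caterpillar); neighbor joining is
scikit-bio's, with negative branch lengths clamped to zero under a
warning; Fitch–Margoliash starts from the NJ topology and hill-climbs by
nearest-neighbor interchange under the 1/d²-weighted least-squares
objective, branch lengths solved non-negatively (scipy `nnls`, weights
capped at 1e6 for zero distances).  Trees other than UPGMA's are
midpoint-rooted.  The consensus is majority-rule over unrooted splits of
*all* produced trees (support = occurrence fraction; a kept split's
length is its mean over the trees containing it); an outgroup can be used
for rooting instead where one is known.  Newick serialization writes
supports as internal labels with 6-significant-digit lengths.

## Synthetic data: what it emulates, and what it does not

Bundles place ideal helices antiparallel on a ring (spacing 10.5 Å) joined
by circular-arc loops with ~3.8 Å steps and 0.15 Å jitter; clashing
layouts are retried with jittered phase and spacing.  Families diverge
along a guide tree by *Brownian* coordinate noise — displacement variance
proportional to branch length (sd = `noise_rate · √bl`) — so pairwise
expected score drop accumulates additively along paths, which is the
property that makes distance-based topology recovery a well-posed ground
truth; per-branch hinge events are available with configurable rate and
angle spread.  Every generator is a pure function of its seed, with
per-branch substreams derived by hashing so results are independent of
traversal order.

The generators emulate: multi-helix topology, coordinate noise, hinge
rotations, terminal extensions, buried ligand sites, and tree-structured
divergence.  They do *not* emulate: side chains (all-atom contact mode is
exercised only on parsed PDB input), sequence-structure coupling
(sequences are random apart from planted motifs), insertions/deletions
along branches (families are length-conserved), beta structure, or
crystallographic artefacts (alternate locations and chain breaks appear
in the parser's test fixtures, not in generated bundles).  Passing tests
therefore demonstrate correctness of the algorithms under controlled
geometry, not performance on experimental structures.

The reference models in `synthetic_refs` are synthetic stand-ins for a
terpene-synthase / nuclear-receptor pair: a shared seven-helix core
(12-residue helices, 6-residue loops), the TS-like copy hinged 115° at
c1–c3 with two extra N-terminal helices and DDxxD planted at the c2/c3
and c6/c7 junctions, the NR-like copy carrying WRS at the matching
position, both under independent 0.25 Å noise.

## Numerical choices and problem sizes

Kabsch uses the SVD solution with reflection correction and rejects
collinear point sets (second singular value < 1e-9 of the first).
Axis–angle ambiguity is resolved by reporting angles in [0°, 180°] with a
right-handed axis.  Tie-breaks are deterministic throughout (UPGMA
lowest-index; DP traceback preference order; consensus splits ranked by
support, then size, then lexicographic leaf order).  Alignment of a
~100–150-residue pair takes on the order of 0.1 s, which sets the test
suite's problem sizes: 7×10–12-residue helix bundles, 10-leaf families,
20 replicates for recovery rates, 50–100 trees for exactness checks, and
null calibrations of 60–200 samples.

## Limitations

- The aligner is a compact reimplementation of the AFP-chaining idea, not
  a drop-in for any published tool; raw scores share the 0–1000 scale and
  semantics (extent × quality, twist-penalised) but not tool-specific
  values.
- UPGMA assumes a molecular clock; on non-clock families it is routinely
  wrong and is retained because the consensus across methods absorbs it.
- The P-value null is synthetic-bundle-based; for experimental structures
  a null matched to the PDB's fold usage would be preferable.
- Helix-detection windows are calibrated to the package's canonical helix
  geometry; real helices with strong curvature or π/3₁₀ segments will
  fray at the ends, which the 60% core-matching overlap absorbs in
  practice.
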