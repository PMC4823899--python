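# Methods

This note documents the models, algorithms and design choices behind the
toolkit, in enough detail to judge what the simulations and tests do — and
do not — establish.

## The question and the two hypotheses

Given a set of aligned amino-acid sequences and a partition of them into
groups, the model-selection ("UCA") test asks whether one phylogenetic tree
connecting everything (common ancestry) explains the data better than
independent trees for the groups (independent origins, IO). Each hypothesis
is scored by the best AIC over a set of substitution models, and

    delta_AIC = AIC(IO) - AIC(UCA),

so positive values favour common ancestry; a gap above 10 is conventionally
read as "essentially no support" for the loser. Under the standard
phylogenetic likelihood the data are the alignment columns, treated as
i.i.d. draws, which is why both hypotheses must normally be scored on the
*same* alignment; the separate-alignment variant below deliberately breaks
that rule and is flagged accordingly.

The crucial modelling fact is that IO is mathematically the limit of a
connecting branch of infinite length: the closed-form Poisson transition
probability

    P(b | a, t) = exp(-t) * 1[a=b] + (1 - exp(-t)) * pi_b

forgets its initial state exactly at t = infinity, where the joint
probability of a pair of states degenerates to independent draws pi_a*pi_b.
A "profile" simulation — every column filled i.i.d. from a frequency vector
pi — is therefore a star tree with infinitely long branches: sequences with
no common ancestor. The toolkit exists to study how the delta-AIC test
behaves on exactly such data.

## Substitution models

Models are GTR-form and time-reversible: Q_ab = s_ab * pi_b off-diagonal.
The model set offered to selection is {Poisson, Poisson+F, LG, LG+G,
LG+I+G, LG+I+G+F}: it contains the generating models of all simulations
here while keeping model selection affordable at desk scale.

* **Poisson family** (all exchangeabilities equal). The rate matrix uses
  the closed form's own convention Q = pi_b - delta(a=b): one replacement
  *event* per site per unit branch length, where an event may redraw the
  same residue. With this convention expm(Q t) equals the closed form
  exactly (machine precision), which the test suite asserts on a grid of t.
* **LG** embeds the published Le–Gascuel exchangeabilities and frequencies
  and is rescaled to one expected *substitution* per unit branch length,
  the standard convention for empirical matrices.
* **+F** sets the frequencies from the data by counting (gaps excluded),
  floored at 1e-6 and renormalised — the ProtTest/phyml convention — and
  contributes 19 free parameters.
* **+G** uses the mean-rate discretisation of a Gamma(alpha, 1/alpha)
  distribution with K = 4 equal-weight categories (category means, not
  medians). **+I** folds the invariant proportion in as an extra zero-rate
  category of weight p_inv, with the remaining categories rescaled to keep
  the overall mean rate at one.

Transition probabilities come from the eigendecomposition of the
symmetrised rate matrix; scaled branch lengths at or above 50 return the
stationary matrix (each row = pi), and the exponent is capped at 1e4. The
simulator's branch length of 2500 is therefore computationally stationary,
as intended.

## Likelihood engine

Felsenstein pruning over compressed column patterns, gaps treated as
missing data (partial-likelihood vector of ones), per-node rescaling with
accumulated log factors against underflow. Correctness is anchored to an
independent oracle: exhaustive enumeration of all joint ancestral states on
three- and four-taxon trees, which the pruning likelihood must match to
1e-8.

Branch lengths live in [1e-8, 50] (expected substitutions / events per
site). The upper bound stands in for infinity: on independently originated
data the likelihood in exp(-t) is maximised at or beyond the bound, and a
fit at the bound is reported with a saturation flag. Two finite-sample
subtleties are handled explicitly:

* a chance *excess* of matching sites gives a genuine finite optimum (often
  t in the 4–10 range on a few hundred sites); this is correct ML
  behaviour, not a failure of the bound;
* on the flat saturated plateau the optimiser tie-breaks *toward* the
  bound (taking the cap whenever its likelihood is within 1e-6 of the
  plateau optimum), so saturation is diagnosable rather than an arbitrary
  plateau point.

Optimisation is coordinate-wise: each sweep runs a pre-order traversal
maintaining exact outside (pre-order) partial vectors and refreshing each
branch's message before its siblings are processed — every one-dimensional
profile is exact for the current parameter vector, so sweeps are monotone.
Each branch is optimised on a log-spaced length grid within a +/- e^2.5
window around its current value (one vectorised likelihood pass over the
whole grid), followed by a parabolic refinement and, when the edge actually
moved, a finer second grid around the optimum; an optimum outside the
window re-centres it next sweep. A degree-2 root's two edges are folded
into one before optimisation (only their sum is identifiable — the pulley
principle) and count as a single parameter in k. Converged edges
(last gain below 0.005 LnL units) are skipped until a neighbour moves.
Gamma shape and p_inv are optimised by bounded one-dimensional searches
(alpha in log space over [0.02, 1e4]) interleaved with branch sweeps, to a
joint tolerance of 1e-3. Because the joint (alpha, lengths) surface can
hold interior local optima on saturated data, each +G fit also screens the
near-homogeneous boundary (alpha at its upper bound, p_inv at its lower)
starting from the input branch lengths, polishing only when the boundary
wins; this preserves the nesting property LnL(LG+G) >= LnL(LG) that model
selection relies on.

Tree search: exhaustive topology enumeration up to five taxa (three
topologies for a quartet); for more taxa, neighbour joining on ML pairwise
distances followed by first-improvement NNI hill climbing (max 20 rounds).
NNI candidates are pre-screened by their raw likelihood and then by
re-optimising the swapped edge only; accepted swaps get full sweeps. The
distance matrix is evaluated jointly on a log-spaced grid of branch lengths
with quadratic refinement (accuracy ~1%, ample for a starting tree), capped
at 10; NJ ties break at the lowest (row, column) index.

Model selection follows the ProtTest3 convention: the topology is searched
once per hypothesis side under a reference model (LG by default) and every
candidate model is then fitted — branch lengths warm-started from the
previous model's optimum — on that fixed topology, the best fit chosen by
AIC. In the two-hypothesis test the single-tree side additionally starts
from the join of the fitted per-group trees (connected by a saturated
branch): the common-ancestry hypothesis nests the independent-origins
structure, and on saturated data a cold NJ start cannot find the
chance-similarity corners the per-group quartet searches exploit, which
would understate the single tree's likelihood. The winning model is also
re-fitted on the runner-up start topology before the final choice.
Pairwise ML distances for starting trees are evaluated jointly on a
log-spaced grid with quadratic refinement (about 1% accuracy — ample for a
starting tree); the standalone two-sequence distance routine uses a
bounded Brent search with the same cap of 10. A fit's parameter count k is the model's free parameters plus one per
branch length; topology is not counted. Under IO each group may select its
own model; the `force_homogeneous` option instead shares one substitution
model across groups (frequencies pooled, alpha/p_inv maximising the summed
group likelihood, parameters counted once), isolating the IO assumption
from substitution-model heterogeneity.

## Simulator

Sequences evolve down a tree from a root drawn i.i.d. from the stationary
frequencies; each site carries one rate category throughout the tree.
Indels (optional) follow a continuous-time events process along each branch
with per-site insertion and deletion rates and geometric fragment lengths
(default rates 0.03 per unit branch length each, q = 0.5, cap 20); true
homology is tracked through a growing master column list, so the gapped
true alignment and the gap-stripped sequences are always consistent.
Inserted residues are drawn from the stationary frequencies (marginally
exact; the residual correlation from not evolving the insertion over the
remainder of its branch is ignored — a second-order effect at the rates
used here).

Three scenario families define the study conditions:

* **Saturated star / two collapsed quartets** (`simulate_star_io`): n = 8
  sequences, 1000 sites, terminal branches 2500, internal branches zero;
  the shared frequency vector is 20 normalised Uniform(0,1) draws, fresh
  per run. This is the simplified profile counterexample: genuinely
  independent sequences from one amino-acid pool.
* **Profile sampling** (`simulate_profile`): columns filled i.i.d. from a
  shared or per-column frequency vector. Shared mode is distributionally
  identical to the saturated star, which a contingency test on column
  patterns confirms.
* **Two quartets B and E** (`simulate_two_groups`): LG+I+G+F with
  alpha = 1.0, p_inv = 0.1, one sampled frequency vector shared by both
  groups (the common amino-acid pool; group-specific vectors would add a
  frequency-heterogeneity signal that is beside the point these
  experiments make). Branch lengths: B terminal 0.3 / internal 0.15, E
  terminal 0.5 / internal 0.25 — stand-ins for empirically derived
  bacterial and eukaryotic quartets; root length 6591 sites. Under IO the
  quartets are simulated independently and juxtaposed column-by-column (no
  cross-group homology); under UCA one eight-leaf tree joins them by a
  finite branch (default total 0.1).

All randomness flows through one numpy Generator per call, so identical
(operation, arguments, seed) is bit-identical.

## Aligner

A deterministic progressive aligner stands in for MUSCLE: guide tree by
UPGMA (average linkage, as MUSCLE itself clusters) on 1 - cosine
similarity of 3-mer count vectors, then
profile–profile merges scored by the BLOSUM62 expected column score
(sum_ab f1_a f2_b S_ab; gap fractions contribute zero) under affine gap
penalties, open 10 / extend 1 on the BLOSUM62 half-bit scale, terminal gaps
included. The three-state (Gotoh) dynamic programme breaks ties
deterministically — residue pair over gap-in-first over gap-in-second — and
its pairwise special case is verified against exhaustive enumeration of the
alignment space (short sequences) and against Biopython's PairwiseAligner
scores. Stripping gaps from any output recovers the inputs exactly.

UPGMA rather than neighbour joining matters here: on the star-like,
non-additive k-mer distances of saturated two-group data, NJ (ours and
scikit-bio's alike) can split a group across the tree, which then forces
the progressive merge to align part of one group against the other group's
profile; average linkage provably keeps clusters together whenever every
within-cluster distance is below every between-cluster distance.

Identity statistics exclude any pair-column where either sequence is
gapped; the column conservation score used for reordering is the column's
mean pairwise identity with ties broken by original column index. The
within-minus-between statistic is the unweighted mean pairwise identity
inside groups minus that across groups.

## Permutation test

The null of independent origins is approximated by shuffling the column
order of one group's rows in the current alignment (one shared permutation,
preserving the group's internal covariance while destroying cross-group
homology), dropping all-gap columns, stripping gaps and realigning the
pooled set. The alignment is re-optimised for the observed data and for
every null replicate alike. Two statistics: the tree length (sum of branch
lengths) of the ML tree under LG, and the within-minus-between identity;
both are expected lower under common ancestry. Replicate b uses seed
seed + b; the p-value is lower-tail with add-one correction,
p = (1 + #{null <= observed}) / (1 + B), ties counting as "as low as".
By default only the first group is shuffled.

## Experiments and problem sizes

The four runners reproduce the headline behaviours at desk scale (sizes
chosen as the package's default working scale; all are configurable):

1. `run_star_pathology` — 100 replicates of the saturated star scenario, delta-AIC
   test on the simulated alignment as-is (no realignment), IO partition =
   the two quartets. Expected: the large majority of replicates favour
   common ancestry (theory predicts delta_AIC ≈ 32 - chi-square(19) under
   this design, i.e. ~97% positive and ~73% above 10).
2. `run_similarity_conditioning` — a 30,000-column two-group simulation per scenario
   (substitution-only, so segment columns are well defined), columns
   reordered by decreasing conservation, tiled into 1000-column segments
   (non-overlapping by default; `stride` overrides), each segment tested
   before and after realignment. Summaries report the identity levels
   above which every IO segment favours common ancestry. A caveat this
   package's runs expose: segments in the ~0.37–0.42 identity band are
   dominated by columns conserved *within* each group at *different*
   states (low-rate and invariant sites with independent roots). Those
   columns carry genuine independent-origins signal that realignment
   cannot camouflage — MAFFT alignments of the same segments give the
   same verdict — so under this generator the "always favours common
   ancestry after realignment" level sits near 0.42 rather than the ~0.25
   reported for the original (unpublished) group parameters.
3. `run_permutation_study` — 50 IO + 50 UCA replicates at 500 sites, B = 50 shufflings,
   both statistics computed on shared alignments. Summaries: KS uniformity
   of IO p-values, rank-sum separation of observed statistics, power at
   p <= 0.05 under UCA.
4. `run_separate_alignment_study` — 10 replicates of the indel-bearing IO scenario at 6591
   sites; each group aligned alone and the pool jointly; reports the
   joint/separate length ratio and the scaled per-site delta-AIC/BIC
   (model set default LG+G, the generating family, keeping the ~7000-column
   fits affordable; `fit_models=False` measures lengths only).

## What the synthetic data do and do not show

The generator realises exactly the processes the test is analysed under:
i.i.d. columns, homogeneous frequencies within a run, tree-shaped
covariance, geometric indels. Real proteins violate most of this —
site-specific frequencies, structural constraints, heterotachy, selection —
so passing tests show the *operating characteristics of the tests under
their own assumptions* (in particular, that the delta-AIC test prefers
common ancestry for genuinely unrelated sequences whenever similarity is
high enough), not that any verdict on real data is correct. The
separate-alignment comparison is reported with an explicit
cross-alignment flag because information criteria computed on different
alignments have no probabilistic interpretation.

## Numerical choices and degenerate inputs

Branch bounds [1e-8, 50]; pairwise-distance cap 10; +F floor 1e-6; alpha in
[0.02, 1e4]; p_inv in [1e-6, 0.9]; branch search window +/- e^2.5 in log
length with a 7-point coarse grid, parabolic refinement and a 5-point fine
grid; sweep tolerance 1e-3 LnL units (1e-4 for the standalone
branch-length optimiser); NNI acceptance margin 0.01 with a raw-likelihood
rejection margin of 30. Empty sequences, duplicate identifiers, residues outside the
20-letter alphabet plus '-', unbalanced Newick, single-group shuffles and
sub-2-sequence groups are rejected with explicit errors. Likelihoods are
floored at 1e-300 before logs; transition-probability rows are clipped at
zero after the eigendecomposition (deviations ~1e-16).

## Known limitations

* NNI-only topology search can miss optima that SPR would find; at eight
  taxa with clear group structure this has no practical effect.
* The homogeneous-IO fit shares alpha/p_inv via a joint one-dimensional
  search rather than full joint optimisation.
* The indel placement algorithm applies substitutions for the whole branch
  before indel events rather than interleaving them in one Gillespie pass.
* Alignment-free guide-tree distances (3-mer cosine) are crude below ~15%
  identity; the progressive merges, not the guide tree, carry the signal
  there.
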