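# Methods

## Problem

Given only time series of node infection states from a few epidemic
outbreaks seeded at known nodes, infer which pairs of nodes of an
undirected simple graph are connected.  The forward model is a
discrete-time stochastic SIR process on the hidden graph; the inverse
problem is solved by converting observed infection-state transitions into
Dempster–Shafer evidence and fusing that evidence at two levels.

## Forward model: discrete-time network SIR

Each node is susceptible (S), infectious (I) or recovered (R).  A run
starts at t = 1 with a single infectious seed node.  Updates are
synchronous: from the state at step t, every susceptible node with k
infectious neighbors becomes infectious at t + 1 with probability
1 − (1 − β)^k (independent per-contact Bernoulli attempts with per-contact
probability β), and every infectious node recovers with probability γ.
Recovery is absorbing.  A run is recorded as a T × N binary time–state
matrix whose (t, j) entry is 1 iff node j is infectious at step t
(S and R both record as 0).  The terminal all-zero extinction row is kept
so the last infection generation still produces a t → t+1 transition pair.

Two modelling choices are not forced by the fusion framework and are made
explicitly here: the synchronous (parallel) update, which matches the
t → t+1 transition pattern used by the edge criterion, and the
1 − (1 − β)^k multi-exposure rule, the standard independent-contact model
for discrete-time network SIR.  A sequential update would shift transition
counts slightly but not the framework's structure.

RNG discipline: replicate r from seed node s draws its generator from
`SeedSequence(entropy=rng_seed, spawn_key=(index(s), r))`, so batches are
reproducible, independent of evaluation order, and no global RNG state is
touched.

## Evidence construction (per seed node)

**Transition counting.**  For every ordered pair (i, j) and every
consecutive step pair, the event "i infectious and j healthy at t; i
healthy and j infectious at t + 1" is the signature of a direct
transmission i → j followed by i's recovery.  Counts are summed over the
M replicates of one seed node into the count matrix MC.

**Association matrix.**  MR = MC / max(MC) scales counts into [0, 1].
The belief context records the off-diagonal extrema Rmax and Rmin and
their midpoint Rmid.  The diagonal is structurally zero (the pattern
cannot fire for i = j) and is excluded from the extrema so it cannot
distort the contrast range.  Never-transmitting pairs are genuine
off-diagonal observations and are included, which makes Rmin = 0 in
practice.

**Belief mapping.**  An association strength x becomes a mass triple on
the frame {T = edge, F = no edge} through its absolute deviations from the
context statistics:

    Summ = |x − Rmax| + |x − Rmin| + |x − Rmid|
    m({T}) = |x − Rmin| / Summ
    m({F}) = |x − Rmax| / Summ
    m({T,F}) = |x − Rmid| / Summ

m({T}) is strictly increasing in x on [Rmin, Rmax].  Note the uncertainty
mass m({T,F}) is largest at the extremes x ∈ {Rmin, Rmax} (value 1/3) and
zero at the midpoint; see *Known limitations*.  A degenerate context
(Rmax = Rmin, no contrast) maps everything to the vacuous mass (0, 0, 1) —
total ignorance — rather than raising an error.

**Intra-node fusion.**  For each unordered pair, the two directional
evidence bodies built from MR(i, j) and MR(j, i) are combined with
Dempster's rule specialized to the two-hypothesis frame
(K = m1_T m2_F + m1_F m2_T; intersecting products renormalized by 1 − K),
and the result written symmetrically.  This yields one evidence-matrix
triple (support, opposition, uncertainty) per seed node.

## Inter-node fusion and decision

Per-seed evidence matrices are folded left-to-right in seed-list order,
elementwise per node pair, with the same combination rule.  Because the
rule is commutative and associative, the fold order only matters at
floating-point level (verified to 1e−9; the three-term numerators are
grouped `a + (b + c)` so scalar combination is bitwise commutative and the
matrix version bitwise symmetric).  The decided adjacency sets
A(i, j) = 1 iff the fused global m({T})(i, j) strictly exceeds the belief
threshold θ.

Total conflict (K = 1, only possible when both bodies carry zero
uncertainty mass) cannot be renormalized.  Default policy is
warn-and-return-vacuous so one pathological pair cannot abort a whole
reconstruction; a strict mode raises instead.  A seed node whose batch
contains no transmission events at all contributes all-vacuous evidence
(the neutral element) with a warning.

## Defaults and parameters

| parameter | default | meaning |
|---|---|---|
| β | 0.5 | per-contact per-step infection probability |
| γ | 1.0 | per-step recovery probability (one-step infectiousness) |
| M | 50 | SIR replicates per seed node |
| seed nodes | first 3 labels | epidemic sources / observation perspectives |
| θ | 0.7 | decision threshold on fused support mass |
| τ | 1 | co-infection count threshold of the baseline |
| max_steps | 4N | safety cap; with γ = 1 extinction occurs within N + 1 steps |

β = 0.5, γ = 1 and θ = 0.7 are the standard study settings for the
moderate-size benchmarks; γ = 1 makes each node infectious for exactly one
step, which is what makes the transition pattern an unambiguous
transmission signature.

## Baseline

The co-infection-counting baseline predicts an edge whenever two nodes are
simultaneously infectious at least τ times across all recorded steps of
all runs.  It conflates direct transmission with independent co-infection:
on a star graph with β = 1 and the hub as seed it predicts exactly the
three leaf–leaf non-edges and none of the true hub edges (TPR 0, FPR 1).
τ = 1 is the default because any larger value is equally unprincipled and
τ = 1 exhibits the baseline's characteristic over-prediction.

## What the test graphs emulate

The bundled 34-node/78-edge karate-club social network provides a real
two-community topology.  The seeded 16-node/39-edge generator produces a
dense connected benchmark of fixed size (uniform over 39-edge subsets,
re-sampled until connected — re-sampling keeps the distribution simple);
the Erdős–Rényi / Barabási–Albert / star / path generators cover sparse,
heavy-tailed and degenerate regimes for property tests.  Synthetic SIR
data are exactly the model the method assumes; real propagation data would
add reporting noise, missed infections and non-Markovian recovery, none of
which are modelled here, so green tests certify correctness of the
algorithm, not robustness to observation error.

## Numerical choices

- Masses are IEEE doubles; exactness claims in tests are checked against a
  rational-arithmetic re-derivation and a generic power-set Dempster
  combiner kept independent of the implementation.
- Mass normalization tolerance 1e−9; oracle-equivalence tolerance 1e−12;
  total-conflict cutoff 1 − K < 1e−12.
- Matrix fusion is fully vectorized; an N = 34 reconstruction with
  3 × 50 runs takes well under a second.

## Known limitations

- **Absolute belief scale vs. ranking.**  The deviation-based belief
  mapping caps m({T}) at 2/3 for a single evidence body, and combining a
  supporting body with an opposing or ignorant one shrinks it further.
  Consequently the fused global support mass for a true edge whose
  evidence is strong but one-directional per seed is ≈ 0.49 (the exact
  chain trace: 5.2/10.6), below the default θ = 0.7, and on the karate
  benchmark at the default settings the maximum global support mass over
  all pairs stays near 0.5, so the θ = 0.7 decision returns few or no
  edges (TPR ≈ 0, FPR 0 in the bundled benchmark runs; the acceptance
  script reports exactly this).  The fused support mass still *ranks*
  true edges far above non-edges — its ROC is informative — but its
  absolute scale is not calibrated to a 0.7 threshold.  The threshold and
  the mapping are kept as defined; recalibrating either is deliberately
  out of scope.
- Reconstruction output is symmetric by construction; directed or weighted
  inference is out of scope, as are alternative combination rules (Yager,
  PCR5) and frames with more than two atoms.
- Seed-node choice is user responsibility; no seed-selection optimization
  is provided.
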