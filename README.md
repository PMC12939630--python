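# epifuse

Reconstruction of an unknown undirected network topology from epidemic
propagation time series, using two-level Dempster–Shafer belief fusion.

Many complex systems — social ties, infrastructure, protein interactions —
have connection structures that cannot be observed directly, while the
*dynamics* running on them (an epidemic, a rumor, a cascading failure) can
be.  `epifuse` addresses this inverse problem for discrete-time stochastic
SIR dynamics: seed an infection at a few known nodes, record who is
infectious when, and infer which node pairs are connected.

## Method in brief

For each seed node s, run M independent SIR simulations (per-contact
infection probability β, recovery probability γ) and record each run as a
binary time–state matrix.  The transition pattern

> i infectious and j healthy at step t;  i healthy and j infectious at t+1

is the signature of a direct transmission i → j.  Counts of this pattern
form a count matrix MC; normalizing by its maximum gives the association
matrix MR ∈ [0, 1]^{N×N}.  Each strength x = MR(i, j) becomes a basic
probability assignment (BPA) on the frame Θ = {T, F} (edge / no edge) via
its deviations from the matrix extrema Rmax, Rmin and the midpoint Rmid:

    m({T}) = |x − Rmin| / Summ,  m({F}) = |x − Rmax| / Summ,
    m({T,F}) = |x − Rmid| / Summ,  Summ = Σ of the three deviations.

**Level 1 (intra-node):** for each pair, the directional bodies from
MR(i, j) and MR(j, i) are combined with Dempster's rule
(m = m₁ ⊕ m₂, conflict K = m₁({T})m₂({F}) + m₁({F})m₂({T}),
renormalization 1/(1−K)), giving one symmetric evidence triple per seed.
**Level 2 (inter-node):** the per-seed evidence matrices are folded
sequentially with the same rule into a global BPA, and the adjacency is
decided by A(i, j) = 1 iff global m({T})(i, j) > θ.

A co-infection-counting baseline (edge iff two nodes are co-infectious ≥ τ
times) and TPR/FPR evaluation over unordered node pairs are included.

## Worked example

```python
from epifuse import (karate_club, ReconstructionConfig, reconstruct_pipeline,
                     confusion)

g = karate_club()                         # 34 nodes, 78 edges
cfg = ReconstructionConfig.with_defaults( # seeds {1,2,3}, beta=0.5, gamma=1,
    g, replicates=50, rng_seed=7)         # M=50, theta=0.7
res = reconstruct_pipeline(g, cfg)

print(res.global_evidence.bpa_t[0, 1])    # fused support mass for pair (1,2)
print(confusion(g, res.adjacency).tpr)    # fraction of true edges recovered
```

prints

```
0.27781620076116126
0.0
```

The first number is the fused belief that nodes 1 and 2 are connected
(they are; the median fused support is 0.21 over true edges versus 0.007
over non-edges in this run, so the evidence separates the classes
well).  The second
shows the headline caveat of the belief mapping: the fused support masses
rank true edges well above non-edges, but their absolute scale stays below
the default decision threshold θ = 0.7, so the thresholded adjacency is
empty here — see `docs/methods.md`, *Known limitations*, for the analysis.

A fully hand-traceable run on the 3-node chain with β = 1, γ = 1, M = 1
gives global support 5.2/10.6 ≈ 0.4906 for each true edge and opposition
728/729 for the non-adjacent pair — values the test suite checks against
exact rational arithmetic.

The same pipeline is available from the shell:

```bash
epifuse fixtures karate -o karate.edgelist
epifuse reconstruct karate.edgelist --seeds 1,2,3 --replicates 50 \
        --rng-seed 7 -o out/
epifuse evaluate --truth karate.edgelist --pred out/adjacency.csv
epifuse benchmark karate.edgelist --rng-seed 7     # fusion vs baseline TSV
```

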