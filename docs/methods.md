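# Methods

## Problem and model

Given a binary circRNA–disease association matrix `Y ∈ {0,1}^{m×n}` and a
disease semantic-similarity matrix (values in [0,1], consumed precomputed —
this package never traverses an ontology), the task is link prediction:
score every pair so that true-but-unobserved associations rank above the
rest.  Two predictors are fused:

**Random walk with restart.**  The heterogeneous network has m circRNA and
n disease nodes.  Its transition matrix has four blocks: within-network
moves are similarity rows normalized to sum 1, scaled by `1−μ` when the
source node has at least one association; cross-network jumps distribute
mass `μ` uniformly over the source's associations.  A node with no
associations keeps all its mass within its own similarity network, so
every row sums to 1 (or 0 for a node with neither similarity nor
associations — such rows are left zero; mass decays toward the restart
distribution and nothing is teleported).  Scoring disease `j` seeds
`p₀` with `1−λ` on that disease and `λ/m` on every circRNA, then iterates

    p ← β Wᵀ p + (1−β) p₀

to the fixed point `(1−β)(I − βWᵀ)^{-1} p₀`.  The transpose convention is
deliberate: `W` is row-stochastic (rows = sources), so only `Wᵀ` applied to
an occupancy vector conserves probability mass.  The walk weight is `β`
and the restart term carries `1−β`; with the default `β = 0.2` the restart
mass is 0.8.  We verified empirically that this literal reading of the
update rule also outperforms the alternative convention (restart mass 0.2)
on the synthetic benchmark, so the naming tension in the surrounding
literature is resolved in favor of the update rule as written.

**Laplacian regularized least squares.**  With `L = D^{-1/2}(D−S)D^{-1/2}`
(`D` = diagonal of row sums; symmetric, PSD, eigenvalues in [0,2]), the
circRNA-space problem `min_F ‖Y−F‖²_F + γ_c tr(Fᵀ L_c F)` has closed form
`F_c = SC (SC + γ_c L_c SC)^{-1} Y`; the disease-space mirror acts on `Yᵀ`,
and `F = (F_c + F_dᵀ)/2`.  The two-space average is the standard LapRLS
construction for bipartite targets; the trade-off weights are deliberately
independent per space (`γ_c = 0.95`, `γ_d = 0.2` by default) and are
distinct parameters from the Gaussian-kernel bandwidth scales, despite the
shared Greek letter in much of the literature.

**Ensemble.**  `Ypre = P + θF`, raw matrices, no per-matrix normalization
by default (an explicit design choice: the soft vote is defined on the
matrices the two models emit).  `θ = 0.3` by default.

## Similarity channels

- Profile kernel: `exp(-γ‖Δprofile‖²)`, `γ = γ′ / mean squared profile
  norm`, `γ′ = 1` by default.  If every profile is empty the bandwidth is
  undefined; the identity matrix is returned (no information ⇒ only
  self-similarity) with a warning.  This arises only under extreme
  cross-validation masking.
- Functional similarity: best-match averaging of semantic similarity over
  the two circRNAs' disease sets; the max over an empty set is 0, so any
  pair involving an associationless circRNA scores 0 off-diagonal.  The
  diagonal is always forced to 1, which keeps the fused matrix
  positive-diagonal and the Laplacian well-defined (row sums ≥ 1, so no
  normalization ever divides by zero).
- Fusion weights `α_c = α_d = 0.5` by default.
- A disease present in the associations but absent from the semantic
  matrix gets semantic similarity 0 to all others and 1 to itself
  (logged); the profile channel is precisely the fallback for diseases
  without ontology terms.

## Hyperparameters

| name | default | role |
|---|---|---|
| `alpha_c`, `alpha_d` | 0.5 | biological vs. profile channel weight |
| `gamma_c_band`, `gamma_d_band` | 1.0 | profile-kernel bandwidth scale |
| `beta` | 0.2 | walk weight (restart mass `1−β`) |
| `lambda_` | 0.1 | restart mass routed to the circRNA layer |
| `mu` | 0.6 | cross-network jump probability |
| `gamma_c_reg`, `gamma_d_reg` | 0.95, 0.2 | LRLS smoothing trade-offs |
| `theta` | 0.3 | soft-voting weight |
| `rwr_tol`, `rwr_max_iter` | 1e-6, 1000 | propagation stopping rule |

The defaults are the published operating point of the method.  The
assignment of 0.95 to the circRNA space and 0.2 to the disease space
follows the "respectively" reading of the source description; both are
exposed in the config.

## Evaluation protocol

Repeated k-fold cross-validation partitions the known positive *pairs*
(not diseases).  Per fold the test positives are set to 0 in `Y` and
**every** similarity channel — both profile kernels *and* the functional
similarity — is recomputed from the masked matrix before fitting either
model; recomputation is what prevents test labels leaking through the
similarity graph, and a sentinel-injection test enforces it.  The fold
AUC uses all pairs except training positives as the ranking population
(negatives = all unknown pairs; deterministic and parameter-free, the
convention of the comparator literature).  AUC is computed in-house via
midranks (Mann–Whitney U normalized by |pos|·|neg|); the scikit-learn
implementation serves only as an independent cross-check in the tests.
Fold AUCs are averaged; a pooled variant is not offered because per-fold
averaging is what the headline numbers report.  Randomness: one master
seed, repeat `r` uses `seed + r`; no global random state.

## Synthetic benchmark

The generator plants signal in both channels the method fuses — without
that, the fusion weights would be untestable.  circRNAs and diseases are
assigned round-robin to matched clusters; associations are Bernoulli
draws at `p_in = 0.5` within matched cluster pairs and `p_out = 0.02`
elsewhere; the semantic matrix is `sem_in = 0.8` within disease clusters,
`sem_out = 0.1` across, ± uniform jitter 0.05, diagonal 1.  The default
"small" instance is 60×20 with 4 clusters — the full pipeline runs in
well under a second — and a "paper-shaped" 585×88 instance at overall
density ≈ 0.0126 exists for scale testing only.  Ten percent of the
drawn within-cluster links are withheld from `Y` as recoverable ground
truth.

What the benchmark does *not* emulate: real degree distributions
(catalogue data is dominated by singleton circRNAs), alias structure,
or ontology-derived similarity; passing here demonstrates correct
mechanics and genuine signal recovery, not real-data accuracy.

A useful calibration: an oracle that scores 1 on every matched-cluster
cell and 0 elsewhere achieves mean CV AUC ≈ 0.874 on the small instance,
because a masked test positive is statistically indistinguishable from a
never-drawn within-cluster cell at `p_in = 0.5`.  The implemented models
reach ≈ 0.78–0.79, i.e. roughly 91% of that ceiling; the ceiling, not the
implementation, is what bounds the attainable AUC on this generator.

## Numerical choices

- Propagation stops when the ℓ1 change drops below `rwr_tol` (default
  1e-6, max 1000 iterations); non-convergence returns the current iterate
  with a flag and a warning.  The fixed point satisfies the residual bound
  ‖p − βWᵀp − (1−β)p₀‖₁ < 10·tol.
- LRLS systems are solved (`scipy.linalg.solve`), never inverted; an
  ill-conditioned or singular system (duplicated association profiles
  make `S` rank-deficient) falls back to least squares with a warning.
- Similarity symmetry is enforced at 1e-10 in memory; file ingestion
  repairs asymmetry up to 1e-6 by averaging and clips [0,1] violations up
  to 1e-9.
- Ties in rankings break by circRNA identifier; tied scores share a dense
  rank in the score table.  Score tables serialize floats with 17
  significant digits, so write→read round-trips are bit-exact.
- Identifier order is first appearance in the edge list; all matrices
  index by identifier, never by external file position.  Distinct circRNA
  alias strings are distinct nodes (no alias merging).

## Known limitations

- An edge list cannot carry isolated nodes, so circRNAs/diseases with no
  associations drop out on serialization round-trips.
- The per-disease RWR loop is dense and O(n·(m+n)²) per fold; fine to a
  few thousand nodes, beyond that a sparse resolvent solve would be the
  next step.
- The AUC convention excludes training positives from the ranking
  population; published numbers elsewhere may count them as negatives and
  are not directly comparable.
- Disease semantic similarity is an input; garbage in, garbage out.
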