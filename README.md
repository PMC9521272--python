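# cda-netfuse

Prediction of circRNA–disease associations by an ensemble of **random walk
with restart** (RWR) and **Laplacian regularized least squares** (LRLS) over
fused similarity networks, with repeated cross-validated AUC evaluation and
per-disease candidate ranking.

Circular RNAs (circRNAs) act as oncogenes or tumor suppressors in many
cancers, but experimentally confirmed circRNA–disease links are sparse.
Given a binary association matrix `Y` (m circRNAs × n diseases) and a
precomputed disease semantic-similarity matrix, this package scores every
circRNA–disease pair so that unobserved but likely links rank highly —
the standard computational route to prioritizing candidate biomarkers for
follow-up.

## Method

1. **Similarity fusion.** Two channels per node type:
   - Gaussian kernel on association profiles,
     `S^ap(i,j) = exp(-γ ‖Y(i,:) − Y(j,:)‖²)` with bandwidth
     `γ = γ′ / mean_k ‖Y(k,:)‖²` (columns of `Y` for diseases);
   - a biological channel — the precomputed disease semantic similarity
     `S^sem`, and for circRNAs the functional similarity it induces by
     best-match averaging over the two circRNAs' disease sets.

   Fused: `SC = α_c S^fun + (1−α_c) S^ap_c`, `SD = α_d S^sem + (1−α_d) S^ap_d`.

2. **RWR.** On the heterogeneous (m+n)-node graph with block transition
   matrix `W` (within-network moves weighted `1−μ`, cross-network jumps
   `μ`), iterate `p ← β Wᵀ p + (1−β) p₀` per seed disease; the circRNA
   block of the fixed point is that disease's score column `P(:, j)`.

3. **LRLS.** With `L` the normalized Laplacian `D^{-1/2}(D−S)D^{-1/2}`,
   the closed form `F_c = SC (SC + γ_c L_c SC)^{-1} Y` (and its disease-space
   mirror on `Yᵀ`) minimizes `‖Y − F‖²_F + γ tr(Fᵀ L F)`;
   `F = (F_c + F_dᵀ)/2`.

4. **Soft voting.** `Ypre = P + θ F`.

Evaluation is repeated k-fold cross-validation over the known positive
pairs: each fold's positives are masked, **all** similarity channels are
recomputed from the masked matrix (no test-label leakage), and the fold
AUC (Mann–Whitney, midranks for ties) ranks the hidden positives against
all unknown pairs.

## Worked example

A planted-cluster benchmark ships with the package (`cda_netfuse.synthetic`):
matched circRNA/disease clusters generate dense within-cluster associations
(`p_in = 0.5`) against a sparse background (`p_out = 0.02`), with a
block-structured semantic matrix, and 10% of the within-cluster links
withheld as recoverable ground truth.

```sh
python examples/02_cross_validate.py
```

prints

```
rwr      mean AUC 0.7812  (fold range 0.685-0.918)
lrls     mean AUC 0.7927  (fold range 0.681-0.889)
ensemble mean AUC 0.7936  (fold range 0.684-0.892)
the ensemble should match or beat both individual models
```

— both predictors recover the planted structure far above chance
(AUC 0.5) and the soft-voting ensemble edges out either alone.  Note a
perfect oracle that knows the cluster assignments tops out near AUC 0.87
on this benchmark, because masked test positives are statistically
indistinguishable from never-drawn within-cluster pairs.  And

```sh
python examples/01_simulate_and_predict.py
```

prints

```
benchmark: 60 circRNAs x 20 diseases, 154 known associations, 16 held-out true links
median rank of the 16 held-out true links among 1046 unknown pairs: top 9% (chance would be ~50%)
```

— the withheld true links concentrate near the top of the unknown-pair
ranking.  See `examples/` for per-disease ranking and the θ sensitivity
sweep.

## Command line

```sh
cda-netfuse simulate --preset small --seed 17 --out-dir data/
cda-netfuse predict --associations data/associations.tsv \
    --disease-sim data/disease_sem.tsv --model ensemble --out scores.tsv
cda-netfuse cv --associations data/associations.tsv \
    --disease-sim data/disease_sem.tsv --folds 5 --repeats 10 --seed 17
cda-netfuse rank --associations data/associations.tsv \
    --disease-sim data/disease_sem.tsv --disease disease01 --top 20
```

Input formats: a 2-column TSV edge list (`circRNA_id<TAB>disease_id`,
`#` comments allowed) and a labelled square similarity TSV.  Hyperparameters
can come from a flat YAML file (`--config`); flags override it.

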