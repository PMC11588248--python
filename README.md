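# frecl — functional regression clustering of expression time courses

Gene-expression time series collected under several conditions (for
example, diurnal expression in four seasons) often contain genes whose
*shapes* differ wildly but whose expression *responds to the conditions
in the same way*. Clustering methods that group curves by shape miss
this structure entirely. `frecl` clusters observations by the
relationship between a functional response and one or more functional
predictors: each cluster is defined by its own function-on-function
linear regression model, and observations are grouped with the model
that explains them best.

## Model and algorithm

For observation *i* in cluster *k*, with response curve *Y<sub>i</sub>*
and predictor curves *X<sub>i1</sub>, …, X<sub>ip</sub>* on a common
domain 𝒯:

> Y<sub>i</sub>(t) = β<sub>0k</sub>(t) + Σ<sub>j</sub> ∫<sub>𝒯</sub>
> β<sub>jk</sub>(t, s) X<sub>ij</sub>(s) ds + ε<sub>i</sub>(t)

where β<sub>0k</sub> is a cluster-specific intercept curve and each
β<sub>jk</sub>(t, s) is a coefficient surface weighting predictor *j*'s
value at time *s* in predicting the response at time *t*. The unknown
partition is estimated by a K-means-type alternation:

1. fit the regression model within each non-empty cluster (penalized
   least squares on tensor-product cubic B-splines, penalty weight by
   generalized cross-validation);
2. reassign every observation to the cluster whose fitted model gives
   its residual curve the smallest L² (or L¹) norm;
3. repeat until two consecutive partitions coincide (or 300 iterations).

Because a single run depends on its random initial partition, the full
procedure performs *L* independent runs, accumulates their binary
co-assignment matrices into a consensus matrix **B**, and K-means-
clusters the rows of **B**. The number of clusters is chosen by an
elbow criterion on MSE(K) = (1/m) Σ<sub>k</sub> Σ<sub>i∈C_k</sub>
r̂²<sub>ik</sub>, the mean squared residual norm under the final
partition.

The package also ships the surrounding toolchain: expression
preprocessing (replicate medians, TPM filtering, centering, local-
quadratic LOESS), a scenario-faithful synthetic-data simulator (iid or
AR(1) functional errors on an hourly 24-point grid), pair-counting
agreement metrics (ARI, Rand index, TPR/TNR), and an FPCA + K-means
oracle baseline for comparison.

## Worked example

Simulate a 3-cluster dataset with AR(1) errors (ρ = 0.5, innovation
variance 0.1), cluster it with 10 consensus runs, and score the result
against the known truth:

```sh
frecl simulate --m 300 --k-true 3 --seed 42 --error ar1 \
      --sigma2 0.1 --rho 0.5 --out-dir data
frecl cluster --response data/response.tsv \
      --predictor data/predictor_1.tsv --predictor data/predictor_2.tsv \
      --predictor data/predictor_3.tsv \
      --k 3 --l 10 --seed 0 --n-basis-t 6 --n-basis-s 6 --out-dir out
frecl evaluate data/truth.tsv out/partition.tsv
```

which prints

```
simulated 300 observations, K_true=3
3 clusters from 10/10 convergent runs
{
  "ari": 1.0,
  "rand_index": 1.0,
  "tpr": 1.0,
  "tnr": 1.0,
  "pairs": {"TP": 14934, "FP": 0, "FN": 0, "TN": 29916}
}
```

All 10 runs converged, the consensus partition matches the simulated
truth exactly (adjusted Rand index 1.0), and every one of the 44 850
observation pairs is classified correctly. `out/` also contains the
dense consensus matrix, a JSON-lines log of every iteration (cluster
sizes and total squared residual) and a manifest sufficient to
regenerate the outputs. The same workflow is available from Python via
`simulate_dataset`, `frecl_consensus` and `adjusted_rand_index`; see
`docs/methods.md` for the methodology and parameter guidance.

Other subcommands: `preprocess` (replicate TPM tables → smoothed,
centered curve sets), `mse-profile` (MSE(K) over a range with the
elbow choice), `baseline` (FPCA + K-means oracle).

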