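# Methods

## The model

The pipeline assumes bulk blood expression is generated by a small number
of non-negative latent programs: with `D` the log2(TPM + 1) genes × samples
matrix, `D ≈ A·P` where `A ≥ 0` (genes × K amplitudes) and `P ≥ 0`
(K × samples pattern values). Each pattern is interpreted as an expression
program (for example a cell-state signature) whose per-sample weight can
rise and fall over a patient's course; the amplitude column is the
"recipe" of genes that program uses.

### Factorization solver

We fit the penalised Frobenius objective

    ‖D − A·P‖²_F + λ_A·Σ|A| + λ_P·Σ|P|

by multiplicative updates (the L1 penalties enter the update denominators,
which preserves non-negativity and the monotone decrease of the
objective), with `n_restarts` random initialisations; the restart with the
lowest final objective wins. This is a deterministic stand-in for sparse
Bayesian NMF samplers with the same `D ≈ A·P` contract and the same
sparsity intent; posterior uncertainty over the factors is deliberately
out of scope. Key numerical choices:

- **Initialisation**: entries uniform on (0, 1] scaled by
  `sqrt(mean(D)/K)`; restart `r` uses seed `seed + r`.
- **Defaults**: `tol = 1e-5` (relative objective change), `max_iter = 2000`,
  `n_restarts = 5`, `λ_A = λ_P = 0.01·mean(D)`, `K = 30` (the study-scale
  pattern count). A small `1e-12` floor in the update denominators guards
  against division by zero.
- **Identifiability**: after the fit each pattern row of `P` is rescaled to
  unit maximum and the inverse scale folded into the matching column of
  `A`, leaving `A·P` unchanged to ~1e-10.
- **Gene filter**: genes with zero variance or detected (value > 0) in
  fewer than 5% of samples are dropped before fitting; all-zero rows make
  the multiplicative updates degenerate.
- **Pseudocount**: the log transform uses log2(TPM + 1).

PCA treats samples as observations and genes as centred variables (no
unit-variance scaling, matching `prcomp` defaults), computed by SVD.
Component signs are fixed so the largest-magnitude loading entry is
positive. A constant matrix returns zero scores with a warning rather
than failing.

### Projection

For a target dataset sharing genes with the source, each target column is
solved independently: ordinary least squares (minimum-norm via SVD when
the shared amplitude matrix is rank-deficient, with a warning) or
non-negative least squares. No intercept and no target re-centring by
default — amplitudes and log2 abundances live on a shared non-negative
scale — with an optional per-gene centring flag for targets on a
different baseline. A minimum shared-gene fraction of 0.5 guards against
silent identifier mismatches; lower overlap requires an explicit override.

### Outcome models

- **AUROC** is always the Mann–Whitney rank statistic (average ranks for
  ties), so it is invariant to monotone transforms of the scores and well
  defined even under perfect separation.
- **Per-timepoint logistic AUROC** fits `died ~ pattern + age + sex`
  in-sample at each timepoint and scores the linear predictor. When the
  unpenalised MLE fails (perfect separation), a lightly ridge-regularised
  fit supplies the scores and the cell is flagged non-converged. Cells
  with fewer than five subjects in either outcome class are flagged
  unreliable.
- **Prognostic vs dynamic**: a pattern is prognostic when its enrolment
  (0 h) AUROC reaches the threshold (default 0.70), dynamic when it
  reaches the threshold only at 48 h or 72 h, otherwise uninformative. The
  threshold parameterises a dichotomy that is qualitative in practice.
- **Random-forest importance**: subjects with known 28-day outcome,
  one row per subject (the enrolment sample by default). For each of
  `n_resplits` stratified 70/30 splits, repeated stratified k-fold CV runs
  on the training portion and Gini importances are averaged over all
  folds, repeats and resplits. Function defaults are the full
  configuration (10 folds × 10 repeats × 10 resplits, 500 trees); the
  end-to-end driver's default config uses 10 × 3 × 10 with 200 trees,
  which preserves the importance ordering at a fraction of the cost —
  the problem sizes used by the shipped driver are a deliberate
  desk-scale choice.
- **Odds ratios** are univariate logistic fits on scaled (mean 0, SD 1,
  ddof = 1) pattern values: OR per 1 SD = exp(β), Wald 95% CI
  exp(β ± 1.96·SE).
- **Differential expression** is a per-gene Welch unequal-variance t-test
  with Benjamini–Hochberg adjustment within the tested gene family. Zero
  variance in both groups yields t = 0, p = 1 when means agree and a
  flagged degenerate p = 0 otherwise.
- **Spearman correlations** use pairwise-complete observations with a
  minimum of five pairs; constant vectors yield missing values.

### Enrichment

All permutation p-values use the add-one estimator `(r + 1)/(n_perm + 1)`,
so p is never zero and its floor is `1/(n_perm + 1)`. When the number of
distinct group assignments is at most `n_perm`, the group-mean test
switches to full enumeration (the observed assignment is then part of the
null, and `p = r/n_total` is exact). The background rank model draws
`set_size` distinct ranks uniformly per iteration per pattern — rejection
sampling in vectorised blocks when the draw is sparse relative to the
gene universe, chunked partial permutations when it is dense (both are
exactly uniform over distinct-rank sets). The two-sample KS test is exact
(network algorithm) for `n·m ≤ 10,000` and asymptotic, tagged as such,
above. Ties in gene statistics receive average ranks; top-N selections
break ties lexicographically on gene identifier.

### Trajectories

Group trajectories are per-(group, timepoint) means over the samples
actually observed; missing cells are omitted, never imputed or
zero-filled. Net displacement is the Euclidean distance between the first
and last *observed* mean coordinates, matching the "net movement" reading
of a trajectory rather than its path length. The recovery index expresses
each sample's signed distance to the healthy mean in healthy-SD units and
regresses it on log(hours + 1) per subject — the log axis because the
collection grid spans 0 to 8,760 hours; raw hours are available as an
option. A negative slope means movement toward the healthy centroid.

## The synthetic cohort generator

The generator emulates the *shape* of a longitudinal sepsis study, not its
biology: 120 sepsis subjects with 28-day outcome counts (63 survived,
54 died, 3 unknown) plus 42 healthy donors by default, sampled on the
canonical grid 0 h, 6 h, 24 h, 48 h, 72 h, 28 d, 6 m, 12 m (internally
0–8,760 hours).

- **Amplitudes** `A_true`: exponential(1) entries with a per-pattern
  sparsity mask (default 70% of genes zeroed per pattern), mimicking the
  sparse structure NMF assumes.
- **Dynamics**: per subject and pattern, survivors follow
  `w(t) = w_healthy + (w_acute − w_healthy)·exp(−t/τ)` (default τ = 48 h);
  non-survivors stay at `w_acute` and contribute no samples after 72 h.
  Subjects with unknown outcome follow survivor dynamics under an
  "unknown" label, so the known-outcome filter has something to remove.
- **Outcome wiring**: *prognostic* patterns shift the non-survivor acute
  mean by `effect_size`·subject-SD (default 1.5 × 0.5); *dynamic* patterns
  separate the groups only through decay-vs-plateau divergence; *null*
  patterns hold every sepsis subject at their acute level regardless of
  outcome or time (keeping them genuinely outcome-free; they consequently
  do not decay in survivors).
- **Missingness**: per-timepoint retention probabilities default to the
  per-timepoint subject fractions a study of this shape reports
  (survivors 60/63 … 14/63; non-survivors 48/54 … 22/54 through 72 h).
- **Noise**: multiplicative log-normal on the TPM scale (default
  σ = 0.2), a Poisson-count mode, or none. Healthy donors contribute one
  enrolment-labelled sample each.

What the generator does *not* emulate — and hence what passing tests do
not demonstrate about real data: library-size and batch effects,
within-subject autocorrelated noise beyond the shared decay curve,
platform differences between projected datasets, gene–gene correlation
beyond the planted low-rank structure, and any real immunology. The decay
form itself is a modelling choice flagged in the generator manifest; real
cohorts only constrain the group means it reproduces.

## The end-to-end driver

`run_pipeline` executes simulate → transform → factorize → classify →
importance → enrich → trajectory, writes every artifact with a manifest
(package and library versions, the global seed and its fixed per-stage
offsets, all parameters) and a log of stage durations, and aborts with
the failing stage's name. The default configuration (2,000 genes, K = 30,
NMF restarts 2 / max_iter 300, the reduced CV settings above) is sized to
run in well under two minutes on a single core; all knobs are exposed in
the flat YAML config, where unknown keys are errors to catch typos.
Writers are bit-deterministic: result tables carry 6 significant digits,
factorization archives full precision.

## Known limitations

- The factorization is a point estimate; restarts probe local optima but
  there are no credible intervals, and K is a config input, never
  inferred.
- The per-timepoint AUROC heatmap is in-sample by design (the held-out
  analysis is the random-forest pipeline); its values are optimistic for
  small timepoint cells and are flagged when class counts fall below 5.
- Greedy cosine matching of recovered to true patterns can understate
  recovery when true patterns are strongly correlated (shared decay
  dynamics make this common in the generator's survivor patterns).
- The exact enumeration fallback of the group-mean permutation test
  triggers only for very small groups; elsewhere p-values are Monte
  Carlo with the usual `1/(n_perm + 1)` resolution floor.
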