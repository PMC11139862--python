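# sepsispatterns

Latent-pattern analysis of longitudinal whole-blood transcriptomes in
sepsis: who recovers, who does not, and which gene-expression programs tell
them apart.

Sepsis is a heterogeneous syndrome: bulk RNA-seq of patient blood collected
repeatedly from enrolment (0 h) through 12 months mixes many immune
programs in every sample. This package implements, as a tested and
reusable pipeline, the analysis style used in longitudinal sepsis cohort
studies:

1. **Factorization.** The log2 TPM matrix `D` (genes × samples) is
   decomposed into non-negative factors, `D ≈ A·P`, where `A` (genes × K)
   gives each gene's amplitude in each of K latent patterns and `P`
   (K × samples) gives each sample's pattern values. The solver is
   L1-penalised multiplicative-update NMF with random restarts, minimising
   `‖D − A·P‖²_F + λ_A·Σ|A| + λ_P·Σ|P|`. A gene-centred PCA (prcomp-style)
   provides the recovery axis.
2. **Projection.** External bulk or single-cell datasets are mapped into
   the learned latent space over shared genes by per-column least squares
   (`min_w ‖d − A_shared·w‖²`, optionally with `w ≥ 0`), so public cohorts
   can be placed on the same pattern axes without renormalisation.
3. **Outcome models.** Pattern values are related to 28-day mortality:
   per-timepoint logistic regression adjusted for age and sex with a
   rank-based AUROC; the prognostic (discriminative at enrolment) vs
   dynamic (discriminative only from 48 h on) dichotomy; random-forest
   Gini importance under repeated stratified 10-fold cross-validation with
   70/30 resplits; additive AUROC over the importance ordering; per-SD
   odds ratios `exp(β)` with Wald 95% CIs; Welch t-tests with
   Benjamini–Hochberg correction; Spearman correlation with clinical
   covariates.
4. **Enrichment.** Permutation tests of cell-type group means for
   projected single-cell values; summed-rank gene-set statistics against a
   background of random rank draws (by default 20 ranks × 10,000 iterations
   per pattern); the exact two-sided two-sample Kolmogorov–Smirnov test.
5. **Trajectories.** Group mean paths through two-pattern space, net
   displacement, per-subject paths, and a recovery index (slope of the
   standardised distance to the healthy-donor centroid against
   log hours).

Because real patient-level cohort data of this kind is access-restricted,
the package ships a first-class synthetic-cohort generator: healthy donors
plus sepsis subjects with known non-negative `A_true`/`P_true`, outcome-
linked temporal dynamics (survivors decay exponentially toward the healthy
mean; non-survivors plateau and contribute no samples after 72 h),
configurable noise, and death/dropout missingness — so every stage is
testable against ground truth.

## Worked example

```python
import sepsispatterns as sp

cfg = sp.SyntheticCohortConfig(n_sepsis_subjects=40, n_healthy=12,
                               outcome_counts=(22, 16, 2), n_genes=400,
                               K_true=4, seed=1)
expr, meta, truth = sp.generate_cohort(cfg)      # 400 genes x 187 samples
D = sp.filter_genes(sp.log_transform(expr))
res = sp.PatternNMF(D, K=4, n_restarts=3, max_iter=1000).fit(seed=1)
print(res.summary())
```

```
Pattern NMF (L1-penalised multiplicative updates)
=================================================
genes: 292   samples: 187   K: 4
lambda_A: 0.0187859   lambda_P: 0.0187859
seed: 1   restarts: 3
iterations (best restart): 520   converged: True
final objective: 2250.71
relative reconstruction error: 0.0930
```

The fit explains the simulated expression to within a 9% relative
Frobenius error under the injected log-normal noise. Classifying the
patterns against 28-day mortality recovers the planted structure:

```python
table = sp.auroc_table(res.P, meta)              # patterns x timepoints AUROC
print(table.round(2).assign(cls=sp.classify_patterns(table, threshold=0.70)))
```

```
             0h    6h   24h   48h   72h         cls
pattern_1  0.75  0.83  0.67  0.63  0.57  prognostic
pattern_2  0.60  0.65  0.78  0.93  1.00     dynamic
pattern_3  0.80  0.94  1.00  1.00  1.00  prognostic
pattern_4  0.64  0.74  0.83  0.90  1.00     dynamic
```

Patterns with AUROC ≥ 0.70 at enrolment are *prognostic*; those crossing
the threshold only from 48 h onward are *dynamic* — mortality information
that emerges as trajectories diverge. Matching recovered pattern rows to
the generator's truth gives cosine similarities of 0.94–0.99.

The same stages are available from the shell:

```sh
sepsispatterns simulate --out cohort/ --seed 1
sepsispatterns factorize --in cohort/expression.tsv --k 30 --seed 1337 --out fact/
sepsispatterns classify-patterns --factorization fact/ --meta cohort/metadata.csv --out auroc.tsv
sepsispatterns run-all --out run/ --seed 1
```

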