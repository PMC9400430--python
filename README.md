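# pairrisk

Rank-based lncRNA-pair prognostic signatures for tumor cohorts.

Many published expression signatures require absolute expression levels,
which makes them fragile across platforms and batches. `pairrisk`
implements the pair-indicator alternative for immune-related long
noncoding RNAs (lncRNAs): for a pair of genes (a, b) a sample is coded

    I_ab(s) = 1  if  x_a(s) > x_b(s),   else 0,

which depends only on the within-sample ordering of the two genes and is
therefore invariant to any monotone per-sample normalization — no batch
correction needed. The pipeline, built for tumor/normal bulk RNA-seq on
the log2(FPKM+1) scale with overall-survival follow-up:

1. **Screen** — lncRNAs coexpressed with immune genes (Pearson r > 0.4,
   p < 0.001 on tumor samples), then differentially expressed tumor vs
   normal (unpaired Wilcoxon rank-sum, Benjamini–Hochberg FDR < 0.01).
2. **Pair** — all k(k−1)/2 ordered-by-listing pairs of the retained
   lncRNAs; pairs whose minority indicator value occurs in ≤ 20% of
   samples are dropped (near-constant pairs cannot predict anything).
3. **Model** — univariate Cox screen (Wald p < 0.01) → lasso-penalized Cox
   over a log-spaced penalty path with 10-fold cross-validated partial-
   likelihood deviance → candidate active sets refit by unpenalized
   multivariate Cox, the 1-year time-dependent AUC picking the winner.
   The risk score of sample s is the exponentiated linear predictor
   `exp(Σ_i β_i · I_i(s))`.
4. **Evaluate** — cumulative/dynamic time-dependent ROC with Kaplan–Meier
   weighting at 1/2/3 years, Youden-index cut-off, high/low risk
   stratification, Kaplan–Meier curves and the log-rank test.
5. **Associate** — risk group vs clinical variables (chi-square/Fisher,
   rank-sum by strata, uni/multivariate Cox independence) and vs immune
   state (Spearman risk–infiltration correlation, checkpoint-gene group
   differences).

A synthetic-cohort generator (`pairrisk.simulate`) reproduces the
statistical structure all of this assumes — differential expression,
lncRNA–immune-gene correlation blocks, pair-driven proportional hazards,
risk-linked infiltration — so the whole pipeline runs and is tested at
desk scale without any data downloads.

## Worked example

```python
import pairrisk as pr

cohort = pr.simulate_cohort(pr.SimScenario(rng_seed=1))
model = pr.PairRiskModel.from_expression(
    cohort["expression"], cohort["annotation"], cohort["clinical"])
results = model.fit()
print(results.summary())
```

prints (abridged):

```
Pair-indicator prognostic Cox model
==============================================================
Samples: 379   Events: 244
Pairs screened: 7526   uniCox p<0.01: 150   selected: 68
...
1-year AUC: 0.814   Youden cut-off: 2.902
High risk: 110   Low risk: 269   log-rank chi2=200.48, p=1.2e-45
```

379 simulated patients; 7,526 pairs survive the minority filter, 150 pass
the univariate screen, and 68 enter the final multivariate model. The
fitted score separates the cohort into 110 high- and 269 low-risk patients
whose survival curves differ far beyond chance (log-rank), and predicts
1-year survival status with AUC 0.81. `results.table` holds the per-pair
coefficient, hazard ratio, 95% CI and Wald p; `results.multi_horizon_roc()`
the 1/2/3-year ROC curves.

The same stages are available as a CLI over TSV files — see
`pairrisk --help` (`simulate`, `screen`, `pair`, `fit`, `stratify`,
`validate`, `clinical`, `immune`, each driven by one YAML config).

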