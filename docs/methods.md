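# Methods

## Model

The core object is a Cox proportional-hazards model whose covariates are
binary gene-pair indicators. For an ordered list of differentially
expressed immune-related lncRNAs g1..gk, every unordered pair (a, b) with a
listed first contributes one covariate per sample,
I_ab(s) = 1{x_a(s) > x_b(s)}, with ties scoring 0 (the rule is strictly
"greater than", so equality falls to the other branch). Because I_ab
depends only on the within-sample ordering of two genes, it is invariant
under any strictly increasing per-sample transform of the expression
values; this is the property that removes the need for cross-platform
normalization or batch correction, and it is asserted directly by the test
suite rather than assumed.

The hazard for sample s is h(t|s) = h0(t) · exp(Σ_i β_i I_i(s)) and the
reported risk score is the exponentiated linear predictor
exp(Σ_i β_i I_i(s)), so a sample with all-zero indicators scores exactly 1.

## Screening thresholds

| parameter | default | meaning |
|---|---|---|
| corr_min | 0.4 | minimum signed Pearson r of a lncRNA with ≥1 immune gene (flag for absolute r) |
| corr_p_max | 0.001 | correlation-test p ceiling |
| de_fdr_max | 0.01 | BH-FDR ceiling for the tumor-vs-normal rank-sum screen |
| unicox_p_max | 0.01 | Wald p ceiling of the univariate Cox pair screen |
| pair_minority_min | 0.20 | minority indicator value must occur in strictly more than this fraction of samples |
| cv_folds | 10 | folds of the cross-validated lasso path |
| roc_horizons | 1, 2, 3 y | evaluation horizons; clinical time declared in days, converted at 365.25 d/y |

Coexpression is computed on tumor samples only by default: the signature
targets tumor biology, and the planted correlation structure of the
generator is defined within-group; a flag pools all samples instead. The
differential-expression test is the unpaired two-sample Wilcoxon rank-sum
(tumor and normal donors are different people, so a paired statistic is
not defined); the exact enumeration null is used when both groups have ≤12
samples with no ties across the pooled values, otherwise the normal
approximation with tie and continuity corrections. BH-FDR is computed
within the immune-related candidate set, matching the screening order.

The minority-frequency filter keeps a pair iff its mean indicator lies
strictly inside (0.20, 0.80). Constant pairs carry no ordering information
and are always dropped; boundary values are excluded (a pair at exactly
20% is removed), and both boundary behaviors are pinned by tests.

## Fitting chain and numerical choices

Univariate and multivariate Cox fits maximize the partial likelihood by
Newton–Raphson with step-halving, tolerance 1e-9 on the coefficient
change, at most 100 iterations. Ties are handled by the Breslow convention
by default — indicator covariates produce heavily tied risk profiles, and
Breslow keeps the batch univariate scan closed-form cheap — with Efron
available behind a flag for sensitivity checks (the Efron fit is
cross-checked against lifelines in the tests). The univariate scan
exploits the binary covariate: risk-set sums reduce to counts, so all
pairs share one sorted pass and a vectorized scalar Newton iteration; a
step clip at ±2 per iteration and a |β| ≤ 30 cap guard the monotone-
likelihood (perfect separation) case, and pairs hitting the cap are
dropped with a warning rather than reported. Wald inference throughout:
se from the inverse observed information, 95% CI as β ± z·se with
z = 1.959964 (the exact 0.975 normal quantile, not 1.96); the reported
HR, CI and p therefore satisfy HR = exp(β) and HR = √(CI_low · CI_high)
identically.

Lasso selection runs scikit-survival's Coxnet over a 50-point log-spaced
penalty path (`alpha_min_ratio` 0.01). The path is scored by 10-fold
cross-validated partial-likelihood deviance in the Verweij–Van
Houwelingen form, folds stratified by event status and fixed by the run
seed. Candidate models are the distinct nonempty active sets at penalties
within one standard error of the best CV deviance; each candidate is
refit by unpenalized multivariate Cox and the candidate whose risk score
has the highest 1-year time-dependent AUC wins (ties: fewer pairs, then
larger penalty). Composing the two criteria this way keeps the CV
deviance as the regularization judge while letting the discrimination
criterion arbitrate among near-equivalent sparsities. The reported
coefficients are always the unpenalized refit — penalized estimates carry
no per-term Wald inference, and the reported table requires CIs and p
values. The univariate p < 0.01 filter binds only at the screening stage;
multivariate p values are reported unfiltered.

## Evaluation

Kaplan–Meier curves use the product-limit estimator; censored-only times
never drop the curve. The two-group log-rank test accumulates observed
minus expected events with the hypergeometric variance (1 df). The
time-dependent ROC at horizon t is the cumulative/dynamic variant with
KM-conditional weighting: with Ŝ the overall KM at t and Ŝ_{>c} the KM
within {score > c},

    Sens(c,t) = [1 − Ŝ_{>c}(t)] · P̂(score>c) / [1 − Ŝ(t)]
    Spec(c,t) = Ŝ_{≤c}(t) · P̂(score≤c) / Ŝ(t).

Cutpoints are the observed unique scores. The raw estimates need not be
monotone in c; they are monotonized by running maxima and the AUC is the
trapezoid over the cutpoint-ordered path from (0,0) to (1,1). With no
censoring before t this reduces exactly to the empirical ROC of the binary
outcome "event by t" (asserted against a brute-force Mann–Whitney
statistic). The nearest-neighbor smoothed variant was deliberately not
implemented: the KM form is parameter-free and exactly testable.

The cut-off maximizes sensitivity + specificity (Youden) on the 1-year ROC
of the training scores, ties resolved toward the smaller cutpoint; samples
exactly at the cut-off are assigned to the low-risk group (strict >).

Association tests: Pearson chi-square without Yates correction, falling
back to Fisher's exact when a 2×2 expected count drops below 5; rank-sum
comparisons of scores across clinical strata (Kruskal–Wallis beyond two
levels); Cox independence models enter the risk on the log scale — the
linear predictor itself — since the score is defined as its exponential;
Spearman correlation for infiltration. Stars encode p < 0.05/0.01/0.001.
Checkpoint-gene comparisons report raw per-test stars, with a BH-adjusted
column alongside for transparency. The age dichotomization for the
chi-square uses the cohort median unless configured.

## Synthetic cohorts

The generator emulates a two-registry design: `n_tumor` = 379 vs
`n_normal` = 88 samples, 300 lncRNAs of which 171 are up- and 7
down-regulated in tumor by 1.5 log2 units, 150 immune genes, and
lncRNA–immune coexpression at population r = 0.6 (each DE lncRNA and half
of the null lncRNAs mix their partner immune gene's latent factor).
Survival is exponential with hazard h0 · exp(Σ β_k I_k) over 7 planted
pairs with coefficient magnitudes 0.37–0.73 (the scale of published pair
signatures), h0 set so an average-risk patient has ~3-year median
survival, and 40% uniform censoring (each censored subject observed at a
uniform fraction of its event time). The two members of each causal pair
share a base mean so the pair indicator is informative (~50/50) rather
than frozen by a mean offset. Age is linked to the linear predictor (≈3
years per SD) to emulate an age–risk association; grade and stage are
drawn independently of risk. Infiltration fractions for six cell types
are strictly increasing functions of the risk rank plus Gaussian noise
(sd 0.05); 12 checkpoint genes shift down and 2 up by 1 log2 unit between
risk halves.

What the generator does **not** model: count-level sequencing noise
(negative-binomial overdispersion on raw counts), batch effects (the pair
transform's invariance is tested via explicit monotone distortions
instead), gene-length/library-size artifacts of FPKM, correlations among
clinical covariates, and informative censoring. Passing tests therefore
demonstrate correctness of the estimators and recoverability of planted
pair-level signal under clean proportional hazards — not robustness to the
full messiness of registry RNA-seq data.

All generators are pure functions of (scenario, seed); the seed is split
into independent expression/survival/infiltration streams so each table is
reproducible in isolation.

## Problem sizes in the tests

Oracle and property tests run on instances of n ≤ 100. Parameter-recovery
studies use 50 replicate cohorts at n_tumor = 400 with 3 planted pairs
(β = 1.2) among ~50 null pairs, 10 null cohorts for the univariate
retention rate, and 20 replicates for the null-AUC calibration; these
sizes give binomial standard errors comfortably inside the asserted
margins. The end-to-end acceptance run uses the full default scenario
(379/88 samples, 178 DE lncRNAs, ~7,500 filtered pairs) and completes in
well under a minute.

## Known limitations

- With many correlated proxy pairs (pairs sharing a causal gene), the
  CV-then-AUC arbitration tends to select supersets of the causal pairs;
  selection is consistent in recall, not sparsity.
- The time-dependent ROC estimator can be non-monotone before
  monotonization at small n; the running-max convention makes the reported
  AUC a deterministic function of the raw estimates but is one of several
  defensible conventions.
- Perfectly separated univariate pair fits are dropped, not reported with
  penalized inference.
- The univariate batch scan is Breslow-only on its fast path; Efron
  requests fall back to per-pair Newton fits.
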