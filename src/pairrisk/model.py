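"""The pair-signature prognostic model.

:class:`PairRiskModel` is the user-facing entry point, in the
model-object/results-object style of statsmodels: construct it from a pair
indicator matrix and a survival table (or straight from expression data via
:meth:`PairRiskModel.from_expression`, which runs the coexpression and
differential-expression screens and the pairing step), call :meth:`fit`,
and get a :class:`PairRiskResults` holding the selected pairs, their
multivariate Cox coefficients with Wald inference, per-sample risk scores,
and evaluation helpers (time-dependent ROC, Youden cut-off stratification,
Kaplan-Meier comparison, log-rank test).

The fitting chain is: univariate Cox screen over all retained pairs (keep
Wald p below a ceiling) -> lasso-penalized Cox over a log-spaced penalty
path with 10-fold cross-validated partial-likelihood deviance -> candidate
active sets within one standard error of the best CV deviance -> each
candidate refit by unpenalized multivariate Cox -> the candidate whose
1-year time-dependent AUC is highest wins (ties: fewer pairs, then smaller
penalty). The reported coefficients are the unpenalized multivariate refit
(penalized fits carry no per-term Wald inference).

The risk score of sample s is exp(sum_i coef_i * indicator_i(s)): the
exponentiated Cox linear predictor, so all-zero indicators give exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .config import PipelineConfig
from .cox import CoxResult, cox_fit, cox_loglik, unicox_scan
from .io import ExpressionMatrix, align_samples
from .pairs import PairIndicatorMatrix, build_pairs, filter_pairs
from .screen import de_gene_ids, differential_expression, immune_coexpression
from .survival_eval import (RiskStratification, TimeROC, km_estimate,
                            logrank_test, stratify, time_dependent_roc,
                            youden_cutoff)

logger = logging.getLogger("pairrisk")


@dataclass
class PairModel:
    """A fitted pair signature: ordered pairs, coefficients, Wald table."""

    pairs: list
    coefs: np.ndarray
    fit_details: pd.DataFrame  # Table-1 schema: Coef, HR, HR.95L, HR.95H, p value
    lambda_path: np.ndarray
    chosen_lambda: float

    def __post_init__(self):
        if len(self.pairs) != len(self.coefs):
            raise ValueError("pairs and coefs length mismatch")


def risk_score(model: PairModel, m: PairIndicatorMatrix) -> pd.Series:
    """exp(sum of coef * indicator) per sample; strictly positive."""
    missing = [p for p in model.pairs if p not in m.indicators.index]
    if missing:
        raise KeyError(f"model pairs missing from indicator matrix: {missing}")
    ind = m.indicators.loc[model.pairs].to_numpy(float)
    lp = model.coefs @ ind
    return pd.Series(np.exp(lp), index=m.indicators.columns, name="risk_score")


def unicox_screen(m: PairIndicatorMatrix, time, event,
                  unicox_p_max: float = 0.01, ties: str = "breslow"):
    """Univariate Cox over every pair; keep Wald p < ceiling.

    Returns ``(retained_table, full_table)``.
    """
    full = unicox_scan(m.indicators, time, event, ties=ties)
    retained = full.loc[full["p value"] < unicox_p_max]
    return retained, full


def _cv_deviance(X, time, event, alphas, folds, seed):
    """Cross-validated partial-likelihood deviance along the alpha path.

    Verweij/Van Houwelingen form: for fold k with coefficients beta_k(a)
    fitted off-fold, the fold deviance is
    -2 [ loglik(all data; beta_k) - loglik(train fold; beta_k) ].
    Folds are stratified by event status so events spread evenly.
    """
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, len(alphas)))
    for k, (tr, _te) in enumerate(skf.split(X, event)):
        est = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas,
                                     fit_baseline_model=False)
        est.fit(X[tr], y[tr])
        coefs = est.coef_  # p x n_fitted_alphas (path may stop early)
        fold_alphas = np.asarray(est.alphas_)
        for j, a in enumerate(alphas):
            beta = coefs[:, int(np.argmin(np.abs(fold_alphas - a)))]
            ll_all = cox_loglik(beta, X, time, event)
            ll_tr = cox_loglik(beta, X[tr], time[tr], event[tr])
            dev[k, j] = -2.0 * (ll_all - ll_tr)
    return dev.mean(axis=0), dev.std(axis=0, ddof=1) / np.sqrt(folds)


def lasso_cox_select(m: PairIndicatorMatrix, time, event,
                     time_years, cv_folds: int = 10, rng_seed: int = 0,
                     ties: str = "breslow", auc_horizon_years: float = 1.0,
                     n_alphas: int = 50) -> PairModel:
    """Select pairs by cross-validated lasso Cox, refit, arbitrate by AUC.

    ``time`` drives the Cox fits (any unit); ``time_years`` drives the
    1-year AUC arbiter. Candidate active sets are the distinct nonempty
    sets along the path whose CV deviance is within one standard error of
    the minimum; each is refit unpenalized and the 1-year AUC of its risk
    score picks the winner.
    """
    if m.n_pairs < 2:
        raise ValueError("lasso selection needs at least 2 retained pairs")
    X = m.indicators.to_numpy(np.float64).T  # samples x pairs
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    path_est = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                      alpha_min_ratio=0.01,
                                      fit_baseline_model=False)
    path_est.fit(X, y)
    alphas = np.asarray(path_est.alphas_)
    coef_path = path_est.coef_  # p x n_alphas
    active_sizes = (coef_path != 0).sum(axis=0)
    if active_sizes.max() == 0:
        raise ValueError("lasso path is all-zero: penalty too large everywhere")

    cv_mean, cv_se = _cv_deviance(X, time, event, list(alphas), cv_folds, rng_seed)
    jbest = int(np.argmin(cv_mean))
    within = cv_mean <= cv_mean[jbest] + cv_se[jbest]

    pair_index = np.asarray(m.pair_ids)
    candidates = {}
    for j in np.where(within & (active_sizes > 0))[0]:
        active = tuple(pair_index[coef_path[:, j] != 0])
        # keep the largest alpha (sparsest fit) producing each distinct set
        if active not in candidates:
            candidates[active] = alphas[j]
    if not candidates:
        # CV window contains only the empty model; fall back to the sparsest
        # nonempty set on the path
        j = int(np.argmax(active_sizes > 0))
        candidates[tuple(pair_index[coef_path[:, j] != 0])] = alphas[j]

    best = None
    for active, alpha in candidates.items():
        sub = m.subset_pairs(list(active))
        refit = cox_fit(sub.indicators.T.astype(float), time, event, ties=ties)
        scores = np.exp(refit.coef.to_numpy() @ sub.indicators.to_numpy(float))
        roc = time_dependent_roc(scores, time_years, event, auc_horizon_years)
        key = (roc.auc, -len(active), -alpha)
        if best is None or key > best[0]:
            best = (key, active, alpha, refit)
    _, active, alpha, refit = best
    logger.info("lasso selected %d pairs at lambda=%.4g (1y AUC=%.3f)",
                len(active), alpha, best[0][0])
    return PairModel(list(active), refit.coef.to_numpy(), refit.table(),
                     alphas, float(alpha))


def multicox_refit(selected_pairs, m: PairIndicatorMatrix, time, event,
                   ties: str = "breslow") -> CoxResult:
    """Unpenalized multivariate Cox on the selected pairs."""
    sub = m.subset_pairs(list(selected_pairs))
    return cox_fit(sub.indicators.T.astype(float), time, event, ties=ties)


class PairRiskModel:
    """Pair-indicator prognostic Cox model, statsmodels-style.

    Parameters
    ----------
    pair_matrix : PairIndicatorMatrix
        Filtered binary pair indicators over tumor samples.
    survival : pandas.DataFrame
        Clinical table indexed by sample id with ``time`` (in the config's
        declared unit) and ``event`` columns; clinical covariates ride
        along for downstream association tests.
    config : PipelineConfig, optional
    """

    def __init__(self, pair_matrix: PairIndicatorMatrix, survival: pd.DataFrame,
                 config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        samples = [s for s in pair_matrix.sample_ids if s in survival.index]
        if len(samples) < pair_matrix.indicators.shape[1]:
            logger.info("dropping %d samples without survival rows",
                        pair_matrix.indicators.shape[1] - len(samples))
        if not samples:
            raise ValueError("no samples shared between pairs and survival table")
        self.pair_matrix = pair_matrix.subset_samples(samples)
        self.survival = survival.loc[samples]
        self.time = self.survival["time"].to_numpy(float)
        self.event = self.survival["event"].to_numpy(int)
        self.time_years = self.config.time_to_years(self.time)
        # populated by from_expression
        self.de_table = None
        self.coexpression_hits = None
        self.immune_related_lncrnas = None

    @classmethod
    def from_expression(cls, expr: ExpressionMatrix, annotation: pd.DataFrame,
                        clinical: pd.DataFrame,
                        config: PipelineConfig | None = None) -> "PairRiskModel":
        """Run the screens and pairing, then build the model.

        Coexpression -> differential expression -> pair construction on
        tumor samples -> minority filter. The intermediate tables are kept
        on the returned model (``de_table``, ``coexpression_hits``).
        """
        config = config or PipelineConfig()
        ids, hits = immune_coexpression(expr, annotation, config)
        if not ids:
            raise ValueError("no immune-related lncRNAs pass the coexpression screen")
        de = differential_expression(expr, ids, config)
        kept = de_gene_ids(de)
        if len(kept) < 2:
            raise ValueError("fewer than 2 differentially expressed "
                             "immune-related lncRNAs")
        tumor = expr.samples_in_group("tumor")
        tumor = [s for s in tumor if s in clinical.index]
        raw_pairs = build_pairs(expr.subset_genes(kept), tumor)
        filtered = filter_pairs(raw_pairs, config.pair_minority_min)
        model = cls(filtered, clinical, config)
        model.de_table = de
        model.coexpression_hits = hits
        model.immune_related_lncrnas = ids
        return model

    def fit(self, rng_seed: int | None = None) -> "PairRiskResults":
        """Run uniCox screen -> lasso selection -> multivariate refit."""
        cfg = self.config
        seed = cfg.rng_seed if rng_seed is None else rng_seed
        retained, full = unicox_screen(self.pair_matrix, self.time, self.event,
                                       cfg.unicox_p_max, cfg.tie_method)
        if len(retained) < 2:
            raise ValueError(
                f"only {len(retained)} pairs pass the univariate screen at "
                f"p<{cfg.unicox_p_max}; cannot run lasso selection")
        sub = self.pair_matrix.subset_pairs(list(retained.index))
        pm = lasso_cox_select(sub, self.time, self.event, self.time_years,
                              cv_folds=cfg.cv_folds, rng_seed=seed,
                              ties=cfg.tie_method)
        scores = risk_score(pm, self.pair_matrix)
        return PairRiskResults(self, pm, retained, full, scores)


class PairRiskResults:
    """Fitted pair signature with evaluation and stratification helpers."""

    def __init__(self, model: PairRiskModel, pair_model: PairModel,
                 unicox_retained: pd.DataFrame, unicox_full: pd.DataFrame,
                 scores: pd.Series):
        self.model = model
        self.pair_model = pair_model
        self.unicox_retained = unicox_retained
        self.unicox_full = unicox_full
        self.risk_scores = scores
        self._cutoff = None

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.pair_model.coefs, index=self.pair_model.pairs,
                         name="coef")

    @property
    def table(self) -> pd.DataFrame:
        """Per-pair Coef, HR, 95% CI and Wald p of the multivariate refit."""
        return self.pair_model.fit_details

    def time_roc(self, horizon_years: float) -> TimeROC:
        return time_dependent_roc(self.risk_scores.to_numpy(),
                                  self.model.time_years, self.model.event,
                                  horizon_years)

    def multi_horizon_roc(self, horizons=None) -> dict:
        horizons = horizons or self.model.config.roc_horizons
        return {h: self.time_roc(h) for h in horizons}

    @property
    def cutoff(self) -> float:
        """Youden cut-off on the 1-year ROC of the fitted risk score."""
        if self._cutoff is None:
            self._cutoff = youden_cutoff(self.time_roc(1.0))
        return self._cutoff

    def stratification(self, cutoff: float | None = None) -> RiskStratification:
        return stratify(self.risk_scores, self.cutoff if cutoff is None else cutoff)

    def km_by_group(self, strat: RiskStratification | None = None) -> dict:
        strat = strat or self.stratification()
        out = {}
        for label in ("high", "low"):
            sel = (strat.assignments == label).to_numpy()
            out[label] = km_estimate(self.model.time_years[sel],
                                     self.model.event[sel])
        return out

    def logrank(self, strat: RiskStratification | None = None):
        strat = strat or self.stratification()
        return logrank_test(self.model.time_years, self.model.event,
                            strat.assignments.to_numpy())

    def predict(self, pair_matrix: PairIndicatorMatrix) -> pd.Series:
        """Risk scores for new samples sharing the model's pairs."""
        return risk_score(self.pair_model, pair_matrix)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Pair-indicator prognostic Cox model",
            "=" * 62,
            f"Samples: {len(self.risk_scores)}   Events: {int(self.model.event.sum())}",
            f"Pairs screened: {len(self.unicox_full)}   "
            f"uniCox p<{cfg.unicox_p_max}: {len(self.unicox_retained)}   "
            f"selected: {len(self.pair_model.pairs)}",
            f"Chosen lasso penalty: {self.pair_model.chosen_lambda:.5g}",
            "",
            self.table.to_string(float_format=lambda v: f"{v:.6g}"),
            "",
        ]
        try:
            roc1 = self.time_roc(1.0)
            strat = self.stratification()
            lr = self.logrank(strat)
            lines += [
                f"1-year AUC: {roc1.auc:.3f}   Youden cut-off: {self.cutoff:.3f}",
                f"High risk: {strat.n_high}   Low risk: {strat.n_low}   "
                f"log-rank chi2={lr.chi2:.2f}, p={lr.p:.3g}",
            ]
        except ValueError:
            lines.append("(1-year evaluation unavailable: no events before horizon)")
        return "\n".join(lines)
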