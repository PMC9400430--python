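import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pairrisk import (chisq_group_vs_clinical, cox_independence,
                      group_difference_tests, immune_correlation,
                      riskscore_by_stratum, stars)
from pairrisk.survival_eval import RiskStratification
from pairrisk.simulate import SimScenario, simulate_infiltration


def strat_for(assignments):
    s = pd.Series(assignments)
    return RiskStratification(np.nan, s, int((s == "high").sum()),
                              int((s == "low").sum()))


class TestStars:
    @pytest.mark.parametrize("p,expected", [
        (0.2, ""), (0.05, ""), (0.049, "*"), (0.01, "*"), (0.009, "**"),
        (0.001, "**"), (0.0009, "***"), (0.0, "***"), (np.nan, ""),
    ])
    def test_thresholds(self, p, expected):
        assert stars(p) == expected


class TestChiSquare:
    def test_identical_distributions_give_zero(self):
        assign = {f"s{i}": "high" for i in range(10)}
        assign.update({f"t{i}": "low" for i in range(10)})
        clinical = pd.DataFrame(
            {"grade": [1] * 5 + [2] * 5 + [1] * 5 + [2] * 5},
            index=list(assign))
        res = chisq_group_vs_clinical(strat_for(assign), clinical, "grade")
        assert res["statistic"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_diagonal_table_statistic_is_n(self):
        # [[10,0],[0,10]]: sum (O-E)^2/E = 20 without correction
        assign = {f"s{i}": "high" for i in range(10)}
        assign.update({f"t{i}": "low" for i in range(10)})
        clinical = pd.DataFrame({"grade": [1] * 10 + [2] * 10},
                                index=list(assign))
        res = chisq_group_vs_clinical(strat_for(assign), clinical, "grade")
        assert res["statistic"] == pytest.approx(20.0)

    def test_bruteforce_pearson_statistic(self):
        rng = np.random.default_rng(0)
        assign = {f"s{i}": ("high" if rng.random() < 0.5 else "low")
                  for i in range(60)}
        clinical = pd.DataFrame({"stage": rng.integers(1, 4, 60)},
                                index=list(assign))
        res = chisq_group_vs_clinical(strat_for(assign), clinical, "stage")
        table = pd.crosstab(pd.Series(assign),
                            clinical["stage"].astype("Int64").astype(str))
        obs = table.to_numpy(float)
        exp = (obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True)
               / obs.sum())
        assert res["statistic"] == pytest.approx(((obs - exp) ** 2 / exp).sum())

    def test_fisher_fallback_matches_hypergeometric_enumeration(self):
        assign = {f"s{i}": "high" for i in range(4)}
        assign.update({f"t{i}": "low" for i in range(4)})
        clinical = pd.DataFrame({"grade": [1, 1, 1, 2, 2, 2, 2, 2]},
                                index=list(assign))
        res = chisq_group_vs_clinical(strat_for(assign), clinical, "grade")
        assert res["test"] == "fisher_exact"
        # enumerate all tables with these margins: row 4/4, col 3/5
        obs = np.array([[3, 1], [0, 4]])
        pmf_obs = stats.hypergeom.pmf(obs[0, 0], 8, 3, 4)
        p_exact = sum(stats.hypergeom.pmf(a, 8, 3, 4)
                      for a in range(0, 4)
                      if stats.hypergeom.pmf(a, 8, 3, 4) <= pmf_obs + 1e-12)
        assert res["p"] == pytest.approx(p_exact, rel=1e-9)


class TestRiskByStratum:
    def test_identical_multisets_give_p_one(self):
        scores = pd.Series([1.0, 2, 3, 3, 2, 1],
                           index=[f"s{i}" for i in range(6)])
        clinical = pd.DataFrame({"grade": [1, 1, 1, 2, 2, 2]},
                                index=scores.index)
        res = riskscore_by_stratum(scores, clinical, "grade")
        assert res["p"] == pytest.approx(1.0)

    def test_separated_strata_exact_p(self):
        scores = pd.Series([1.0, 2, 3, 4, 5, 6],
                           index=[f"s{i}" for i in range(6)])
        clinical = pd.DataFrame({"grade": [1, 1, 1, 2, 2, 2]},
                                index=scores.index)
        res = riskscore_by_stratum(scores, clinical, "grade")
        assert res["p"] == pytest.approx(0.1)
        assert res["effect"] == pytest.approx(3.0)

    def test_single_stratum_is_an_error(self):
        scores = pd.Series([1.0, 2.0], index=["a", "b"])
        clinical = pd.DataFrame({"grade": [1, 1]}, index=["a", "b"])
        with pytest.raises(ValueError, match="grade"):
            riskscore_by_stratum(scores, clinical, "grade")


class TestCoxIndependence:
    @staticmethod
    def planted(rng, n=250, link=1.0):
        lp = rng.normal(0, 1, n)
        time = rng.exponential(1.0 / (0.02 * np.exp(link * lp)))
        event = (rng.random(n) > 0.3).astype(int)
        idx = [f"s{i}" for i in range(n)]
        clinical = pd.DataFrame({
            "time": time, "event": event,
            "age": rng.normal(60, 10, n),
            "grade": rng.integers(1, 4, n),
            "stage": rng.integers(1, 5, n)}, index=idx)
        scores = pd.Series(np.exp(lp), index=idx)
        return scores, clinical

    def test_constant_covariates_reduce_to_univariate(self):
        rng = np.random.default_rng(0)
        scores, clinical = self.planted(rng)
        clinical["age"] = 60.0
        clinical["grade"] = 2
        clinical["stage"] = 3
        table = cox_independence(scores, clinical)
        uni = table.query("model == 'univariate' and term == 'risk'")
        multi = table.query("model == 'multivariate' and term == 'risk'")
        assert multi["coef"].iloc[0] == pytest.approx(uni["coef"].iloc[0],
                                                      abs=1e-8)

    def test_planted_risk_survives_adjustment(self):
        hits = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            scores, clinical = self.planted(rng)
            table = cox_independence(scores, clinical)
            p = table.query("model == 'multivariate' and term == 'risk'")[
                "p"].iloc[0]
            hits += int(p < 0.001)
        assert hits >= 9

    def test_collinear_covariates_are_an_error(self):
        rng = np.random.default_rng(1)
        scores, clinical = self.planted(rng)
        clinical["stage"] = clinical["grade"]
        with pytest.raises(ValueError, match="collinear"):
            cox_independence(scores, clinical)


class TestImmuneCorrelation:
    def test_perfect_monotone_gives_rho_one(self):
        scores = pd.Series(np.arange(1.0, 21.0),
                           index=[f"s{i}" for i in range(20)])
        infil = pd.DataFrame([scores.rank().to_numpy()],
                             index=["t_cell"], columns=scores.index)
        res = immune_correlation(scores, infil)
        assert res.loc[0, "statistic"] == pytest.approx(1.0)
        assert bool(res.loc[0, "significant"])

    def test_constant_fraction_flagged_excluded(self):
        scores = pd.Series(np.arange(10.0), index=[f"s{i}" for i in range(10)])
        infil = pd.DataFrame([np.full(10, 0.2)], index=["mast_cell"],
                             columns=scores.index)
        res = immune_correlation(scores, infil)
        assert np.isnan(res.loc[0, "p"])
        assert not bool(res.loc[0, "significant"])

    def test_independent_fractions_small_rho(self):
        rhos = []
        for rep in range(10):
            rng = np.random.default_rng(rep)
            n = 374
            scores = pd.Series(rng.uniform(0, 5, n),
                               index=[f"s{i}" for i in range(n)])
            infil = pd.DataFrame([rng.uniform(0, 1, n)], index=["x"],
                                 columns=scores.index)
            rhos.append(immune_correlation(scores, infil).loc[0, "statistic"])
        assert np.mean(np.abs(rhos)) < 0.1

    def test_spearman_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        n = 50
        scores = pd.Series(rng.uniform(0.1, 5, n),
                           index=[f"s{i}" for i in range(n)])
        frac = rng.uniform(0, 1, n)
        infil = pd.DataFrame([frac], index=["x"], columns=scores.index)
        r1 = immune_correlation(scores, infil).loc[0, "statistic"]
        r2 = immune_correlation(np.exp(scores), infil).loc[0, "statistic"]
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestGroupDifferences:
    def test_identical_groups_no_stars(self):
        cols = [f"s{i}" for i in range(8)]
        assign = dict(zip(cols, ["high"] * 4 + ["low"] * 4))
        values = pd.DataFrame([[1.0, 2, 3, 4, 1, 2, 3, 4]], index=["g"],
                              columns=cols)
        res = group_difference_tests(values, strat_for(assign))
        assert (res["stars"] == "").all()

    def test_planted_checkpoint_shift_direction_recovered(self):
        s = SimScenario(rng_seed=5)
        rng = np.random.default_rng(5)
        n = 374
        risk = pd.Series(rng.uniform(0.5, 4.0, n),
                         index=[f"s{i}" for i in range(n)])
        _, checkpoint = simulate_infiltration(risk, s)
        assign = pd.Series(np.where(risk > risk.median(), "high", "low"),
                           index=risk.index)
        res = group_difference_tests(checkpoint, strat_for(assign.to_dict()))
        res = res.set_index("variable")
        down = [g for g in checkpoint.index
                if g not in ("CD276", "TNFRSF25")]
        frac = np.mean([res.loc[g, "direction"] == "lower_in_high"
                        for g in down])
        assert frac >= 0.95
        assert res.loc["CD276", "direction"] == "higher_in_high"

    def test_single_expressing_sample_flagged(self):
        cols = [f"s{i}" for i in range(6)]
        assign = dict(zip(cols, ["high"] * 3 + ["low"] * 3))
        values = pd.DataFrame([[0.0, 0, 0, 2.5, 0, 0]], index=["g"],
                              columns=cols)
        res = group_difference_tests(values, strat_for(assign))
        assert bool(res.loc[0, "low_information"])
        assert 0 <= res.loc[0, "p"] <= 1

    def test_missing_group_is_an_error(self):
        cols = ["s0", "s1"]
        values = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=cols)
        with pytest.raises(ValueError, match="both risk groups"):
            group_difference_tests(values, strat_for({"s0": "high",
                                                      "s1": "high"}))
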