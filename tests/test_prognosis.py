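"""Cox screening, stepwise selection, risk scores, KM and tdROC."""

import numpy as np
import pandas as pd
import pytest

from pagicross.config import SimConfig
from pagicross.io import DataError
from pagicross import prognosis as pg
from pagicross import synthio

from conftest import cox_newton_oracle


def surv_frame(time, event, **extra):
    n = len(time)
    idx = pd.Index([f"s{i}" for i in range(n)], name="sample")
    df = pd.DataFrame({"time_years": time, "event": event}, index=idx)
    for k, v in extra.items():
        df[k] = v
    return df


@pytest.fixture(scope="module")
def survival_sim():
    """A cohort large enough for stable Cox fits (planted coefficients)."""
    cfg = SimConfig(n_genes=300, n_lnc=40, n_pathways=4, n_dysregulated=2,
                    pathway_size_range=(40, 60), n_case=150, n_control=20,
                    n_modules=1, module_size=60, seed=31)
    pc = synthio.simulate_pathways(cfg)
    mrna, _, truth = synthio.simulate_counts(cfg, pc)
    surv = synthio.simulate_survival(cfg, mrna, truth)
    case = list(surv.index)
    expr = pd.DataFrame(np.log2(mrna.counts[case].to_numpy() + 1.0),
                        index=mrna.counts.index, columns=case)
    z = pg.standardize_expression(expr, case)
    return z, surv, truth


class TestUnivariateCox:
    def test_matches_newton_oracle_on_hand_dataset(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        event = np.ones(10, dtype=int)
        x = np.array([0.5, -1.2, 0.3, 2.0, -0.7, 1.1, 0.0, -1.5, 0.8, -0.2])
        expr = pd.DataFrame([x], index=["g"],
                            columns=[f"s{i}" for i in range(10)])
        surv = surv_frame(time, event)
        out = pg.univariate_cox(expr, surv, p_cut=0.5)
        beta_oracle = cox_newton_oracle(x, time, event)
        assert out.loc["g", "coef"] == pytest.approx(beta_oracle, abs=1e-6)
        assert out.loc["g", "HR"] == pytest.approx(np.exp(beta_oracle),
                                                   rel=1e-6)

    def test_constant_gene_dropped(self, caplog):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            {"g_ok": rng.normal(size=20), "g_const": 1.0}).T
        expr.columns = [f"s{i}" for i in range(20)]
        surv = surv_frame(rng.exponential(5, 20),
                          rng.integers(0, 2, 20) | 1)
        with caplog.at_level("WARNING"):
            out = pg.univariate_cox(expr, surv)
        assert "g_const" not in out.index
        assert "g_ok" in out.index

    def test_planted_gene_passes_screen(self, survival_sim):
        z, surv, truth = survival_sim
        genes = list(truth.prognostic_genes)
        out = pg.univariate_cox(z.loc[genes], surv, p_cut=0.01)
        assert out["keep"].all()
        assert (out["coef"] < 0).all()  # protective

    def test_too_few_events_rejected(self):
        surv = surv_frame([1, 2, 3, 4], [1, 1, 0, 0])
        expr = pd.DataFrame([[0.1, 0.2, 0.3, 0.4]], index=["g"],
                            columns=surv.index)
        with pytest.raises(DataError, match="events"):
            pg.univariate_cox(expr, surv)


class TestStepwiseCox:
    def test_single_informative_gene_is_noop(self, survival_sim):
        z, surv, truth = survival_sim
        gene = list(truth.prognostic_genes)[0]
        model = pg.stepwise_cox(z.loc[[gene]], surv)
        assert model.genes == [gene]
        assert model.coefficients[gene] < 0

    def test_pure_noise_gene_eliminated_with_informative_kept(self, survival_sim):
        z, surv, truth = survival_sim
        genes = list(truth.prognostic_genes)
        rng = np.random.default_rng(1)
        noise = pd.DataFrame(rng.normal(size=(1, z.shape[1])),
                             index=["noise"], columns=z.columns)
        stacked = pd.concat([z.loc[genes], noise])
        model = pg.stepwise_cox(stacked, surv)
        assert set(genes) <= set(model.genes)

    def test_planted_coefficients_recovered(self, survival_sim):
        z, surv, truth = survival_sim
        genes = list(truth.prognostic_genes)
        rng = np.random.default_rng(2)
        noise = pd.DataFrame(rng.normal(size=(8, z.shape[1])),
                             index=[f"n{i}" for i in range(8)],
                             columns=z.columns)
        model = pg.stepwise_cox(pd.concat([z.loc[genes], noise]), surv)
        assert set(genes) <= set(model.genes)
        err = np.mean([abs(model.coefficients[g] - truth.prognostic_genes[g])
                       for g in genes])
        assert err < 0.35  # n=150 cases; tighter bounds need larger cohorts

    def test_train_rows_only_determine_model(self, survival_sim):
        z, surv, truth = survival_sim
        genes = list(truth.prognostic_genes)
        train = list(surv.index[:100])
        m1 = pg.stepwise_cox(z.loc[genes], surv, train_samples=train)
        z2 = z.copy()
        z2.loc[:, surv.index[100:]] *= 5.0  # perturb test columns only
        m2 = pg.stepwise_cox(z2.loc[genes], surv, train_samples=train)
        assert m1.genes == m2.genes
        pd.testing.assert_series_equal(m1.coefficients, m2.coefficients)


class TestRiskSplit:
    def model(self, coefs, cutoff=0.0):
        genes = list(coefs)
        return pg.RiskModel(genes, pd.Series(coefs), aic=0.0,
                            train_median_cutoff=cutoff)

    def test_score_arithmetic(self):
        model = self.model({"CD40_like": -1.13, "SMAD7_like": -1.41})
        expr = pd.DataFrame({"s1": [1.0, 1.0]},
                            index=["CD40_like", "SMAD7_like"])
        assert model.risk_score(expr)["s1"] == pytest.approx(-2.54)

    def test_even_train_set_splits_in_halves(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=82)
        expr = pd.DataFrame([scores], index=["g"],
                            columns=[f"s{i}" for i in range(82)])
        model = self.model({"g": 1.0}, cutoff=float(np.median(scores)))
        surv = surv_frame(np.ones(82), np.ones(82, dtype=int))
        out = pg.risk_split(model, expr, surv)
        assert (out["risk_class"] == "high").sum() == 41
        assert (out["risk_class"] == "low").sum() == 41

    def test_all_equal_scores_all_low(self, caplog):
        expr = pd.DataFrame([[2.0] * 6], index=["g"],
                            columns=[f"s{i}" for i in range(6)])
        model = self.model({"g": 1.0}, cutoff=2.0)
        surv = surv_frame(np.ones(6), np.ones(6, dtype=int))
        with caplog.at_level("WARNING"):
            out = pg.risk_split(model, expr, surv)
        assert (out["risk_class"] == "low").all()

    def test_missing_gene_raises(self):
        model = self.model({"absent": 1.0})
        expr = pd.DataFrame([[1.0]], index=["g"], columns=["s1"])
        with pytest.raises(DataError, match="absent"):
            model.risk_score(expr)


class TestKmLogrank:
    def test_no_events_reported_na(self):
        surv = surv_frame([1, 2, 3, 4], [0, 0, 0, 0])
        classes = pd.Series(["high", "high", "low", "low"],
                            index=surv.index)
        out = pg.km_logrank(surv, classes)
        assert np.isnan(out["p"])
        for curve in out["curves"].values():
            assert (curve.to_numpy() == 1.0).all()

    def test_identical_groups_statistic_zero(self):
        time = [1, 2, 3, 4, 1, 2, 3, 4]
        event = [1, 0, 1, 0, 1, 0, 1, 0]
        surv = surv_frame(time, event)
        classes = pd.Series(["high"] * 4 + ["low"] * 4, index=surv.index)
        out = pg.km_logrank(surv, classes)
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)
        assert out["p"] == pytest.approx(1.0)

    def test_km_drop_after_first_death(self):
        surv = surv_frame([1, 2, 3, 4, 5], [1, 0, 0, 0, 0])
        classes = pd.Series(["high"] * 5, index=surv.index)
        from lifelines import KaplanMeierFitter
        km = KaplanMeierFitter()
        km.fit(surv["time_years"], surv["event"])
        assert km.survival_function_.loc[1.0].iloc[0] == pytest.approx(
            1 - 1 / 5)

    def test_empty_class_raises(self):
        surv = surv_frame([1, 2], [1, 1])
        classes = pd.Series(["high", "high"], index=surv.index)
        with pytest.raises(DataError):
            pg.km_logrank(surv, classes)


class TestIndependentPrognostic:
    def test_hr_identity_and_protective_sign(self, survival_sim):
        z, surv, truth = survival_sim
        genes = list(truth.prognostic_genes)
        coefs = pd.Series(truth.prognostic_genes)
        score = pd.Series(coefs.to_numpy() @ z.loc[genes].to_numpy(),
                          index=z.columns)
        out = pg.independent_prognostic(surv, score)
        np.testing.assert_allclose(out["HR"], np.exp(out["coef"]), rtol=1e-9)
        # the score aggregates hazard: higher score -> higher risk (HR > 1)
        assert out.loc["riskScore", "HR"] > 1.0
        assert out.loc["riskScore", "p"] < 0.01


class TestTimeDependentAuc:
    def test_perfect_separation_gives_auc_one(self):
        # events exactly for the top half of the score, no censoring
        time = np.array([1, 1.5, 2, 2.5, 9, 9.5, 10, 10.5])
        event = np.array([1, 1, 1, 1, 1, 1, 1, 1])
        score = pd.Series([5, 6, 7, 8, 1, 2, 3, 4],
                          index=[f"s{i}" for i in range(8)], dtype=float)
        surv = surv_frame(time, event)
        auc = pg.time_dependent_auc(surv, surv, score, [3.0])
        assert auc.loc[3.0] == pytest.approx(1.0)

    def test_planted_signal_discriminates(self, survival_sim):
        z, surv, truth = survival_sim
        genes = list(truth.prognostic_genes)
        coefs = pd.Series(truth.prognostic_genes)
        score = pd.Series(coefs.to_numpy() @ z.loc[genes].to_numpy(),
                          index=z.columns)
        auc = pg.time_dependent_auc(surv, surv, score, [5.0])
        assert auc.loc[5.0] > 0.7

    def test_multi_index_table_contains_all_indices(self, survival_sim):
        z, surv, truth = survival_sim
        genes = list(truth.prognostic_genes)
        coefs = pd.Series(truth.prognostic_genes)
        score = pd.Series(coefs.to_numpy() @ z.loc[genes].to_numpy(),
                          index=z.columns)
        table = pg.multi_index_auc(surv, surv, score, 5.0)
        assert set(table.index) == {"riskScore", "braaksc", "ceradsc",
                                    "dcfdx_lv"}
        assert table["riskScore"] >= table[["braaksc", "ceradsc",
                                            "dcfdx_lv"]].max() - 0.15
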