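"""Prognostic risk modelling: Cox screen, stepwise AIC, risk score, KM, tdROC.

The model is a multivariate Cox proportional-hazards fit over module genes
that survive a univariate screen (p < 0.01), reduced by backward stepwise
elimination to the lowest-AIC subset. The per-sample risk score is
``sum_k coef_k * x_k`` over the signature genes; samples split into
high/low risk at the training-median score, and discrimination is measured
with the IPCW cumulative/dynamic time-dependent AUC.

Partial-likelihood fitting is delegated to lifelines; event times here are
continuous so tie-handling conventions coincide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .io import DataError

logger = logging.getLogger(__name__)

MIN_EVENTS = 10


@dataclass
class RiskModel:
    """Fitted prognostic signature: genes, coefficients, AIC, train cutoff."""

    genes: list[str]
    coefficients: pd.Series
    aic: float
    train_median_cutoff: float

    def risk_score(self, expr: pd.DataFrame) -> pd.Series:
        """riskScore = sum_k coef(k) * x(k) for each sample (expr column)."""
        missing = [g for g in self.genes if g not in expr.index]
        if missing:
            raise DataError(f"model genes absent from expression: {missing}")
        x = expr.loc[self.genes].to_numpy(dtype=float)
        return pd.Series(self.coefficients.to_numpy() @ x,
                         index=expr.columns, name="riskScore")

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "coef": self.coefficients,
            "HR": np.exp(self.coefficients),
        }).rename_axis(index="gene")

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "coefficients": {g: float(c)
                             for g, c in self.coefficients.items()},
            "aic": float(self.aic),
            "train_median_cutoff": float(self.train_median_cutoff),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RiskModel":
        coefs = pd.Series(d["coefficients"], dtype=float)[d["genes"]]
        return cls(list(d["genes"]), coefs, float(d["aic"]),
                   float(d["train_median_cutoff"]))


def standardize_expression(expr: pd.DataFrame,
                           train_samples) -> pd.DataFrame:
    """Per-gene z-scoring with mean/sd taken from the training columns only."""
    train = expr[list(train_samples)].to_numpy(dtype=float)
    mean = train.mean(axis=1)
    sd = train.std(axis=1)
    sd[sd == 0] = 1.0
    z = (expr.to_numpy(dtype=float) - mean[:, None]) / sd[:, None]
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def _cox_frame(expr: pd.DataFrame, surv: pd.DataFrame,
               genes: list[str]) -> pd.DataFrame:
    samples = [s for s in surv.index if s in expr.columns]
    df = expr.loc[genes, samples].T.copy()
    df["time"] = surv.loc[samples, "time_years"].to_numpy(dtype=float)
    df["event"] = surv.loc[samples, "event"].to_numpy(dtype=int)
    return df


def _check_events(surv: pd.DataFrame) -> None:
    if int(surv["event"].sum()) < MIN_EVENTS:
        raise DataError(f"need at least {MIN_EVENTS} events")


def univariate_cox(expr: pd.DataFrame, surv: pd.DataFrame,
                   p_cut: float = 0.01) -> pd.DataFrame:
    """Single-gene proportional-hazards screen with Wald p-values.

    Constant and non-converging genes are dropped with a warning. Returns a
    table of coef, HR, p and the keep flag (p < ``p_cut``).
    """
    _check_events(surv)
    rows = []
    for gene in expr.index:
        df = _cox_frame(expr, surv, [gene])
        if df[gene].std() == 0:
            logger.warning("gene %s constant: dropped from Cox screen", gene)
            continue
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except (ConvergenceError, ValueError) as exc:
            logger.warning("gene %s failed to converge (%s): dropped",
                           gene, exc)
            continue
        rows.append({
            "gene": gene,
            "coef": float(cph.params_[gene]),
            "HR": float(np.exp(cph.params_[gene])),
            "p": float(cph.summary.loc[gene, "p"]),
        })
    out = pd.DataFrame(rows, columns=["gene", "coef", "HR", "p"]).set_index("gene")
    out["keep"] = out["p"] < p_cut
    return out


def _null_log_partial_likelihood(time: np.ndarray, event: np.ndarray) -> float:
    """Breslow log partial likelihood of the covariate-free model."""
    order = np.argsort(time)
    time, event = time[order], event[order]
    n = len(time)
    ll = 0.0
    for i in range(n):
        if event[i]:
            at_risk = np.sum(time >= time[i])
            ll -= np.log(at_risk)
    return float(ll)


def _fit_multivariate(df: pd.DataFrame, genes: list[str]):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph = CoxPHFitter()
            cph.fit(df[genes + ["time", "event"]], duration_col="time",
                    event_col="event")
        except ConvergenceError:
            # near-collinear covariates: stabilise with a light ridge
            logger.warning("multivariate Cox near-singular for %d genes; "
                           "refitting with a small L2 penalty", len(genes))
            cph = CoxPHFitter(penalizer=0.01, l1_ratio=0.0)
            cph.fit(df[genes + ["time", "event"]], duration_col="time",
                    event_col="event")
    return cph


def stepwise_cox(expr: pd.DataFrame, surv: pd.DataFrame,
                 train_samples=None) -> RiskModel:
    """Backward stepwise multivariate Cox by lowest AIC.

    Starts from the full model over the supplied genes and repeatedly
    removes the single covariate whose removal lowers AIC most (the empty
    model counts as a candidate endpoint) until no removal helps. AIC =
    -2 logPL + 2 (#covariates). The training-median risk score becomes the
    classification cutoff.
    """
    genes = list(expr.index)
    if not genes:
        raise DataError("no genes supplied to stepwise_cox")
    if train_samples is None:
        train_samples = [s for s in surv.index if s in expr.columns]
    surv_train = surv.loc[[s for s in train_samples if s in surv.index]]
    _check_events(surv_train)
    df = _cox_frame(expr, surv_train, genes)

    current = list(genes)
    try:
        cph = _fit_multivariate(df, current)
    except (ConvergenceError, ValueError) as exc:
        raise DataError(f"full multivariate Cox fit failed: {exc}") from exc
    aic = -2.0 * cph.log_likelihood_ + 2.0 * len(current)
    null_aic = -2.0 * _null_log_partial_likelihood(
        df["time"].to_numpy(), df["event"].to_numpy())

    while current:
        best_drop, best_aic, best_fit = None, aic, cph
        for gene in current:
            remaining = [g for g in current if g != gene]
            if remaining:
                try:
                    cand = _fit_multivariate(df, remaining)
                except (ConvergenceError, ValueError):
                    continue
                cand_aic = -2.0 * cand.log_likelihood_ + 2.0 * len(remaining)
            else:
                cand, cand_aic = None, null_aic
            if cand_aic < best_aic:
                best_drop, best_aic, best_fit = gene, cand_aic, cand
        if best_drop is None:
            break
        assert best_aic < aic  # accepted steps strictly lower AIC
        current = [g for g in current if g != best_drop]
        aic, cph = best_aic, best_fit

    if not current:
        raise DataError("stepwise elimination removed every gene; relax the "
                        "univariate screen threshold")
    coefs = pd.Series({g: float(cph.params_[g]) for g in current})
    scores = coefs.to_numpy() @ expr.loc[current,
                                         surv_train.index].to_numpy(dtype=float)
    cutoff = float(np.median(scores))
    return RiskModel(current, coefs, float(aic), cutoff)


def risk_split(model: RiskModel, expr: pd.DataFrame,
               surv: pd.DataFrame) -> pd.DataFrame:
    """Score every survival sample and classify against the train cutoff.

    High risk means score strictly above the training-median cutoff, so an
    even training set with distinct scores splits exactly in half; all-equal
    scores land entirely in the low-risk class (with a warning).
    """
    samples = [s for s in surv.index if s in expr.columns]
    scores = model.risk_score(expr[samples])
    if scores.nunique() == 1:
        logger.warning("all risk scores identical: every sample low-risk")
    cls = np.where(scores > model.train_median_cutoff, "high", "low")
    out = pd.DataFrame({"riskScore": scores, "risk_class": cls},
                       index=scores.index)
    if "split" in surv.columns:
        out["split"] = surv.loc[out.index, "split"]
    return out


def km_logrank(surv: pd.DataFrame, classes: pd.Series) -> dict:
    """Product-limit curves per risk class plus the two-group log-rank test.

    With no events anywhere both curves are identically 1 and the test is
    reported as NA.
    """
    levels = sorted(classes.unique())
    if len(levels) != 2:
        raise DataError(f"need exactly 2 risk classes, got {levels}")
    curves = {}
    for lev in levels:
        idx = classes.index[classes == lev]
        if len(idx) == 0:
            raise DataError(f"risk class {lev} has no samples")
        km = KaplanMeierFitter()
        km.fit(surv.loc[idx, "time_years"], surv.loc[idx, "event"],
               label=str(lev))
        curves[lev] = km.survival_function_
    if surv.loc[classes.index, "event"].sum() == 0:
        return {"curves": curves, "statistic": float("nan"),
                "p": float("nan")}
    a, b = levels
    ia, ib = classes.index[classes == a], classes.index[classes == b]
    res = logrank_test(
        surv.loc[ia, "time_years"], surv.loc[ib, "time_years"],
        surv.loc[ia, "event"], surv.loc[ib, "event"])
    return {"curves": curves, "statistic": float(res.test_statistic),
            "p": float(res.p_value)}


def independent_prognostic(surv: pd.DataFrame, scores: pd.Series,
                           covariates=("braaksc", "ceradsc", "dcfdx_lv")
                           ) -> pd.DataFrame:
    """One multivariate Cox fit of risk score plus clinical covariates.

    Returns forest-plot quantities: HR = exp(coef), Wald 95% CI and p per
    covariate.
    """
    _check_events(surv)
    samples = [s for s in surv.index if s in scores.index]
    df = pd.DataFrame({"riskScore": scores.loc[samples]})
    for c in covariates:
        df[c] = surv.loc[samples, c].to_numpy(dtype=float)
    df["time"] = surv.loc[samples, "time_years"].to_numpy(dtype=float)
    df["event"] = surv.loc[samples, "event"].to_numpy(dtype=int)
    const = [c for c in df.columns[:-2] if df[c].std() == 0]
    if const:
        logger.warning("constant covariates dropped: %s", const)
        df = df.drop(columns=const)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError) as exc:
        raise DataError(f"multivariate prognostic fit failed: {exc}") from exc
    s = cph.summary
    out = pd.DataFrame({
        "coef": s["coef"],
        "HR": s["exp(coef)"],
        "HR_lower_95": s["exp(coef) lower 95%"],
        "HR_upper_95": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    out.index.name = "covariate"
    return out


def _surv_array(surv: pd.DataFrame):
    return Surv.from_arrays(event=surv["event"].astype(bool),
                            time=surv["time_years"].astype(float))


def time_dependent_auc(surv_train: pd.DataFrame, surv_eval: pd.DataFrame,
                       scores: pd.Series, times) -> pd.Series:
    """IPCW cumulative/dynamic AUC(t) of a score at the requested times.

    The censoring distribution is estimated by KM on the training table.
    Times with no cases or no controls (or outside follow-up) yield NaN.
    """
    est = scores.loc[surv_eval.index].to_numpy(dtype=float)
    out = {}
    for t in times:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                auc, _ = cumulative_dynamic_auc(
                    _surv_array(surv_train), _surv_array(surv_eval),
                    est, [t])
            out[t] = float(auc[0])
        except (ValueError, ZeroDivisionError):
            out[t] = float("nan")
    return pd.Series(out, name="AUC").rename_axis(index="time")


def multi_index_auc(surv_train: pd.DataFrame, surv_eval: pd.DataFrame,
                    scores: pd.Series, reference_time: float,
                    covariates=("braaksc", "ceradsc", "dcfdx_lv")
                    ) -> pd.Series:
    """Compare AUC of the risk score and each clinical index at one time."""
    out = {"riskScore": time_dependent_auc(surv_train, surv_eval, scores,
                                           [reference_time]).iloc[0]}
    for c in covariates:
        vals = surv_eval[c].astype(float)
        out[c] = time_dependent_auc(surv_train, surv_eval, vals,
                                    [reference_time]).iloc[0]
    return pd.Series(out, name=f"AUC@{reference_time:g}y")
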