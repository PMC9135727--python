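"""Cox risk-score prognostic modelling and survival stratification.

A univariate proportional-hazards screen keeps genes with Wald p < 0.05;
the surviving panel enters one multivariate Cox fit (Efron tie handling via
lifelines).  Each sample's risk score is the linear predictor

    score = sum_g w_g * expr_g

with ``w_g`` the multivariate log-hazard coefficient (``score_mode='hr'``
uses exp(coef) instead, reproducing the literal "HR x expression" wording
some studies print).  The cohort splits at the median score into high/low
risk; discrimination is assessed by the log-rank test, Kaplan–Meier curves
and IPCW time-dependent AUC at 1/3/5 years (365/1095/1825 days).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import concordance_index
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

logger = logging.getLogger("immlnc")

YEAR_DAYS = 365
DEFAULT_HORIZONS = [365, 1095, 1825]


@dataclass
class RiskModel:
    """Gene panel, multivariate Cox coefficients and the stratification rule."""

    genes: list[str]
    coefs: dict[str, float]
    score_mode: str = "log_hr"   # weights: 'log_hr' -> coef, 'hr' -> exp(coef)
    cutoff: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("risk model genes must be unique")
        if self.score_mode not in ("log_hr", "hr"):
            raise ValueError("score_mode must be 'log_hr' or 'hr'")

    @property
    def hr(self) -> dict[str, float]:
        return {g: float(np.exp(c)) for g, c in self.coefs.items()}

    def weights(self) -> pd.Series:
        w = pd.Series(self.coefs).loc[self.genes]
        return np.exp(w) if self.score_mode == "hr" else w

    def to_json(self) -> str:
        return json.dumps(
            {
                "genes": self.genes,
                "coefs": self.coefs,
                "hr": self.hr,
                "score_mode": self.score_mode,
                "cutoff": self.cutoff,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "RiskModel":
        d = json.loads(text)
        return cls(
            genes=d["genes"], coefs=d["coefs"],
            score_mode=d.get("score_mode", "log_hr"), cutoff=d.get("cutoff", float("nan")),
        )


def _align(expr: pd.DataFrame, survival: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    shared = expr.columns.intersection(survival.index)
    if len(shared) < 4:
        raise ValueError("fewer than 4 samples shared between expression and survival")
    return expr[shared], survival.loc[shared]


def univariate_cox_screen(
    expr: pd.DataFrame, survival: pd.DataFrame, p_thresh: float = 0.05
) -> pd.DataFrame:
    """Per-gene proportional-hazards fits; Wald two-sided p, pass at p < thresh.

    Zero-variance or non-converging genes are skipped with a log entry and
    appear in the output with NaN statistics and ``passed=False``.
    """
    expr, survival = _align(expr, survival)
    if int(survival["event"].sum()) < 2:
        raise ValueError("need at least 2 observed events for a Cox screen")
    rows = {}
    for gene in expr.index:
        x = expr.loc[gene]
        if x.std() == 0:
            logger.info("univariate_cox_screen: %s skipped (constant expression)", gene)
            rows[gene] = (np.nan, np.nan, np.nan, False)
            continue
        df = pd.DataFrame({"time": survival["time"], "event": survival["event"], "x": x})
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="time", event_col="event")
        except Exception as exc:  # noqa: BLE001 - any fit failure is a skip
            logger.info("univariate_cox_screen: %s skipped (%s)", gene, exc)
            rows[gene] = (np.nan, np.nan, np.nan, False)
            continue
        coef = float(cph.params_["x"])
        p = float(cph.summary.loc["x", "p"])
        rows[gene] = (coef, float(np.exp(coef)), p, p < p_thresh)
    out = pd.DataFrame.from_dict(
        rows, orient="index", columns=["coef", "hr", "pval", "passed"]
    )
    out.index.name = "gene_id"
    return out


def fit_risk_model(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    genes,
    score_mode: str = "log_hr",
    epv_guard: bool = True,
    ridge_penalty: float = 0.1,
) -> RiskModel:
    """One multivariate Cox fit over a gene panel.

    Refuses panels larger than n_samples/5 unless ``epv_guard=False``.
    A collinear or otherwise non-converging panel triggers a
    ridge-stabilized refit with a warning.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene panel")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"panel genes absent from expression: {missing[:5]}")
    expr, survival = _align(expr, survival)
    if epv_guard and len(genes) >= expr.shape[1] / 5:
        raise ValueError(
            f"panel of {len(genes)} genes too large for {expr.shape[1]} samples "
            "(events-per-variable guard; pass epv_guard=False to override)"
        )
    df = expr.loc[genes].T.copy()
    df["time"] = survival["time"]
    df["event"] = survival["event"]
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception:  # noqa: BLE001
        warnings.warn("multivariate Cox fit failed; refitting with ridge penalty")
        cph = CoxPHFitter(penalizer=ridge_penalty, l1_ratio=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    coefs = {g: float(cph.params_[g]) for g in genes}
    model = RiskModel(genes=genes, coefs=coefs, score_mode=score_mode)
    scores = risk_score(model, expr)
    model.cutoff = float(np.median(scores))
    return model


def risk_score(model: RiskModel, expr) -> pd.Series | float:
    """Weighted sum of panel-gene expression for one sample or a matrix.

    ``expr`` is either a Series indexed by gene (one sample) or a
    genes-by-samples DataFrame.  Missing panel genes raise by name.
    """
    w = model.weights()
    if isinstance(expr, pd.Series):
        missing = [g for g in model.genes if g not in expr.index]
        if missing:
            raise KeyError(f"expression missing model gene(s): {missing}")
        return float(w @ expr.loc[model.genes])
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        raise KeyError(f"expression missing model gene(s): {missing}")
    return pd.Series(w @ expr.loc[model.genes], index=expr.columns, name="risk_score")


def stratify_median(scores: pd.Series, cutoff: float | None = None) -> pd.DataFrame:
    """Split samples into high/low risk at the (training) median.

    ``high`` iff score > cutoff; ties go low.  Returns a DataFrame with
    columns ``risk_score`` and ``group``.
    """
    if len(scores) < 4:
        raise ValueError("need at least 4 samples to stratify")
    if scores.nunique() == 1:
        raise ValueError("all risk scores identical; no stratification possible")
    if cutoff is None:
        cutoff = float(np.median(scores))
    group = np.where(scores > cutoff, "high", "low")
    return pd.DataFrame({"risk_score": scores, "group": group}, index=scores.index)


def km_logrank(
    strata: pd.DataFrame, survival: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], float, float]:
    """Kaplan–Meier curves per stratum plus the two-group log-rank test."""
    shared = strata.index.intersection(survival.index)
    strata, survival = strata.loc[shared], survival.loc[shared]
    curves: dict[str, pd.DataFrame] = {}
    for name in ("high", "low"):
        mask = strata["group"] == name
        if mask.sum() == 0:
            raise ValueError(f"stratum {name!r} is empty")
        if survival.loc[mask, "event"].sum() == 0:
            warnings.warn(f"stratum {name!r} has no observed events")
        kmf = KaplanMeierFitter()
        kmf.fit(survival.loc[mask, "time"], survival.loc[mask, "event"], label=name)
        curves[name] = kmf.survival_function_
    hi = strata["group"] == "high"
    res = logrank_test(
        survival.loc[hi, "time"], survival.loc[~hi, "time"],
        event_observed_A=survival.loc[hi, "event"],
        event_observed_B=survival.loc[~hi, "event"],
    )
    return curves, float(res.test_statistic), float(res.p_value)


def time_dependent_auc(
    scores: pd.Series,
    survival: pd.DataFrame,
    horizons=None,
    train_survival: pd.DataFrame | None = None,
) -> dict[int, float]:
    """Cumulative/dynamic AUC with IPCW weights at fixed horizons (days).

    Horizons past the last follow-up time (or before the first event) are
    skipped with a warning.  ``train_survival`` supplies the censoring
    distribution; defaults to the evaluation cohort itself.
    """
    horizons = list(DEFAULT_HORIZONS if horizons is None else horizons)
    shared = scores.index.intersection(survival.index)
    scores, survival = scores.loc[shared], survival.loc[shared]
    if train_survival is None:
        train_survival = survival
    y_test = Surv.from_arrays(
        event=survival["event"].astype(bool), time=survival["time"]
    )
    y_train = Surv.from_arrays(
        event=train_survival["event"].astype(bool), time=train_survival["time"]
    )
    event_times = survival.loc[survival["event"] == 1, "time"]
    if len(event_times) == 0:
        raise ValueError("no observed events; AUC undefined")
    t_max = survival["time"].max()
    out: dict[int, float] = {}
    for h in horizons:
        if h >= t_max or h < event_times.min():
            warnings.warn(f"horizon {h} outside follow-up; skipped")
            continue
        auc, _ = cumulative_dynamic_auc(y_train, y_test, scores.to_numpy(), [h])
        out[int(h)] = float(auc[0])
    return out


def apply_external(
    model: RiskModel,
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    use_training_cutoff: bool = False,
    allow_missing: bool = False,
    horizons=None,
) -> dict:
    """Apply a frozen risk model to an external cohort.

    Scores use the training coefficients unchanged.  The split uses the
    external cohort's own median by default (``use_training_cutoff=True``
    reuses the stored training cutoff).  Missing panel genes: more than 20%
    is always an error; fewer are dropped (with their weights) only when
    ``allow_missing=True``.

    Returns a dict with ``scores``, ``strata``, ``km`` curves, ``logrank``
    (chi2, p), ``auc`` and ``c_index``.
    """
    missing = [g for g in model.genes if g not in expr.index]
    if missing:
        if len(missing) > 0.2 * len(model.genes):
            raise KeyError(f"external cohort missing >20% of model genes: {missing[:5]}")
        if not allow_missing:
            raise KeyError(
                f"external cohort missing model gene(s) {missing}; "
                "pass allow_missing=True to drop them"
            )
        logger.warning("apply_external: dropping %d missing genes: %s", len(missing), missing)
        kept = [g for g in model.genes if g not in missing]
        model = RiskModel(
            genes=kept,
            coefs={g: model.coefs[g] for g in kept},
            score_mode=model.score_mode,
            cutoff=model.cutoff,
        )
    expr, survival = _align(expr, survival)
    scores = risk_score(model, expr)
    cutoff = model.cutoff if use_training_cutoff else None
    strata = stratify_median(scores, cutoff=cutoff)
    curves, chi2, p = km_logrank(strata, survival)
    aucs = time_dependent_auc(scores, survival, horizons=horizons)
    cidx = concordance_index(survival["time"], -scores, survival["event"])
    return {
        "scores": scores,
        "strata": strata,
        "km": curves,
        "logrank": (chi2, p),
        "auc": aucs,
        "c_index": float(cidx),
    }
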