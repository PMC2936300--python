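"""Survival evaluation core: Cox risk scores, time-specific incident/dynamic
ROC curves, AUC(t), the integrated concordance index C, and the repeated
random-split cross-validation engine.

Time-specific classification follows the incident/dynamic framework: at a
yearly horizon t, *cases* are subjects observed to die in the interval
(t-1, t] and *controls* are subjects (censored or not) still under
observation beyond t.  AUC(t) is the Mann-Whitney probability that a case
outscores a control (ties credit 1/2), and the concordance index C is the
unweighted mean of the defined yearly AUC(t) values, t = 1..19 by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cox import CoxData, CoxFitResult, cox_fit_prepared
from .cohort import CohortTable
from .config import CVConfig

__all__ = [
    "RiskModel", "TimeROC", "ConcordanceResult", "fit_cox",
    "incident_dynamic_roc", "auc_t", "concordance_C", "cv_evaluate",
    "cv_evaluate_many", "logrank_test", "km_estimate",
]


# ---------------------------------------------------------------------------
# risk models


@dataclass
class RiskModel:
    """A fitted proportional-hazards model: variable list + coefficients.

    The per-subject risk score is the linear predictor
    ``M_i = sum_v beta_v * x_iv`` (no intercept; adding a constant to any
    column shifts all scores equally and leaves every rank statistic
    unchanged).
    """

    variables: list[str]
    beta: np.ndarray
    se: np.ndarray = field(default=None)  # type: ignore[assignment]
    converged: bool = True
    n_train: int = 0
    ties_method: str = "efron"
    loglik: float = float("nan")
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.variables) != len(self.beta):
            raise ValueError("|variables| must equal |beta|")
        if self.se is None:
            self.se = np.full(len(self.beta), np.nan)

    def scores(self, table: CohortTable) -> np.ndarray:
        return table.design_matrix(self.variables) @ self.beta

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def summary(self) -> pd.DataFrame:
        z = self.beta / self.se
        from scipy.stats import norm
        p = 2 * norm.sf(np.abs(z))
        return pd.DataFrame({
            "variable": self.variables,
            "coef": self.beta,
            "hr": np.exp(self.beta),
            "hr_lo95": np.exp(self.beta - 1.96 * self.se),
            "hr_hi95": np.exp(self.beta + 1.96 * self.se),
            "p": p,
        })


def fit_cox(table: CohortTable, variables: list[str], **kwargs) -> RiskModel:
    """Fit a Cox PH model (Efron tie handling) on the full table.

    Constant columns are dropped with a record in ``model.dropped``;
    non-convergence (e.g. monotone likelihood from a rare indicator) is
    recorded on the ``converged`` flag, not raised.
    """
    missing = [v for v in variables if v not in table.predictors.columns]
    if missing:
        raise KeyError(f"variables absent from table: {missing}")
    if table.event.sum() < 2:
        raise ValueError("need at least 2 events to fit")
    X = table.design_matrix(variables)
    keep = np.std(X, axis=0) > 0
    dropped = [v for v, k in zip(variables, keep) if not k]
    used = [v for v, k in zip(variables, keep) if k]
    if not used:
        raise ValueError("all requested predictors are constant")
    res = cox_fit_prepared(X[:, keep], CoxData(table.time_years, table.event),
                           **kwargs)
    return RiskModel(
        variables=used, beta=res.beta, se=res.se, converged=res.converged,
        n_train=res.n, loglik=res.loglik, dropped=dropped,
    )


# ---------------------------------------------------------------------------
# time-specific ROC machinery


def _case_control_masks(time, event, t, bin_width=1.0):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    cases = (event == 1) & (time > t - bin_width) & (time <= t)
    controls = time > t
    return cases, controls


@dataclass
class TimeROC:
    """Incident/dynamic ROC curve at horizon t.

    ``one_minus_specificity`` (x) and ``sensitivity`` (y) are monotone,
    anchored at (0,0) and (1,1); interior points correspond to thresholds
    "predict death if M > c" over distinct observed scores c.
    """

    t: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    n_cases: int
    n_controls: int

    def auc(self) -> float:
        """Trapezoidal area under the curve."""
        return float(np.trapezoid(self.sensitivity, self.one_minus_specificity))

    def to_frame(self) -> pd.DataFrame:
        """Curve as a table (for TSV export / plotting)."""
        return pd.DataFrame({
            "one_minus_specificity": self.one_minus_specificity,
            "sensitivity": self.sensitivity,
        })


def incident_dynamic_roc(M, time, event, t, bin_width: float = 1.0) -> TimeROC:
    """Time-specific ROC from incident sensitivity / dynamic specificity.

    Raises ``ValueError`` when the horizon has no cases or no controls; the
    caller is expected to skip such horizons.
    """
    M = np.asarray(M, dtype=float)
    cases, controls = _case_control_masks(time, event, t, bin_width)
    nc, nk = int(cases.sum()), int(controls.sum())
    if nc == 0 or nk == 0:
        raise ValueError(f"horizon t={t} undefined: {nc} cases, {nk} controls")
    # sweep thresholds from high to low so the curve runs (0,0) -> (1,1)
    cs = np.sort(np.unique(M[cases | controls]))[::-1]
    sens = np.concatenate(([0.0], [(M[cases] > c).mean() for c in cs], [1.0]))
    fpr = np.concatenate(([0.0], [(M[controls] > c).mean() for c in cs], [1.0]))
    return TimeROC(
        t=t, thresholds=cs, sensitivity=sens, one_minus_specificity=fpr,
        n_cases=nc, n_controls=nk,
    )


def _auc_from_masks(M, cases, controls):
    nc, nk = int(cases.sum()), int(controls.sum())
    if nc == 0 or nk == 0:
        return np.nan
    # Mann-Whitney with half-credit for ties, via sorted-control bisection
    ctrl = np.sort(M[controls])
    lo = np.searchsorted(ctrl, M[cases], side="left")
    hi = np.searchsorted(ctrl, M[cases], side="right")
    return float((lo + 0.5 * (hi - lo)).sum() / (nc * nk))


def auc_t(M, time, event, t, bin_width: float = 1.0) -> float:
    """Mann-Whitney AUC(t) over case-control pairs at horizon t.

    Cases are deaths in (t-1, t]; controls are subjects observed beyond t;
    tied scores credit 1/2.  Returns NaN for horizons with no cases or no
    controls (the undefined-horizon signal).
    """
    M = np.asarray(M, dtype=float)
    cases, controls = _case_control_masks(time, event, t, bin_width)
    return float(_auc_from_masks(M, cases, controls))


def concordance_C(M, time, event, grid=tuple(range(1, 20))) -> float:
    """Integrated concordance: unweighted mean of the defined yearly AUC(t).

    Invariant to strictly increasing transforms of M.  Raises if every
    horizon in the grid is undefined.
    """
    aucs = np.array([auc_t(M, time, event, t) for t in grid])
    defined = ~np.isnan(aucs)
    if not defined.any():
        raise ValueError("all horizons undefined")
    return float(aucs[defined].mean())


# ---------------------------------------------------------------------------
# cross-validation engine


@dataclass
class ConcordanceResult:
    """Aggregated per-horizon AUC(t) and concordance over CV trials."""

    auc_by_t: pd.DataFrame  # columns: t, auc_mean, auc_sd, n_trials_defined
    C_mean: float
    C_sd: float
    n_trials: int
    n_failed_trials: int

    def to_tsv(self, path) -> None:
        self.auc_by_t.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump({
                "C_mean": self.C_mean, "C_sd": self.C_sd,
                "n_trials": self.n_trials,
                "n_failed_trials": self.n_failed_trials,
                "auc_by_t": self.auc_by_t.to_dict(orient="list"),
            }, fh, indent=2, default=float)


def _trial_split(n, n_train, seed_seq):
    rng = np.random.default_rng(seed_seq)
    perm = rng.permutation(n)
    return perm[:n_train], perm[n_train:]


def cv_evaluate_many(
    table: CohortTable,
    variable_sets: list[list[str]],
    cv: CVConfig,
    beta_tol: float = 1e-5,
    warm_start: list[np.ndarray] | None = None,
) -> list[ConcordanceResult]:
    """Evaluate many variable sets over the *same* CV splits.

    Per trial: split subjects into train (``floor(train_fraction * n)``) and
    test, fit each candidate Cox model on the train rows (warm-started from
    its previous trial's coefficients), score the test rows, and record the
    defined yearly AUC(t) and their mean (the trial's C).  Trials whose fit
    does not converge, or with no defined horizon, count as failed for that
    set and are excluded from the aggregates.

    Sharing splits across candidate sets both amortizes the risk-set
    bookkeeping and removes between-split noise from candidate comparisons
    (common random numbers).
    """
    n = table.n_subjects
    n_train, n_test = cv.split_sizes(n)
    if n_train < 2 or n_test < 1:
        raise ValueError(f"cohort of {n} too small to split")
    cols = {v: i for i, v in enumerate(table.variable_names)}
    for vs in variable_sets:
        missing = [v for v in vs if v not in cols]
        if missing:
            raise KeyError(f"variables absent from table: {missing}")
    Xall = table.predictors.to_numpy(dtype=float)
    time, event = table.time_years, table.event
    grid = np.asarray(list(cv.time_grid), dtype=float)
    n_sets = len(variable_sets)
    idx_sets = [np.array([cols[v] for v in vs]) for vs in variable_sets]

    sum_auc = np.zeros((n_sets, len(grid)))
    sumsq_auc = np.zeros((n_sets, len(grid)))
    cnt_auc = np.zeros((n_sets, len(grid)), dtype=int)
    sum_C = np.zeros(n_sets)
    sumsq_C = np.zeros(n_sets)
    n_ok = np.zeros(n_sets, dtype=int)
    n_failed = np.zeros(n_sets, dtype=int)
    warm: list[np.ndarray | None] = (
        [None] * n_sets if warm_start is None else list(warm_start)
    )

    for trial in range(cv.n_trials):
        # child seed [master, trial]: any trial is replayable in isolation
        tr, te = _trial_split(n, n_train, np.random.SeedSequence([cv.master_seed, trial]))
        data = CoxData(time[tr], event[tr])
        if data.n_events < 2:
            n_failed += 1
            continue
        t_te, e_te = time[te], event[te]
        masks = [_case_control_masks(t_te, e_te, t) for t in grid]
        Xtr_full = Xall[tr]
        Xte_full = Xall[te]
        for s in range(n_sets):
            Xtr = Xtr_full[:, idx_sets[s]]
            sd = Xtr.std(axis=0)
            if np.any(sd == 0):
                n_failed[s] += 1
                continue
            res = cox_fit_prepared(Xtr, data, beta0=warm[s],
                                   want_se=False, beta_tol=beta_tol)
            if not res.converged:
                n_failed[s] += 1
                warm[s] = None
                continue
            warm[s] = res.beta
            M = Xte_full[:, idx_sets[s]] @ res.beta
            aucs = np.array([_auc_from_masks(M, c, k) for c, k in masks])
            defined = ~np.isnan(aucs)
            if not defined.any():
                n_failed[s] += 1
                continue
            sum_auc[s, defined] += aucs[defined]
            sumsq_auc[s, defined] += aucs[defined] ** 2
            cnt_auc[s, defined] += 1
            Ct = aucs[defined].mean()
            sum_C[s] += Ct
            sumsq_C[s] += Ct ** 2
            n_ok[s] += 1

    out = []
    for s in range(n_sets):
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_auc = np.where(cnt_auc[s] > 0, sum_auc[s] / np.maximum(cnt_auc[s], 1), np.nan)
            var_auc = sumsq_auc[s] / np.maximum(cnt_auc[s], 1) - mean_auc ** 2
            sd_auc = np.sqrt(np.maximum(var_auc, 0.0))
            if n_ok[s] > 0:
                cm = sum_C[s] / n_ok[s]
                csd = float(np.sqrt(max(sumsq_C[s] / n_ok[s] - cm ** 2, 0.0)))
            else:
                cm, csd = np.nan, np.nan
        out.append(ConcordanceResult(
            auc_by_t=pd.DataFrame({
                "t": grid, "auc_mean": mean_auc, "auc_sd": sd_auc,
                "n_trials_defined": cnt_auc[s],
            }),
            C_mean=float(cm), C_sd=csd,
            n_trials=cv.n_trials, n_failed_trials=int(n_failed[s]),
        ))
    return out


def cv_evaluate(table: CohortTable, variables: list[str], cv: CVConfig,
                **kwargs) -> ConcordanceResult:
    """Cross-validated concordance of one variable set (see
    :func:`cv_evaluate_many`)."""
    return cv_evaluate_many(table, [list(variables)], cv, **kwargs)[0]


# ---------------------------------------------------------------------------
# classical survival statistics (delegated to lifelines)


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p) with 1 df."""
    from lifelines.statistics import logrank_test as _lr
    group = np.asarray(group).astype(bool)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if group.all() or (~group).all():
        raise ValueError("both groups must be non-empty")
    res = _lr(time[group], time[~group], event[group], event[~group])
    return float(res.test_statistic), float(res.p_value)


def km_estimate(time, event, alpha: float = 0.05) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate with Greenwood-based 95% bands.

    Returns a step-function table with columns
    ``time, survival, lower, upper``.
    """
    from lifelines import KaplanMeierFitter
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(np.asarray(time, dtype=float), np.asarray(event, dtype=int))
    ci = kmf.confidence_interval_survival_function_
    return pd.DataFrame({
        "time": kmf.survival_function_.index.to_numpy(),
        "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
        "lower": ci.iloc[:, 0].to_numpy(),
        "upper": ci.iloc[:, 1].to_numpy(),
    })


def km_quantile_times(time, event, levels=(0.9, 0.8, 0.7, 0.6)) -> dict[float, float]:
    """First times at which KM survival drops to each level (calibration aid)."""
    km = km_estimate(time, event)
    out = {}
    for q in levels:
        below = km.loc[km["survival"] <= q, "time"]
        out[q] = float(below.iloc[0]) if len(below) else float("inf")
    return out
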