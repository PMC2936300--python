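"""Model search: univariate and adjusted screens, exhaustive bivariate
screen with two-stage refinement, forward selection with a knee-based
stopping rule, and the drop-one check.

All screens evaluate candidate Cox models with the cross-validated
concordance criterion from :mod:`agemine.metrics`; candidates within one
screening step share CV splits (common random numbers), so comparisons
between candidates are not confounded by split luck.  Everything is
deterministic for a fixed master seed and invariant to cohort row order up
to that seed's splits.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import CohortTable
from .config import CVConfig
from .metrics import ConcordanceResult, RiskModel, cv_evaluate, cv_evaluate_many, fit_cox

__all__ = [
    "SearchTrace", "univariate_screen", "adjusted_screen", "bivariate_screen",
    "forward_selection", "knee_select", "refine_selection", "drop_one_check",
]


@dataclass
class SearchStep:
    p: int
    added_variable: str
    mean_C: float
    sd_C: float
    se_C: float
    n_trials: int

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.mean_C - 1.96 * self.se_C, self.mean_C + 1.96 * self.se_C)


@dataclass
class SearchTrace:
    """Forward-selection path: model size, variable added, mean C per step."""

    start: tuple[str, str]
    steps: list[SearchStep] = field(default_factory=list)
    loss: np.ndarray | None = None
    p_star: int | None = None

    @property
    def sizes(self) -> np.ndarray:
        return np.array([s.p for s in self.steps])

    @property
    def mean_C(self) -> np.ndarray:
        return np.array([s.mean_C for s in self.steps])

    def variables_at(self, p: int) -> list[str]:
        """The model (variable list) of size p along the path."""
        if p < self.steps[0].p or p > self.steps[-1].p:
            raise ValueError(f"no model of size {p} on this trace")
        out = list(self.start)
        for s in self.steps:
            if s.p <= 2:
                continue
            if s.p <= p:
                out.append(s.added_variable)
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(s) for s in self.steps])
        if self.loss is not None:
            df["loss"] = self.loss
        return df


def _wald_p(beta: float, se: float) -> float:
    if not np.isfinite(se) or se == 0:
        return np.nan
    return float(2 * norm.sf(abs(beta / se)))


# ---------------------------------------------------------------------------
# screens


def univariate_screen(table: CohortTable, cv: CVConfig,
                      variables: list[str] | None = None) -> pd.DataFrame:
    """Full-data Cox HR/CI/p plus cross-validated mean C, per variable.

    Returns a DataFrame ranked by mean C (rank 1 = largest); variables whose
    full-data fit fails are flagged rather than dropped.
    """
    variables = variables or table.variable_names
    results = cv_evaluate_many(table, [[v] for v in variables], cv)
    rows = []
    for v, res in zip(variables, results):
        hr = lo = hi = p = np.nan
        ok = False
        try:
            m = fit_cox(table, [v])
            if m.converged and not m.dropped:
                b, se = m.beta[0], m.se[0]
                hr, lo, hi = np.exp(b), np.exp(b - 1.96 * se), np.exp(b + 1.96 * se)
                p = _wald_p(b, se)
                ok = True
        except ValueError:
            pass
        rows.append(dict(variable=v, hr=hr, hr_lo95=lo, hr_hi95=hi, p=p,
                         mean_C=res.C_mean, sd_C=res.C_sd,
                         n_failed_trials=res.n_failed_trials, fit_ok=ok))
    df = pd.DataFrame(rows).sort_values("mean_C", ascending=False,
                                        kind="stable", ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def adjusted_screen(table: CohortTable, adjust_sets: list[list[str]],
                    variables: list[str] | None = None,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Count of variables significant (Wald p < alpha) after adjustment.

    For each adjustment set, every screened variable is fit jointly with the
    set and its own adjusted p-value recorded; a variable appearing in its
    own adjustment set is skipped for that set.
    """
    variables = variables or table.variable_names
    rows = []
    for adj in adjust_sets:
        missing = [a for a in adj if a not in table.predictors.columns]
        if missing:
            raise KeyError(f"adjustment covariates absent: {missing}")
        n_sig = 0
        n_tested = 0
        for v in variables:
            if v in adj:
                continue
            try:
                m = fit_cox(table, [v] + list(adj))
            except ValueError:
                continue
            if not m.converged or v not in m.variables:
                continue
            i = m.variables.index(v)
            n_tested += 1
            if _wald_p(m.beta[i], m.se[i]) < alpha:
                n_sig += 1
        rows.append(dict(adjustment=", ".join(adj) if adj else "(none)",
                         n_adjusters=len(adj), n_tested=n_tested,
                         n_significant=n_sig))
    return pd.DataFrame(rows)


def bivariate_screen(
    table: CohortTable,
    cv_coarse: CVConfig,
    top_m: int = 200,
    cv_fine: CVConfig | None = None,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Evaluate all unordered variable pairs at coarse CV depth, then
    re-evaluate the ``top_m`` pairs at fine depth.

    Returns the pair ranking with both estimates (``mean_C_fine`` is NaN for
    pairs outside the refined set); final order is by fine C where
    available, else coarse C.
    """
    variables = variables or table.variable_names
    pairs = list(itertools.combinations(variables, 2))
    coarse = cv_evaluate_many(table, [list(p) for p in pairs], cv_coarse)
    df = pd.DataFrame({
        "var1": [a for a, _ in pairs], "var2": [b for _, b in pairs],
        "mean_C_coarse": [r.C_mean for r in coarse],
        "n_failed_coarse": [r.n_failed_trials for r in coarse],
    })
    df = df.sort_values("mean_C_coarse", ascending=False, kind="stable",
                        ignore_index=True)
    df["mean_C_fine"] = np.nan
    if cv_fine is not None and len(df):
        m = min(top_m, len(df))
        top_pairs = [[df.var1[i], df.var2[i]] for i in range(m)]
        fine = cv_evaluate_many(table, top_pairs, cv_fine)
        df.loc[: m - 1, "mean_C_fine"] = [r.C_mean for r in fine]
        df["final_C"] = df["mean_C_fine"].fillna(df["mean_C_coarse"])
        df = df.sort_values("final_C", ascending=False, kind="stable",
                            ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# forward selection


def _pick_best(cands: list[str], results: list[ConcordanceResult],
               rank_of: dict[str, int]) -> tuple[str, ConcordanceResult] | None:
    """Tie-break: higher mean C, then better univariate rank, then name."""
    best = None
    for v, r in zip(cands, results):
        if not np.isfinite(r.C_mean):
            continue
        key = (-r.C_mean, rank_of.get(v, np.inf), v)
        if best is None or key < best[0]:
            best = (key, v, r)
    if best is None:
        return None
    return best[1], best[2]


def forward_selection(
    table: CohortTable,
    start: tuple[str, str],
    cv_step: CVConfig,
    max_p: int = 30,
    candidates: list[str] | None = None,
    univariate_rank: dict[str, int] | None = None,
) -> SearchTrace:
    """Greedy forward search from a starting pair.

    At each step, every remaining variable is added to the current model and
    evaluated at ``cv_step`` depth over shared splits; the variable with the
    highest mean C joins the model (ties broken by univariate-screen rank,
    then name).  Candidates whose fits fail in every trial are treated as
    failed candidates (e.g. columns collinear with the model).  Stops at
    ``max_p`` or when no candidate is evaluable.
    """
    start = tuple(start)
    if len(start) != 2 or any(v not in table.predictors.columns for v in start):
        raise ValueError(f"invalid start pair {start}")
    rank_of = univariate_rank or {}
    pool = [v for v in (candidates or table.variable_names) if v not in start]
    model = list(start)
    trace = SearchTrace(start=start)  # type: ignore[arg-type]

    res0 = cv_evaluate(table, model, cv_step)
    n_ok = max(res0.n_trials - res0.n_failed_trials, 1)
    trace.steps.append(SearchStep(2, "+".join(start), res0.C_mean, res0.C_sd,
                                  res0.C_sd / np.sqrt(n_ok), res0.n_trials))
    step_seed = cv_step.master_seed
    while len(model) < max_p and pool:
        step_seed += 1  # fresh splits each step, deterministic overall
        cv = replace(cv_step, master_seed=step_seed)
        # warm-start candidate fits from the current model's full-data fit
        try:
            base_beta = fit_cox(table, model).beta
            warm = [np.append(base_beta, 0.0)] * len(pool) \
                if len(base_beta) == len(model) else None
        except ValueError:
            warm = None
        results = cv_evaluate_many(table, [model + [v] for v in pool], cv,
                                   warm_start=warm)
        pick = _pick_best(pool, results, rank_of)
        if pick is None:
            break
        v, r = pick
        model.append(v)
        pool.remove(v)
        n_ok = max(r.n_trials - r.n_failed_trials, 1)
        trace.steps.append(SearchStep(len(model), v, r.C_mean, r.C_sd,
                                      r.C_sd / np.sqrt(n_ok), r.n_trials))
    return trace


def knee_select(trace: SearchTrace) -> int:
    """Model size at the knee of the size-vs-concordance curve.

    Both axes are min-max rescaled to [0,1] (size ascending on x, mean C on
    y); the loss at each step is the Euclidean distance from the rescaled
    point to the ideal upper-left corner (0, 1); the selected size p* is the
    argmin, with ties going to the smaller model.  Sets ``trace.loss`` and
    ``trace.p_star``.
    """
    if len(trace.steps) < 3:
        raise ValueError("knee selection needs a trace with at least 3 steps")
    p = trace.sizes.astype(float)
    C = trace.mean_C
    x = (p - p.min()) / (p.max() - p.min())
    c_range = C.max() - C.min()
    if c_range == 0:
        warnings.warn("constant mean C along trace; knee degenerate, "
                      "returning smallest size")
        trace.loss = np.ones_like(x)
        trace.p_star = int(p.min())
        return trace.p_star
    y = (C - C.min()) / c_range
    loss = np.sqrt(x ** 2 + (1.0 - y) ** 2)
    trace.loss = loss
    trace.p_star = int(p[int(np.argmin(loss))])  # argmin ties -> smaller p
    return trace.p_star


def refine_selection(
    table: CohortTable,
    trace: SearchTrace,
    cv_mid: CVConfig,
    top_k: int = 10,
    cv_deep: CVConfig | None = None,
    candidates: list[str] | None = None,
    univariate_rank: dict[str, int] | None = None,
) -> tuple[RiskModel, ConcordanceResult, SearchTrace]:
    """Re-run forward selection to depth ``trace.p_star`` with a two-stage
    evaluation per step: all candidates at mid depth, then the step's top
    ``top_k`` at deep depth.  Returns the final full-data model, its deep
    concordance estimate, and the refined trace.
    """
    if trace.p_star is None:
        knee_select(trace)
    p_star = trace.p_star
    cv_deep = cv_deep or cv_mid
    rank_of = univariate_rank or {}
    start = tuple(trace.start)
    pool = [v for v in (candidates or table.variable_names) if v not in start]
    model = list(start)
    refined = SearchTrace(start=start)  # type: ignore[arg-type]
    res0 = cv_evaluate(table, model, cv_deep)
    n_ok = max(res0.n_trials - res0.n_failed_trials, 1)
    refined.steps.append(SearchStep(2, "+".join(start), res0.C_mean, res0.C_sd,
                                    res0.C_sd / np.sqrt(n_ok), res0.n_trials))
    step_seed = cv_mid.master_seed
    while len(model) < p_star and pool:
        step_seed += 1
        mid = cv_evaluate_many(table, [model + [v] for v in pool],
                               replace(cv_mid, master_seed=step_seed))
        res_of = dict(zip(pool, mid))
        order = sorted(
            (v for v in pool if np.isfinite(res_of[v].C_mean)),
            key=lambda v: (-res_of[v].C_mean, rank_of.get(v, np.inf), v),
        )
        short = order[:top_k]
        if not short:
            break
        if cv_deep == cv_mid:  # identical depths: mid results are the deep ones
            deep = [res_of[v] for v in short]
        else:
            deep = cv_evaluate_many(table, [model + [v] for v in short],
                                    replace(cv_deep, master_seed=step_seed + 10_000))
        pick = _pick_best(short, deep, rank_of)
        if pick is None:
            break
        v, r = pick
        model.append(v)
        pool.remove(v)
        n_ok = max(r.n_trials - r.n_failed_trials, 1)
        refined.steps.append(SearchStep(len(model), v, r.C_mean, r.C_sd,
                                        r.C_sd / np.sqrt(n_ok), r.n_trials))
    final = fit_cox(table, model)
    deep_res = cv_evaluate(table, model, cv_deep)
    return final, deep_res, refined


def drop_one_check(table: CohortTable, model: RiskModel,
                   cv: CVConfig) -> pd.DataFrame:
    """Mean C of every leave-one-variable-out reduction of ``model``.

    Flags reduced models whose mean C matches or exceeds the full model's
    (a sign the dropped term carries no predictive weight).
    """
    if len(model.variables) < 2:
        raise ValueError("drop-one check needs a model with >= 2 variables")
    sets = [[v for v in model.variables if v != d] for d in model.variables]
    results = cv_evaluate_many(table, [model.variables] + sets, cv)
    full = results[0]
    rows = [dict(dropped_variable=d, mean_C=r.C_mean, sd_C=r.C_sd,
                 full_model_C=full.C_mean,
                 no_worse_than_full=bool(r.C_mean >= full.C_mean))
            for d, r in zip(model.variables, results[1:])]
    return pd.DataFrame(rows)
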