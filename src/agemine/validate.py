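"""Post-selection validation: leave-one-out risk scoring, median-split
Kaplan-Meier analyses, cause-specific hazards, cross-cause permutation
validation, deficit-index and random-model baselines, and survivor-outcome
association tests.

None of these steps re-uses scored subjects' outcomes for fitting: LOOCV
fits exclude the scored subject, and cross-cause fits never see the test
cause's subjects except through the permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cox import CoxData, cox_fit_prepared
from .cohort import CohortTable
from .config import CVConfig
from .metrics import RiskModel, concordance_C, cv_evaluate_many, fit_cox, \
    km_estimate, logrank_test

DOCUMENTED_CAUSES = ("cardiovascular", "cancer", "other")


# ---------------------------------------------------------------------------
# risk scores


@dataclass
class RiskScoreSet:
    """Per-subject LOOCV risk scores, raw and cohort-standardized."""

    raw_score: np.ndarray
    standardized_score: np.ndarray
    failed: np.ndarray  # subjects whose leave-one-out fit did not converge

    def __len__(self) -> int:
        return len(self.raw_score)


def loocv_scores(table: CohortTable, variables: list[str]) -> RiskScoreSet:
    """Score each subject from a model fit on the other n-1 subjects.

    Scores are then standardized to cohort mean 0, SD 1 (failed folds are
    flagged and excluded from the standardization constants).
    """
    n = table.n_subjects
    X = table.design_matrix(variables)
    time, event = table.time_years, table.event
    warm = fit_cox(table, variables).beta
    raw = np.full(n, np.nan)
    failed = np.zeros(n, dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        res = cox_fit_prepared(X[keep], CoxData(time[keep], event[keep]),
                               beta0=warm, want_se=False, beta_tol=1e-6)
        if not res.converged:
            failed[i] = True
            continue
        raw[i] = X[i] @ res.beta
    ok = ~failed
    mu, sd = raw[ok].mean(), raw[ok].std()
    std = (raw - mu) / sd
    return RiskScoreSet(raw_score=raw, standardized_score=std, failed=failed)


# ---------------------------------------------------------------------------
# stratified Kaplan-Meier


def median_split_km(
    scores: RiskScoreSet, table: CohortTable,
    subset: np.ndarray | None = None,
    cause: str | None = None,
) -> dict:
    """Low- vs high-risk Kaplan-Meier curves split at the whole-cohort
    median score, with a log-rank test.

    ``subset`` restricts the analysis (e.g. smokers only); ``cause``
    restricts to subjects dying of one documented cause, censoring deaths
    of any other cause.
    """
    s = scores.standardized_score
    median = np.nanmedian(s)
    high = s > median
    mask = np.ones(len(table), dtype=bool) if subset is None else np.asarray(subset, bool)
    time = table.time_years[mask]
    event = table.event[mask].copy()
    if cause is not None:
        event = ((table.cause[mask] == cause) & (event == 1)).astype(int)
    grp = high[mask]
    if grp.all() or (~grp).all():
        raise ValueError("median split left one group empty in this subset")
    chi2, p = logrank_test(time, event, grp)
    return {
        "km_high": km_estimate(time[grp], event[grp]),
        "km_low": km_estimate(time[~grp], event[~grp]),
        "n_high": int(grp.sum()), "n_low": int((~grp).sum()),
        "logrank_chi2": chi2, "logrank_p": p,
    }


# ---------------------------------------------------------------------------
# cause-specific analyses


def cause_specific_hazards(
    table: CohortTable, variable: str, cause: str | None = None,
) -> dict:
    """Univariate Cox HR treating deaths of ``cause`` as events and deaths
    of any other cause as censored; ``cause=None`` pools all documented
    causes (the all-cause analysis)."""
    if cause is None:
        event = (np.isin(table.cause, DOCUMENTED_CAUSES)).astype(int)
    else:
        event = ((table.cause == cause) & (table.event == 1)).astype(int)
        if event.sum() < 2:
            raise ValueError(f"fewer than 2 deaths of cause {cause!r}")
    sub = CohortTable(table.predictors, table.time_years, event,
                      np.where(event == 1, "other", "alive"),
                      table.metadata)
    m = fit_cox(sub, [variable])
    b, se = m.beta[0], m.se[0]
    return {
        "variable": variable, "cause": cause or "all-documented",
        "hr": float(np.exp(b)), "hr_lo95": float(np.exp(b - 1.96 * se)),
        "hr_hi95": float(np.exp(b + 1.96 * se)), "n_events": int(event.sum()),
        "converged": m.converged,
    }


def cross_cause_validation(
    table: CohortTable,
    variables: list[str],
    train_cause: str,
    test_cause: str,
    n_perm: int = 10_000,
    seed: int = 0,
    grid=tuple(range(1, 20)),
) -> dict:
    """Train on subjects who died of one cause, test on those who died of
    another, against a permutation null.

    Both sets contain deceased subjects only (all events).  The null
    permutes training survival times among training subjects before each
    refit; p is the one-sided fraction of null concordances at least as
    large as the observed one (add-one corrected).
    """
    if train_cause == test_cause:
        raise ValueError("train and test causes must differ")
    tr_mask = table.cause == train_cause
    te_mask = table.cause == test_cause
    if tr_mask.sum() < len(variables) + 2 or te_mask.sum() < 2:
        raise ValueError("cause groups too small")
    Xtr = table.design_matrix(variables)[tr_mask]
    Xte = table.design_matrix(variables)[te_mask]
    t_tr = table.time_years[tr_mask]
    t_te = table.time_years[te_mask]
    e_tr = np.ones(int(tr_mask.sum()), dtype=int)
    e_te = np.ones(int(te_mask.sum()), dtype=int)

    fit = cox_fit_prepared(Xtr, CoxData(t_tr, e_tr), want_se=False)
    C_obs = concordance_C(Xte @ fit.beta, t_te, e_te, grid)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 23]))
    null = np.full(n_perm, np.nan)
    warm = fit.beta
    for b in range(n_perm):
        t_perm = rng.permutation(t_tr)
        res = cox_fit_prepared(Xtr, CoxData(t_perm, e_tr), beta0=None,
                               want_se=False, beta_tol=1e-5)
        if not res.converged:
            continue
        try:
            null[b] = concordance_C(Xte @ res.beta, t_te, e_te, grid)
        except ValueError:
            continue
    ok = ~np.isnan(null)
    p = (1 + np.sum(null[ok] >= C_obs)) / (1 + ok.sum())
    return {
        "train_cause": train_cause, "test_cause": test_cause,
        "n_train": int(tr_mask.sum()), "n_test": int(te_mask.sum()),
        "C_obs": float(C_obs), "null_C": null[ok], "p": float(p),
    }


# ---------------------------------------------------------------------------
# deficit index


@dataclass
class DeficitRule:
    """Binarization of one variable into a 0/1 health deficit."""

    variable: str
    op: str  # "ge", "le", "eq"
    cut: float

    def apply(self, x: np.ndarray) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            if self.op == "ge":
                out = (x >= self.cut).astype(float)
            elif self.op == "le":
                out = (x <= self.cut).astype(float)
            elif self.op == "eq":
                out = (x == self.cut).astype(float)
            else:
                raise ValueError(f"unknown op {self.op!r}")
        out[np.isnan(x)] = np.nan
        return out


@dataclass
class DeficitIndex:
    n_deficits_evaluated: np.ndarray
    proportion_present: np.ndarray


def default_deficit_rules(table: CohortTable, n_rules: int = 15) -> list[DeficitRule]:
    """A synthetic analogue of an accumulation-of-deficits rule set:
    worst-quintile cuts on the first continuous variables, top-category cuts
    on ordinals, and presence cuts on binary indicators."""
    rules: list[DeficitRule] = []
    for v in table.variables_of_class("continuous"):
        if len(rules) >= n_rules * 2 // 3:
            break
        x = table.predictors[v].to_numpy(dtype=float)
        rules.append(DeficitRule(v, "ge", float(np.nanquantile(x, 0.8))))
    for v in table.variables_of_class("ordinal"):
        if len(rules) >= n_rules - 2:
            break
        x = table.predictors[v].to_numpy(dtype=float)
        rules.append(DeficitRule(v, "ge", float(np.nanquantile(x, 0.8))))
    for v in table.variables_of_class("indicator") + table.variables_of_class("categorical"):
        if len(rules) >= n_rules:
            break
        rules.append(DeficitRule(v, "eq", 1.0))
    return rules[:n_rules]


def deficit_index(table: CohortTable, rules: list[DeficitRule]) -> DeficitIndex:
    """Proportion of evaluable deficits present per subject; missing
    components reduce the denominator."""
    if len(rules) < 10:
        raise ValueError("a deficit index needs at least 10 rules")
    D = np.column_stack([
        r.apply(table.predictors[r.variable].to_numpy(dtype=float)) for r in rules
    ])
    evaluated = (~np.isnan(D)).sum(axis=1)
    if np.any(evaluated == 0):
        raise ValueError("subject with zero evaluable deficits")
    present = np.nansum(D, axis=1)
    return DeficitIndex(
        n_deficits_evaluated=evaluated,
        proportion_present=present / evaluated,
    )


# ---------------------------------------------------------------------------
# baselines


def random_model_baseline(
    table: CohortTable, cv: CVConfig, p: int = 13, n_models: int = 100,
    pool: list[str] | None = None, seed: int = 0,
) -> pd.DataFrame:
    """Concordance distribution of random p-variable models.

    ``pool`` restricts eligible variables (e.g. to the top of the
    univariate ranking); sampling is without replacement within a model.
    """
    pool = list(pool or table.variable_names)
    if len(pool) < p:
        raise ValueError("pool smaller than model size")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    models = [sorted(rng.choice(pool, size=p, replace=False)) for _ in range(n_models)]
    results = cv_evaluate_many(table, models, cv)
    return pd.DataFrame({
        "model": [", ".join(m) for m in models],
        "mean_C": [r.C_mean for r in results],
        "n_failed_trials": [r.n_failed_trials for r in results],
    })


# ---------------------------------------------------------------------------
# survivor outcomes


def _compact_letters(names: list[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: groups sharing a letter are not significantly
    different (insertion algorithm over the significant-difference pairs)."""
    letters: list[set[str]] = [set(names)]
    for a, b in distinct:
        new = []
        for grp in letters:
            if a in grp and b in grp:
                new.append(grp - {a})
                new.append(grp - {b})
            else:
                new.append(grp)
        # absorb subsets
        letters = []
        for g in new:
            if not any(g < h or g == h for h in letters):
                letters = [h for h in letters if not h < g]
                letters.append(g)
    letters.sort(key=lambda g: [names.index(x) for x in sorted(g, key=names.index)][0])
    out = {nm: "" for nm in names}
    for i, g in enumerate(letters):
        ch = chr(ord("a") + i)
        for nm in g:
            out[nm] += ch
    return out


def survivor_outcome_anova(
    scores: RiskScoreSet, groups: np.ndarray, alpha: float = 0.05,
) -> dict:
    """One-way ANOVA of standardized risk scores across survivor outcome
    groups, with Tukey-Kramer post-hoc letters.

    ``groups`` is an ordinal/categorical grouping of the scored subjects
    (NaN / None entries are dropped).  Returns F, p, per-group means and a
    compact letter display at ``alpha``.
    """
    from scipy.stats import f_oneway
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    g = pd.Series(groups)
    s = pd.Series(scores.standardized_score)
    keep = g.notna() & s.notna()
    g, s = g[keep], s[keep]
    level_names = [str(x) for x in sorted(g.unique())]
    if len(level_names) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    samples = [s[g == lv].to_numpy() for lv in sorted(g.unique())]
    if any(len(x) < 2 for x in samples):
        raise ValueError("every group needs n >= 2")
    F, p = f_oneway(*samples)
    tuk = pairwise_tukeyhsd(s.to_numpy(), g.astype(str).to_numpy(), alpha=alpha)
    distinct = {
        (str(a), str(b))
        for (a, b), rej in zip(
            [(r[0], r[1]) for r in tuk.summary().data[1:]], tuk.reject)
        if rej
    }
    letters = _compact_letters(level_names, distinct)
    means = {lv: float(np.mean(x)) for lv, x in zip(level_names, samples)}
    return {"F": float(F), "p": float(p), "group_means": means,
            "letters": letters, "n_per_group": {lv: len(x) for lv, x in zip(level_names, samples)}}
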