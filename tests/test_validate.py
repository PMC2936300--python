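"""LOOCV scoring, KM splits, cause-specific and cross-cause validation,
deficit index, baselines, and survivor-outcome ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr, ttest_ind

from agemine.config import CategoricalCensus, CVConfig
from agemine.metrics import fit_cox
from agemine.synthetic import generate_cohort
from agemine.validate import (DeficitRule, RiskScoreSet,
                              cause_specific_hazards, cross_cause_validation,
                              default_deficit_rules, deficit_index,
                              loocv_scores, median_split_km,
                              random_model_baseline, survivor_outcome_anova)

from conftest import small_config


@pytest.fixture(scope="module")
def informative_cohort():
    cfg = small_config(n_subjects=900, seed=47)
    return generate_cohort(cfg, return_truth=True)


@pytest.fixture(scope="module")
def big_null_cohort():
    """Full-size cohort with no predictor-outcome association; large n keeps
    the leave-one-out influence artifact negligible."""
    cfg = small_config(n_subjects=4097, n_continuous=6, n_ordinal=0,
                       categorical_census=CategoricalCensus(2, 0, 0),
                       n_informative=0, n_heavy_tailed=0, n_high_missing=0,
                       true_betas={}, latent_hazard_coef=0.0,
                       survivor_outcomes=False, seed=53)
    return generate_cohort(cfg)


@pytest.fixture(scope="module")
def big_shared_cohort():
    """Full-size cohort with 13 informative variables of strong effect.

    Cross-cause sets contain deceased subjects only, and conditioning on
    death within the 20-year follow-up removes most score-time association
    (default-strength effects leave the true score at C ~ 0.53-0.55
    there), so this detection fixture uses deliberately strong effects
    (|log HR| = 0.35 per SD) to give the permutation test decisive power."""
    cfg = small_config(n_subjects=4097, n_continuous=16, n_ordinal=0,
                       categorical_census=CategoricalCensus(2, 0, 0),
                       n_informative=13, n_heavy_tailed=0, n_high_missing=0,
                       true_betas={f"cont_{i:03d}": 0.35 for i in range(1, 14)},
                       survivor_outcomes=False, seed=59)
    return generate_cohort(cfg, return_truth=True)


@pytest.fixture(scope="module")
def informative_scores(informative_cohort):
    table, truth = informative_cohort
    return loocv_scores(table, sorted(truth.true_betas))


def test_loocv_standardization_and_duplicates(informative_scores,
                                              informative_cohort):
    scores = informative_scores
    ok = ~scores.failed
    assert abs(scores.standardized_score[ok].mean()) < 1e-8
    assert abs(scores.standardized_score[ok].std() - 1) < 1e-6
    # scores correlate with the truth: deceased score higher than survivors
    table, _ = informative_cohort
    dead = table.event == 1
    assert scores.standardized_score[dead].mean() > \
        scores.standardized_score[~dead].mean() + 0.2


def test_loocv_null_cohort_uncorrelated(big_null_cohort):
    scores = loocv_scores(big_null_cohort, ["cont_001", "cont_002"])
    rho, _ = spearmanr(scores.standardized_score, big_null_cohort.time_years)
    assert abs(rho) < 0.05


def test_median_split_sizes_and_separation(informative_scores,
                                           informative_cohort):
    table, _ = informative_cohort
    res = median_split_km(informative_scores, table)
    assert abs(res["n_high"] - res["n_low"]) <= 1
    assert res["logrank_p"] < 0.001
    # cause subset: deaths of other causes censored, separation persists
    sub = median_split_km(informative_scores, table, cause="cancer")
    assert sub["logrank_p"] < 0.05


def test_median_split_null(big_null_cohort):
    """Scores independent of survival give no group separation."""
    rng = np.random.default_rng(61)
    s = rng.normal(size=len(big_null_cohort))
    scores = RiskScoreSet(raw_score=s, standardized_score=(s - s.mean()) / s.std(),
                          failed=np.zeros(len(s), dtype=bool))
    res = median_split_km(scores, big_null_cohort)
    assert res["logrank_p"] > 0.001


def test_cause_specific_pooled_equals_all_documented(informative_cohort):
    table, truth = informative_cohort
    v = sorted(truth.true_betas)[0]
    pooled = cause_specific_hazards(table, v, cause=None)
    # censoring convention: pooled documented causes == all-cause events
    all_events = fit_cox(table, [v])
    assert pooled["hr"] == pytest.approx(float(np.exp(all_events.beta[0])),
                                         rel=1e-6)


def test_cause_specific_shared_effect_agrees_across_causes(informative_cohort):
    table, truth = informative_cohort
    v = sorted(truth.true_betas)[0]  # effect identical across causes
    rows = [cause_specific_hazards(table, v, c)
            for c in ("cardiovascular", "cancer", "other")]
    for a in rows:
        for b in rows:
            assert a["hr_lo95"] <= b["hr_hi95"] and b["hr_lo95"] <= a["hr_hi95"]


def test_cross_cause_shared_signal_significant(big_shared_cohort):
    table, truth = big_shared_cohort
    results = [
        cross_cause_validation(table, sorted(truth.true_betas), a, b,
                               n_perm=300, seed=1)
        for a, b in (("cardiovascular", "cancer"), ("cancer", "other"),
                     ("other", "cardiovascular"))
    ]
    assert all(r["C_obs"] > 0.5 for r in results)
    assert min(r["p"] for r in results) < 0.05
    assert sum(r["p"] < 0.10 for r in results) >= 2
    for r in results:
        assert 0.45 < np.mean(r["null_C"]) < 0.55


def test_cross_cause_negative_control(null_cohort):
    res = cross_cause_validation(null_cohort, ["cont_001", "cont_002"],
                                 "cancer", "other", n_perm=200, seed=2)
    assert res["p"] > 0.05


def test_cross_cause_requires_distinct_causes(informative_cohort):
    table, truth = informative_cohort
    with pytest.raises(ValueError):
        cross_cause_validation(table, sorted(truth.true_betas),
                               "cancer", "cancer", n_perm=10)


# ---------------------------------------------------------------------------
# deficit index


def test_deficit_index_denominator_rule():
    n = 1
    cols = {f"d{i}": np.zeros(1) for i in range(12)}
    for i in range(3):
        cols[f"d{i}"] = np.ones(1)
    cols["d10"][0] = np.nan
    cols["d11"][0] = np.nan
    df = pd.DataFrame(cols)
    from agemine.cohort import CohortTable, VariableMeta
    meta = [VariableMeta(c, "continuous") for c in df.columns]
    table = CohortTable(df, np.ones(1), np.ones(1, dtype=int),
                        np.array(["other"], dtype=object), meta)
    rules = [DeficitRule(c, "ge", 0.5) for c in df.columns]
    d = deficit_index(table, rules)
    assert d.n_deficits_evaluated[0] == 10
    assert d.proportion_present[0] == pytest.approx(0.3)
    # all absent -> 0
    zero_table = CohortTable(pd.DataFrame({c: np.zeros(1) for c in df.columns}),
                             np.ones(1), np.ones(1, dtype=int),
                             np.array(["other"], dtype=object), meta)
    assert deficit_index(zero_table, rules).proportion_present[0] == 0.0


def test_deficit_index_requires_enough_rules(informative_cohort):
    table, _ = informative_cohort
    with pytest.raises(ValueError):
        deficit_index(table, default_deficit_rules(table)[:5])


def test_deficit_index_beats_chance_but_not_model(informative_cohort):
    table, truth = informative_cohort
    d = deficit_index(table, default_deficit_rules(table))
    tmp = table.copy()
    tmp.predictors["deficit_index"] = d.proportion_present
    tmp.metadata = pd.concat([tmp.metadata, pd.DataFrame([{
        "name": "deficit_index", "var_class": "continuous", "n_levels": None,
        "missing_fraction": 0.0, "log_transformed": False,
        "source_var": None, "level": None}])], ignore_index=True)
    cv = CVConfig(n_trials=80, master_seed=3)
    from agemine.metrics import cv_evaluate
    d_res = cv_evaluate(tmp, ["deficit_index"], cv)
    m_res = cv_evaluate(table, sorted(truth.true_betas), cv)
    assert d_res.C_mean > 0.5
    assert d_res.C_mean < m_res.C_mean


# ---------------------------------------------------------------------------
# random baseline


def test_random_baseline_degenerate_and_dominance(informative_cohort):
    table, truth = informative_cohort
    p_all = len(table.variable_names)
    cv = CVConfig(n_trials=10, master_seed=5)
    deg = random_model_baseline(table, cv, p=p_all, n_models=3, seed=0)
    assert deg["model"].nunique() == 1
    with pytest.raises(ValueError):
        random_model_baseline(table, cv, p=p_all + 1, n_models=1)
    # the true model beats the random-model distribution's upper tail
    base = random_model_baseline(table, CVConfig(n_trials=30, master_seed=6),
                                 p=5, n_models=25, seed=1)
    from agemine.metrics import cv_evaluate
    true_C = cv_evaluate(table, sorted(truth.true_betas),
                         CVConfig(n_trials=30, master_seed=6)).C_mean
    assert true_C > base["mean_C"].quantile(0.9)


# ---------------------------------------------------------------------------
# survivor-outcome ANOVA


def test_anova_two_groups_equals_squared_t():
    rng = np.random.default_rng(9)
    s = rng.normal(size=120)
    g = np.repeat([0, 1], 60)
    scores = RiskScoreSet(raw_score=s, standardized_score=(s - s.mean()) / s.std(),
                          failed=np.zeros(120, dtype=bool))
    res = survivor_outcome_anova(scores, g)
    t, p = ttest_ind(scores.standardized_score[g == 0],
                     scores.standardized_score[g == 1])
    assert res["F"] == pytest.approx(t ** 2, rel=1e-9)
    assert res["p"] == pytest.approx(p, rel=1e-9)


def test_anova_detects_latent_linked_outcomes(informative_cohort,
                                              informative_scores):
    """Survivors' cognitive-style outcome groups order the risk scores."""
    table, _ = informative_cohort
    alive = table.cause == "alive"
    mmse = table.outcomes["outcome_mmse"].to_numpy()
    groups = np.full(len(table), np.nan)
    bins = np.nanquantile(mmse[alive], [0.25, 0.5, 0.75])
    groups[alive] = np.digitize(mmse[alive], bins)
    res = survivor_outcome_anova(informative_scores, groups)
    assert res["p"] < 0.03
    means = [res["group_means"][k] for k in sorted(res["group_means"])]
    assert means[0] > means[-1]  # worse cognition <-> higher risk score
    assert set("".join(res["letters"].values())) <= set("abcdefgh")


def test_anova_rejects_single_group(informative_scores):
    with pytest.raises(ValueError):
        survivor_outcome_anova(informative_scores,
                               np.zeros(len(informative_scores)))
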