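"""Missingness filter, Grubbs/log transform, coding, MCA, kNN imputation."""

import numpy as np
import pandas as pd
import pytest

from agemine.cohort import CohortTable, VariableMeta
from agemine.config import CategoricalCensus
from agemine.preprocess import (encode_categoricals, filter_by_missingness,
                                grubbs_statistic, knn_impute, mca_coordinates,
                                preprocess_pipeline, select_log_transform)
from agemine.synthetic import generate_cohort, inject_missingness

from conftest import small_config


def _table(columns: dict, classes: dict, n_levels: dict | None = None):
    df = pd.DataFrame(columns)
    n = len(df)
    meta = [VariableMeta(c, classes[c], n_levels=(n_levels or {}).get(c))
            for c in df.columns]
    return CohortTable(df, np.linspace(1, 10, n), np.ones(n, dtype=int),
                       np.array(["other"] * n, dtype=object), meta)


# ---------------------------------------------------------------------------
# missingness filter


def test_filter_counts():
    rng = np.random.default_rng(0)
    cols = {}
    for i in range(10):
        x = rng.normal(size=100)
        if i < 2:
            x[:6] = np.nan  # 6% missing -> excluded at the 5% threshold
        cols[f"v{i}"] = x
    table = _table(cols, {f"v{i}": "continuous" for i in range(10)})
    out, rep = filter_by_missingness(table, 0.05)
    assert len(out.variable_names) == 8
    assert set(rep.excluded_variables) == {"v0", "v1"}
    assert all(f > 0.05 for f in rep.excluded_variables.values())


def test_filter_identity_without_missing(small_cohort):
    table, _ = small_cohort
    out, rep = filter_by_missingness(table, 0.05)
    assert out.variable_names == table.variable_names
    assert not rep.excluded_variables


def test_filter_default_cohort_restores_configured_census(small_cohort_missing):
    table, cfg = small_cohort_missing
    out, _ = filter_by_missingness(table, 0.05)
    census = out.metadata["var_class"].value_counts()
    assert census["continuous"] == cfg.n_continuous
    assert census["ordinal"] == cfg.n_ordinal
    assert census["categorical"] == cfg.categorical_census.n_variables


# ---------------------------------------------------------------------------
# Grubbs / log transform


def test_grubbs_hand_computations():
    G, p = grubbs_statistic([1, 1, 1, 10])
    assert G == pytest.approx(1.5)
    G, _ = grubbs_statistic([-1, 0, 1])
    assert G == pytest.approx(1.0)
    with pytest.raises(ValueError):
        grubbs_statistic([2.0, 2.0, 2.0])
    with pytest.raises(ValueError):
        grubbs_statistic([1.0, 2.0])


def test_grubbs_null_calibration():
    """Clean Gaussian samples essentially never hit the 1e-3 threshold."""
    rng = np.random.default_rng(1)
    hits = sum(grubbs_statistic(rng.normal(size=1000))[1] < 1e-3
               for _ in range(60))
    assert hits <= 1


def test_log_transform_shift_rule_and_null():
    rng = np.random.default_rng(2)
    heavy = np.exp(rng.normal(size=300)) - 1.0  # min <= 0: shift = 1 - min
    gauss = rng.normal(size=300)
    table = _table({"heavy": heavy, "gauss": gauss},
                   {"heavy": "continuous", "gauss": "continuous"})
    out, rep = select_log_transform(table)
    assert "heavy" in rep.log_transformed
    assert "gauss" not in rep.log_transformed
    shift = 1.0 - heavy.min()
    np.testing.assert_allclose(out.predictors["heavy"], np.log(heavy + shift))
    # flagged in metadata and skipped on re-run
    out2, rep2 = select_log_transform(out)
    assert not rep2.log_transformed
    assert out2.predictors.equals(out.predictors)


def test_log_transform_detects_planted_heavy_tails(small_cohort):
    table, _ = small_cohort
    _, rep = select_log_transform(table)
    planted = {f"cont_{i:03d}" for i in (10, 11, 12)}  # lognormal-shaped
    assert planted <= set(rep.log_transformed)


# ---------------------------------------------------------------------------
# indicator coding


def test_encode_three_class_one_hot():
    x = np.array([0, 1, 2, 1, 0, 2.0])
    table = _table({"c": x}, {"c": "categorical"}, {"c": 3})
    out, rep = encode_categoricals(table)
    assert rep.indicator_map["c"] == ["c=0", "c=1", "c=2"]
    block = out.predictors[["c=0", "c=1", "c=2"]].to_numpy()
    np.testing.assert_allclose(block.sum(axis=1), 1.0)
    assert np.all((block == 0) | (block == 1))


def test_encode_binary_single_indicator_and_census():
    cfg = small_config()
    table = generate_cohort(cfg)
    out, rep = encode_categoricals(table)
    census = cfg.categorical_census
    n_ind = (out.metadata["var_class"] == "indicator").sum()
    assert n_ind == census.n_indicators
    # binary variables keep a single column under their own name
    assert "cat_001" in out.variable_names
    assert set(out.predictors["cat_001"].unique()) <= {0.0, 1.0}


def test_encode_missing_cell_blanks_whole_block():
    x = np.array([0, 1, 2, np.nan, 0.0])
    table = _table({"c": x}, {"c": "categorical"}, {"c": 3})
    out, _ = encode_categoricals(table)
    assert out.predictors.loc[3, ["c=0", "c=1", "c=2"]].isna().all()


# ---------------------------------------------------------------------------
# MCA


def test_mca_perfectly_correlated_binaries():
    rng = np.random.default_rng(3)
    a = rng.integers(0, 2, size=200).astype(float)
    table = _table({"a": a, "b": a.copy()},
                   {"a": "categorical", "b": "categorical"},
                   {"a": 2, "b": 2})
    coords, retained = mca_coordinates(table, n_dims=1)
    assert retained > 0.99
    g0 = coords[a == 0, 0]
    g1 = coords[a == 1, 0]
    assert np.sign(g0.mean()) == -np.sign(g1.mean())
    assert np.allclose(g0.std(), 0) and np.allclose(g1.std(), 0)


def test_mca_independent_binaries_spread_inertia():
    rng = np.random.default_rng(4)
    cols = {f"b{i}": rng.integers(0, 2, size=4000).astype(float)
            for i in range(6)}
    table = _table(cols, {k: "categorical" for k in cols}, {k: 2 for k in cols})
    _, r1 = mca_coordinates(table, n_dims=1)
    # 6 independent balanced binaries: 6 non-null dimensions of ~equal
    # inertia -> each dimension holds ~1/6 of the total
    assert r1 == pytest.approx(1 / 6, abs=0.03)


def test_mca_ndims_bound():
    rng = np.random.default_rng(5)
    a = rng.integers(0, 2, size=50).astype(float)
    table = _table({"a": a}, {"a": "categorical"}, {"a": 2})
    with pytest.raises(ValueError):
        mca_coordinates(table, n_dims=5)


# ---------------------------------------------------------------------------
# kNN imputation


def test_knn_imputes_shared_value_among_identical_subjects():
    n = 21
    cols = {"x": np.full(n, 3.7), "y": np.arange(n, dtype=float)}
    cols["x"][0] = np.nan
    table = _table(cols, {"x": "continuous", "y": "continuous"})
    out, rep = knn_impute(table, k=20)
    assert out.predictors.loc[0, "x"] == pytest.approx(3.7)
    assert rep.imputed_cell_count == 1


def test_knn_binary_mode_and_block_sum():
    rng = np.random.default_rng(6)
    n = 45
    # subjects 1..25 are near subject 0 in feature space and all carry b=1;
    # subjects 26.. are far away and carry b=0
    z = np.concatenate([np.zeros(26), np.full(n - 26, 100.0)])
    z += rng.normal(scale=0.01, size=n)
    b = np.concatenate([[np.nan], np.ones(25), np.zeros(n - 26)])
    c = rng.integers(0, 3, size=n).astype(float)
    c[1] = np.nan
    table = _table({"b": b, "c": c, "z": z},
                   {"b": "categorical", "c": "categorical", "z": "continuous"},
                   {"b": 2, "c": 3})
    enc, _ = encode_categoricals(table)
    out, _ = knn_impute(enc, k=20)
    assert out.predictors.loc[0, "b"] == 1.0  # all 20 neighbors carry 1
    block = out.predictors[["c=0", "c=1", "c=2"]].to_numpy()
    np.testing.assert_allclose(block.sum(axis=1), 1.0)


def test_knn_beats_column_mean_on_correlated_cohort():
    # strong shared structure (latent R^2 = 0.64) so neighborhoods carry
    # real information about a subject's missing coordinates
    cfg = small_config(n_subjects=600, latent_loading=0.8, seed=17)
    complete = generate_cohort(cfg)
    enc, _ = encode_categoricals(complete)
    rng = np.random.default_rng(8)
    pred = enc.predictors.copy()
    cont = enc.variables_of_class("continuous")
    mask = rng.uniform(size=(len(pred), len(cont))) < 0.01
    truth_vals = pred[cont].to_numpy().copy()
    M = pred[cont].to_numpy()
    M[mask] = np.nan
    pred[cont] = M
    holed = enc.replace(predictors=pred)
    out, _ = knn_impute(holed, k=20)
    got = out.predictors[cont].to_numpy()
    err_knn = np.abs(got[mask] - truth_vals[mask]).mean()
    col_mean = np.nanmean(M, axis=0)
    err_mean = np.abs(np.broadcast_to(col_mean, M.shape)[mask]
                      - truth_vals[mask]).mean()
    assert err_knn < err_mean
    # imputed continuous cells stay inside the observed range of their column
    lo, hi = np.nanmin(M, axis=0), np.nanmax(M, axis=0)
    rows, cols = np.where(mask)
    assert np.all(got[mask] >= lo[cols]) and np.all(got[mask] <= hi[cols])


def test_pipeline_output_complete_and_on_scale(small_cohort_missing):
    table, cfg = small_cohort_missing
    out, rep = preprocess_pipeline(table)
    assert not out.predictors.isna().any().any()
    # ordinal columns stay on the observed integer scale
    for v in out.variables_of_class("ordinal"):
        assert set(np.unique(out.predictors[v])) <= set(range(cfg.ordinal_levels))
    # indicator blocks sum to one per subject
    ind = out.metadata[out.metadata["var_class"] == "indicator"]
    for src, grp in ind.groupby("source_var"):
        cols = list(grp["name"])
        if len(cols) > 1:
            np.testing.assert_allclose(
                out.predictors[cols].sum(axis=1).to_numpy(), 1.0)


def test_pipeline_idempotent(small_cohort_missing):
    table, _ = small_cohort_missing
    once, rep1 = preprocess_pipeline(table)
    twice, rep2 = preprocess_pipeline(once)
    assert twice.predictors.equals(once.predictors)
    assert not rep2.excluded_variables
    assert not rep2.log_transformed
    assert rep2.imputed_cell_count == 0
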