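"""Mixed-type preprocessing: missingness filter, outlier-driven log
transform, indicator coding, multiple correspondence analysis, and
k-nearest-neighbor imputation.

Pipeline order is fixed:

    missingness filter -> Grubbs/log transform -> indicator coding
        -> MCA coordinates -> kNN imputation

and re-running the pipeline on its own output is a no-op (variables already
excluded stay excluded, transformed variables carry a ``log_transformed``
flag and are not re-tested, categorical variables are already coded, and no
missing cells remain).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable, VariableMeta


@dataclass
class PreprocessReport:
    """Record of everything each preprocessing stage did."""

    excluded_variables: dict[str, float] = field(default_factory=dict)
    log_transformed: dict[str, float] = field(default_factory=dict)  # name -> Grubbs p
    indicator_map: dict[str, list[str]] = field(default_factory=dict)
    mca_inertia_retained: float | None = None
    imputed_cell_count: int = 0
    skipped: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(vars(self), fh, indent=2, default=float)


# ---------------------------------------------------------------------------
# stage 1: missingness filter


def filter_by_missingness(
    table: CohortTable, threshold: float = 0.05,
    report: PreprocessReport | None = None,
) -> tuple[CohortTable, PreprocessReport]:
    """Drop predictors whose missing fraction strictly exceeds ``threshold``."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    if table.n_subjects == 0:
        raise ValueError("empty table")
    report = report or PreprocessReport()
    frac = table.predictors.isna().mean()
    drop = list(frac.index[frac > threshold])
    for name in drop:
        report.excluded_variables[name] = float(frac[name])
    keep = [c for c in table.predictors.columns if c not in drop]
    meta = table.metadata[table.metadata["name"].isin(keep)].copy()
    meta["missing_fraction"] = meta["name"].map(frac).astype(float)
    return table.replace(predictors=table.predictors[keep], metadata=meta), report


# ---------------------------------------------------------------------------
# stage 2: Grubbs outlier test and log transform


def grubbs_statistic(x) -> tuple[float, float]:
    """Two-sided single-outlier Grubbs test.

    G = max_i |x_i - mean| / sd (sd with n-1 denominator); the p-value comes
    from the classical t-distribution relation for the critical value.
    Missing values are dropped first.  Raises on n < 3 or a constant vector.
    """
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    n = len(x)
    if n < 3:
        raise ValueError("Grubbs test needs at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("Grubbs statistic undefined for a constant vector")
    G = float(np.max(np.abs(x - x.mean())) / sd)
    # invert G = (n-1)/sqrt(n) * sqrt(t^2 / (n-2+t^2)) for the t quantile
    denom = (n - 1) ** 2 - n * G ** 2
    if denom <= 0:
        return G, 0.0
    t = np.sqrt(n * (n - 2) * G ** 2 / denom)
    p = float(min(1.0, 2 * n * stats.t.sf(t, n - 2)))
    return G, p


def select_log_transform(
    table: CohortTable, alpha: float = 1e-3,
    report: PreprocessReport | None = None,
) -> tuple[CohortTable, PreprocessReport]:
    """Log-transform continuous variables with strong outlier evidence.

    Variables with Grubbs p < ``alpha`` are replaced by ``log(x + shift)``
    with shift 0 when min > 0, else ``1 - min``.  Variables already flagged
    ``log_transformed`` are skipped (idempotency); constant or too-short
    vectors are skipped with a log entry.
    """
    report = report or PreprocessReport()
    pred = table.predictors.copy()
    meta = table.metadata.copy()
    flagged = set(meta.loc[meta["log_transformed"].astype(bool), "name"])
    for name in table.variables_of_class("continuous"):
        if name in flagged:
            continue
        x = pred[name].to_numpy(dtype=float)
        try:
            _, p = grubbs_statistic(x)
        except ValueError as err:
            report.skipped.append(f"{name}: {err}")
            continue
        if p < alpha:
            obs_min = np.nanmin(x)
            shift = 0.0 if obs_min > 0 else 1.0 - obs_min
            pred[name] = np.log(x + shift)
            meta.loc[meta["name"] == name, "log_transformed"] = True
            report.log_transformed[name] = float(p)
    return table.replace(predictors=pred, metadata=meta), report


# ---------------------------------------------------------------------------
# stage 3: indicator coding


def encode_categoricals(
    table: CohortTable, report: PreprocessReport | None = None,
) -> tuple[CohortTable, PreprocessReport]:
    """One-hot code categorical variables; leave ordinals as integer scores.

    Two-class variables become a single 0/1 indicator (keeping their name);
    n > 2-class variables become n indicators, one per class (full,
    deliberately redundant coding — downstream variable selection is
    expected to pick a non-redundant subset).  A missing categorical cell
    yields NaN across the variable's whole indicator block.
    """
    report = report or PreprocessReport()
    new_cols: dict[str, np.ndarray] = {}
    new_meta: list[dict] = []
    for _, m in table.metadata.iterrows():
        name = m["name"]
        x = table.predictors[name].to_numpy(dtype=float)
        if m["var_class"] != "categorical":
            new_cols[name] = x
            new_meta.append(dict(m))
            continue
        levels = np.unique(x[~np.isnan(x)])
        if len(levels) <= 1:
            report.skipped.append(f"{name}: single observed level, not coded")
            continue
        if len(levels) == 2:
            ind = np.where(np.isnan(x), np.nan, (x == levels[1]).astype(float))
            new_cols[name] = ind
            new_meta.append(dict(
                name=name, var_class="indicator", n_levels=2,
                missing_fraction=m["missing_fraction"], log_transformed=False,
                source_var=name, level=str(levels[1]),
            ))
            report.indicator_map[name] = [name]
        else:
            made = []
            for lev in levels:
                col = f"{name}={lev:g}"
                new_cols[col] = np.where(np.isnan(x), np.nan,
                                         (x == lev).astype(float))
                new_meta.append(dict(
                    name=col, var_class="indicator", n_levels=2,
                    missing_fraction=m["missing_fraction"],
                    log_transformed=False, source_var=name, level=f"{lev:g}",
                ))
                made.append(col)
            report.indicator_map[name] = made
    pred = pd.DataFrame(new_cols)
    meta = pd.DataFrame(new_meta)
    return table.replace(predictors=pred, metadata=meta), report


# ---------------------------------------------------------------------------
# stage 4: multiple correspondence analysis


def _disjunctive_matrix(table: CohortTable) -> tuple[np.ndarray, list[str]]:
    """Complete disjunctive (full one-hot) matrix over the categorical block.

    Works both before coding (var_class == categorical) and after
    (indicator columns grouped by source variable; single-indicator binary
    variables are expanded back to two complementary columns).  Missing
    cells are replaced by the variable's mean profile (observed level
    frequencies), the standard passive treatment for coordinates.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    meta = table.metadata
    cat_vars = meta.loc[meta["var_class"] == "categorical", "name"]
    if len(cat_vars):
        for name in cat_vars:
            x = table.predictors[name].to_numpy(dtype=float)
            levels = np.unique(x[~np.isnan(x)])
            Z = (x[:, None] == levels[None, :]).astype(float)
            miss = np.isnan(x)
            if miss.any():
                Z[miss] = Z[~miss].mean(axis=0)
            blocks.append(Z)
            names.extend(f"{name}={lev:g}" for lev in levels)
    else:
        ind = meta[meta["var_class"] == "indicator"]
        for source, grp in ind.groupby("source_var", sort=False):
            cols = list(grp["name"])
            Z1 = table.predictors[cols].to_numpy(dtype=float)
            if Z1.shape[1] == 1:  # binary coded as one indicator: expand
                Z = np.hstack([1.0 - Z1, Z1])
                names.extend([f"{source}=neg", f"{source}=pos"])
            else:
                Z = Z1
                names.extend(cols)
            miss = np.isnan(Z).any(axis=1)
            if miss.any():
                Z = Z.copy()
                Z[miss] = Z[~miss].mean(axis=0)
            blocks.append(Z)
    if not blocks:
        raise ValueError("no categorical variables for MCA")
    return np.hstack(blocks), names


def _mca_svd(table: CohortTable):
    Z, _ = _disjunctive_matrix(table)
    total = Z.sum()
    P = Z / total
    r = P.sum(axis=1)  # equal when every variable is answered
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, _ = np.linalg.svd(S, full_matrices=False)
    keep = sv > 1e-12  # drop null dimensions (rank <= J - Q)
    return U[:, keep], sv[keep], r


def mca_coordinates(
    table: CohortTable, n_dims: int = 8, clamp: bool = False,
) -> tuple[np.ndarray, float]:
    """Subject standard coordinates from MCA of the categorical block.

    Returns ``(coords, inertia_retained)`` where coords is (n_subjects,
    n_dims) and inertia_retained is the proportion of total indicator-matrix
    inertia carried by the first ``n_dims`` dimensions.  ``clamp`` reduces
    ``n_dims`` to the available rank instead of raising.
    """
    U, sv, r = _mca_svd(table)
    if n_dims > len(sv):
        if not clamp:
            raise ValueError(
                f"n_dims={n_dims} exceeds available dimensions {len(sv)}")
        n_dims = len(sv)
    inertia = sv ** 2
    retained = float(inertia[:n_dims].sum() / inertia.sum())
    coords = (U[:, :n_dims] / np.sqrt(r)[:, None])
    return coords, retained


# ---------------------------------------------------------------------------
# stage 5: kNN imputation


def knn_impute(
    table: CohortTable, k: int = 20, mca_dims: int = 8,
    report: PreprocessReport | None = None,
) -> tuple[CohortTable, PreprocessReport]:
    """Impute missing cells from each subject's k nearest neighbors.

    Distance: Euclidean over z-scored continuous + ordinal columns
    concatenated with the MCA standard coordinates (categoricals enter the
    metric only through MCA).  Rows with missing entries use
    pairwise-complete distances (scaled by the fraction of comparable
    coordinates).  Imputed values: neighbor mean (continuous), lower
    neighbor median (ordinal), neighbor mode (categorical indicator blocks,
    ties to the smallest level) — so indicator blocks still sum to one.
    Equidistant neighbors are broken deterministically by subject index.
    """
    from sklearn.metrics.pairwise import nan_euclidean_distances

    report = report or PreprocessReport()
    n = table.n_subjects
    if not 0 < k < n:
        raise ValueError("k must be in [1, n_subjects)")
    pred = table.predictors.copy()
    meta = table.metadata
    cont = table.variables_of_class("continuous")
    ordi = table.variables_of_class("ordinal")
    ind_meta = meta[meta["var_class"] == "indicator"]
    blocks = {s: list(g["name"]) for s, g in ind_meta.groupby("source_var", sort=False)}

    numeric = pred[cont + ordi].to_numpy(dtype=float)
    mu = np.nanmean(numeric, axis=0)
    sd = np.nanstd(numeric, axis=0)
    sd[sd == 0] = 1.0
    F = (numeric - mu) / sd
    if blocks:
        coords, _ = mca_coordinates(table, n_dims=mca_dims, clamp=True)
        F = np.hstack([F, coords])

    na = pred.isna()
    need = np.flatnonzero(na.any(axis=1).to_numpy())
    all_missing = np.flatnonzero(na.all(axis=1).to_numpy())
    if len(all_missing):
        raise ValueError(f"subjects with all predictors missing: {all_missing[:5]}")
    if len(need) == 0:
        return table, report

    D = nan_euclidean_distances(F[need], F)
    D[np.arange(len(need)), need] = np.inf  # exclude self
    D = np.nan_to_num(D, nan=np.inf)       # no comparable coordinates at all
    # k smallest, deterministic tie-break by subject index
    idx = np.argsort(D, axis=1, kind="stable")[:, :k]

    class_of = dict(zip(meta["name"], meta["var_class"]))
    pos_of = {c: i for i, c in enumerate(pred.columns)}
    V = pred.to_numpy(dtype=float)  # impute in-place on the array
    na_arr = na.to_numpy()
    col_means = np.nanmean(V, axis=0)

    imputed = 0
    for row_i, subj in enumerate(need):
        nb = idx[row_i]
        for j in np.flatnonzero(na_arr[subj]):
            col = pred.columns[j]
            cls = class_of[col]
            if cls == "indicator":
                continue  # handled block-wise below
            vals = V[nb, j]
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                fill = float(col_means[j])
            elif cls == "ordinal":
                fill = float(np.sort(vals)[(len(vals) - 1) // 2])  # lower median
            else:
                fill = float(vals.mean())
            V[subj, j] = fill
            imputed += 1
        # categorical blocks: neighbor modal level
        for source, cols in blocks.items():
            jj = [pos_of[c] for c in cols]
            miss = na_arr[subj, jj]
            if not miss.any():
                continue
            B = V[np.ix_(nb, jj)]
            ok = ~np.isnan(B).any(axis=1)
            if len(cols) == 1:  # binary single indicator: mode of 0/1
                vals = B[ok, 0]
                V[subj, jj[0]] = 1.0 if vals.sum() > len(vals) / 2 else 0.0
            else:
                counts = B[ok].sum(axis=0)
                win = int(np.argmax(counts))  # argmax ties to smallest level
                V[subj, jj] = 0.0
                V[subj, jj[win]] = 1.0
            imputed += int(miss.sum())
    report.imputed_cell_count += imputed
    pred = pd.DataFrame(V, columns=pred.columns)
    return table.replace(predictors=pred), report


# ---------------------------------------------------------------------------
# the full pipeline


def preprocess_pipeline(
    table: CohortTable,
    missing_threshold: float = 0.05,
    grubbs_alpha: float = 1e-3,
    knn_k: int = 20,
    mca_dims: int = 8,
) -> tuple[CohortTable, PreprocessReport]:
    """Filter -> log-transform -> code -> MCA -> impute, with one report."""
    table, report = filter_by_missingness(table, missing_threshold)
    table, report = select_log_transform(table, grubbs_alpha, report)
    table, report = encode_categoricals(table, report)
    if (table.metadata["var_class"] == "indicator").any():
        _, retained = mca_coordinates(table, n_dims=mca_dims, clamp=True)
        report.mca_inertia_retained = retained
    table, report = knn_impute(table, k=knn_k, mca_dims=mca_dims, report=report)
    return table, report
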