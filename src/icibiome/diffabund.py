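"""Per-cohort differential-abundance effect estimation.

Each implemented ensemble member reports, per feature, an effect on its own
native scale with a standard error, so the meta-analysis layer can pool the
per-cohort estimates with a random-effects model — always within one method,
never across methods:

* ``smd`` — Hedges' g standardized mean difference on arcsine-square-root
  transformed relative abundances;
* ``bias_corrected_loglinear`` — a log-linear regression on reconstructed
  counts with an iteratively estimated sample-specific sampling-fraction
  offset and a median-based bias correction of the group coefficient;
* ``logit_tss_lm`` — ordinary least squares of logit-transformed,
  total-sum-scaled relative abundances on the group (plus covariates).

Two-tailed Wilcoxon rank-sum tests are estimated alongside for the consensus
panel's per-cohort cells; they carry no standard error and are not pooled.
Effect direction is always taken from the group-mean relative abundance
comparison (responder-up vs responder-down).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .tables import AbundanceTable
from .transforms import arcsine_sqrt

POOLED_METHODS = ("smd", "bias_corrected_loglinear", "logit_tss_lm")

EFFECT_COLUMNS = [
    "feature", "cohort", "method", "effect", "se", "ci_low", "ci_high", "p", "direction",
]


def _directions(table: AbundanceTable, labels: pd.Series) -> pd.Series:
    """responder_up / responder_down from mean relative abundances."""
    lab = labels.loc[table.data.index]
    mean_r = table.data[lab == 1].mean(axis=0)
    mean_nr = table.data[lab == 0].mean(axis=0)
    return pd.Series(
        np.where(mean_r >= mean_nr, "responder_up", "responder_down"),
        index=table.data.columns,
    )


def prevalence_mask(table: AbundanceTable, min_prevalence: float = 0.1) -> pd.Series:
    """Features detected in at least ``min_prevalence`` of the cohort's samples.

    Features below the gate are recorded as not estimable in that cohort
    (they appear as blank cells in the cross-cohort panel).
    """
    return (table.data > 0).mean(axis=0) >= min_prevalence


def _check_groups(labels: pd.Series) -> tuple[pd.Index, pd.Index]:
    r = labels.index[labels == 1]
    nr = labels.index[labels == 0]
    if len(r) == 0 or len(nr) == 0:
        raise ValueError("both responder and nonresponder groups must be nonempty")
    return r, nr


def wilcoxon_effect(table: AbundanceTable, labels: pd.Series) -> pd.DataFrame:
    """Two-tailed Wilcoxon rank-sum p per feature, with direction.

    Exact enumeration when the combined sample size is at most 20 and the
    feature is tie-free; otherwise the normal approximation with tie and
    continuity corrections.
    """
    labels = labels.loc[labels.index.intersection(table.data.index)]
    r_ids, nr_ids = _check_groups(labels)
    rows = []
    directions = _directions(table, labels)
    for feat in table.data.columns:
        x = table.data.loc[r_ids, feat].to_numpy()
        y = table.data.loc[nr_ids, feat].to_numpy()
        tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if (len(x) + len(y) <= 20 and tie_free) else "asymptotic"
        p = float(scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
        rows.append({"feature": feat, "cohort": table.cohort, "method": "wilcoxon",
                     "effect": np.nan, "se": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                     "p": min(p, 1.0), "direction": directions[feat]})
    return pd.DataFrame(rows, columns=EFFECT_COLUMNS)


def hedges_g(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Hedges' g and its variance for two samples (x = responders).

    g = J * (mean_x - mean_y) / s_pooled with J = 1 - 3/(4N - 9);
    var(g) = N/(n_x n_y) + g^2 / (2N).
    """
    nx, ny = len(x), len(y)
    n = nx + ny
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (n - 2)
    if sp2 == 0:
        return np.nan, np.nan
    j = 1.0 - 3.0 / (4.0 * n - 9.0)
    g = j * (np.mean(x) - np.mean(y)) / np.sqrt(sp2)
    var = n / (nx * ny) + g**2 / (2.0 * n)
    return float(g), float(var)


def smd_effect(table: AbundanceTable, labels: pd.Series) -> pd.DataFrame:
    """Hedges' g per feature on arcsine-sqrt transformed relative abundances."""
    labels = labels.loc[labels.index.intersection(table.data.index)]
    r_ids, nr_ids = _check_groups(labels)
    if len(r_ids) < 2 or len(nr_ids) < 2:
        raise ValueError("each group needs at least 2 samples for an SMD")
    transformed = pd.DataFrame(
        arcsine_sqrt(table), index=table.data.index, columns=table.data.columns
    )
    directions = _directions(table, labels)
    rows = []
    for feat in table.data.columns:
        g, var = hedges_g(
            transformed.loc[r_ids, feat].to_numpy(), transformed.loc[nr_ids, feat].to_numpy()
        )
        if np.isnan(g):
            # zero pooled variance: effect undefined, feature flagged via NaN
            rows.append({"feature": feat, "cohort": table.cohort, "method": "smd",
                         "effect": np.nan, "se": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan, "direction": directions[feat]})
            continue
        se = np.sqrt(var)
        z = g / se
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        rows.append({"feature": feat, "cohort": table.cohort, "method": "smd",
                     "effect": g, "se": se, "ci_low": g - 1.959963984540054 * se,
                     "ci_high": g + 1.959963984540054 * se, "p": max(min(p, 1.0), 5e-324),
                     "direction": directions[feat]})
    return pd.DataFrame(rows, columns=EFFECT_COLUMNS)


def _ols_per_feature(
    y: np.ndarray, x: np.ndarray, coef_idx: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized OLS of each column of y on design x; classical SE + t-test p
    for the coefficient at ``coef_idx``. Returns (beta, se, p)."""
    n, k = x.shape
    if n <= k:
        raise ValueError("more design columns than samples")
    xtx = x.T @ x
    if np.linalg.matrix_rank(xtx) < k:
        raise ValueError("rank-deficient design: aliased columns present")
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (x.T @ y)  # k x features
    resid = y - x @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[coef_idx, coef_idx])
    b = beta[coef_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, b / se, np.nan)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), dof)
    return b, se, p


def _covariate_design(covariates: pd.DataFrame | None, index: pd.Index) -> np.ndarray:
    if covariates is None or covariates.shape[1] == 0:
        return np.empty((len(index), 0))
    cov = covariates.loc[index]
    cols = []
    for name in cov.columns:
        col = cov[name]
        if pd.api.types.is_numeric_dtype(col):
            v = col.to_numpy(dtype=float)
            if np.isnan(v).any():
                raise ValueError(f"covariate {name!r} has missing values")
            cols.append(v - v.mean())
        else:
            codes, uniq = pd.factorize(col, sort=True)
            if (codes < 0).any():
                raise ValueError(f"covariate {name!r} has missing values")
            cols.extend(np.eye(len(uniq))[codes][:, 1:].T)
    return np.column_stack(cols) if cols else np.empty((len(index), 0))


def logit_tss_lm(
    table: AbundanceTable,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    eps: float = 1e-6,
) -> pd.DataFrame:
    """OLS of logit(total-sum-scaled abundance) on group (+ covariates).

    Relative abundances are re-closed per sample (total-sum scaling), squeezed
    into (eps, 1-eps) and logit transformed; the reported effect is the group
    coefficient with its classical standard error and t-test p value.
    """
    labels = labels.loc[labels.index.intersection(table.data.index)]
    _check_groups(labels)
    sub = AbundanceTable(table.data.loc[labels.index], table.level, table.cohort).renormalized()
    p = np.clip(sub.values, eps, 1.0 - eps)
    y = np.log(p / (1.0 - p))
    group = labels.to_numpy(dtype=float)
    x = np.column_stack(
        [np.ones(len(group)), group, _covariate_design(covariates, labels.index)]
    )
    b, se, pv = _ols_per_feature(y, x, coef_idx=1)
    directions = _directions(sub, labels)
    out = pd.DataFrame({
        "feature": sub.data.columns, "cohort": table.cohort, "method": "logit_tss_lm",
        "effect": b, "se": se, "ci_low": b - 1.959963984540054 * se,
        "ci_high": b + 1.959963984540054 * se, "p": np.clip(pv, 5e-324, 1.0),
        "direction": directions.values,
    })
    return out[EFFECT_COLUMNS]


def bias_corrected_loglinear(
    counts: pd.DataFrame,
    labels: pd.Series,
    covariates: pd.DataFrame | None = None,
    library_cutoff: int = 1000,
    cohort: str = "",
    tol: float = 1e-6,
    max_iter: int = 100,
) -> pd.DataFrame:
    """Bias-corrected log-linear differential abundance on reconstructed counts.

    Model: ``ln(count_ij + 1) = d_i + X_i beta_j + e_ij`` where ``d_i`` is a
    sample-specific sampling-fraction offset. ``d`` and the per-feature OLS
    coefficients are estimated by alternating updates until the offsets
    stabilize; the group coefficient is then bias-corrected by subtracting its
    across-feature median (most features are assumed null, so the median
    captures the residual sampling-fraction confounding). Inference is a
    normal z-test; samples with library size below ``library_cutoff`` are
    dropped. Non-convergence is flagged in the ``converged`` column.
    """
    labels = labels.loc[labels.index.intersection(counts.index)]
    keep = counts.loc[labels.index].sum(axis=1) >= library_cutoff
    labels = labels[keep[keep].index]
    r, nr = _check_groups(labels)
    del r, nr
    c = counts.loc[labels.index]
    y = np.log(c.to_numpy(dtype=float) + 1.0)
    group = labels.to_numpy(dtype=float)
    x = np.column_stack(
        [np.ones(len(group)), group, _covariate_design(covariates, labels.index)]
    )
    if x.shape[1] < 2:
        raise ValueError("design must include a group term beyond the intercept")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design: aliased columns present")

    xtx_inv = np.linalg.inv(x.T @ x)
    proj = xtx_inv @ x.T
    d = np.zeros(len(labels))
    converged = False
    for _ in range(max_iter):
        beta = proj @ (y - d[:, None])
        fitted = x @ beta
        d_new = (y - fitted).mean(axis=1)
        if np.abs(d_new - d).max() < tol:
            d = d_new
            converged = True
            break
        d = d_new

    beta = proj @ (y - d[:, None])
    resid = y - d[:, None] - x @ beta
    dof = len(labels) - x.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    b = beta[1] - np.median(beta[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, b / se, np.nan)
    p = np.clip(2.0 * scipy.stats.norm.sf(np.abs(z)), 5e-324, 1.0)

    rel = AbundanceTable(
        c.div(c.sum(axis=1).replace(0, np.nan), axis=0).fillna(0.0), cohort=cohort
    )
    directions = _directions(rel, labels)
    out = pd.DataFrame({
        "feature": c.columns, "cohort": cohort, "method": "bias_corrected_loglinear",
        "effect": b, "se": se, "ci_low": b - 1.959963984540054 * se,
        "ci_high": b + 1.959963984540054 * se, "p": p, "direction": directions.values,
    })
    out = out[EFFECT_COLUMNS]
    out["converged"] = converged
    return out


def cohort_effects(
    table: AbundanceTable,
    metadata,
    outcome: str = "orr",
    covariate_columns: list[str] | None = None,
    min_prevalence: float = 0.1,
    library_cutoff: int = 1000,
) -> pd.DataFrame:
    """All implemented methods for one cohort; long-format effect table.

    Features below the prevalence gate are excluded (not estimable in this
    cohort). Requires ``total_reads`` in the metadata for the count-based
    model.
    """
    from .transforms import counts_from_relabund

    labels = metadata.labels(outcome, table.sample_ids)
    mask = prevalence_mask(
        AbundanceTable(table.data.loc[labels.index], table.level, table.cohort),
        min_prevalence,
    )
    sub = AbundanceTable(table.data.loc[labels.index, mask[mask].index],
                         table.level, table.cohort)
    covs = None
    if covariate_columns:
        covs = metadata.data.loc[labels.index, covariate_columns]
    counts, _ = counts_from_relabund(
        AbundanceTable(table.data.loc[labels.index], table.level, table.cohort),
        metadata, library_cutoff,
    )
    frames = [
        wilcoxon_effect(sub, labels),
        smd_effect(sub, labels),
        logit_tss_lm(sub, labels, covariates=covs),
        bias_corrected_loglinear(
            counts[sub.data.columns], labels, covariates=covs,
            library_cutoff=library_cutoff, cohort=table.cohort,
        ),
    ]
    return pd.concat(frames, ignore_index=True)


def load_plugin_effects(path) -> pd.DataFrame:
    """Read an externally computed effect table (TSV with the standard columns).

    The method name is prefixed ``plugin:`` unless already so, letting
    ensemble members estimated outside this package join the meta-analysis.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(EFFECT_COLUMNS) - {"ci_low", "ci_high", "direction"} - set(df.columns)
    if missing:
        raise ValueError(f"plug-in effect table lacks columns: {sorted(missing)}")
    df["method"] = [
        m if str(m).startswith("plugin:") else f"plugin:{m}" for m in df["method"]
    ]
    return df
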