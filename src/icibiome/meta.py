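"""Random-effects synthesis across cohorts and the consensus biomarker panel.

Per feature and per method, cohort-level effects ``theta_k`` with sampling
variances ``v_k`` are pooled under the additive heterogeneity model
``theta_k ~ N(mu, v_k + tau^2)``. ``tau^2`` is estimated by restricted
maximum likelihood (Fisher scoring, the default) or the DerSimonian-Laird
moment estimator; inference on the pooled ``mu`` is a Wald z-test with
inverse-variance weights ``w_k = 1/(v_k + tau^2)``.

The consensus panel collects features whose random-effects p value is below
``alpha`` in at least ``min_methods`` of the pooled methods, annotated with
per-cohort Wilcoxon p values and responder-up/-down directions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

_Z975 = 1.959963984540054


@dataclass
class MetaSummary:
    """Pooled effect for one feature under one method."""

    feature: str
    method: str
    mu_hat: float
    se: float
    ci_low: float
    ci_high: float
    p_re: float
    tau2: float
    k: int
    q: float = np.nan


def dersimonian_laird_tau2(theta: np.ndarray, v: np.ndarray) -> float:
    """Closed-form DerSimonian-Laird moment estimator of tau^2 (clamped at 0)."""
    w = 1.0 / v
    mu_fe = (w * theta).sum() / w.sum()
    q = (w * (theta - mu_fe) ** 2).sum()
    df = len(theta) - 1
    c = w.sum() - (w**2).sum() / w.sum()
    if c <= 0:
        return 0.0
    return max(0.0, (q - df) / c)


def reml_tau2(theta: np.ndarray, v: np.ndarray, tol: float = 1e-10,
              max_iter: int = 100) -> float:
    """REML estimate of tau^2 by Fisher scoring (intercept-only model).

    With W = diag(1/(v + tau^2)) and P = W - W11'W/(1'W1), iterate
    ``tau^2 += (theta'P P theta - tr(P)) / tr(P P)`` until convergence,
    clamping at zero.
    """
    k = len(theta)
    if k == 1:
        return 0.0
    tau2 = max(dersimonian_laird_tau2(theta, v), 1e-6)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        sw = w.sum()
        p_theta = w * theta - w * (w * theta).sum() / sw
        # tr(P) and tr(P^2) for P = W - ww'/sum(w); theta'PPtheta = ||P theta||^2
        tr_p = sw - (w**2).sum() / sw
        tr_pp = (w**2).sum() - 2.0 * (w**3).sum() / sw + ((w**2).sum() / sw) ** 2
        score = 0.5 * ((p_theta**2).sum() - tr_p)
        info = 0.5 * tr_pp
        if info <= 0:
            break
        step = score / info
        new = tau2 + step
        if new < 0:
            new = tau2 / 2.0 if tau2 > tol else 0.0
        if abs(new - tau2) < tol:
            tau2 = new
            break
        tau2 = new
    if tau2 < 1e-8 * float(np.mean(v)):
        return 0.0
    return max(0.0, tau2)


def random_effects(
    estimates: pd.DataFrame, estimator: str = "REML"
) -> MetaSummary:
    """Pool one feature+method's per-cohort estimates.

    ``estimates`` needs columns ``effect`` and ``se`` (one row per cohort);
    rows with missing effect/se are excluded before pooling.
    """
    est = estimates.dropna(subset=["effect", "se"])
    if len(est) == 0:
        raise ValueError("no estimable cohorts to pool")
    theta = est["effect"].to_numpy(dtype=float)
    v = est["se"].to_numpy(dtype=float) ** 2
    if (v <= 0).any():
        raise ValueError("zero-variance study: cannot pool")
    feature = str(est["feature"].iloc[0]) if "feature" in est else ""
    method = str(est["method"].iloc[0]) if "method" in est else ""
    if estimator == "REML":
        tau2 = reml_tau2(theta, v)
    elif estimator == "DL":
        tau2 = dersimonian_laird_tau2(theta, v)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    w = 1.0 / (v + tau2)
    mu = (w * theta).sum() / w.sum()
    se = 1.0 / np.sqrt(w.sum())
    z = mu / se
    p = float(np.clip(2.0 * scipy.stats.norm.sf(abs(z)), 5e-324, 1.0))
    return MetaSummary(
        feature=feature, method=method, mu_hat=float(mu), se=float(se),
        ci_low=float(mu - _Z975 * se), ci_high=float(mu + _Z975 * se),
        p_re=p, tau2=float(tau2), k=len(est),
    )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def pool_effects(
    effects: pd.DataFrame, estimator: str = "REML", min_k: int = 2
) -> pd.DataFrame:
    """Random-effects summaries for every feature x pooled method.

    Methods without standard errors (``wilcoxon``) are skipped. Features
    estimable in fewer than ``min_k`` cohorts are excluded; BH adjustment is
    applied across features within each method.
    """
    pooled_rows = []
    methods = [m for m in effects["method"].unique() if m != "wilcoxon"]
    for method in methods:
        sub = effects[effects["method"] == method].dropna(subset=["effect", "se"])
        for feature, grp in sub.groupby("feature", sort=True):
            if len(grp) < min_k:
                continue
            s = random_effects(grp, estimator=estimator)
            pooled_rows.append({
                "feature": feature, "method": method, "mu_hat": s.mu_hat, "se": s.se,
                "ci_low": s.ci_low, "ci_high": s.ci_high, "p_re": s.p_re,
                "tau2": s.tau2, "k": s.k,
            })
    out = pd.DataFrame(
        pooled_rows, columns=["feature", "method", "mu_hat", "se", "ci_low",
                              "ci_high", "p_re", "tau2", "k"],
    )
    out["q"] = np.nan
    for method in out["method"].unique():
        idx = out.index[out["method"] == method]
        out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p_re"])
    return out


def consensus_panel(
    summaries: pd.DataFrame,
    effects: pd.DataFrame | None = None,
    alpha: float = 0.05,
    min_methods: int = 3,
) -> pd.DataFrame:
    """Features with random-effects p < alpha in at least ``min_methods`` methods.

    ``summaries`` is the output of :func:`pool_effects`. When the per-cohort
    ``effects`` table is given, each panel row is annotated with the cohorts'
    two-tailed Wilcoxon p values (the heatmap cells, reported when < 0.05)
    and their responder-up/-down directions; the consensus direction is the
    majority per-cohort direction.
    """
    n_methods = summaries["method"].nunique()
    if min_methods > n_methods:
        raise ValueError(
            f"min_methods={min_methods} exceeds the {n_methods} pooled method(s) available"
        )
    hits = (
        summaries[summaries["p_re"] < alpha]
        .groupby("feature")["method"]
        .nunique()
        .rename("n_methods_significant")
    )
    panel = hits[hits >= min_methods].reset_index()
    if effects is not None and len(panel):
        wil = effects[effects["method"] == "wilcoxon"]
        cells = wil.pivot(index="feature", columns="cohort", values="p")
        dirs = wil.pivot(index="feature", columns="cohort", values="direction")
        consensus_dir = dirs.apply(
            lambda row: "responder_up"
            if (row.dropna() == "responder_up").mean() >= 0.5 else "responder_down",
            axis=1,
        )
        panel = panel.set_index("feature")
        panel["direction"] = consensus_dir.reindex(panel.index)
        for cohort in cells.columns:
            panel[f"wilcoxon_p:{cohort}"] = cells[cohort].reindex(panel.index)
            panel[f"direction:{cohort}"] = dirs[cohort].reindex(panel.index)
        panel = panel.reset_index()
    return panel
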