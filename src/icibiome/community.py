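"""Diversity, Aitchison distance, PERMANOVA, batch correction and small-sample
categorical tests.

PERMANOVA here is the sequential (Type-I) multi-term variant: the Gower-
centered inner-product matrix of the distance matrix is partitioned over an
ordered list of model terms, and each term's pseudo-F is referenced to free
permutations of sample identity. This mirrors the behaviour of the classical
``adonis`` implementation; term order is part of the model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.spatial.distance
import scipy.stats

from .transforms import ClrTable


def shannon(sample: np.ndarray | pd.Series) -> float:
    """Shannon diversity H = -sum p ln p over p > 0 (natural log)."""
    p = np.asarray(sample, dtype=float)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def richness(sample: np.ndarray | pd.Series) -> int:
    """Number of features with nonzero abundance."""
    p = np.asarray(sample, dtype=float)
    return int((p > 0).sum())


def aitchison_distance(clr_table: ClrTable) -> pd.DataFrame:
    """Pairwise Euclidean distance between CLR vectors (Aitchison distance)."""
    x = clr_table.values
    d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(x, metric="euclidean"))
    return pd.DataFrame(d, index=clr_table.sample_ids, columns=clr_table.sample_ids)


@dataclass
class PermanovaResult:
    """Sequential PERMANOVA partition: one row per term plus residual/total."""

    table: pd.DataFrame  # term, df, SumOfSqs, R2, F, p
    n_perm: int

    def r2(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "R2"])

    def p(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


def _design_columns(meta: pd.DataFrame, term: str) -> np.ndarray:
    """Dummy-code a categorical term (drop-first) or center a numeric one."""
    col = meta[term]
    if pd.api.types.is_numeric_dtype(col):
        v = col.to_numpy(dtype=float)
        if np.isnan(v).any():
            raise ValueError(f"term {term!r} has missing values")
        if np.ptp(v) == 0:
            raise ValueError(f"term {term!r} is constant across samples")
        return (v - v.mean())[:, None]
    codes, uniq = pd.factorize(col, sort=True)
    if (codes < 0).any():
        raise ValueError(f"term {term!r} has missing values")
    if len(uniq) < 2:
        raise ValueError(f"term {term!r} is constant across samples")
    dummies = np.eye(len(uniq))[codes][:, 1:]
    return dummies


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    rank = int((np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(r).max())).sum())
    q = q[:, :rank]
    return q @ q.T


def permanova(
    dist: pd.DataFrame | np.ndarray,
    metadata: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> PermanovaResult:
    """Sequential multi-term PERMANOVA on a distance matrix.

    Terms are added in the given order; each term's sum of squares is the
    increment in explained (Gower-centered) variation over the preceding
    terms. ``p = (1 + #{F_perm >= F_obs}) / (n_perm + 1)`` under free
    permutation of rows. Samples with missing values in any term must be
    removed by the caller.
    """
    if isinstance(dist, pd.DataFrame):
        meta = metadata.loc[dist.index]
        d = dist.to_numpy(dtype=float)
    else:
        meta = metadata
        d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or len(meta) != n:
        raise ValueError("distance matrix and metadata are not aligned")
    if not terms:
        raise ValueError("at least one model term is required")

    # Gower centering: G = (I - 11'/n) (-D^2/2) (I - 11'/n)
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    ss_total = float(np.trace(g))

    ones = np.ones((n, 1))
    hats = [_hat(ones)]
    dfs = []
    design = ones
    for term in terms:
        cols = _design_columns(meta, term)
        design = np.hstack([design, cols])
        h = _hat(design)
        dfs.append(int(round(np.trace(h) - np.trace(hats[-1]))))
        hats.append(h)
    if any(df == 0 for df in dfs):
        bad = terms[dfs.index(0)]
        raise ValueError(f"term {bad!r} is aliased with preceding terms")
    # projectors onto each term's increment and the residual
    projs = [hats[i + 1] - hats[i] for i in range(len(terms))]
    resid_proj = np.eye(n) - hats[-1]
    df_res = n - int(round(np.trace(hats[-1])))

    def f_stats(gm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ss = np.array([float((p * gm).sum()) for p in projs])
        ss_res = float((resid_proj * gm).sum())
        # a residual that is zero up to rounding makes F infinite; clamp so the
        # permutation comparison is not driven by floating-point noise
        if ss_res <= 1e-12 * abs(ss_total):
            f = np.full(len(ss), np.inf)
        else:
            f = (ss / np.array(dfs)) / (ss_res / df_res)
        return ss, f

    ss_obs, f_obs = f_stats(g)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        perm = rng.permutation(n)
        _, f_perm = f_stats(g[np.ix_(perm, perm)])
        exceed += f_perm >= f_obs
    pvals = (exceed + 1) / (n_perm + 1)

    rows = [
        {"term": t, "df": dfs[i], "SumOfSqs": ss_obs[i], "R2": ss_obs[i] / ss_total,
         "F": f_obs[i], "p": pvals[i]}
        for i, t in enumerate(terms)
    ]
    ss_res = ss_total - ss_obs.sum()
    rows.append({"term": "Residual", "df": df_res, "SumOfSqs": ss_res,
                 "R2": ss_res / ss_total, "F": np.nan, "p": np.nan})
    rows.append({"term": "Total", "df": n - 1, "SumOfSqs": ss_total, "R2": 1.0,
                 "F": np.nan, "p": np.nan})
    return PermanovaResult(pd.DataFrame(rows), n_perm)


def eb_batch_correct(
    clr_table: ClrTable, batch_labels: pd.Series | list[str]
) -> pd.DataFrame:
    """Empirical-Bayes (ComBat-style) batch correction of CLR values.

    Per feature, batch location/scale parameters are estimated, shrunk toward
    parametric across-feature priors (normal for location, inverse-gamma for
    scale) and removed. Returns the adjusted matrix with the input's index and
    columns; values are no longer exactly zero-sum per sample. A single batch
    returns the input unchanged; singleton batches are rejected.
    """
    batches = pd.Series(batch_labels, index=clr_table.data.index) if not isinstance(
        batch_labels, pd.Series
    ) else batch_labels.loc[clr_table.data.index]
    counts = batches.value_counts()
    if (counts < 2).any():
        singles = list(counts.index[counts < 2])
        raise ValueError(f"singleton batch(es) not correctable: {singles}")
    if len(counts) == 1:
        return clr_table.data.copy()

    import anndata
    import scanpy as sc

    adata = anndata.AnnData(
        X=clr_table.values.copy(),
        obs=pd.DataFrame({"batch": batches.astype(str).values}, index=clr_table.data.index),
    )
    corrected = sc.pp.combat(adata, key="batch", inplace=False)
    return pd.DataFrame(corrected, index=clr_table.data.index, columns=clr_table.data.columns)


def fisher_exact_test(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]]."""
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be nonnegative integers")
    return float(scipy.stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
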