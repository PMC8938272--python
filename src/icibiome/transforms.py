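"""Compositional and machine-learning feature transforms.

Centered log-ratio (CLR) values are ``x_ij = ln(p_ij / g(p_i))`` where
``g`` is the per-sample geometric mean after zero replacement; the machine
learning normalization is the max-abundance filter -> log10(p + pseudocount)
-> per-feature z-score stack, with parameters frozen on the training cohort
so external cohorts can be normalized "in the same way".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .tables import AbundanceTable, SampleMetadata

#: level -> (max-abundance cutoff, log10 pseudocount)
ML_DEFAULTS = {"species": (1e-4, 1e-5), "KO": (1e-6, 1e-9), "EC": (1e-6, 1e-9)}


@dataclass
class ClrTable:
    """Centered log-ratio values, same shape as the source abundance table."""

    data: pd.DataFrame
    level: str = "species"
    cohort: str = ""

    def __post_init__(self) -> None:
        sums = self.data.to_numpy(dtype=float).sum(axis=1)
        if np.abs(sums).max() > 1e-9:
            raise ValueError("CLR rows must sum to zero")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def clr(table: AbundanceTable, zero_strategy: str | float = "half_min_nonzero") -> ClrTable:
    """Centered log-ratio transform of a relative-abundance table.

    Zeros are replaced before taking logs — by half the smallest nonzero
    abundance in the table (``"half_min_nonzero"``, the default) or by an
    explicit positive pseudocount — and samples are reclosed. Each returned
    sample's values sum to zero (CLR identity), and the transform is
    invariant to positive rescaling of the input composition.
    """
    x = table.values
    if (x.sum(axis=1) <= 0).any():
        raise ValueError("all-zero sample: CLR undefined")
    if isinstance(zero_strategy, str):
        if zero_strategy != "half_min_nonzero":
            raise ValueError(f"unknown zero_strategy {zero_strategy!r}")
        eps = x[x > 0].min() / 2.0
    else:
        eps = float(zero_strategy)
        if eps <= 0:
            raise ValueError("pseudocount must be positive")
    y = np.where(x > 0, x, eps)
    y = y / y.sum(axis=1, keepdims=True)
    logs = np.log(y)
    centered = logs - logs.mean(axis=1, keepdims=True)
    df = pd.DataFrame(centered, index=table.data.index, columns=table.data.columns)
    return ClrTable(df, level=table.level, cohort=table.cohort)


def arcsine_sqrt(table: AbundanceTable | pd.DataFrame | np.ndarray) -> np.ndarray:
    """Variance-stabilizing arcsine-square-root transform, y = asin(sqrt(p))."""
    x = table.values if isinstance(table, AbundanceTable) else np.asarray(table, dtype=float)
    if (x < 0).any() or (x > 1).any():
        raise ValueError("arcsine-sqrt requires values in [0, 1]")
    return np.arcsin(np.sqrt(x))


@dataclass
class FrozenNormalization:
    """Training-cohort normalization parameters for transfer to new cohorts."""

    feature_ids: list[str]
    cutoff: float
    pseudocount: float
    mean: np.ndarray
    sd: np.ndarray
    level: str

    def __post_init__(self) -> None:
        if (self.sd <= 0).any():
            raise ValueError("frozen sd must be positive for all retained features")


class AbundanceNormalizer(BaseEstimator, TransformerMixin):
    """Filter + log10 + z-score normalizer with frozen-parameter transfer.

    fit() drops features whose maximum training abundance is below the
    level-specific cutoff (1e-4 for species, 1e-6 for gene families), freezes
    the retained-feature list and the per-feature mean/sd of
    ``log10(p + pseudocount)``. transform() applies the frozen parameters:
    features absent from an external cohort are imputed as zero abundance
    before the log, and external-only features are ignored, so a model
    trained on one cohort scores any other.
    """

    def __init__(self, level: str = "species", cutoff: float | None = None,
                 pseudocount: float | None = None):
        self.level = level
        self.cutoff = cutoff
        self.pseudocount = pseudocount

    def _resolved(self) -> tuple[float, float]:
        d_cut, d_pc = ML_DEFAULTS.get(self.level, ML_DEFAULTS["KO"])
        return (self.cutoff if self.cutoff is not None else d_cut,
                self.pseudocount if self.pseudocount is not None else d_pc)

    def fit(self, X: AbundanceTable | pd.DataFrame, y=None) -> "AbundanceNormalizer":
        df = X.data if isinstance(X, AbundanceTable) else pd.DataFrame(X)
        cutoff, pc = self._resolved()
        keep = df.columns[df.max(axis=0) >= cutoff]
        if len(keep) == 0:
            raise ValueError(f"no features pass the max-abundance cutoff {cutoff}")
        logged = np.log10(df[keep].to_numpy(dtype=float) + pc)
        mean = logged.mean(axis=0)
        sd = logged.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = list(np.asarray(keep)[sd == 0])[:5]
            raise ValueError(
                f"retained feature(s) constant across training samples (sd=0): {bad}"
            )
        self.frozen_ = FrozenNormalization(
            feature_ids=list(keep), cutoff=cutoff, pseudocount=pc,
            mean=mean, sd=sd, level=self.level,
        )
        return self

    def transform(self, X: AbundanceTable | pd.DataFrame) -> np.ndarray:
        frozen = self.frozen_
        df = X.data if isinstance(X, AbundanceTable) else pd.DataFrame(X)
        aligned = df.reindex(columns=frozen.feature_ids, fill_value=0.0)
        logged = np.log10(aligned.to_numpy(dtype=float) + frozen.pseudocount)
        return (logged - frozen.mean) / frozen.sd


def ml_preprocess(
    table: AbundanceTable, level: str | None = None, **kwargs
) -> tuple[np.ndarray, FrozenNormalization]:
    """Fit the ML normalization on a training table and return the matrix."""
    norm = AbundanceNormalizer(level=level or table.level, **kwargs).fit(table)
    return norm.transform(table), norm.frozen_


def apply_frozen(frozen: FrozenNormalization, table: AbundanceTable) -> np.ndarray:
    """Normalize an external table with training-cohort frozen parameters."""
    norm = AbundanceNormalizer(level=frozen.level)
    norm.frozen_ = frozen
    return norm.transform(table)


def counts_from_relabund(
    table: AbundanceTable, metadata: SampleMetadata, library_cutoff: int = 1000
) -> tuple[pd.DataFrame, pd.Series]:
    """Reconstruct integer counts as relative abundance x total reads.

    Rounding is half-even for determinism. Returns the count matrix and a
    boolean per-sample flag for libraries below ``library_cutoff`` reads
    (flagged, not dropped; downstream models drop them).
    """
    meta = metadata.aligned_to(table)
    if "total_reads" not in meta.columns or meta["total_reads"].isna().any():
        missing = [] if "total_reads" not in meta.columns else list(
            meta.index[meta["total_reads"].isna()][:5]
        )
        raise ValueError(f"total_reads missing for samples {missing or 'all'}")
    reads = meta["total_reads"].to_numpy(dtype=float)
    counts = np.rint(table.values * reads[:, None]).astype(np.int64)
    df = pd.DataFrame(counts, index=table.data.index, columns=table.data.columns)
    low = pd.Series(reads < library_cutoff, index=table.data.index, name="low_depth")
    return df, low
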