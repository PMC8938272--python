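"""Readers, writers and containers for abundance tables and clinical metadata.

The on-disk dialect is the merged-table TSV produced by common taxonomic
profilers: first column ``clade_name`` holds pipe-delimited taxonomy strings
(``k__...|s__Species``) for species-level rows, KEGG-ortholog identifiers
(``K00001``) for gene-family tables, or EC numbers for enzyme tables;
remaining columns are one sample each. Values may be percentages (0-100) or
fractions; this is autodetected from per-sample column sums.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LEVELS = ("species", "KO", "EC")

_KO_RE = re.compile(r"^K\d{5}$")
_EC_RE = re.compile(r"^(EC[: ._-]?)?\d+\.\d+(\.\d+){0,2}(\.[\dn-]+)?$")

#: Row names treated as unassigned mass and dropped before renormalization.
UNASSIGNED_NAMES = frozenset(
    {"UNKNOWN", "UNCLASSIFIED", "unclassified", "unknown", "-1", "UNMAPPED", "UNGROUPED"}
)

METADATA_CATEGORICAL = {
    "orr": {"R", "NR"},
    "pfs12": {"R", "NR"},
    "gender": {"M", "F"},
    "performance_status": {"0", "1", "2", "3", "unknown"},
    "previous_therapy": {"yes", "no"},
    "ppi": {"yes", "no"},
    "antibiotics": {"yes", "no"},
    "steroids": {"yes", "no"},
    "toxicity": {"yes", "no"},
    "colitis": {"yes", "no"},
    "ici_regimen": {"combination", "single_agent"},
}

METADATA_NUMERIC = ("age", "bmi", "mMED", "PDI", "hPDI", "uPDI", "total_reads")

METADATA_COLUMNS = ("cohort",) + tuple(METADATA_CATEGORICAL) + METADATA_NUMERIC


@dataclass
class AbundanceTable:
    """Samples x features relative abundances for one cohort.

    ``data`` is indexed by sample id with one column per feature; values are
    nonnegative fractions. ``level`` is one of ``species``, ``KO``, ``EC``.
    """

    data: pd.DataFrame
    level: str = "species"
    cohort: str = ""

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {LEVELS}")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate feature ids")
        if (self.data.values < 0).any():
            raise ValueError("negative abundance values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def renormalized(self) -> "AbundanceTable":
        """Close each sample's composition to sum one."""
        sums = self.data.sum(axis=1)
        if (sums <= 0).any():
            bad = list(sums.index[sums <= 0])
            raise ValueError(f"all-zero samples cannot be renormalized: {bad}")
        return AbundanceTable(self.data.div(sums, axis=0), self.level, self.cohort)


@dataclass
class SampleMetadata:
    """Per-sample clinical metadata, indexed by sample id.

    Categorical fields use controlled vocabularies (see
    ``METADATA_CATEGORICAL``); missing values are represented by NaN.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if "cohort" not in self.data.columns:
            raise ValueError("metadata must contain a 'cohort' column")
        if "orr" not in self.data.columns and "pfs12" not in self.data.columns:
            raise ValueError("metadata must contain at least one of 'orr'/'pfs12'")
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def aligned_to(self, table: AbundanceTable) -> pd.DataFrame:
        missing = set(table.sample_ids) - set(self.data.index)
        if missing:
            raise KeyError(f"samples missing from metadata: {sorted(missing)[:5]}")
        return self.data.loc[table.sample_ids]

    def labels(self, outcome: str, samples: list[str] | None = None) -> pd.Series:
        """Binary outcome series (1 = responder) with missing entries dropped."""
        col = self.data[outcome] if samples is None else self.data.loc[samples, outcome]
        col = col.dropna()
        return (col == "R").astype(int)


def _is_level_row(name: str, level: str) -> bool:
    if level == "species":
        return "s__" in name and "t__" not in name
    if level == "KO":
        return bool(_KO_RE.match(name))
    if level == "EC":
        return bool(_EC_RE.match(name)) and not _KO_RE.match(name)
    raise ValueError(f"unknown level {level!r}")


def read_merged_table(
    path: str | Path,
    level: str = "species",
    cohort: str = "",
    renormalize: bool = True,
    keep_unassigned: bool = False,
) -> AbundanceTable:
    """Read a merged-table TSV, keeping only rows at the requested level.

    Percentages are detected from per-sample sums and converted to fractions;
    species rows are the clades containing ``s__`` but no strain marker
    ``t__``. Unassigned/unclassified rows are dropped unless
    ``keep_unassigned`` is set.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    raw = raw[[c for c in raw.columns if not str(c).startswith("#")]]
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique()[:5]
        raise ValueError(f"duplicate feature ids in {path}: {list(dups)}")
    values = raw.apply(pd.to_numeric, errors="raise")
    if (values.values < 0).any():
        raise ValueError(f"negative abundance value in {path}")
    if not keep_unassigned:
        values = values[~values.index.astype(str).str.strip().isin(UNASSIGNED_NAMES)]
    mask = [_is_level_row(str(name), level) for name in values.index]
    values = values[mask]
    if values.empty:
        raise ValueError(f"no rows at level {level!r} in {path}")
    # percent-vs-fraction autodetection on the median per-sample sum
    if values.sum(axis=0).median() > 1.5:
        values = values / 100.0
    table = AbundanceTable(values.T, level=level, cohort=cohort)
    if renormalize and level == "species":
        table = table.renormalized()
    return table


def write_merged_table(table: AbundanceTable, path: str | Path, as_percent: bool = True) -> Path:
    """Write a table in the merged-TSV dialect (features as rows)."""
    path = Path(path)
    out = table.data.T
    if as_percent:
        out = out * 100.0
    out.index.name = "clade_name"
    out.to_csv(path, sep="\t", float_format="%.17g")
    return path


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a clinical-metadata TSV.

    Empty strings and "NA" are missing. Unknown categorical values are
    preserved as missing with a warning rather than dropping the sample.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, na_values=["", "NA"], keep_default_na=False
    )
    if "cohort" not in df.columns:
        raise ValueError(f"metadata file {path} lacks required column 'cohort'")
    if "orr" not in df.columns and "pfs12" not in df.columns:
        raise ValueError(f"metadata file {path} lacks both 'orr' and 'pfs12'")
    for col, vocab in METADATA_CATEGORICAL.items():
        if col not in df.columns:
            continue
        extra = "unknown" if col == "performance_status" else None
        bad = df[col].dropna()[~df[col].dropna().isin(vocab)]
        if len(bad):
            warnings.warn(
                f"metadata column {col!r}: {len(bad)} value(s) outside vocabulary "
                f"{sorted(vocab)} set to missing (e.g. {bad.iloc[0]!r})",
                stacklevel=2,
            )
            df.loc[bad.index, col] = np.nan
        del extra
    for col in METADATA_NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "total_reads" in df.columns:
        df["total_reads"] = df["total_reads"].round().astype("Int64")
    return SampleMetadata(df)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> Path:
    path = Path(path)
    out = metadata.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA")
    return path


def merge_cohorts(tables: list[AbundanceTable]) -> AbundanceTable:
    """Pool cohorts into one table over the union of features.

    Features absent from a cohort are filled with zero, so per-sample sums are
    unchanged; cohort provenance is retained in the returned table's
    ``cohort`` field as a comma-joined list and per sample via the original
    sample ids (unique across cohorts by precondition).
    """
    if not tables:
        raise ValueError("no tables to merge")
    level = tables[0].level
    if any(t.level != level for t in tables):
        raise ValueError("cannot merge tables at different levels")
    all_ids: list[str] = []
    for t in tables:
        all_ids.extend(t.sample_ids)
    if len(set(all_ids)) != len(all_ids):
        raise ValueError("duplicate sample ids across cohorts")
    merged = pd.concat([t.data for t in tables], axis=0).fillna(0.0)
    cohort = ",".join(t.cohort for t in tables)
    return AbundanceTable(merged, level=level, cohort=cohort)


def cohort_of_samples(tables: list[AbundanceTable]) -> pd.Series:
    """Map each sample id to the cohort of the table it came from."""
    pairs = {}
    for t in tables:
        for s in t.sample_ids:
            pairs[s] = t.cohort
    return pd.Series(pairs, name="cohort")
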