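"""Synthetic multi-cohort study generator.

Emulates the statistical structure the cross-cohort analysis assumes:
sparse compositional species profiles (feature-wise log-normal abundance with
Bernoulli presence, then closure), dominant cohort batch effects (additive
location and multiplicative scale on the log scale, per cohort x feature),
weak planted response-associated features, correlated clinical covariates,
paired 6-month (ORR) and 12-month (PFS12) endpoints with partial concordance
(responders may progress between 6 and 12 months, never the reverse), and
log-normal total read depths. All draws descend from one root seed through
``numpy.random.SeedSequence`` stream splitting, so studies are byte-for-byte
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import (
    AbundanceTable,
    SampleMetadata,
    write_merged_table,
    write_metadata,
)


@dataclass
class CovariateSpec:
    """One clinical covariate and its (optional) imprint on the microbiome.

    ``kind`` is ``binary`` (yes/no with probability ``prevalence``),
    ``continuous`` (standard normal, scaled/shifted by ``loc``/``scale``), or
    ``categorical`` (levels drawn from ``levels`` with ``probs``). If
    ``affected_features`` is nonempty, the covariate shifts those features'
    log abundance by ``effect_size`` (times the standardized value for
    continuous covariates).
    """

    kind: str = "binary"
    prevalence: float = 0.3
    loc: float = 0.0
    scale: float = 1.0
    levels: tuple = ()
    probs: tuple = ()
    affected_features: tuple[int, ...] = ()
    effect_size: float = 0.0


def default_covariates() -> dict[str, CovariateSpec]:
    """Clinical covariates mirroring the melanoma-cohort metadata schema."""
    return {
        "gender": CovariateSpec("categorical", levels=("M", "F"), probs=(0.6, 0.4)),
        "age": CovariateSpec("continuous", loc=62.0, scale=12.0),
        "bmi": CovariateSpec("continuous", loc=28.0, scale=4.0),
        "performance_status": CovariateSpec(
            "categorical", levels=("0", "1", "2", "3"), probs=(0.55, 0.35, 0.07, 0.03)
        ),
        "previous_therapy": CovariateSpec("binary", prevalence=0.25),
        "ppi": CovariateSpec("binary", prevalence=0.27),
        "antibiotics": CovariateSpec("binary", prevalence=0.16),
        "steroids": CovariateSpec("binary", prevalence=0.15),
        "toxicity": CovariateSpec("binary", prevalence=0.3),
        "colitis": CovariateSpec("binary", prevalence=0.1),
        "ici_regimen": CovariateSpec(
            "categorical", levels=("combination", "single_agent"), probs=(0.33, 0.67)
        ),
        "mMED": CovariateSpec("continuous", loc=4.0, scale=1.5),
        "PDI": CovariateSpec("continuous", loc=55.0, scale=6.0),
        "hPDI": CovariateSpec("continuous", loc=55.0, scale=8.0),
        "uPDI": CovariateSpec("continuous", loc=55.0, scale=8.0),
    }


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults are the reference study."""

    n_cohorts: int = 5
    samples_per_cohort: list[int] = field(default_factory=lambda: [60] * 5)
    n_species: int = 300
    n_functions: int = 150
    base_logmean_scale: float = 2.0
    prevalence_range: tuple[float, float] = (0.15, 0.95)
    batch_location_sd: float = 1.5
    batch_scale_sd: float = 0.25
    planted_up: tuple[int, ...] = ()
    planted_down: tuple[int, ...] = ()
    effect_size: float = 1.0
    planted_prevalence: tuple[float, float] | None = (0.85, 0.98)
    response_rate_per_cohort: list[float] = field(default_factory=lambda: [0.55] * 5)
    orr_pfs12_concordance: float = 0.9
    covariate_spec: dict[str, CovariateSpec] = field(default_factory=default_covariates)
    within_sd: float = 0.8
    reads_logmean: float = float(np.log(1e7))
    reads_logsd: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise ValueError("samples_per_cohort length must equal n_cohorts")
        if len(self.response_rate_per_cohort) != self.n_cohorts:
            raise ValueError("response_rate_per_cohort length must equal n_cohorts")
        if set(self.planted_up) & set(self.planted_down):
            raise ValueError("planted_up and planted_down must be disjoint")
        for idx in list(self.planted_up) + list(self.planted_down):
            if not (0 <= idx < self.n_species):
                raise ValueError(f"planted feature index {idx} outside [0, {self.n_species})")
        for spec in self.covariate_spec.values():
            for idx in spec.affected_features:
                if not (0 <= idx < self.n_species):
                    raise ValueError(f"covariate feature index {idx} out of range")
            if not np.isfinite(spec.effect_size):
                raise ValueError("covariate effect sizes must be finite")
        if not all(0 < r < 1 for r in self.response_rate_per_cohort):
            raise ValueError("response rates must lie in (0, 1)")
        if not (0 <= self.orr_pfs12_concordance <= 1):
            raise ValueError("orr_pfs12_concordance must lie in [0, 1]")
        lo, hi = self.prevalence_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("prevalence_range must satisfy 0 < lo <= hi <= 1")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect_size must be finite")


@dataclass
class SyntheticStudy:
    """Generated cohorts plus ground truth for recovery checks."""

    tables: dict[str, AbundanceTable]
    function_tables: dict[str, AbundanceTable]
    metadata: SampleMetadata
    truth: dict

    @property
    def cohorts(self) -> list[str]:
        return list(self.tables)


def _species_name(j: int) -> str:
    return (
        f"k__Bacteria|p__Synthphyla|c__Synthclass|o__Ered|f__Synthaceae"
        f"|g__Synthgenus|s__synthetic_sp_{j:04d}"
    )


def generate_study(config: SimulationConfig) -> SyntheticStudy:
    """Draw a full multi-cohort study from the configured conditions.

    Per sample, species log abundance = baseline + cohort batch location +
    planted/covariate shifts + noise scaled by the cohort batch-scale factor;
    values are exponentiated, zeroed where a feature-wise Bernoulli presence
    draw fails, and closed to sum one.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss_global, ss_cohorts, ss_functions = root.spawn(3)
    rng = np.random.default_rng(ss_global)

    n_sp = config.n_species
    base = rng.normal(0.0, config.base_logmean_scale, n_sp)
    prevalence = rng.uniform(*config.prevalence_range, n_sp)
    planted = np.array(sorted(config.planted_up) + sorted(config.planted_down), dtype=int)
    if len(planted) and config.planted_prevalence is not None:
        prevalence[planted] = rng.uniform(*config.planted_prevalence, len(planted))
    if len(planted):
        # planted biomarkers are moderate-abundance species: a planted feature
        # that dominates the community would, once shifted, imprint a closure
        # artifact on every other feature
        base[planted] = rng.normal(0.0, min(1.0, config.base_logmean_scale), len(planted))
    sigma = config.within_sd * rng.uniform(0.8, 1.2, n_sp)
    effect = np.zeros(n_sp)
    effect[list(config.planted_up)] = config.effect_size
    effect[list(config.planted_down)] = -config.effect_size

    feature_ids = [_species_name(j) for j in range(n_sp)]
    cohort_names = [f"COHORT{c + 1}" for c in range(config.n_cohorts)]
    cohort_streams = ss_cohorts.spawn(config.n_cohorts)

    tables: dict[str, AbundanceTable] = {}
    meta_rows = []
    for c, (name, stream) in enumerate(zip(cohort_names, cohort_streams)):
        crng = np.random.default_rng(stream)
        n = config.samples_per_cohort[c]
        batch_loc = crng.normal(0.0, config.batch_location_sd, n_sp)
        batch_scale = np.exp(crng.normal(0.0, config.batch_scale_sd, n_sp))

        orr = (crng.random(n) < config.response_rate_per_cohort[c]).astype(int)
        # responders may progress between months 6 and 12; one-way flips only
        flip = crng.random(n) >= config.orr_pfs12_concordance
        pfs12 = np.where((orr == 1) & flip, 0, orr)

        covs: dict[str, np.ndarray] = {}
        shift = np.zeros((n, n_sp))
        for cov_name, spec in config.covariate_spec.items():
            if spec.kind == "binary":
                val = (crng.random(n) < spec.prevalence).astype(int)
                z = val.astype(float)
                covs[cov_name] = np.where(val == 1, "yes", "no")
            elif spec.kind == "continuous":
                z = crng.normal(0.0, 1.0, n)
                covs[cov_name] = spec.loc + spec.scale * z
            elif spec.kind == "categorical":
                covs[cov_name] = crng.choice(spec.levels, size=n, p=spec.probs or None)
                z = np.zeros(n)
            else:
                raise ValueError(f"unknown covariate kind {spec.kind!r}")
            if spec.affected_features and spec.effect_size:
                shift[:, list(spec.affected_features)] += spec.effect_size * z[:, None]

        logs = (
            base
            + batch_loc
            + shift
            + orr[:, None] * effect
            + crng.normal(0.0, 1.0, (n, n_sp)) * (sigma * batch_scale)
        )
        present = crng.random((n, n_sp)) < prevalence
        raw = np.where(present, np.exp(logs), 0.0)
        # guard: a sample with nothing present keeps its single largest draw
        empty = ~present.any(axis=1)
        if empty.any():
            raw[empty, np.argmax(logs[empty], axis=1)] = np.exp(
                logs[empty, np.argmax(logs[empty], axis=1)]
            )
        closed = raw / raw.sum(axis=1, keepdims=True)

        sample_ids = [f"{name}_S{i:03d}" for i in range(n)]
        tables[name] = AbundanceTable(
            pd.DataFrame(closed, index=sample_ids, columns=feature_ids),
            level="species", cohort=name,
        )
        reads = np.exp(crng.normal(config.reads_logmean, config.reads_logsd, n))
        for i, sid in enumerate(sample_ids):
            row = {"sample_id": sid, "cohort": name,
                   "orr": "R" if orr[i] else "NR", "pfs12": "R" if pfs12[i] else "NR",
                   "total_reads": int(round(reads[i]))}
            for cov_name in config.covariate_spec:
                v = covs[cov_name][i]
                row[cov_name] = float(v) if isinstance(v, (float, np.floating)) else str(v)
            meta_rows.append(row)

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    metadata = SampleMetadata(meta)

    ss_contrib, ss_fnoise = ss_functions.spawn(2)
    contribution = _default_contribution_matrix(
        np.random.default_rng(ss_contrib), n_sp, config.n_functions
    )
    truth = {
        "planted_up": [feature_ids[j] for j in sorted(config.planted_up)],
        "planted_down": [feature_ids[j] for j in sorted(config.planted_down)],
        "effect_size": config.effect_size,
        "covariate_links": {
            name: [feature_ids[j] for j in spec.affected_features]
            for name, spec in config.covariate_spec.items()
            if spec.affected_features
        },
        "seed": config.seed,
    }
    study = SyntheticStudy(tables=tables, function_tables={}, metadata=metadata, truth=truth)
    study.function_tables = generate_function_tables(study, contribution, seed=ss_fnoise)
    return study


def _default_contribution_matrix(rng: np.random.Generator, n_species: int,
                                 n_functions: int) -> np.ndarray:
    """Sparse nonnegative species -> function weights (~5 contributors each)."""
    c = np.zeros((n_species, n_functions))
    for f in range(n_functions):
        k = rng.integers(3, 8)
        contributors = rng.choice(n_species, size=k, replace=False)
        c[contributors, f] = rng.gamma(2.0, 1.0, k)
    return c


def generate_function_tables(
    study: SyntheticStudy,
    contribution_matrix: np.ndarray,
    noise_sd: float = 0.3,
    seed: int | np.random.SeedSequence = 0,
) -> dict[str, AbundanceTable]:
    """Gene-family tables as the closure of species' weighted contributions.

    ``function_abundance = closure(species @ weights * lognormal noise)``, so
    planted species signal propagates to their linked functions. Weights must
    be nonnegative with rows matching the species axis.
    """
    c = np.asarray(contribution_matrix, dtype=float)
    if (c < 0).any():
        raise ValueError("contribution weights must be nonnegative")
    first = next(iter(study.tables.values()))
    if c.shape[0] != len(first.feature_ids):
        raise ValueError("contribution matrix rows must match species")
    ko_ids = [f"K{f + 1:05d}" for f in range(c.shape[1])]
    rng = np.random.default_rng(seed)
    out = {}
    for name, table in study.tables.items():
        raw = table.values @ c
        raw = raw * np.exp(rng.normal(0.0, noise_sd, raw.shape))
        sums = raw.sum(axis=1, keepdims=True)
        closed = np.divide(raw, sums, out=np.zeros_like(raw), where=sums > 0)
        out[name] = AbundanceTable(
            pd.DataFrame(closed, index=table.sample_ids, columns=ko_ids),
            level="KO", cohort=name,
        )
    return out


def write_fixture_set(study: SyntheticStudy, directory: str | Path) -> dict[str, Path]:
    """Write one merged TSV per cohort per level, metadata, and the truth manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, table in study.tables.items():
        paths[f"species:{name}"] = write_merged_table(
            table, directory / f"{name}_species.tsv"
        )
    for name, table in study.function_tables.items():
        paths[f"KO:{name}"] = write_merged_table(
            table, directory / f"{name}_KO.tsv", as_percent=False
        )
    paths["metadata"] = write_metadata(study.metadata, directory / "metadata.tsv")
    manifest = directory / "truth.json"
    manifest.write_text(json.dumps(study.truth, indent=2))
    paths["truth"] = manifest
    return paths


def reference_config(seed: int = 0) -> SimulationConfig:
    """The reference synthetic study: 5 cohorts x 60 samples, 300 species,
    10 responder-enriched and 10 responder-depleted species at log effect 1.0."""
    return SimulationConfig(
        planted_up=tuple(range(10)),
        planted_down=tuple(range(10, 20)),
        covariate_spec={
            **default_covariates(),
            "ppi": CovariateSpec(
                "binary", prevalence=0.27,
                affected_features=tuple(range(30, 38)), effect_size=0.6,
            ),
            "antibiotics": CovariateSpec(
                "binary", prevalence=0.16,
                affected_features=tuple(range(40, 45)), effect_size=0.8,
            ),
        },
        seed=seed,
    )


def null_config(seed: int = 0, n_cohorts: int = 3, samples: int = 40,
                n_species: int = 200) -> SimulationConfig:
    """A no-signal study: no planted features, no covariate-microbiome links."""
    return SimulationConfig(
        n_cohorts=n_cohorts,
        samples_per_cohort=[samples] * n_cohorts,
        n_species=n_species,
        n_functions=100,
        planted_up=(),
        planted_down=(),
        effect_size=0.0,
        response_rate_per_cohort=[0.5] * n_cohorts,
        seed=seed,
    )
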