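import warnings

import numpy as np
import pandas as pd
import pytest

import icibiome as ib

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def reference_study():
    """The reference synthetic study: 5 cohorts x 60 samples, 300 species,
    20 planted response-associated species at log effect 1.0."""
    return ib.generate_study(ib.reference_config(seed=1))


@pytest.fixture(scope="session")
def reference_effects(reference_study):
    """Per-cohort differential-abundance effects for the reference study."""
    from icibiome.diffabund import cohort_effects

    frames = [
        cohort_effects(t, reference_study.metadata, outcome="orr")
        for t in reference_study.tables.values()
    ]
    return pd.concat(frames, ignore_index=True)


@pytest.fixture
def toy_table():
    """Three samples x four species, no zeros, rows summing to one."""
    data = pd.DataFrame(
        [[0.5, 0.25, 0.125, 0.125],
         [0.25, 0.25, 0.25, 0.25],
         [0.4, 0.3, 0.2, 0.1]],
        index=["s1", "s2", "s3"],
        columns=[f"k__B|s__sp_{j}" for j in range(4)],
    )
    return ib.AbundanceTable(data, level="species", cohort="TOY")


@pytest.fixture
def small_labeled_table():
    """40-sample single-cohort table with one strongly shifted species."""
    rng = np.random.default_rng(7)
    n, p = 40, 30
    labels = np.array([1, 0] * (n // 2))
    logs = rng.normal(0.0, 1.0, (n, p))
    logs[:, 0] += 2.0 * labels
    raw = np.exp(logs)
    closed = raw / raw.sum(axis=1, keepdims=True)
    idx = [f"s{i:02d}" for i in range(n)]
    table = ib.AbundanceTable(
        pd.DataFrame(closed, index=idx, columns=[f"k__B|s__sp_{j}" for j in range(p)]),
        cohort="SMALL",
    )
    return table, pd.Series(labels, index=idx)
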