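import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import hccbayes as hb

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scheme() -> hb.CutoffScheme:
    return hb.reference_scheme()


@pytest.fixture(scope="session")
def counts() -> hb.DivisionCountTable:
    return hb.reference_counts()


@pytest.fixture(scope="session")
def reference_cohort(scheme, counts) -> hb.LabeledDataset:
    """A deterministic realization of the reference count table."""
    return hb.materialize_exact_counts(counts, scheme, seed=20160)


def random_count_table(
    rng: np.random.Generator,
    n_markers: int = 3,
    class_sizes: tuple[int, int] = (20, 30),
    max_divisions: int = 3,
) -> hb.DivisionCountTable:
    """A random table satisfying the per-marker column-sum invariant."""
    tables = {}
    for j in range(1, n_markers + 1):
        k = int(rng.integers(2, max_divisions + 1))
        rows = [
            rng.multinomial(class_sizes[i], np.ones(k) / k) for i in (0, 1)
        ]
        tables[j] = np.stack(rows)
    return hb.DivisionCountTable(tables, class_sizes)


def random_pattern(
    rng: np.random.Generator, table: hb.DivisionCountTable
) -> hb.DiscretizedPattern:
    return hb.DiscretizedPattern.from_mapping(
        {
            j: int(rng.integers(1, table.counts[j].shape[1] + 1))
            for j in table.marker_ids
        }
    )
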