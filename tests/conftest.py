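import numpy as np
import pandas as pd
import pytest

from painconnectome import connectivity, normalization, synthetic


@pytest.fixture(scope="session")
def tiny_spec():
    """Small cohort spec: all 7 groups, 3-4 subjects each, short series."""
    return synthetic.dhcp_like_cohort_spec(
        seed=42, scale=0.03, infant_series_length=400, adult_series_length=400
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    records, truth = synthetic.simulate_cohort(tiny_spec)
    meta = pd.DataFrame(
        {
            "subject": [r.id for r in records],
            "group": [r.group for r in records],
            "pma": [r.pma if r.pma is not None else np.nan for r in records],
        }
    )
    return records, meta, truth


@pytest.fixture(scope="session")
def tiny_normalized(tiny_cohort):
    """Full QC -> reference -> r-norm -> presence chain on the tiny cohort."""
    records, meta, _ = tiny_cohort
    vectors = [
        connectivity.connection_vector(r.timeseries, subject_id=r.id) for r in records
    ]
    table = connectivity.cohort_connection_table(vectors)
    return normalization.normalize_cohort(table, meta), meta
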