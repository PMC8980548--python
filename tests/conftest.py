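import numpy as np
import pandas as pd
import pytest

from hdmprof import Cohort, DEFAULT_PANEL


def make_cohort(rows, panel=DEFAULT_PANEL):
    """Build a small cohort from (patient_id, age, region, levels) tuples.

    ``levels`` is either a full list in panel order or a dict of
    molecule -> level (everything else 0.0).
    """
    records = []
    for pid, age, region, levels in rows:
        if isinstance(levels, dict):
            full = {m: float(levels.get(m, 0.0)) for m in panel}
        else:
            assert len(levels) == len(panel)
            full = {m: float(v) for m, v in zip(panel, levels)}
        records.append({"patient_id": pid, "age": age, "region": region, "tige": np.nan, **full})
    return Cohort(pd.DataFrame.from_records(records), panel)


@pytest.fixture
def toy_cohort():
    """Four patients, two regions, mixed ages; levels straddle 0.35."""
    return make_cohort(
        [
            ("p1", 5.0, "North", {"Der f 2": 1.0, "Der p 2": 2.5}),
            ("p2", 17.9, "North", {"Der f 2": 0.35, "Der p 23": 0.4}),
            ("p3", 18.0, "South", {"Der p 23": 3.0}),
            ("p4", 40.0, "South", {"Der f 2": 0.349}),
        ]
    )


@pytest.fixture
def small_synthetic():
    """A seeded 300-patient synthetic cohort with its binary matrix."""
    from hdmprof import binarize, generate, preset_ukraine_like, with_seed

    config = with_seed(preset_ukraine_like(n_patients=300), 42)
    cohort = generate(config)
    return cohort, binarize(cohort)
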