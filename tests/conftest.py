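import numpy as np
import pandas as pd
import pytest

from guildflow import AbundanceTable, SampleMetadata


@pytest.fixture
def small_metadata():
    """3 subjects x 2 timepoints."""
    rows = []
    for s in range(3):
        for tp in ("0", "10"):
            rows.append(
                {
                    "sample_id": f"S{s}.t{tp}",
                    "subject_id": f"S{s}",
                    "timepoint": tp,
                    "sex": "F" if s % 2 == 0 else "M",
                }
            )
    return SampleMetadata(pd.DataFrame(rows), ["0", "10"])


@pytest.fixture
def small_table(small_metadata):
    rng = np.random.default_rng(42)
    raw = rng.lognormal(size=(4, 6))
    return AbundanceTable(
        [f"F{i}" for i in range(4)],
        small_metadata.sample_ids,
        raw / raw.sum(axis=0),
        "relative",
    )


def make_metadata(n_subjects, timepoints):
    rows = []
    for s in range(n_subjects):
        for tp in timepoints:
            rows.append(
                {
                    "sample_id": f"S{s:02d}.t{tp}",
                    "subject_id": f"S{s:02d}",
                    "timepoint": str(tp),
                    "sex": "F" if s % 2 == 0 else "M",
                }
            )
    return SampleMetadata(pd.DataFrame(rows), [str(t) for t in timepoints])
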