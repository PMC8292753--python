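import numpy as np
import pandas as pd
import pytest

from circalux.types import ObservationDay


@pytest.fixture
def day_factory():
    """Build a 288-slot observation day from a values array."""

    def make(values, kind="lux", source_id="s1", season="winter", day_index=0,
             partial=False):
        values = np.asarray(values, dtype=float)
        return ObservationDay(
            source_id=source_id,
            kind=kind,
            season=season,
            day_index=day_index,
            start=pd.Timestamp("2018-12-18 17:00"),
            values=values,
            cadence_min=1440.0 / len(values),
            partial=partial,
        )

    return make


@pytest.fixture
def write_csv(tmp_path):
    """Write a timestamp,value CSV and return its path."""

    def make(rows, name="sensor.csv", header="timestamp,value"):
        p = tmp_path / name
        p.write_text(header + "\n" + "\n".join(rows) + "\n")
        return p

    return make
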