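import numpy as np
import pandas as pd
import pytest

from vo2energetics import BreathSeries, CohortSpec, PhaseMarks, make_subject


@pytest.fixture
def marks():
    return PhaseMarks(0.0, 60.0, 180.0, 600.0)


def series_from_arrays(time, vo2, marks, mass=80.0, **channels):
    df = pd.DataFrame({"time": np.asarray(time, float),
                       "vo2": np.asarray(vo2, float)})
    for k, v in channels.items():
        df[k] = v
    return BreathSeries(df, marks, mass)


@pytest.fixture
def flat_series(marks):
    """1 Hz constant-VO2 session spanning all three phases."""
    t = np.arange(0.5, 600.0, 1.0)
    return series_from_arrays(t, np.full(len(t), 2000.0), marks)


@pytest.fixture
def default_profile():
    """A deterministic synthetic subject at the default cohort spec."""
    return make_subject(CohortSpec(master_seed=11), 0)
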