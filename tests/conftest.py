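import numpy as np
import pytest

from poultrychain.core import AccelStream
from poultrychain.slaughter import SlaughterRecord

# One flock's inspection sheet as recorded by slaughterhouse operators:
# a 200-bird sample from a 5040-bird lot, graded A.
INSPECTION_ROW = dict(
    flock_id="flock-2019-0430",
    sample_size=200,
    weight_range=3.42,
    farm_weight=3.42,
    total_hematoms=23,
    broken_wing=21,
    hematoma_wings=11,
    hematoma_armpit=0,
    breast=12,
    broken_bones=9,
    overscalded=0,
    bad_extraction_viscera=1,
    bad_plucked=0,
    bad_wash=0,
    scab=0,
    crops=0,
    knuckles=0,
    dead_in_transport=3,
    confiscated=8,
    numbers_of_chickens=5040,
    meat_quality="A",
)

#: the use case's cross-phase KPI vector driving the advisor demonstration
USE_CASE_KPIS = {
    "emergency_situation": 68.30,
    "abrupt_movements": 9.32,
    "high_temperature": 0.0,
    "high_relative_humidity": 17.0,
    "low_temperature": 0.0,
}


@pytest.fixture
def inspection_record():
    return SlaughterRecord(**INSPECTION_ROW)


def make_stream(modules, t0=0.0, rate=1.0, **kwargs):
    """AccelStream with a prescribed per-sample module, split evenly over axes."""
    modules = np.asarray(modules, dtype=float)
    axis = modules / np.sqrt(3.0)
    ts = t0 + np.arange(len(modules)) / rate
    return AccelStream(ts, axis.copy(), axis.copy(), axis.copy(),
                       sample_rate=rate, **kwargs)
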