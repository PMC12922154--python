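import numpy as np
import pytest

from saccadekde import AmplitudeUnit, SaccadeRecord, SaccadeTable


def make_table(directions, amplitudes, unit=AmplitudeUnit.PX, geometry=None, group=None):
    """Build a SaccadeTable from parallel direction/amplitude arrays."""
    records = tuple(
        SaccadeRecord(
            direction_deg=float(d),
            amplitude_value=float(a),
            amplitude_unit=unit,
            group=group,
        )
        for d, a in zip(directions, amplitudes)
    )
    return SaccadeTable(records=records, geometry=geometry, source="test")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_table(rng):
    """200 saccades: direction vM-ish around 90, gamma amplitudes."""
    d = np.rad2deg(rng.vonmises(np.pi / 2, 4.0, 200)) % 360.0
    a = rng.gamma(4.0, 30.0, 200)
    return make_table(d, a)
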