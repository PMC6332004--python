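import numpy as np
import pytest

from transwellkit import (
    AP_TO_BL,
    BL_TO_AP,
    InsertGeometry,
    TransportSeries,
)
from transwellkit.datasets import reference_study


@pytest.fixture(scope="session")
def ref():
    """Reference twelve-coumarin study tables as domain objects."""
    return reference_study()


@pytest.fixture
def geometry():
    return InsertGeometry()


def make_series(
    times_min,
    q_umol,
    *,
    compound_id="X",
    direction=AP_TO_BL,
    replicate=0,
    c0=50.0,
    geometry=None,
    teer=None,
):
    """Concise TransportSeries constructor for tests."""
    return TransportSeries(
        compound_id=compound_id,
        direction=direction,
        replicate=replicate,
        times=tuple(np.atleast_1d(times_min)),
        q_cum=tuple(np.atleast_1d(q_umol)),
        c0=c0,
        geometry=geometry or InsertGeometry(),
        teer=teer,
    )


@pytest.fixture
def series_factory():
    return make_series
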