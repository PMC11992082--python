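import numpy as np
import pytest

from evorescue import (
    CultureType,
    KineticCurve,
    PlateLayout,
    TransferTrajectory,
    Treatment,
    make_layout,
)


@pytest.fixture
def meta():
    return PlateLayout("A1", CultureType.MUTUALISM, Treatment.SALINITY,
                       dose=3.0, replicate=1)


@pytest.fixture
def proto_meta():
    return PlateLayout("P1", CultureType.PROTOTROPH, Treatment.SALINITY,
                       dose=3.0, replicate=1)


def curve(od, meta, dt_min=5.0):
    od = np.asarray(od, dtype=float)
    return KineticCurve(np.arange(len(od)) * dt_min, od, meta)


def traj(od, meta, stress_start=4):
    od = np.asarray(od, dtype=float)
    return TransferTrajectory(np.arange(1, len(od) + 1), od, stress_start, meta)


@pytest.fixture
def small_layout(tmp_path):
    """CSV layout with two mutualism wells, a prototroph and a blank."""
    path = tmp_path / "layout.csv"
    path.write_text(
        "id,culture_type,treatment,dose,replicate\n"
        "A1,mutualism,salinity,3.0,1\n"
        "A2,mutualism,salinity,3.0,2\n"
        "P1,prototroph,none,0,1\n"
        "B1,blank,none,0,1\n"
    )
    return path
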