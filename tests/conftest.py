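from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True)
settings.load_profile("reproducible")

from pvloop import (
    BrachialPressure,
    PVLoop,
    VolumeTimeSeries,
    generate_volume_curve,
)


@pytest.fixture
def rectangle_loop() -> PVLoop:
    """Analytic 100 mmHg x 100 mL rectangle: ejection 200->100 mL at
    100 mmHg, filling 100->200 mL at 0.001 mmHg (pressures must stay
    positive only for volumes; zero pressure is allowed)."""
    return PVLoop(
        volumes=np.array([200.0, 100.0, 100.0, 200.0]),
        pressures=np.array([100.0, 100.0, 0.0, 0.0]),
        v0=0.0,
        heart_rate=60.0,
    )


@pytest.fixture
def default_vts() -> VolumeTimeSeries:
    return generate_volume_curve(edv=200.0, ef=0.5, hr=60.0, n_frames=30)


def random_patient(rng: np.random.Generator) -> tuple[VolumeTimeSeries, BrachialPressure]:
    """Draw one physiologically plausible synthetic patient."""
    edv = rng.uniform(120.0, 350.0)
    ef = rng.uniform(0.12, 0.55)
    hr = rng.uniform(50.0, 100.0)
    sbp = rng.uniform(95.0, 175.0)
    dbp = rng.uniform(55.0, min(sbp - 20.0, 100.0))
    n_frames = int(rng.integers(25, 41))
    vts = generate_volume_curve(edv=edv, ef=ef, hr=hr, n_frames=n_frames)
    return vts, BrachialPressure(sbp=sbp, dbp=dbp)
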