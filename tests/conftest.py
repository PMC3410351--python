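from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from flycourt import ParameterVector

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_vector(
    couple_id: str = "c1",
    healthy: bool = True,
    *,
    orientation: float = 100.0,
    vibration: float = 50.0,
    licking: int = 5,
    atc: int = 0,
    copulated: bool = False,
    nse: int = 10,
    total: float = 600.0,
) -> ParameterVector:
    """Shorthand constructor for test parameter vectors."""
    return ParameterVector(
        couple_id=couple_id,
        healthy=healthy,
        orientation_time_s=orientation,
        vibration_time_s=vibration,
        licking_count=licking,
        atc_count=atc,
        copulated=copulated,
        nse_count=nse,
        total_time_s=total,
    )


@pytest.fixture
def vector_factory():
    return make_vector


@pytest.fixture
def separable_dataset():
    """Eight couples, perfectly separable: healthy iff nse <= 5."""
    rows = [
        ("h1", True, 2),
        ("h2", True, 3),
        ("h3", True, 5),
        ("h4", True, 4),
        ("s1", False, 9),
        ("s2", False, 12),
        ("s3", False, 30),
        ("s4", False, 8),
    ]
    return [
        make_vector(cid, healthy, nse=nse, orientation=50.0 + 10 * i)
        for i, (cid, healthy, nse) in enumerate(rows)
    ]


@pytest.fixture
def noisy_dataset():
    """Eight couples with one mislabeled fly: no perfect single interval."""
    rows = [
        ("h1", True, 2, 1),
        ("h2", True, 4, 3),
        ("h3", True, 5, 3),
        ("h4", True, 11, 0),  # healthy outlier in the sick nse range
        ("s1", False, 9, 3),
        ("s2", False, 12, 1),
        ("s3", False, 3, 0),  # sick outlier in the healthy nse range
        ("s4", False, 14, 2),
    ]
    return [
        make_vector(cid, healthy, nse=nse, atc=atc, vibration=20.0 + 5 * i)
        for i, (cid, healthy, nse, atc) in enumerate(rows)
    ]
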